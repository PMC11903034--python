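"""Cell-cycle occupancy QTL mapping.

Membership of each cell-cycle stage is treated as a separate binary
trait and scanned genome-wide with logistic regression on the
standardized genotype plus ln(total UMIs) as a technical covariate.
LOD = (l_full - l_null) / ln 10.  Genome-wide significance uses a
permutation family-wise error rate threshold: segregant identities are
permuted against genotypes within batch and the 95th percentile of the
per-permutation maximum LOD is the 5% FWER cutoff.  Chromosome III is
excluded by default because its markers are linked to the mating locus,
which is strongly distorted in MATa-sorted experiments.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd

from .eqtl_scan import permute_genotype_rows

logger = logging.getLogger("onepot")

_ETA_CLIP = 30.0
EXCLUDED_CHROMS = ("chrIII",)


def _logistic_ll(y: np.ndarray, eta: np.ndarray) -> np.ndarray:
    eta = np.clip(eta, -_ETA_CLIP, _ETA_CLIP)
    return y * eta - np.log1p(np.exp(eta))


def _fit_logistic(y: np.ndarray, X: np.ndarray, tol: float = 1e-8,
                  max_iter: int = 100) -> tuple[np.ndarray, float]:
    beta = np.zeros(X.shape[1])
    p_bar = np.clip(y.mean(), 1e-6, 1 - 1e-6)
    beta[0] = np.log(p_bar / (1 - p_bar))
    ll_old = -np.inf
    for _ in range(max_iter):
        eta = np.clip(X @ beta, -_ETA_CLIP, _ETA_CLIP)
        p = 1.0 / (1.0 + np.exp(-eta))
        w = np.maximum(p * (1 - p), 1e-10)
        z = eta + (y - p) / w
        sw = np.sqrt(w)
        beta, *_ = np.linalg.lstsq(X * sw[:, None], z * sw, rcond=None)
        ll = _logistic_ll(y, X @ beta).sum()
        if abs(ll - ll_old) < tol:
            break
        ll_old = ll
    return beta, float(ll)


def _firth_logistic(y: np.ndarray, X: np.ndarray, tol: float = 1e-6,
                    max_iter: int = 100) -> tuple[np.ndarray, float]:
    """Jeffreys-prior penalized logistic fit for separated data."""
    beta = np.zeros(X.shape[1])
    for _ in range(max_iter):
        eta = np.clip(X @ beta, -_ETA_CLIP, _ETA_CLIP)
        p = 1.0 / (1.0 + np.exp(-eta))
        w = np.maximum(p * (1 - p), 1e-10)
        XW = X * w[:, None]
        info = X.T @ XW
        cov = np.linalg.pinv(info)
        h = np.einsum("ij,jk,ik->i", X, cov, XW)
        score = X.T @ (y - p + h * (0.5 - p))
        step = cov @ score
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            break
    eta = np.clip(X @ beta, -_ETA_CLIP, _ETA_CLIP)
    p = 1.0 / (1.0 + np.exp(-eta))
    w = np.maximum(p * (1 - p), 1e-10)
    sign, logdet = np.linalg.slogdet(X.T @ (X * w[:, None]))
    ll = _logistic_ll(y, eta).sum() + 0.5 * logdet
    return beta, float(ll)


def _scan_logistic(y: np.ndarray, S: np.ndarray, G: np.ndarray,
                   tol: float = 1e-8, max_iter: int = 50
                   ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised per-marker logistic LR scan: [S, g] vs S.

    Returns (lr, beta_g, separated flag).  Markers showing quasi-complete
    separation are refit with a Firth penalty and flagged.
    """
    n, p = S.shape
    m = G.shape[1]
    beta0, ll0 = _fit_logistic(y, S)
    beta = np.tile(np.append(beta0, 0.0), (m, 1))
    ll = np.full(m, -np.inf)
    for _ in range(max_iter):
        eta = np.clip(S @ beta[:, :p].T + G * beta[:, p][None, :],
                      -_ETA_CLIP, _ETA_CLIP)
        prob = 1.0 / (1.0 + np.exp(-eta))
        w = np.maximum(prob * (1 - prob), 1e-10)
        z = eta + (y[:, None] - prob) / w
        wg = w * G
        SWS = np.einsum("nm,np,nq->mpq", w, S, S, optimize=True)
        SWg = np.einsum("nm,np->mp", wg, S)
        gWg = np.einsum("nm,nm->m", wg, G)
        SWz = np.einsum("nm,np->mp", w * z, S)
        gWz = np.einsum("nm,nm->m", wg, z)
        A = np.empty((m, p + 1, p + 1))
        A[:, :p, :p] = SWS
        A[:, :p, p] = SWg
        A[:, p, :p] = SWg
        A[:, p, p] = gWg
        rhs = np.concatenate([SWz, gWz[:, None]], axis=1)
        beta = np.linalg.solve(A, rhs[..., None])[..., 0]
        eta = np.clip(S @ beta[:, :p].T + G * beta[:, p][None, :],
                      -_ETA_CLIP, _ETA_CLIP)
        ll_new = _logistic_ll(y[:, None], eta).sum(axis=0)
        done = np.abs(ll_new - ll) < tol
        ll = ll_new
        if done.all():
            break
    separated = ~np.isfinite(ll) | (np.abs(beta[:, p]) > 15.0)
    for j in np.flatnonzero(separated):
        Xj = np.column_stack([S, G[:, j]])
        bj, llj = _firth_logistic(y, Xj)
        beta[j] = bj
        ll[j] = llj
        logger.info("marker %d: quasi-complete separation; Firth refit", j)
    lr = 2.0 * (ll - ll0)
    return lr, beta[:, p], separated


@dataclasses.dataclass
class OccupancyScan:
    """Per-stage occupancy scan results over the retained markers."""

    stages: list[str]
    markers: pd.DataFrame          # chrom, pos of retained (non-chrIII) markers
    marker_idx: np.ndarray         # indices into the input marker set
    lod: dict[str, np.ndarray]
    effect: dict[str, np.ndarray]
    separated: dict[str, np.ndarray]


def occupancy_scan(stage_labels: np.ndarray, X: np.ndarray,
                   markers: pd.DataFrame, ln_umis: np.ndarray,
                   exclude_chroms: tuple[str, ...] = EXCLUDED_CHROMS
                   ) -> OccupancyScan:
    """Logistic genome scan of stage membership for every stage.

    ``X`` is the standardized cell x marker genotype matrix; markers on
    ``exclude_chroms`` are removed from the scan entirely.
    """
    stage_labels = np.asarray(stage_labels, dtype=object)
    stages = [s for s in pd.unique(stage_labels) if s is not None]
    if len(stages) < 2:
        raise ValueError("need >= 2 stages for occupancy mapping")
    keep = ~markers["chrom"].isin(exclude_chroms).to_numpy()
    marker_idx = np.flatnonzero(keep)
    Xk = X[:, marker_idx]
    S = np.column_stack([np.ones(len(stage_labels)), ln_umis])
    ok = np.array([s is not None for s in stage_labels])
    lod, effect, sep = {}, {}, {}
    for s in stages:
        y = (stage_labels[ok] == s).astype(float)
        lr, bg, flag = _scan_logistic(y, S[ok], Xk[ok])
        lod[s] = np.maximum(lr, 0.0) / (2.0 * np.log(10.0))
        effect[s] = bg
        sep[s] = flag
    return OccupancyScan(stages=stages,
                         markers=markers.iloc[marker_idx].reset_index(drop=True),
                         marker_idx=marker_idx, lod=lod, effect=effect,
                         separated=sep)


def fwer_threshold(stage_labels: np.ndarray, X: np.ndarray,
                   markers: pd.DataFrame, ln_umis: np.ndarray,
                   seg_of_cell: np.ndarray, batch: np.ndarray,
                   n_perm: int = 1000, alpha: float = 0.05, seed: int = 0,
                   exclude_chroms: tuple[str, ...] = EXCLUDED_CHROMS
                   ) -> tuple[dict[str, float], dict[str, np.ndarray]]:
    """Permutation FWER thresholds: (1-alpha) quantile of max-LOD nulls.

    Segregant identities are permuted against genotypes within batch
    (cells of one segregant move together); the genome-wide maximum LOD
    per permutation per stage forms the null.  Returns per-stage
    thresholds and the raw permutation maxima.
    """
    if n_perm < 100:
        raise ValueError("need n_perm >= 100 for a stable FWER threshold")
    rng = np.random.default_rng(seed)
    stage_labels = np.asarray(stage_labels, dtype=object)
    stages = [s for s in pd.unique(stage_labels) if s is not None]
    keep = ~markers["chrom"].isin(exclude_chroms).to_numpy()
    Xk = X[:, keep]
    S = np.column_stack([np.ones(len(stage_labels)), ln_umis])
    ok = np.array([s is not None for s in stage_labels])
    maxima: dict[str, list[float]] = {s: [] for s in stages}
    for _ in range(n_perm):
        Xp = permute_genotype_rows(Xk, seg_of_cell, batch, rng)
        for s in stages:
            y = (stage_labels[ok] == s).astype(float)
            lr, _, _ = _scan_logistic(y, S[ok], Xp[ok])
            maxima[s].append(float(np.max(lr) / (2.0 * np.log(10.0))))
    thresholds = {s: float(np.quantile(maxima[s], 1.0 - alpha))
                  for s in stages}
    return thresholds, {s: np.array(v) for s, v in maxima.items()}


def call_occupancy_qtls(scan: OccupancyScan,
                        thresholds: dict[str, float]) -> pd.DataFrame:
    """Peak markers per stage per chromosome exceeding the FWER threshold."""
    rows = []
    chroms = scan.markers["chrom"].to_numpy()
    for s in scan.stages:
        thr = thresholds[s]
        for chrom in dict.fromkeys(chroms):
            idx = np.flatnonzero(chroms == chrom)
            vals = scan.lod[s][idx]
            k = int(np.argmax(vals))
            rows.append({"stage": s, "chrom": chrom,
                         "marker": int(scan.marker_idx[idx[k]]),
                         "pos": int(scan.markers["pos"].to_numpy()[idx[k]]),
                         "lod": float(vals[k]),
                         "effect": float(scan.effect[s][idx[k]]),
                         "threshold": thr,
                         "significant": bool(vals[k] > thr)})
    return pd.DataFrame(rows)
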