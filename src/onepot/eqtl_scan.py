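"""Negative-binomial GLM eQTL scans with LOD scores and permutation FDR.

Per-transcript UMI counts are modelled as NB with log-linear mean

    mu = exp(b_i + Xt b_t + Xb b_b + Xg b_g),    Var(Y) = mu + mu^2 / theta

where Xt is ln(total UMIs per cell) (compositional control), Xb are
batch indicators and Xg the standardized genotype probability at a
marker.  theta is estimated once per transcript (joint fit with the
closest marker) and held fixed in all subsequent scans for that
transcript.  Likelihood-ratio statistics become LOD scores by dividing
by 2 ln 10; significance comes from permutations of segregant identity
within batch.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .io_formats import ExpressionMatrix

logger = logging.getLogger("onepot")

TWO_LN10 = 2.0 * np.log(10.0)
THETA_BOUNDS = (1e-3, 1e5)
_ETA_CLIP = 30.0


# ---------------------------------------------------------------------------
# NB GLM fitting


def nb_loglik(y: np.ndarray, mu: np.ndarray, theta: float) -> float:
    """Negative binomial log-likelihood (size theta, mean mu)."""
    y = np.asarray(y, float)
    return float(np.sum(
        special.gammaln(y + theta) - special.gammaln(theta)
        - special.gammaln(y + 1.0) + theta * np.log(theta)
        + y * np.log(mu) - (y + theta) * np.log(mu + theta)))


@dataclasses.dataclass
class NBFit:
    beta: np.ndarray
    se: np.ndarray
    loglik: float
    theta: float
    converged: bool
    n_iter: int
    theta_at_bound: bool = False


def _irls(y: np.ndarray, X: np.ndarray, theta: float,
          beta0: np.ndarray | None = None, tol: float = 1e-8,
          max_iter: int = 100) -> tuple[np.ndarray, float, bool, int]:
    """IRLS for NB regression with log link at fixed theta."""
    n, p = X.shape
    if beta0 is None:
        mu0 = np.full(n, max(y.mean(), 1e-8))
        eta = np.log(mu0) * np.ones(n)
        beta = np.zeros(p)
        beta[0] = np.log(max(y.mean(), 1e-8))
        eta = X @ beta
    else:
        beta = beta0.copy()
        eta = X @ beta
    ll_old = -np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        mu = np.exp(np.clip(eta, -_ETA_CLIP, _ETA_CLIP))
        w = mu / (1.0 + mu / theta)
        z = eta + (y - mu) / mu
        sw = np.sqrt(w)
        beta, *_ = np.linalg.lstsq(X * sw[:, None], z * sw, rcond=None)
        eta = X @ beta
        mu = np.exp(np.clip(eta, -_ETA_CLIP, _ETA_CLIP))
        ll = nb_loglik(y, mu, theta)
        if abs(ll - ll_old) < tol:
            converged = True
            break
        ll_old = ll
    return beta, ll, converged, it


def _observed_info_se(y: np.ndarray, X: np.ndarray, beta: np.ndarray,
                      theta: float) -> np.ndarray:
    mu = np.exp(np.clip(X @ beta, -_ETA_CLIP, _ETA_CLIP))
    w = theta * mu * (y + theta) / (mu + theta) ** 2
    info = X.T @ (X * w[:, None])
    try:
        cov = np.linalg.inv(info)
        return np.sqrt(np.maximum(np.diag(cov), 0.0))
    except np.linalg.LinAlgError:
        return np.full(len(beta), np.nan)


def fit_nb_glm(y: np.ndarray, X: np.ndarray, theta: float | None = None,
               tol: float = 1e-8, max_iter: int = 100) -> NBFit:
    """Fit an NB regression; estimates theta by profile likelihood if None.

    With theta supplied, IRLS maximises the likelihood over beta alone.
    Otherwise IRLS for beta alternates with a bounded 1-D maximisation
    of the profile likelihood over theta in [1e-3, 1e5].  Standard
    errors come from the observed information at the optimum.
    """
    y = np.asarray(y, float)
    X = np.asarray(X, float)
    if X.shape[0] <= X.shape[1]:
        raise ValueError("need more observations than coefficients")
    if theta is not None:
        beta, ll, conv, it = _irls(y, X, theta, tol=tol, max_iter=max_iter)
        se = _observed_info_se(y, X, beta, theta)
        return NBFit(beta=beta, se=se, loglik=ll, theta=theta,
                     converged=conv, n_iter=it)

    state: dict = {}

    def profile_negll(log_theta: float) -> float:
        th = np.exp(log_theta)
        beta, ll, conv, _ = _irls(y, X, th, beta0=state.get("beta"),
                                  tol=tol, max_iter=max_iter)
        state["beta"] = beta
        return -ll

    res = optimize.minimize_scalar(
        profile_negll, bounds=np.log(THETA_BOUNDS), method="bounded",
        options={"xatol": 1e-6})
    # the profile flattens as theta -> inf for Poisson-like data, where
    # the bounded search can stall at an interior point; check the bounds
    candidates = [float(res.x), np.log(THETA_BOUNDS[1]), np.log(THETA_BOUNDS[0])]
    best = min(candidates, key=profile_negll)
    theta_hat = float(np.exp(best))
    beta, ll, conv, it = _irls(y, X, theta_hat, beta0=state.get("beta"),
                               tol=tol, max_iter=max_iter)
    se = _observed_info_se(y, X, beta, theta_hat)
    at_bound = (theta_hat <= THETA_BOUNDS[0] * 1.01
                or theta_hat >= THETA_BOUNDS[1] * 0.99)
    if at_bound:
        logger.warning("theta estimate %.3g at search bound", theta_hat)
    return NBFit(beta=beta, se=se, loglik=ll, theta=theta_hat,
                 converged=conv, n_iter=it, theta_at_bound=at_bound)


def estimate_theta(y: np.ndarray, X_local: np.ndarray) -> float:
    """Per-transcript theta from the joint fit with the closest marker.

    The estimate is reused (fixed) in every genome scan for that
    transcript; unmodelled effects inflate it conservatively.
    """
    return fit_nb_glm(y, X_local, theta=None).theta


def lod_from_lr(lr) -> np.ndarray | float:
    """LOD = likelihood-ratio statistic / (2 ln 10); negatives clamp to 0."""
    lr = np.asarray(lr, float)
    if np.any(lr < 0):
        logger.warning("negative likelihood-ratio statistic clamped to 0")
    out = np.maximum(lr, 0.0) / TWO_LN10
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# marker / transcript preparation


def standardize_genotypes(G: np.ndarray) -> np.ndarray:
    """Scale each marker column to mean 0, SD 1 (population SD)."""
    G = np.asarray(G, float)
    mean = G.mean(axis=0)
    sd = G.std(axis=0)
    sd = np.where(sd == 0, 1.0, sd)
    return (G - mean) / sd


def prune_markers(G: np.ndarray, markers: pd.DataFrame,
                  r_max: float = 0.999) -> np.ndarray:
    """Greedy per-chromosome LD pruning: drop markers correlated > r_max
    with the last retained marker; the first marker is always kept.

    Returns the retained marker indices.
    """
    if G.shape[1] < 2:
        return np.arange(G.shape[1])
    keep: list[int] = []
    for chrom in dict.fromkeys(markers["chrom"]):
        idx = np.flatnonzero((markers["chrom"] == chrom).to_numpy())
        last = idx[0]
        keep.append(last)
        for j in idx[1:]:
            a, b = G[:, last], G[:, j]
            sa, sb = a.std(), b.std()
            r = 0.0 if sa == 0 or sb == 0 else float(
                np.corrcoef(a, b)[0, 1])
            if abs(r) <= r_max:
                keep.append(j)
                last = j
    return np.array(sorted(keep))


def filter_transcripts(expr: ExpressionMatrix, min_cells: int = 128) -> np.ndarray:
    """Indices of transcripts detected (count >= 1) in >= min_cells cells."""
    detected = np.asarray((expr.counts > 0).sum(axis=0)).ravel()
    keep = np.flatnonzero(detected >= min_cells)
    if keep.size == 0:
        raise ValueError("no transcript passes the detection filter")
    return keep


def closest_marker(markers: pd.DataFrame, chrom: str, pos: int) -> int | None:
    """Index of the marker nearest to (chrom, pos); None if chromosome absent."""
    on = np.flatnonzero((markers["chrom"] == chrom).to_numpy())
    if on.size == 0:
        return None
    d = np.abs(markers["pos"].to_numpy()[on] - pos)
    return int(on[np.argmin(d)])


def base_design(expr: ExpressionMatrix) -> np.ndarray:
    """Covariate matrix: intercept, ln(total UMIs), batch indicators."""
    n = expr.n_cells
    ln_umis = np.log(np.maximum(expr.cell_meta["total_umis"].to_numpy(float), 1.0))
    cols = [np.ones(n), ln_umis]
    batches = pd.Categorical(expr.cell_meta["batch"])
    for level in batches.categories[1:]:
        cols.append((batches == level).astype(float))
    return np.column_stack(cols)


# ---------------------------------------------------------------------------
# vectorised LR scan across markers (shared fixed theta)


def _scan_lr(y: np.ndarray, S: np.ndarray, G: np.ndarray, theta: float,
             tol: float = 1e-6, max_iter: int = 50
             ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """LR statistic of [S, g] vs S for every marker column g of G.

    All marker models share the fixed theta; IRLS runs for all markers
    simultaneously.  Returns (lr, beta_g, se_g) arrays over markers.
    """
    n, p = S.shape
    m = G.shape[1]
    beta0, ll0, _, _ = _irls(y, S, theta)
    # batched IRLS: coefficient vector per marker = [shared p, marker 1]
    beta = np.tile(np.append(beta0, 0.0), (m, 1))  # m x (p+1)
    ll = np.full(m, -np.inf)
    active = np.ones(m, bool)
    for _ in range(max_iter):
        eta = S @ beta[:, :p].T + G * beta[:, p][None, :]   # n x m
        mu = np.exp(np.clip(eta, -_ETA_CLIP, _ETA_CLIP))
        w = mu / (1.0 + mu / theta)
        z = eta + (y[:, None] - mu) / mu
        wg = w * G
        # normal equations per marker
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
        eta = S @ beta[:, :p].T + G * beta[:, p][None, :]
        mu = np.exp(np.clip(eta, -_ETA_CLIP, _ETA_CLIP))
        ll_new = (special.gammaln(y[:, None] + theta).sum()
                  - n * special.gammaln(theta) - special.gammaln(y + 1.0).sum()
                  + n * theta * np.log(theta)
                  + (y[:, None] * np.log(mu)).sum(axis=0)
                  - ((y[:, None] + theta) * np.log(mu + theta)).sum(axis=0))
        done = np.abs(ll_new - ll) < tol
        ll = ll_new
        if done.all():
            break
    # observed-information SE for the marker coefficient
    w_obs = theta * mu * (y[:, None] + theta) / (mu + theta) ** 2
    wg = w_obs * G
    SWS = np.einsum("nm,np,nq->mpq", w_obs, S, S, optimize=True)
    SWg = np.einsum("nm,np->mp", wg, S)
    gWg = np.einsum("nm,nm->m", wg, G)
    A[:, :p, :p] = SWS
    A[:, :p, p] = SWg
    A[:, p, :p] = SWg
    A[:, p, p] = gWg
    try:
        cov = np.linalg.inv(A)
        se_g = np.sqrt(np.maximum(cov[:, p, p], 0.0))
    except np.linalg.LinAlgError:
        se_g = np.full(m, np.nan)
    lr = 2.0 * (ll - ll0)
    return lr, beta[:, p], se_g


# ---------------------------------------------------------------------------
# permutations


def permute_genotype_rows(X: np.ndarray, seg_of_cell: np.ndarray,
                          batch: np.ndarray,
                          rng: np.random.Generator) -> np.ndarray:
    """Permute segregant identities against genotypes within each batch.

    All cells of one segregant (within a batch) move together: each
    segregant group's genotype rows are replaced by those of another
    segregant group from the same batch.
    """
    X = np.asarray(X)
    out = X.copy()
    for b in np.unique(batch):
        cells_b = np.flatnonzero(batch == b)
        segs = seg_of_cell[cells_b]
        uniq = np.unique(segs)
        perm = rng.permutation(len(uniq))
        # representative genotype row per segregant group
        rep = {s: cells_b[segs == s][0] for s in uniq}
        for i, s in enumerate(uniq):
            src = rep[uniq[perm[i]]]
            out[cells_b[segs == s]] = X[src]
    return out


# ---------------------------------------------------------------------------
# scans


@dataclasses.dataclass
class ScanResult:
    """Genome-scan output: LOD and effect matrices over transcripts x markers."""

    transcripts: pd.DataFrame
    markers: pd.DataFrame
    lod: np.ndarray
    beta: np.ndarray
    se: np.ndarray
    theta: np.ndarray
    perm_max: np.ndarray | None = None  # n_perm x transcripts x chromosomes
    chrom_of_marker: np.ndarray | None = None


def local_scan(expr: ExpressionMatrix, X: np.ndarray, markers: pd.DataFrame,
               transcript_idx: np.ndarray | None = None,
               seg_of_cell: np.ndarray | None = None,
               n_perm: int = 5, seed: int = 0,
               thetas: dict[int, float] | None = None) -> pd.DataFrame:
    """Local eQTL test at the closest pruned marker for each transcript.

    ``X`` is the standardized cell x marker genotype matrix restricted
    to the pruned marker set described by ``markers`` (chrom, pos rows).
    Returns one row per testable transcript with the LR statistic, LOD,
    effect, SE, theta and permutation-FDR-adjusted p-value.
    """
    rng = np.random.default_rng(seed)
    if transcript_idx is None:
        transcript_idx = np.arange(expr.n_transcripts)
    S = base_design(expr)
    batch = expr.cell_meta["batch"].to_numpy()
    if seg_of_cell is None:
        seg_of_cell = (expr.cell_meta["segregant"].to_numpy()
                       if "segregant" in expr.cell_meta else
                       np.arange(expr.n_cells))
    Y = expr.counts.tocsc()

    perms = [permute_genotype_rows(X, seg_of_cell, batch, rng)
             for _ in range(n_perm)]

    rows = []
    obs_lod = []
    perm_lod = [[] for _ in range(n_perm)]
    for t in transcript_idx:
        tr = expr.transcripts.iloc[t]
        cm = closest_marker(markers, tr["chrom"], tr["pos"])
        if cm is None:
            logger.info("transcript %s: no marker on %s; skipped",
                        tr["name"], tr["chrom"])
            continue
        y = np.asarray(Y[:, t].todense()).ravel().astype(float)
        g = X[:, [cm]]
        Xfull = np.column_stack([S, g])
        theta = (thetas or {}).get(t)
        if theta is None:
            theta = estimate_theta(y, Xfull)
        lr, beta_g, se_g = _scan_lr(y, S, g, theta)
        lod = float(lod_from_lr(lr[0]))
        obs_lod.append(lod)
        for k, Xp in enumerate(perms):
            lr_p, _, _ = _scan_lr(y, S, Xp[:, [cm]], theta)
            perm_lod[k].append(float(lod_from_lr(lr_p[0])))
        rows.append({"transcript": tr["name"], "chrom": tr["chrom"],
                     "pos": tr["pos"], "marker": cm, "lr": float(lr[0]),
                     "lod": lod, "beta": float(beta_g[0]),
                     "se": float(se_g[0]), "theta": theta})
    result = pd.DataFrame(rows)
    if len(result):
        fdr = permutation_fdr(np.array(obs_lod), np.array(perm_lod))
        result["p_fdr"] = fdr.adjust(result["lod"].to_numpy())
    return result


def genome_scan(expr: ExpressionMatrix, X: np.ndarray, markers: pd.DataFrame,
                transcript_idx: np.ndarray, thetas: dict[int, float],
                cell_subset: np.ndarray | None = None) -> ScanResult:
    """LOD matrix over transcripts x markers at fixed per-transcript theta.

    ``cell_subset`` restricts to cells of one cell-cycle stage; theta
    must have been estimated on all cells beforehand.
    """
    if cell_subset is not None:
        expr_s = expr.subset_cells(cell_subset)
        Xs = X[cell_subset]
    else:
        expr_s, Xs = expr, X
    S = base_design(expr_s)
    Y = expr_s.counts.tocsc()
    n_t = len(transcript_idx)
    m = Xs.shape[1]
    lod = np.zeros((n_t, m))
    beta = np.zeros((n_t, m))
    se = np.zeros((n_t, m))
    th = np.zeros(n_t)
    for i, t in enumerate(transcript_idx):
        y = np.asarray(Y[:, t].todense()).ravel().astype(float)
        lr, b, s = _scan_lr(y, S, Xs, thetas[t])
        lod[i] = lod_from_lr(lr)
        beta[i], se[i] = b, s
        th[i] = thetas[t]
    return ScanResult(transcripts=expr.transcripts.iloc[transcript_idx],
                      markers=markers, lod=lod, beta=beta, se=se, theta=th,
                      chrom_of_marker=markers["chrom"].to_numpy())


# ---------------------------------------------------------------------------
# peaks, FDR, combined scans, interactions


@dataclasses.dataclass
class EqtlPeak:
    transcript: str
    transcript_chrom: str
    scan_chrom: str
    marker: int
    lod: float
    beta: float
    se: float
    ci_left: int
    ci_right: int
    p_fdr: float = np.nan
    stage: str = "all"


def find_peaks(lod_row: np.ndarray, chrom_of_marker: np.ndarray
               ) -> list[tuple[str, int, int, int]]:
    """Per-chromosome peak and 1.5-LOD-drop CI from one transcript's scan.

    Returns (chrom, peak index, ci_left index, ci_right index) tuples;
    ties break to the leftmost marker, and the CI is the contiguous run
    of markers around the peak with LOD >= peak - 1.5, clipped at the
    chromosome ends.
    """
    out = []
    for chrom in dict.fromkeys(chrom_of_marker):
        idx = np.flatnonzero(chrom_of_marker == chrom)
        vals = lod_row[idx]
        k = int(np.argmax(vals))  # argmax returns the leftmost maximum
        thr = vals[k] - 1.5
        left = k
        while left > 0 and vals[left - 1] >= thr:
            left -= 1
        right = k
        while right < len(vals) - 1 and vals[right + 1] >= thr:
            right += 1
        out.append((chrom, int(idx[k]), int(idx[left]), int(idx[right])))
    return out


@dataclasses.dataclass
class FdrMap:
    """Threshold -> FDR mapping from a permutation scheme."""

    thresholds: np.ndarray
    fdr: np.ndarray

    def adjust(self, lods: np.ndarray) -> np.ndarray:
        lods = np.asarray(lods, float)
        lo, hi = self.thresholds[0], self.thresholds[-1]
        out = np.interp(lods, self.thresholds, self.fdr)
        out[lods < lo] = 1.0
        out[lods > hi] = self.fdr[-1]
        return out


def permutation_fdr(observed_max: np.ndarray, perm_max: np.ndarray,
                    step: float = 0.01, t_min: float = 0.1) -> FdrMap:
    """FDR(t) = E_perm[#{perm max > t}] / #{observed max > t}, capped at 1.

    Thresholds run from ``t_min`` to ``t_min`` + max observed LOD in
    steps of ``step``; the curve is made monotone non-increasing in t.
    A threshold with zero observed exceedances maps to FDR 1 before
    monotonisation.
    """
    observed_max = np.asarray(observed_max, float)
    perm_max = np.asarray(perm_max, float)
    if perm_max.ndim == 1:
        perm_max = perm_max[None, :]
    t_max = t_min + (observed_max.max() if observed_max.size else 1.0)
    thresholds = np.arange(t_min, t_max + step / 2, step)
    obs_counts = (observed_max[None, :] > thresholds[:, None]).sum(axis=1)
    exp_counts = (perm_max[None, :, :] > thresholds[:, None, None]
                  ).sum(axis=2).mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        raw = np.where(obs_counts > 0, exp_counts / np.maximum(obs_counts, 1), 1.0)
    raw = np.minimum(raw, 1.0)
    mono = np.minimum.accumulate(raw)  # non-increasing in t
    return FdrMap(thresholds=thresholds, fdr=mono)


def call_peaks(scan: ScanResult, perm_scans: list[ScanResult],
               stage: str = "all") -> pd.DataFrame:
    """Peaks per (transcript, chromosome) with permutation FDR p-values.

    Observed and permuted maxima are collected per transcript per
    scanned chromosome, pooled into one FDR map, and each peak's
    adjusted p interpolated at its LOD.
    """
    chroms = list(dict.fromkeys(scan.chrom_of_marker))
    names = scan.transcripts["name"].to_numpy()
    t_chrom = scan.transcripts["chrom"].to_numpy()
    obs_max, peaks = [], []
    for i in range(len(names)):
        for chrom, pk, lo, hi in find_peaks(scan.lod[i], scan.chrom_of_marker):
            obs_max.append(scan.lod[i, pk])
            peaks.append(EqtlPeak(
                transcript=names[i], transcript_chrom=t_chrom[i],
                scan_chrom=chrom, marker=pk, lod=float(scan.lod[i, pk]),
                beta=float(scan.beta[i, pk]), se=float(scan.se[i, pk]),
                ci_left=lo, ci_right=hi, stage=stage))
    perm_max = []
    for ps in perm_scans:
        pm = []
        for i in range(len(names)):
            for chrom in chroms:
                idx = np.flatnonzero(ps.chrom_of_marker == chrom)
                pm.append(ps.lod[i, idx].max())
        perm_max.append(pm)
    fdr = permutation_fdr(np.array(obs_max), np.array(perm_max))
    adj = fdr.adjust(np.array(obs_max))
    rows = []
    for p, a in zip(peaks, adj):
        p.p_fdr = float(a)
        rows.append(dataclasses.asdict(p))
    df = pd.DataFrame(rows)
    df["distant"] = df["transcript_chrom"] != df["scan_chrom"]
    df["peak_pos"] = scan.markers["pos"].to_numpy()[df["marker"]]
    df["ci_left_pos"] = scan.markers["pos"].to_numpy()[df["ci_left"]]
    df["ci_right_pos"] = scan.markers["pos"].to_numpy()[df["ci_right"]]
    return df


def combined_stage_scan(stage_scans: dict[str, ScanResult],
                        stage_perm_scans: dict[str, list[ScanResult]]
                        ) -> tuple[ScanResult, list[ScanResult]]:
    """Sum LOD matrices (observed and permuted) across cell-cycle stages.

    All stages must share the marker grid and transcript set; the summed
    matrices feed the usual peak calling and permutation FDR.
    """
    stages = list(stage_scans)
    first = stage_scans[stages[0]]
    for s in stages[1:]:
        if not first.markers[["chrom", "pos"]].equals(
                stage_scans[s].markers[["chrom", "pos"]]):
            raise ValueError("stage scans use different marker grids")
    lod = sum(stage_scans[s].lod for s in stages)
    combined = ScanResult(transcripts=first.transcripts, markers=first.markers,
                          lod=lod, beta=first.beta, se=first.se,
                          theta=first.theta,
                          chrom_of_marker=first.chrom_of_marker)
    n_perm = len(stage_perm_scans[stages[0]])
    perm_combined = []
    for k in range(n_perm):
        plod = sum(stage_perm_scans[s][k].lod for s in stages)
        perm_combined.append(ScanResult(
            transcripts=first.transcripts, markers=first.markers, lod=plod,
            beta=first.beta, se=first.se, theta=first.theta,
            chrom_of_marker=first.chrom_of_marker))
    return combined, perm_combined


def interaction_test(beta_i: np.ndarray, se_i: np.ndarray,
                     beta_j: np.ndarray, se_j: np.ndarray) -> pd.DataFrame:
    """Contrast eQTL effects between two cell-cycle stages.

    Z = (b_i - b_j) / sqrt(se_i^2 + se_j^2), two-sided normal p, and
    Benjamini-Hochberg q computed jointly across the supplied family.
    """
    beta_i, se_i = np.atleast_1d(beta_i).astype(float), np.atleast_1d(se_i).astype(float)
    beta_j, se_j = np.atleast_1d(beta_j).astype(float), np.atleast_1d(se_j).astype(float)
    if np.any(se_i <= 0) or np.any(se_j <= 0):
        raise ValueError("standard errors must be positive")
    z = (beta_i - beta_j) / np.sqrt(se_i ** 2 + se_j ** 2)
    p = 2.0 * stats.norm.sf(np.abs(z))
    from statsmodels.stats.multitest import multipletests
    q = multipletests(p, method="fdr_bh")[1] if len(p) else p
    return pd.DataFrame({"z": z, "p": p, "q": q})
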