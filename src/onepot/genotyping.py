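"""HMM genotype inference from sparse single-cell allelic counts.

Each haploid cell's genome is a mosaic of the two parental genomes.  At
every transcribed SNP we observe ``r`` parent-A reads out of ``D`` total;
reads err independently at rate ``e`` (default 0.005).  A two-state HMM
per chromosome (states = parental alleles, priors 0.5/0.5, binomial
emissions, transitions from the genetic map through the Haldane map
function) yields posterior genotype probabilities by forward-backward,
imputing masked or unobserved sites through the transitions.
"""

from __future__ import annotations

import dataclasses
import logging
from math import comb

import numpy as np
import pandas as pd

from ._mapfun import MAP_FUNCTIONS
from .io_formats import AlleleCountMatrix, GeneticMap

logger = logging.getLogger("onepot")


@dataclasses.dataclass
class ErrorModel:
    """Per-read sequencing error probability."""

    e: float = 0.005

    def __post_init__(self) -> None:
        if not 0.0 <= self.e < 0.5:
            raise ValueError("error rate must be in [0, 0.5)")


@dataclasses.dataclass
class GenotypePosterior:
    """Posterior P(parent-A allele) per cell x marker.

    ``markers`` carries chrom, pos and interpolated cM for every site
    (including masked ones, whose genotypes are imputed).  Hard calls
    binarize at 0.5: call A (=1) iff P(A) > 0.5, else B (=0); the tie at
    exactly 0.5 goes to B.
    """

    cells: np.ndarray
    markers: pd.DataFrame
    p_a: np.ndarray

    def __post_init__(self) -> None:
        self.p_a = np.asarray(self.p_a, float)
        if self.p_a.shape != (len(self.cells), len(self.markers)):
            raise ValueError("p_a shape must be cells x markers")
        if np.any(self.p_a < 0) or np.any(self.p_a > 1):
            raise ValueError("posterior probabilities must lie in [0, 1]")

    @property
    def hard_calls(self) -> np.ndarray:
        return binarize(self)

    @property
    def confidence(self) -> np.ndarray:
        """Per-cell mean posterior confidence, mean(max(P, 1-P))."""
        return np.maximum(self.p_a, 1.0 - self.p_a).mean(axis=1)


# ---------------------------------------------------------------------------
# site / cell QC


def filter_sites(ac: AlleleCountMatrix,
                 maf_threshold: float = 0.05) -> AlleleCountMatrix:
    """Mask sites with extremely distorted pooled allele frequencies.

    A site whose pooled minor-allele read fraction is strictly below
    ``maf_threshold`` is treated as missing for the HMM (masked); its
    position is retained so its genotype can be imputed.
    """
    totA = np.asarray(ac.countsA.sum(axis=0), float).ravel()
    totB = np.asarray(ac.countsB.sum(axis=0), float).ravel()
    depth = totA + totB
    with np.errstate(invalid="ignore"):
        frac = np.where(depth > 0, totA / np.maximum(depth, 1), 0.0)
    maf = np.minimum(frac, 1.0 - frac)
    keep = (maf >= maf_threshold) & (depth > 0)
    if not keep.any():
        raise ValueError(
            "all sites masked by the minor-allele-frequency filter; "
            "inspect the input allele counts")
    n_masked = int((~keep).sum())
    if n_masked:
        logger.info("masked %d / %d sites (pooled MAF < %g)",
                    n_masked, ac.n_sites, maf_threshold)
    return AlleleCountMatrix(cells=ac.cells, sites=ac.sites,
                             countsA=ac.countsA, countsB=ac.countsB,
                             mask=keep)


def detect_doublets(ac: AlleleCountMatrix, tau: float = 0.10) -> np.ndarray:
    """Flag cells with an excessive fraction of apparently-heterozygous sites.

    For each cell, among sites with total depth >= 2, computes the
    fraction where both parental alleles are observed; flags the cell if
    that fraction exceeds ``tau``.  Cells without any depth-2 site are
    left unflagged.
    """
    A = ac.countsA.toarray()
    B = ac.countsB.toarray()
    informative = (A + B) >= 2
    het = (A > 0) & (B > 0) & informative
    n_inf = informative.sum(axis=1)
    frac = np.divide(het.sum(axis=1), n_inf, out=np.zeros(ac.n_cells),
                     where=n_inf > 0)
    no_sites = int((n_inf == 0).sum())
    if no_sites:
        logger.info("%d cells had no sites with depth >= 2; left unflagged",
                    no_sites)
    return frac > tau


# ---------------------------------------------------------------------------
# HMM pieces


def emission_probs(r: int, D: int, e: float) -> tuple[float, float]:
    """Probability of observing r parent-A reads of D under each genotype.

    pA = C(D,r) (1-e)^r e^(D-r);  pB = C(D,r) e^r (1-e)^(D-r).
    """
    if not 0 <= r <= D:
        raise ValueError("need 0 <= r <= D")
    c = comb(D, r)
    return (c * (1 - e) ** r * e ** (D - r),
            c * e ** r * (1 - e) ** (D - r))


def transition_matrix(d_cM: float, map_function: str = "haldane") -> np.ndarray:
    """2x2 genotype transition matrix for a marker gap of ``d_cM``."""
    if d_cM < 0:
        raise ValueError("distance must be non-negative")
    r = float(MAP_FUNCTIONS[map_function](d_cM))
    return np.array([[1 - r, r], [r, 1 - r]])


def infer_genotypes(ac: AlleleCountMatrix, gmap: GeneticMap,
                    em: ErrorModel | None = None, prior: float = 0.5,
                    map_function: str = "haldane") -> GenotypePosterior:
    """Forward-backward genotype posteriors for every cell and site.

    Sites between map markers get their cM by linear interpolation.
    Masked sites contribute flat emissions and are imputed through the
    transitions.  Posteriors are independent across cells; the recursion
    uses per-step normalisation for numerical stability.
    """
    em = em or ErrorModel()
    e = em.e
    loge, log1e = np.log(e), np.log(1.0 - e)
    mapfun = MAP_FUNCTIONS[map_function]
    map_chroms = set(gmap.chromosomes)
    missing = [c for c in ac.sites["chrom"].unique() if c not in map_chroms]
    if missing:
        raise ValueError(f"chromosomes absent from genetic map: {missing}")

    n_cells = ac.n_cells
    p_a = np.empty((n_cells, ac.n_sites))
    markers = ac.sites[["chrom", "pos"]].copy()
    markers["cM"] = np.nan

    A_all = ac.countsA.toarray()
    D_all = (ac.countsA + ac.countsB).toarray()

    for chrom in ac.sites["chrom"].unique():
        idx = np.flatnonzero((ac.sites["chrom"] == chrom).to_numpy())
        cm = gmap.interpolate_cM(chrom, ac.sites["pos"].to_numpy()[idx])
        markers.loc[markers.index[idx], "cM"] = cm
        rA = A_all[:, idx]
        D = D_all[:, idx]
        usable = ac.mask[idx]
        # unnormalised emissions; the binomial coefficient is shared by
        # both states and cancels in the posterior
        with np.errstate(over="ignore"):
            eA = np.exp(rA * log1e + (D - rA) * loge)
            eB = np.exp(rA * loge + (D - rA) * log1e)
        flat = (D == 0) | ~usable[None, :]
        eA[flat] = 1.0
        eB[flat] = 1.0

        m = len(idx)
        rfrac = mapfun(np.diff(cm))
        # forward with scaling
        alpha = np.empty((n_cells, m, 2))
        a = np.column_stack([prior * eA[:, 0], (1 - prior) * eB[:, 0]])
        a /= a.sum(axis=1, keepdims=True)
        alpha[:, 0] = a
        for j in range(1, m):
            r = rfrac[j - 1]
            pred = np.column_stack([
                a[:, 0] * (1 - r) + a[:, 1] * r,
                a[:, 0] * r + a[:, 1] * (1 - r)])
            a = pred * np.column_stack([eA[:, j], eB[:, j]])
            a /= a.sum(axis=1, keepdims=True)
            alpha[:, j] = a
        # backward with scaling
        b = np.ones((n_cells, 2))
        post = np.empty((n_cells, m))
        prod = alpha[:, m - 1] * b
        post[:, m - 1] = prod[:, 0] / prod.sum(axis=1)
        for j in range(m - 2, -1, -1):
            r = rfrac[j]
            bn = b * np.column_stack([eA[:, j + 1], eB[:, j + 1]])
            b = np.column_stack([
                bn[:, 0] * (1 - r) + bn[:, 1] * r,
                bn[:, 0] * r + bn[:, 1] * (1 - r)])
            b /= b.sum(axis=1, keepdims=True)
            prod = alpha[:, j] * b
            post[:, j] = prod[:, 0] / prod.sum(axis=1)
        p_a[:, idx] = post

    return GenotypePosterior(cells=ac.cells, markers=markers, p_a=p_a)


def binarize(gp: GenotypePosterior) -> np.ndarray:
    """Hard genotype calls: 1 (parent A) iff P(A) > 0.5, else 0 (parent B)."""
    return (gp.p_a > 0.5).astype(np.int8)


# ---------------------------------------------------------------------------
# segregant matching and uniqueness


def match_segregant(posterior_row: np.ndarray,
                    reference: np.ndarray) -> tuple[int | None, float]:
    """Match one cell's posterior vector to the most correlated reference row.

    Returns (best index, Pearson correlation); ties break to the lowest
    reference index.  A constant posterior (or reference) vector has no
    defined correlation and yields (None, nan).
    """
    x = np.asarray(posterior_row, float)
    if np.std(x) == 0:
        return None, float("nan")
    ref = np.asarray(reference, float)
    xc = x - x.mean()
    rc = ref - ref.mean(axis=1, keepdims=True)
    denom = np.sqrt((xc ** 2).sum()) * np.sqrt((rc ** 2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        cors = (rc @ xc) / denom
    cors = np.where(np.isfinite(cors), cors, -np.inf)
    if not np.isfinite(cors).any():
        return None, float("nan")
    best = int(np.argmax(cors))
    return best, float(cors[best])


def match_segregants(gp: GenotypePosterior,
                     reference: np.ndarray) -> pd.DataFrame:
    """Vectorised ``match_segregant`` over all cells."""
    rows = [match_segregant(gp.p_a[i], reference) for i in range(len(gp.cells))]
    return pd.DataFrame(rows, columns=["segregant", "correlation"])


def uniqueness_filter(hard_calls: np.ndarray, total_umis: np.ndarray,
                      dup_tolerance: int = 0,
                      trigger_fraction: float = 0.10) -> np.ndarray:
    """Retain unique genotype vectors when duplication is widespread.

    Cells whose genotype vectors are within ``dup_tolerance`` Hamming
    mismatches of another cell's form duplicate groups.  If the fraction
    of cells in such groups exceeds ``trigger_fraction``, only the
    highest-UMI cell of each group is kept; otherwise all cells pass.
    Returns a boolean retained mask.
    """
    hc = np.asarray(hard_calls)
    umis = np.asarray(total_umis)
    n = hc.shape[0]
    if dup_tolerance == 0:
        _, group, counts = np.unique(hc, axis=0, return_inverse=True,
                                     return_counts=True)
    else:
        group = np.full(n, -1)
        gid = 0
        for i in range(n):
            if group[i] >= 0:
                continue
            group[i] = gid
            dist = (hc[i + 1:] != hc[i]).sum(axis=1)
            near = np.flatnonzero(dist <= dup_tolerance) + i + 1
            group[near[group[near] < 0]] = gid
            gid += 1
        counts = np.bincount(group)
    dup_fraction = (counts[group] > 1).mean()
    if dup_fraction <= trigger_fraction:
        return np.ones(n, bool)
    retained = np.zeros(n, bool)
    for g in np.unique(group):
        members = np.flatnonzero(group == g)
        retained[members[np.argmax(umis[members])]] = True
    logger.info("uniqueness filter: %.1f%% duplicated cells; kept %d / %d",
                100 * dup_fraction, int(retained.sum()), n)
    return retained
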