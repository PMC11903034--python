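"""Cell-cycle stage assignment and stage-dependent expression tests.

Stages are assigned deterministically from marker-gene expression:
counts are normalised to log1p counts-per-10k, each marker gene is
z-scored across cells, a stage's score is the mean z of its markers,
and a cell takes the argmax stage (ties break in the fixed stage order
M/G1 -> G2/M).  Haploids use five stages; diploids four (MFA1, the G1
marker, is not expressed in diploids).
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd
from scipy import stats

from . import eqtl_scan
from .io_formats import ExpressionMatrix
from .simdata import DIPLOID_STAGES, HAPLOID_STAGES

logger = logging.getLogger("onepot")

HAPLOID_MARKERS: dict[str, list[str]] = {
    "M/G1": ["PIR1", "EGT2", "ASH1", "DSE1", "DSE2", "CTS1"],
    "G1": ["MFA1"],
    "G1/S": ["CSI1", "TOS4", "POL30", "PRY2", "AXL2", "CLN2"],
    "S": ["HTB1", "HHF2"],
    "G2/M": ["HOF1", "PHO3", "MMR1", "CLB2", "WSC4", "CDC5", "CHS2"],
}


@dataclasses.dataclass
class MarkerPanel:
    """Stage -> marker gene lists; no gene may serve two stages."""

    stages: dict[str, list[str]]

    def __post_init__(self) -> None:
        seen: dict[str, str] = {}
        for stage, genes in self.stages.items():
            for g in genes:
                if g in seen:
                    raise ValueError(f"gene {g} assigned to both "
                                     f"{seen[g]} and {stage}")
                seen[g] = stage

    @classmethod
    def haploid(cls) -> "MarkerPanel":
        return cls({s: list(HAPLOID_MARKERS[s]) for s in HAPLOID_STAGES})

    @classmethod
    def diploid(cls) -> "MarkerPanel":
        return cls({s: list(HAPLOID_MARKERS[s]) for s in DIPLOID_STAGES})

    @property
    def stage_order(self) -> list[str]:
        return list(self.stages)


@dataclasses.dataclass
class StageAssignment:
    cells: np.ndarray
    stage: np.ndarray            # object array; None for unassignable cells
    scores: pd.DataFrame         # per-cell per-stage mean marker z-score

    @property
    def assigned(self) -> np.ndarray:
        return np.array([s is not None for s in self.stage])


def assign_stage(expr: ExpressionMatrix, panel: MarkerPanel) -> StageAssignment:
    """Score-based stage assignment from the marker panel.

    Marker genes missing from the expression matrix are dropped with a
    warning; a stage losing all its markers is an error.  Cells with
    zero total counts get no label and are excluded downstream.
    """
    names = expr.transcripts["name"].to_numpy()
    name_to_idx = {n: i for i, n in enumerate(names)}
    total = expr.cell_meta["total_umis"].to_numpy(float)
    ok = total > 0
    # log1p counts-per-10k, marker genes only
    stage_scores = {}
    for stage, genes in panel.stages.items():
        idx = [name_to_idx[g] for g in genes if g in name_to_idx]
        dropped = [g for g in genes if g not in name_to_idx]
        if dropped:
            logger.warning("stage %s: marker genes %s absent; dropped",
                           stage, dropped)
        if not idx:
            raise ValueError(f"stage {stage}: no marker genes resolvable")
        sub = np.asarray(expr.counts[:, idx].todense(), float)
        cp10k = np.zeros_like(sub)
        cp10k[ok] = np.log1p(sub[ok] / total[ok, None] * 1e4)
        mean = cp10k[ok].mean(axis=0)
        sd = cp10k[ok].std(axis=0)
        sd = np.where(sd == 0, 1.0, sd)
        z = (cp10k - mean) / sd
        stage_scores[stage] = z.mean(axis=1)
    scores = pd.DataFrame(stage_scores)
    order = panel.stage_order
    mat = scores[order].to_numpy()
    best = np.argmax(mat, axis=1)  # argmax -> first (earliest-stage) on ties
    labels = np.array([order[b] for b in best], dtype=object)
    labels[~ok] = None
    if (~ok).any():
        logger.info("%d cells with zero counts left unassigned", int((~ok).sum()))
    return StageAssignment(cells=expr.cells, stage=labels, scores=scores)


def stage_variation_test(expr: ExpressionMatrix, stages: np.ndarray,
                         transcript_idx: np.ndarray | None = None
                         ) -> pd.DataFrame:
    """Likelihood-ratio test per gene for expression varying with stage.

    Full model: NB regression on intercept, ln(UMIs), batch and stage
    indicators; reduced model drops the stage terms.  theta is estimated
    under the full model and reused in the reduced fit.  LRT df is
    (#stages - 1); q-values are Benjamini-Hochberg across genes.
    """
    stages = np.asarray(stages, dtype=object)
    present = [s for s in pd.unique(stages) if s is not None]
    if len(present) < 2:
        raise ValueError("stage variation test needs >= 2 stages present")
    keep_cells = np.flatnonzero(np.array([s is not None for s in stages]))
    sub = expr.subset_cells(keep_cells)
    stage_sub = stages[keep_cells]
    S = eqtl_scan.base_design(sub)
    stage_cat = pd.Categorical(stage_sub, categories=present)
    dummies = np.column_stack([(stage_cat == s).astype(float)
                               for s in present[1:]])
    df = len(present) - 1
    if transcript_idx is None:
        transcript_idx = np.arange(expr.n_transcripts)
    Y = sub.counts.tocsc()
    rows = []
    for t in transcript_idx:
        y = np.asarray(Y[:, t].todense()).ravel().astype(float)
        if y.sum() == 0:
            logger.info("transcript %s all-zero; skipped",
                        expr.transcripts["name"].iloc[t])
            continue
        Xfull = np.column_stack([S, dummies])
        full = eqtl_scan.fit_nb_glm(y, Xfull, theta=None)
        red = eqtl_scan.fit_nb_glm(y, S, theta=full.theta)
        lr = max(0.0, 2.0 * (full.loglik - red.loglik))
        p = stats.chi2.sf(lr, df)
        rows.append({"transcript": expr.transcripts["name"].iloc[t],
                     "lr": lr, "df": df, "p": p})
    out = pd.DataFrame(rows)
    if len(out):
        from statsmodels.stats.multitest import multipletests
        out["q"] = multipletests(out["p"].to_numpy(), method="fdr_bh")[1]
    return out
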