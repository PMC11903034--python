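"""Synthetic crosses and single-cell datasets.

The generator mirrors the statistical model the pipeline assumes: haploid
segregant genotypes are Markov chains along each chromosome with switch
probabilities given by the Haldane map function; per-transcript UMI
counts are negative binomial with a log-linear mean in depth, batch,
cell-cycle stage and planted eQTL effects; allelic reads at informative
sites are Poisson in depth and binomial in the sequencing error rate;
doublets are sums of two independent cells.  Truth tables are always
emitted so downstream evaluation can be truth-aware.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
import scipy.sparse as sp

from ._mapfun import MAP_FUNCTIONS
from .io_formats import AlleleCountMatrix, ExpressionMatrix, GeneticMap

_ROMAN = ["I", "II", "III", "IV", "V", "VI", "VII", "VIII", "IX", "X",
          "XI", "XII", "XIII", "XIV", "XV", "XVI", "XVII", "XVIII", "XIX", "XX"]

HAPLOID_STAGES = ["M/G1", "G1", "G1/S", "S", "G2/M"]
DIPLOID_STAGES = ["M/G1", "G1/S", "S", "G2/M"]


def chrom_name(i: int) -> str:
    """Roman-numeral chromosome name (0-based index -> 'chrI', ...)."""
    return f"chr{_ROMAN[i]}"


# ---------------------------------------------------------------------------
# designs


@dataclasses.dataclass
class StageModel:
    """Baseline cell-cycle stage probabilities, optionally genotype-dependent.

    If ``occupancy_marker`` is set, cells carrying the parent-A allele at
    that marker have their stage log-odds shifted by ``occupancy_effects``
    (one log-odds term per stage) before renormalisation.
    """

    stages: list[str] = dataclasses.field(default_factory=lambda: list(HAPLOID_STAGES))
    probs: np.ndarray | None = None
    occupancy_marker: int | None = None
    occupancy_effects: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.probs is None:
            self.probs = np.full(len(self.stages), 1.0 / len(self.stages))
        self.probs = np.asarray(self.probs, float)
        if len(self.probs) != len(self.stages):
            raise ValueError("one probability per stage required")
        if abs(self.probs.sum() - 1.0) > 1e-12:
            raise ValueError("stage probabilities must sum to 1")
        if self.occupancy_effects is not None:
            self.occupancy_effects = np.asarray(self.occupancy_effects, float)
            if len(self.occupancy_effects) != len(self.stages):
                raise ValueError("one occupancy effect per stage required")

    def stage_probs(self, genotype: int) -> np.ndarray:
        if self.occupancy_marker is None or genotype == 0:
            return self.probs
        w = self.probs * np.exp(genotype * self.occupancy_effects)
        return w / w.sum()


@dataclasses.dataclass
class TranscriptModel:
    """Generative parameters for one transcript.

    ``baseline_log_mean`` is the log expected count at unit depth; the
    realised NB mean multiplies in the cell's depth, batch, stage and any
    planted eQTL effects.  ``theta`` is the NB size parameter (expression
    noise is 1/theta).  ``eqtl_effects`` maps marker index -> log
    fold-change per parent-A allele.
    """

    name: str
    chrom: str
    pos: int
    baseline_log_mean: float
    theta: float = 5.0
    stage_effects: dict[str, float] = dataclasses.field(default_factory=dict)
    batch_effects: dict[str, float] = dataclasses.field(default_factory=dict)
    eqtl_effects: dict[int, float] = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.theta <= 0:
            raise ValueError("theta must be positive")


@dataclasses.dataclass
class SimDesign:
    """Full generative specification for a one-pot experiment."""

    genetic_map: GeneticMap
    transcript_models: list[TranscriptModel]
    n_segregants: int = 200
    n_cells: int = 5000
    # log-normal per-cell total depth; defaults give a median near 1500 UMIs
    depth_log_mean: float = float(np.log(1500.0))
    depth_log_sd: float = 0.35
    batches: list[tuple[str, float]] = dataclasses.field(
        default_factory=lambda: [("b0", 1.0)])
    stage_model: StageModel = dataclasses.field(default_factory=StageModel)
    site_rates: np.ndarray | None = None
    error_rate: float = 0.005
    doublet_rate: float = 0.0
    seed: int = 0
    map_function: str = "haldane"

    def __post_init__(self) -> None:
        if self.n_segregants < 1 or self.n_cells < 1:
            raise ValueError("n_segregants and n_cells must be positive")
        if not 0.0 <= self.error_rate <= 1.0:
            raise ValueError("error_rate must be in [0, 1]")
        if not 0.0 <= self.doublet_rate <= 1.0:
            raise ValueError("doublet_rate must be in [0, 1]")
        if self.site_rates is None:
            # ~2/3 of depth informative, spread evenly over sites
            n_sites = self.genetic_map.n_markers
            self.site_rates = np.full(n_sites, 0.66 / n_sites)
        self.site_rates = np.asarray(self.site_rates, float)
        if np.any(self.site_rates < 0):
            raise ValueError("site_rates must be non-negative")
        if len(self.site_rates) != self.genetic_map.n_markers:
            raise ValueError("one site rate per map marker required")
        frac = sum(f for _, f in self.batches)
        if abs(frac - 1.0) > 1e-9:
            raise ValueError("batch fractions must sum to 1")
        for tm in self.transcript_models:
            for m in tm.eqtl_effects:
                if not 0 <= m < self.genetic_map.n_markers:
                    raise ValueError(
                        f"transcript {tm.name}: eqtl marker {m} outside map")


@dataclasses.dataclass
class AseSimDesign:
    """Grid design for F1-hybrid allele-specific count simulations.

    ``fc_grid`` are allele log2 fold-changes on the mean; ``dfc_grid``
    are log2 fold-changes on dispersion (noise = 1/theta, so a positive
    value makes the alternate allele noisier).  ``total_expression_level``
    is the expected total allelic UMI count per cell for the transcript;
    presets: ``"median"`` = 1 (a typical transcript passing the 64-cell
    observation filter) and ``"top-5%"`` = 10 (a highly expressed one).
    """

    n_cells: int = 5000
    fc_grid: tuple[float, ...] = (0.0,)
    dfc_grid: tuple[float, ...] = (0.0,)
    total_expression_level: float | str = "median"
    base_theta: float = 5.0
    n_reps: int = 250
    seed: int = 0

    _PRESETS = {"median": 1.0, "top-5%": 10.0}

    def __post_init__(self) -> None:
        if self.n_cells < 1 or self.n_reps < 1:
            raise ValueError("n_cells and n_reps must be positive")
        if not self.fc_grid or not self.dfc_grid:
            raise ValueError("fold-change grids must be non-empty")
        if isinstance(self.total_expression_level, str):
            try:
                self.total_expression_level = self._PRESETS[self.total_expression_level]
            except KeyError as exc:
                raise ValueError(
                    f"unknown expression preset {self.total_expression_level!r}; "
                    f"use one of {sorted(self._PRESETS)}") from exc


# ---------------------------------------------------------------------------
# map + genotypes


def simulate_map(n_chrom: int, markers_per_chrom: int, chrom_length_cM: float,
                 chrom_length_bp: int) -> GeneticMap:
    """Uniform marker grid: each chromosome spans [0, chrom_length_cM]."""
    if min(n_chrom, markers_per_chrom) < 1 or min(chrom_length_cM, chrom_length_bp) <= 0:
        raise ValueError("all arguments must be positive")
    rows = []
    for c in range(n_chrom):
        if markers_per_chrom == 1:
            bp = np.array([chrom_length_bp // 2])
            cm = np.array([0.0])
        else:
            bp = np.linspace(1, chrom_length_bp, markers_per_chrom).round().astype(int)
            cm = np.linspace(0.0, chrom_length_cM, markers_per_chrom)
        rows.append(pd.DataFrame({"chrom": chrom_name(c), "pos": bp, "cM": cm}))
    return GeneticMap(markers=pd.concat(rows, ignore_index=True))


def simulate_segregants(gmap: GeneticMap, n: int,
                        seed: int | np.random.Generator = 0,
                        map_function: str = "haldane") -> np.ndarray:
    """Draw ``n`` recombinant haploid genotype vectors (1 = parent-A allele).

    Each chromosome is an independent two-state Markov chain: the first
    marker is Bernoulli(0.5) and adjacent markers switch with the
    recombination fraction of the map function applied to their cM gap.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if gmap.n_markers == 0:
        raise ValueError("empty genetic map")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    mapfun = MAP_FUNCTIONS[map_function]
    geno = np.empty((n, gmap.n_markers), dtype=np.int8)
    for chrom in gmap.chromosomes:
        sub = gmap.chrom_slice(chrom)
        idx = sub.index.to_numpy()
        cm = sub["cM"].to_numpy(float)
        r = mapfun(np.diff(cm))
        col = rng.integers(0, 2, size=n, dtype=np.int8)
        geno[:, idx[0]] = col
        for j, rj in enumerate(r, start=1):
            switch = rng.random(n) < rj
            col = np.where(switch, 1 - col, col)
            geno[:, idx[j]] = col
    return geno


def random_transcript_models(gmap: GeneticMap, n_transcripts: int,
                             seed: int | np.random.Generator = 0, *,
                             baseline_range: tuple[float, float] = (-7.0, -4.5),
                             theta: float = 5.0,
                             n_local_eqtl: int = 0,
                             local_effect: float = 0.3) -> list[TranscriptModel]:
    """Transcripts at random marker positions, optionally with local eQTLs.

    The first ``n_local_eqtl`` transcripts get a planted effect of
    ``local_effect`` (log fold-change per parent-A allele) at the marker
    they sit on.  Baseline log means are uniform over ``baseline_range``
    (log expected count at unit depth; with a median depth of ~1500 UMIs
    the default range spans roughly 1 to 17 expected counts per cell).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if n_local_eqtl > n_transcripts:
        raise ValueError("n_local_eqtl cannot exceed n_transcripts")
    marker_at = rng.integers(0, gmap.n_markers, size=n_transcripts)
    baselines = rng.uniform(*baseline_range, size=n_transcripts)
    models = []
    for i in range(n_transcripts):
        m = int(marker_at[i])
        row = gmap.markers.iloc[m]
        eqtl = {m: local_effect} if i < n_local_eqtl else {}
        models.append(TranscriptModel(
            name=f"T{i:04d}", chrom=row["chrom"], pos=int(row["pos"]),
            baseline_log_mean=float(baselines[i]), theta=theta,
            eqtl_effects=eqtl))
    return models


# ---------------------------------------------------------------------------
# full experiment


@dataclasses.dataclass
class SyntheticDataset:
    """A simulated one-pot experiment with full ground truth."""

    expr: ExpressionMatrix
    allele_counts: AlleleCountMatrix
    genotypes: np.ndarray          # segregant x marker, {0,1}
    cell_segregant: np.ndarray     # per-cell segregant index (primary for doublets)
    cell_stage: np.ndarray         # per-cell true stage label
    cell_doublet: np.ndarray       # per-cell bool
    truth_eqtl: pd.DataFrame       # transcript, marker, effect
    truth_stage: pd.DataFrame      # transcript, stage, effect

    @property
    def cell_genotypes(self) -> np.ndarray:
        """Per-cell true genotype vector (primary segregant for doublets)."""
        return self.genotypes[self.cell_segregant]


def simulate_experiment(design: SimDesign) -> SyntheticDataset:
    """Generate a complete synthetic one-pot dataset from a SimDesign."""
    rng = np.random.default_rng(design.seed)
    gmap = design.genetic_map
    n_cells, n_markers = design.n_cells, gmap.n_markers
    tms = design.transcript_models

    genotypes = simulate_segregants(gmap, design.n_segregants, rng,
                                    design.map_function)

    seg_idx = rng.integers(0, design.n_segregants, size=n_cells)
    depth = np.exp(rng.normal(design.depth_log_mean, design.depth_log_sd,
                              size=n_cells))
    batch_labels = [b for b, _ in design.batches]
    batch = rng.choice(len(batch_labels), size=n_cells,
                       p=[f for _, f in design.batches])

    # stages, genotype-dependent when an occupancy QTL is planted
    sm = design.stage_model
    stages = np.empty(n_cells, dtype=object)
    if sm.occupancy_marker is None:
        stages[:] = rng.choice(sm.stages, size=n_cells, p=sm.probs)
    else:
        g_occ = genotypes[seg_idx, sm.occupancy_marker]
        for gval in (0, 1):
            m = g_occ == gval
            if m.any():
                stages[m] = rng.choice(sm.stages, size=m.sum(),
                                       p=sm.stage_probs(gval))

    def _draw_counts(cells: np.ndarray, seg_of_cell: np.ndarray) -> sp.csr_matrix:
        """NB transcript counts for the given cell indices (vectorised)."""
        nc = len(cells)
        g = genotypes[seg_of_cell[cells]]
        log_depth = np.log(depth[cells])
        cols = []
        for tm in tms:
            eta = tm.baseline_log_mean + log_depth
            for b, eff in tm.batch_effects.items():
                eta = eta + eff * (np.asarray(batch_labels)[batch[cells]] == b)
            for s, eff in tm.stage_effects.items():
                eta = eta + eff * (stages[cells] == s)
            for m, eff in tm.eqtl_effects.items():
                eta = eta + eff * g[:, m]
            mu = np.exp(eta)
            # NB as gamma-Poisson
            lam = rng.gamma(tm.theta, mu / tm.theta, size=nc)
            cols.append(rng.poisson(lam))
        return sp.csr_matrix(np.column_stack(cols))

    def _draw_alleles(cells: np.ndarray,
                      seg_of_cell: np.ndarray) -> tuple[sp.csr_matrix, sp.csr_matrix]:
        """Poisson site depth, binomial allele assignment with error."""
        g = genotypes[seg_of_cell[cells]]
        lam = depth[cells, None] * design.site_rates[None, :]
        D = rng.poisson(lam)
        p_a = np.where(g == 1, 1.0 - design.error_rate, design.error_rate)
        rA = rng.binomial(D, p_a)
        return sp.csr_matrix(rA), sp.csr_matrix(D - rA)

    all_cells = np.arange(n_cells)
    counts = _draw_counts(all_cells, seg_idx)
    cA, cB = _draw_alleles(all_cells, seg_idx)

    # doublets: overlay an independent partner cell's counts
    doublet = rng.random(n_cells) < design.doublet_rate
    if doublet.any():
        idx = np.flatnonzero(doublet)
        partner = seg_idx.copy()
        partner[idx] = rng.integers(0, design.n_segregants, size=len(idx))
        add = sp.lil_matrix(counts.shape, dtype=np.int64)
        add[idx] = _draw_counts(idx, partner)
        counts = (counts + add.tocsr()).tocsr()
        pA, pB = _draw_alleles(idx, partner)
        addA = sp.lil_matrix(cA.shape, dtype=np.int64)
        addB = sp.lil_matrix(cB.shape, dtype=np.int64)
        addA[idx], addB[idx] = pA, pB
        cA = (cA + addA.tocsr()).tocsr()
        cB = (cB + addB.tocsr()).tocsr()

    barcodes = np.array([f"cell{i:05d}" for i in range(n_cells)])
    transcripts = pd.DataFrame({
        "name": [tm.name for tm in tms],
        "chrom": [tm.chrom for tm in tms],
        "pos": [tm.pos for tm in tms],
    })
    cell_meta = pd.DataFrame({
        "batch": np.asarray(batch_labels)[batch],
        "stage": stages,
        "segregant": seg_idx,
        "doublet": doublet,
    })
    expr = ExpressionMatrix(cells=barcodes, transcripts=transcripts,
                            counts=counts.astype(np.int64), cell_meta=cell_meta)
    sites = gmap.markers[["chrom", "pos"]].copy()
    sites["alleleA"] = "A"
    sites["alleleB"] = "G"
    ac = AlleleCountMatrix(cells=barcodes, sites=sites,
                           countsA=cA.astype(np.int64), countsB=cB.astype(np.int64))

    truth_eqtl = pd.DataFrame(
        [(tm.name, m, eff) for tm in tms for m, eff in tm.eqtl_effects.items()],
        columns=["transcript", "marker", "effect"])
    truth_stage = pd.DataFrame(
        [(tm.name, s, eff) for tm in tms for s, eff in tm.stage_effects.items()],
        columns=["transcript", "stage", "effect"])
    return SyntheticDataset(expr=expr, allele_counts=ac, genotypes=genotypes,
                            cell_segregant=seg_idx, cell_stage=stages,
                            cell_doublet=doublet, truth_eqtl=truth_eqtl,
                            truth_stage=truth_stage)


# ---------------------------------------------------------------------------
# F1 hybrid allele-specific counts


@dataclasses.dataclass
class AseGeneData:
    """Stacked allelic counts for one gene: two rows per cell.

    ``allele`` is 0 for the reference parental allele, 1 for the
    alternate; ``cell`` maps each row back to its cell.  The layout is
    exactly what ``ase_noise.fit_ase_model`` consumes.
    """

    counts: np.ndarray
    allele: np.ndarray
    cell: np.ndarray
    stage: np.ndarray | None = None
    batch: np.ndarray | None = None
    total_umis: np.ndarray | None = None
    truth: dict | None = None


def simulate_f1_hybrid(design: AseSimDesign) -> list[AseGeneData]:
    """Simulate allele-specific counts over the design's fold-change grid.

    Returns one dataset per (fc, dfc, rep) combination.  Allelic means
    split the fixed total so the reference allele mean is T/(1+FC) and
    the alternate T*FC/(1+FC); the alternate allele's dispersion (1/theta)
    is scaled by the dispersion fold-change.
    """
    out = []
    T = float(design.total_expression_level)
    for i_fc, fc_log2 in enumerate(design.fc_grid):
        for i_dfc, dfc_log2 in enumerate(design.dfc_grid):
            fc = 2.0 ** fc_log2
            dfc = 2.0 ** dfc_log2
            mu_ref = T / (1.0 + fc)
            mu_alt = T * fc / (1.0 + fc)
            theta_ref = design.base_theta
            theta_alt = design.base_theta / dfc
            for rep in range(design.n_reps):
                rng = np.random.default_rng(
                    np.random.SeedSequence((design.seed, i_fc, i_dfc, rep)))
                n = design.n_cells
                y_ref = rng.poisson(rng.gamma(theta_ref, mu_ref / theta_ref, n))
                y_alt = rng.poisson(rng.gamma(theta_alt, mu_alt / theta_alt, n))
                counts = np.empty(2 * n, dtype=np.int64)
                counts[0::2] = y_ref
                counts[1::2] = y_alt
                allele = np.tile([0, 1], n)
                cell = np.repeat(np.arange(n), 2)
                out.append(AseGeneData(
                    counts=counts, allele=allele, cell=cell,
                    truth={"fc_log2": fc_log2, "dfc_log2": dfc_log2,
                           "rep": rep, "mu_ref": mu_ref, "mu_alt": mu_alt,
                           "theta_ref": theta_ref, "theta_alt": theta_alt}))
    return out
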