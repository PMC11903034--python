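# Methods

## Setting

A "one-pot" single-cell eQTL experiment profiles tens of thousands of
haploid recombinant yeast segregants (or F1 hybrid diploids) in a single
scRNA-seq run. The same UMI counts serve three purposes: per-cell
genome-wide genotypes (from allelic counts at transcribed SNPs),
per-transcript expression, and a cell-cycle stage label. This package
implements the full chain — simulation, genotyping, stage assignment,
eQTL scans, allele-specific noise analysis, occupancy-QTL mapping and
hotspot detection — with a synthetic-data generator that reproduces the
statistical structure every stage assumes, so the whole pipeline is
testable without sequencing data.

## Genotype inference (`genotyping`)

Each chromosome of a haploid cell is a two-state hidden Markov chain
over the genotype-informative sites:

- **Priors** 0.5 / 0.5 for the two parental alleles.
- **Emissions**: with `r` parent-A reads out of depth `D` and per-read
  error `e` (default 0.005), `p(r | A) ∝ (1−e)^r e^(D−r)` and
  symmetrically for B. The binomial coefficient is common to both
  states and cancels in the posterior.
- **Transitions**: the recombination fraction for a cM gap `d` comes
  from the Haldane map function `r = ½(1 − e^(−2d/100))` (no
  interference). The map function is shared verbatim with the
  simulator so inference and generation are self-consistent; Kosambi is
  available as an option. Site cM positions are linearly interpolated
  from the genetic map.
- **Decoding**: forward–backward posteriors (not Viterbi), vectorised
  across cells with per-step normalisation. Sites masked by the pooled
  minor-allele-frequency filter (< 5%, strict) or with no reads emit
  flat likelihoods, i.e. their genotypes are imputed through the
  transitions.

Hard calls binarise at P(A) > 0.5; the measure-zero tie at exactly 0.5
goes to B (documented arbitrary choice). Doublets are flagged when the
fraction of depth≥2 sites showing both parental alleles exceeds `tau`
(default 0.10; the source procedure states no number). Duplicate
genotypes (Hamming distance ≤ 0 by default) trigger filtering only when
they exceed 10% of cells, in which case the highest-UMI cell per
duplicate group is kept. Cells are matched to reference segregants by
Pearson correlation of the posterior vector against each reference row;
constant vectors have no defined correlation and report no-match.

Correctness is anchored on an independent oracle: for ≤ 12 markers the
posterior equals an exhaustive sum over all 2^k genotype paths to
1e-10.

## Cell-cycle stages (`cellcycle`)

The published workflow (variance-stabilised graph clustering plus
manual annotation) is interactive and not reproducible in batch; it is
replaced by a deterministic marker-score classifier. Counts are
normalised to log1p counts-per-10k, each marker gene is z-scored across
cells (population SD), a stage's score is the mean z of its markers and
the cell takes the argmax stage, with ties broken in the fixed order
M/G1 → G1 → G1/S → S → G2/M. Haploids use five stages and the
22-gene panel (M/G1: PIR1, EGT2, ASH1, DSE1, DSE2, CTS1; G1: MFA1;
G1/S: CSI1, TOS4, POL30, PRY2, AXL2, CLN2; S: HTB1, HHF2; G2/M: HOF1,
PHO3, MMR1, CLB2, WSC4, CDC5, CHS2); diploids use four stages, dropping
MFA1 (not expressed in diploids). Stage labels may also be supplied
externally to every downstream module.

Stage-dependent expression is tested per gene by a likelihood-ratio
test between NB regressions with and without stage indicators
(covariates: intercept, ln total UMIs, batch), df = #stages − 1,
Benjamini–Hochberg across genes.

## Negative-binomial eQTL scans (`eqtl_scan`)

For transcript counts `Y` over cells the model is

    E[Y] = μ,   Var(Y) = μ + μ²/θ,
    μ = exp(β_i + X_t β_t + X_b β_b + X_g β_g)

with `X_t = ln(total UMIs)` controlling compositional effects, `X_b`
batch indicators and `X_g` the standardized (mean 0, SD 1) genotype
probability at a marker. Fitting is IRLS with a log link
(|Δ logLik| < 1e-8, ≤ 100 iterations); θ is estimated per transcript by
a bounded (1e-3…1e5) profile-likelihood search *once*, on the design
containing the closest marker, and reused in every scan for that
transcript — conservative, since unmodelled effects inflate θ̂.
Standard errors come from the observed information. Genome scans run a
batched IRLS across all markers simultaneously (shared covariate block,
per-marker normal equations), which keeps a 5 000-cell × hundreds-of-
markers scan in tens of milliseconds.

Markers are first pruned per chromosome (greedy left-to-right, drop
when |r| > 0.999 with the last retained marker); on HMM posteriors at
realistic UMI density this thins a dense map to a few-cM effective
grid. Transcripts must be detected in ≥ 128 cells.

LOD = LR / (2 ln 10). Peaks are the per-chromosome argmax (leftmost on
ties) with a 1.5-LOD-drop CI: the contiguous run around the peak with
LOD ≥ peak − 1.5, clipped at chromosome ends. Significance is by
permutation: segregant identities are shuffled against genotypes within
batch (all cells of a segregant move together), five permutations by
default; FDR(t) = E_perm[#max-LOD > t] / #observed > t over thresholds
0.1 … 0.1 + max LOD in steps of 0.01, capped at 1 and made monotone
non-increasing; per-peak adjusted p by linear interpolation at the
peak's LOD. Maxima are collected per (transcript, chromosome). The
combined-stage test sums observed and permuted LOD matrices across
stages before peak calling. Cell-cycle interactions contrast two
stages' effects with Z = (β_i − β_j)/√(SE_i² + SE_j²), two-sided normal
p, BH within the caller-specified family.

## Allele-specific expression and noise (`ase_noise`)

In an F1 hybrid the two alleles of a gene give two stacked count rows
per cell. The joint NB model carries the allele effect (and optional
ln-UMI, batch, stage and allele×stage terms) in the mean and an
allele-specific dispersion:

    ln θ(row) = τ0 + X_k τ1

"Noise" is 1/θ; the allele noise fold-change is `exp(−τ1)`. The fit is
a quasi-Newton (L-BFGS-B) maximisation with analytic gradients, warm-
started from a common-dispersion IRLS fit; the observed information is
a central-difference Hessian. The t-statistic of τ1 tests noise
effects; the mean (β_k) and noise (τ1) families are BH-adjusted
separately. Swapping allele labels negates β_k and τ1 exactly, and
pinning τ1 = 0 reduces the model to an ordinary NB regression (both are
tested).

Pooled-diploid cells are classified by a per-site binomial likelihood
(p = e, ½, 1−e for allele-A dosage 0, 1, 2), argmax with a 2-log-unit
margin; the construction is this package's own, as is the margin
default. Analysis is restricted to cells with < 20 000 total UMIs and
genes with allelic counts observed in ≥ 64 cells.

The bias experiment simulates 250 instantiations per grid point of
allelic × dispersion fold-changes at 5 000 cells and refits the
intercept+allele model. Two expression presets are provided: "median"
(1 expected allelic UMI per cell, both alleles combined) and "top-5%"
(10). The median preset is deliberately the sparsest level at which the
τ1 Wald test matches its nominal distribution (reported SE ≈ empirical
sampling SD); below it the likelihood is too flat for a quadratic
approximation and the test turns sharply conservative. At very low
counts (≈ 0.05 allelic UMIs/cell) the typical dispersion fold-change
estimate collapses toward 1 — the documented downward-bias regime —
while occasional fits explode upward, so the bias is summarised by
medians and sign tests rather than means. Significant genes feed a
robust (Huber M-estimation) regression of noise change on expression
change; a gene violates the global trend iff its noise-effect 95% CI
and the pointwise 95% CI of the fitted line are disjoint.

## Cell-cycle occupancy QTLs (`occupancy`)

Stage membership is a binary trait per stage, scanned by logistic
regression on the standardized genotype plus ln(total UMIs), with
LOD = (ℓ_full − ℓ_null)/ln 10. Chromosome III is excluded (mating-locus
linkage distorts its allele frequencies in MATa-sorted populations).
Quasi-complete separation triggers a Firth (Jeffreys-prior) refit,
flagged in the output. The genome-wide 5% threshold is the 95th
percentile of per-permutation maximum LODs (segregant-within-batch
permutations, ≥ 100 required, default 1000); the cited FWER procedure
is not reproduced in the source text, so this permutation stand-in is
the documented substitute.

## Hotspots (`hotspots`)

The genome is tiled into half-open 50-kb bins. Each FDR < 0.05 peak is
assigned to the bin containing its peak-marker coordinate (point
assignment; a marker at the final base of a chromosome belongs to the
last bin) and counts only if the transcript lies on a different
chromosome than the bin. Under a Poisson null with λ = total distant
count / #bins, each bin's upper-tail p is Bonferroni-corrected by the
bin count; adjacent significant bins merge. A hotspot's CI takes the
up-to-20 highest-LOD member eQTLs, the 10th percentile of their left CI
ends and 90th of their right ends (linear-interpolation percentiles),
extended two markers outward on the pruned grid and clipped at the
chromosome.

## Synthetic data (`simdata`)

Segregant genotypes are per-chromosome Markov chains (first marker
Bernoulli(0.5), switch probability = map-function recombination
fraction of the cM gap). Per-cell total depth is log-normal (median
≈ 1500 UMIs, log-SD 0.35 by default; the source reports medians only).
Transcript counts are gamma-Poisson (NB) with log-linear means in
ln(depth), batch, stage and planted eQTL effects. Allelic reads are
Poisson per site (rate = site_rate × depth; by default ~⅔ of depth
spread evenly over sites, giving ~1000 informative UMIs at median
depth) followed by binomial allele assignment with error 0.005.
Poisson-per-site is an assumption — the real per-site read-depth
distribution is not published. Doublets sum the counts of two
independently drawn cells; occupancy QTLs tilt the stage distribution
multiplicatively in log-odds by genotype. All randomness derives from a
single integer seed (`numpy` Generator with derived SeedSequences);
fixed seeds give bit-identical outputs. Truth tables (genotypes,
segregant assignments, stages, doublet flags, planted effects) are
always returned.

One consequence of compositional normalisation deserves note: in a
small simulated transcriptome, planted effects (stage or eQTL) shift a
cell's *total* UMIs, so after conditioning on ln(total) the remaining
transcripts acquire real, if weak, associations of the opposite sign.
This is a genuine property of relative-abundance data, not an artefact
of the implementation — with thousands of transcripts the leak is
negligible, but calibration experiments in this package always use
datasets with no planted effects anywhere.

What the generator does **not** emulate: ambient RNA, UMI collisions,
gene-length or GC biases, segregation distortion (other than chrIII
being excludable downstream), crossover interference, and correlated
transcriptional programs beyond the explicit stage/batch/eQTL terms.
Passing tests therefore demonstrate correctness of the inference
machinery under the model's own assumptions, not robustness to every
artefact of real libraries.

## Problem sizes used in the test suite

Chosen so the pipeline's statistical claims are testable at desk scale:
genotyping accuracy uses 200 segregants × ~25 cells with 1000 markers
and ~1000 informative UMIs per cell; GLM coverage uses 200 replicates
of 5000 cells; FDR calibration uses 200 transcripts × 3000 cells with
5 permutations; ASE calibration uses 250 instantiations of 5000 cells
(150 for the low-count bias sign test, which needs the larger
replicate count for adequate sign-test power); occupancy detection uses
100 runs of 10 000 cells × 200 segregants on a 100-marker genome with a
single 100-permutation threshold shared across the iid runs; hotspot
recovery uses 50 runs of 5000 cells with 50 planted trans targets and
2 permutations per run for the FDR map (the package default stays 5).

## Known limitations

- The NB scans use fixed-effect models only; the random-effect variant
  for repeatedly sampled segregants is out of scope.
- θ̂ at a search bound is flagged but not regularised across
  transcripts.
- The Wald t-test for τ1 is conservative below ~1 allelic UMI/cell;
  interpret noise calls for very sparse genes cautiously.
- The marker-score stage classifier is a deterministic surrogate for
  the published clustering workflow; its absolute accuracy on real data
  is unquantified (labels can be supplied externally).
- Hotspot peak-to-bin assignment is by peak coordinate, not CI overlap;
  a peak whose CI spans a bin boundary counts once.
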