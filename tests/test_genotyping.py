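import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
from scipy import stats

from onepot import genotyping, io_formats, simdata
from onepot.genotyping import ErrorModel

from conftest import brute_force_posterior


def _ac_from_arrays(A, B, chrom="chrI", positions=None):
    n_sites = A.shape[1]
    if positions is None:
        positions = np.arange(1, n_sites + 1) * 100
    sites = pd.DataFrame({"chrom": chrom, "pos": positions,
                          "alleleA": "A", "alleleB": "G"})
    return io_formats.AlleleCountMatrix(
        cells=np.array([f"c{i}" for i in range(A.shape[0])]), sites=sites,
        countsA=sp.csr_matrix(A), countsB=sp.csr_matrix(B))


def _uniform_map(chrom="chrI", n=10, span_cM=90.0, span_bp=1_000_000):
    return io_formats.GeneticMap(markers=pd.DataFrame({
        "chrom": chrom,
        "pos": np.linspace(1, span_bp, n).astype(int),
        "cM": np.linspace(0, span_cM, n)}))


class TestEmissionProbs:
    def test_single_read_values(self):
        pA, pB = genotyping.emission_probs(1, 1, 0.005)
        assert pA == pytest.approx(0.995)
        assert pB == pytest.approx(0.005)

    def test_symmetry_at_half_depth(self):
        e = 0.01
        pA, pB = genotyping.emission_probs(1, 2, e)
        assert pA == pytest.approx(pB)
        assert pA == pytest.approx(2 * e * (1 - e))

    def test_ten_concordant_reads(self):
        pA, _ = genotyping.emission_probs(10, 10, 0.005)
        assert pA == pytest.approx(0.995 ** 10)
        assert pA == pytest.approx(0.95111, abs=1e-5)

    def test_swap_reads_swaps_states(self):
        for r, D in [(0, 3), (1, 4), (2, 5)]:
            pA, pB = genotyping.emission_probs(r, D, 0.005)
            qA, qB = genotyping.emission_probs(D - r, D, 0.005)
            assert pA == pytest.approx(qB)
            assert pB == pytest.approx(qA)

    def test_invalid_reads_rejected(self):
        with pytest.raises(ValueError):
            genotyping.emission_probs(3, 2, 0.005)


class TestTransitionMatrix:
    def test_zero_distance_is_identity(self):
        assert np.allclose(genotyping.transition_matrix(0.0), np.eye(2))

    def test_infinite_distance_is_uniform(self):
        assert np.allclose(genotyping.transition_matrix(1e9),
                           np.full((2, 2), 0.5))

    def test_one_cM(self):
        T = genotyping.transition_matrix(1.0)
        assert T[0, 1] == pytest.approx(0.009901, abs=1e-6)
        assert np.allclose(T.sum(axis=1), 1.0)

    def test_negative_distance_rejected(self):
        with pytest.raises(ValueError):
            genotyping.transition_matrix(-1.0)


class TestFilterSites:
    def test_maf_boundary_strict_less_than(self):
        # site 0: pooled A fraction 0.02 -> masked; site 1: 0.5 -> kept;
        # site 2: exactly 0.05 -> kept (strict "<")
        A = np.array([[2, 50, 5]] * 1)
        B = np.array([[98, 50, 95]] * 1)
        ac = _ac_from_arrays(A, B)
        out = genotyping.filter_sites(ac, maf_threshold=0.05)
        assert list(out.mask) == [False, True, True]

    def test_all_masked_is_hard_error(self):
        A = np.array([[100, 100]])
        B = np.array([[0, 0]])
        with pytest.raises(ValueError):
            genotyping.filter_sites(_ac_from_arrays(A, B))


class TestDetectDoublets:
    def test_pure_cell_unflagged(self):
        A = np.array([[3, 2, 0, 0]])
        B = np.array([[0, 0, 3, 2]])
        assert not genotyping.detect_doublets(_ac_from_arrays(A, B), 0.1)[0]

    def test_tau_one_flags_nothing(self):
        A = np.array([[2, 2], [1, 1]])
        B = np.array([[2, 2], [1, 1]])
        assert not genotyping.detect_doublets(_ac_from_arrays(A, B), 1.0).any()

    def test_synthetic_doublets_flagged(self):
        """Cells summing two segregants show both alleles at ~half the
        informative sites and must be flagged at tau=0.1."""
        # many sparse sites, as in real data (~1 read per expressed SNP)
        gmap = simdata.simulate_map(2, 150, 80.0, 1_000_000)
        models = simdata.random_transcript_models(gmap, 3, seed=0)
        design = simdata.SimDesign(
            genetic_map=gmap, transcript_models=models,
            n_segregants=100, n_cells=1000, doublet_rate=0.5, seed=13)
        ds = simdata.simulate_experiment(design)
        flags = genotyping.detect_doublets(ds.allele_counts, tau=0.1)
        truth = ds.cell_doublet
        # the two pooled segregants differ at ~half their markers
        flagged_rate = flags[truth].mean()
        false_rate = flags[~truth].mean()
        assert flagged_rate >= 0.90
        assert false_rate <= 0.05


class TestInferGenotypes:
    def test_single_site_bayes(self):
        ac = _ac_from_arrays(np.array([[1]]), np.array([[0]]))
        gmap = io_formats.GeneticMap(markers=pd.DataFrame(
            {"chrom": ["chrI"], "pos": [100], "cM": [0.0]}))
        gp = genotyping.infer_genotypes(ac, gmap, ErrorModel(0.005))
        assert gp.p_a[0, 0] == pytest.approx(0.995)

    def test_perfect_linkage_conflict_is_symmetric(self):
        # one A read at site 1, one B read at site 2, zero distance apart
        ac = _ac_from_arrays(np.array([[1, 0]]), np.array([[0, 1]]))
        gmap = io_formats.GeneticMap(markers=pd.DataFrame(
            {"chrom": ["chrI", "chrI"], "pos": [100, 200], "cM": [0.0, 0.0]}))
        gp = genotyping.infer_genotypes(ac, gmap)
        assert np.allclose(gp.p_a[0], 0.5)

    def test_unlinked_sites_reduce_to_per_site_bayes(self):
        ac = _ac_from_arrays(np.array([[2, 0, 1]]), np.array([[0, 1, 1]]))
        gmap = io_formats.GeneticMap(markers=pd.DataFrame(
            {"chrom": "chrI", "pos": [100, 200, 300],
             "cM": [0.0, 1e5, 2e5]}))
        gp = genotyping.infer_genotypes(ac, gmap, ErrorModel(0.005))
        for j, (r, D) in enumerate([(2, 2), (0, 1), (1, 2)]):
            pA, pB = genotyping.emission_probs(r, D, 0.005)
            assert gp.p_a[0, j] == pytest.approx(pA / (pA + pB), abs=1e-12)

    @pytest.mark.parametrize("k,seed", [(3, 0), (6, 1), (9, 2), (12, 3)])
    def test_forward_backward_equals_path_enumeration(self, k, seed):
        """Posterior must match exhaustive 2^k path enumeration to 1e-10."""
        rng = np.random.default_rng(seed)
        D = rng.integers(0, 4, size=k)
        rA = rng.binomial(D, 0.7)
        cm = np.sort(rng.uniform(0, 40, size=k))
        ac = _ac_from_arrays(rA[None, :], (D - rA)[None, :])
        gmap = io_formats.GeneticMap(markers=pd.DataFrame(
            {"chrom": "chrI", "pos": np.arange(1, k + 1) * 100, "cM": cm}))
        gp = genotyping.infer_genotypes(ac, gmap, ErrorModel(0.005))
        expected = brute_force_posterior(rA, D, cm, e=0.005)
        assert np.allclose(gp.p_a[0], expected, atol=1e-10)

    def test_masked_site_imputed_through_transitions(self):
        # strong A evidence flanking a masked site at small distances
        A = np.array([[5, 0, 5]])
        B = np.array([[0, 0, 0]])
        ac = _ac_from_arrays(A, B)
        ac.mask = np.array([True, False, True])
        gmap = io_formats.GeneticMap(markers=pd.DataFrame(
            {"chrom": "chrI", "pos": [100, 200, 300], "cM": [0.0, 1.0, 2.0]}))
        gp = genotyping.infer_genotypes(ac, gmap)
        assert gp.p_a[0, 1] > 0.95

    def test_missing_chromosome_reported(self):
        ac = _ac_from_arrays(np.array([[1]]), np.array([[0]]), chrom="chrV")
        gmap = _uniform_map("chrI")
        with pytest.raises(ValueError, match="chrV"):
            genotyping.infer_genotypes(ac, gmap)


class TestBinarize:
    def test_thresholding_with_tie_to_b(self):
        gp = genotyping.GenotypePosterior(
            cells=np.array(["c0"]),
            markers=pd.DataFrame({"chrom": ["chrI"] * 3, "pos": [1, 2, 3],
                                  "cM": [0.0, 1.0, 2.0]}),
            p_a=np.array([[0.6, 0.4, 0.5]]))
        assert list(genotyping.binarize(gp)[0]) == [1, 0, 0]


class TestMatchSegregant:
    def test_identical_reference_matches_perfectly(self):
        ref = np.array([[1, 0, 1, 0, 1], [0, 0, 1, 1, 1]], float)
        best, cor = genotyping.match_segregant(ref[0], ref)
        assert best == 0
        assert cor == pytest.approx(1.0)

    def test_complement_has_negative_correlation(self):
        ref = np.array([[1, 0, 1, 0, 1]], float)
        _, cor = genotyping.match_segregant(1 - ref[0], ref)
        assert cor == pytest.approx(-1.0)

    def test_constant_posterior_reports_no_match(self):
        ref = np.array([[1, 0, 1], [0, 1, 0]], float)
        best, cor = genotyping.match_segregant(np.full(3, 0.5), ref)
        assert best is None
        assert np.isnan(cor)

    def test_simulated_cells_match_true_segregant(self):
        # enough chromosomes that genotype vectors are never constant
        # and distinct segregants rarely collide
        gmap = simdata.simulate_map(8, 25, 80.0, 1_000_000)
        models = simdata.random_transcript_models(gmap, 3, seed=1)
        design = simdata.SimDesign(
            genetic_map=gmap, transcript_models=models,
            n_segregants=50, n_cells=500, seed=14)
        ds = simdata.simulate_experiment(design)
        acf = genotyping.filter_sites(ds.allele_counts)
        gp = genotyping.infer_genotypes(acf, gmap)
        match = genotyping.match_segregants(gp, ds.genotypes.astype(float))
        informative = np.asarray(ds.allele_counts.depth.sum(axis=1)).ravel()
        rich = informative >= 1000
        hit = (match["segregant"].to_numpy()[rich]
               == ds.cell_segregant[rich]).mean()
        assert hit >= 0.95


class TestUniquenessFilter:
    def test_duplicates_above_trigger_keep_highest_umi(self):
        hc = np.array([[1, 0, 1], [1, 0, 1], [0, 1, 0]])
        umis = np.array([1000, 500, 800])
        kept = genotyping.uniqueness_filter(hc, umis)
        assert list(kept) == [True, False, True]

    def test_all_distinct_passes_everything(self):
        hc = np.array([[1, 0], [0, 1], [1, 1]])
        kept = genotyping.uniqueness_filter(hc, np.array([10, 20, 30]))
        assert kept.all()

    def test_below_trigger_no_filtering(self):
        # 2 duplicated cells out of 40 = 5% < 10% trigger
        rng = np.random.default_rng(0)
        hc = rng.integers(0, 2, size=(40, 30))
        hc[1] = hc[0]
        kept = genotyping.uniqueness_filter(hc, rng.integers(100, 1000, 40))
        assert kept.all()


class TestAccuracyProperties:
    def test_accuracy_increases_with_informative_umis(self):
        """Hard-call accuracy must rise with per-cell informative depth."""
        gmap = simdata.simulate_map(2, 100, 80.0, 1_000_000)
        models = simdata.random_transcript_models(gmap, 3, seed=0)
        design = simdata.SimDesign(
            genetic_map=gmap, transcript_models=models,
            n_segregants=80, n_cells=600, seed=21,
            depth_log_sd=0.8,  # wide depth spread to expose the trend
            site_rates=np.full(200, 0.10 / 200))  # sparse allelic coverage
        ds = simdata.simulate_experiment(design)
        acf = genotyping.filter_sites(ds.allele_counts)
        gp = genotyping.infer_genotypes(acf, gmap)
        acc = (gp.hard_calls == ds.cell_genotypes).mean(axis=1)
        depth = np.asarray(ds.allele_counts.depth.sum(axis=1)).ravel()
        rho, p = stats.spearmanr(depth, acc)
        assert rho > 0
        assert p < 0.01
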