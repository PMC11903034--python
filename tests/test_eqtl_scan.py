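import numpy as np
import pandas as pd
import pytest
from scipy import stats

from onepot import eqtl_scan, genotyping, simdata
from onepot.eqtl_scan import (FdrMap, base_design, fit_nb_glm, find_peaks,
                              lod_from_lr, permutation_fdr,
                              standardize_genotypes)


def _nb_loglik_direct(y, mu, theta):
    """Independent oracle: scipy's NB pmf with size theta, mean mu."""
    p = theta / (theta + mu)
    return stats.nbinom.logpmf(y, theta, p).sum()


class TestFitNbGlm:
    def test_intercept_only_mle_is_log_mean(self):
        rng = np.random.default_rng(0)
        y = rng.poisson(4.0, size=400).astype(float)
        fit = fit_nb_glm(y, np.ones((400, 1)), theta=2.0)
        assert fit.beta[0] == pytest.approx(np.log(y.mean()), abs=1e-9)

    def test_loglik_matches_direct_evaluation(self):
        rng = np.random.default_rng(1)
        n = 50
        x = rng.normal(size=n)
        mu = np.exp(1.0 + 0.5 * x)
        theta = 2.0
        y = rng.poisson(rng.gamma(theta, mu / theta)).astype(float)
        X = np.column_stack([np.ones(n), x])
        fit = fit_nb_glm(y, X, theta=theta)
        mu_hat = np.exp(X @ fit.beta)
        assert fit.loglik == pytest.approx(
            _nb_loglik_direct(y, mu_hat, theta), abs=1e-6)

    def test_matches_statsmodels_at_fixed_theta(self):
        import statsmodels.api as sm
        rng = np.random.default_rng(2)
        n = 1000
        x = rng.normal(size=n)
        theta = 3.0
        mu = np.exp(0.5 + 0.4 * x)
        y = rng.poisson(rng.gamma(theta, mu / theta)).astype(float)
        X = np.column_stack([np.ones(n), x])
        fit = fit_nb_glm(y, X, theta=theta)
        ref = sm.GLM(y, X, family=sm.families.NegativeBinomial(
            alpha=1 / theta)).fit()
        assert np.allclose(fit.beta, ref.params, atol=1e-6)
        assert fit.loglik == pytest.approx(ref.llf, abs=1e-6)

    def test_theta_recovery(self):
        rng = np.random.default_rng(3)
        hits = 0
        for _ in range(20):
            n = 5000
            mu = np.full(n, 20.0)
            y = rng.poisson(rng.gamma(2.0, mu / 2.0)).astype(float)
            fit = fit_nb_glm(y, np.ones((n, 1)), theta=None)
            hits += 1.7 <= fit.theta <= 2.3
        assert hits >= 18

    def test_poisson_data_estimates_negligible_noise(self):
        # Poisson counts are the theta -> inf limit: 1/theta ~ 0
        rng = np.random.default_rng(4)
        y = rng.poisson(15.0, size=5000).astype(float)
        fit = fit_nb_glm(y, np.ones((5000, 1)), theta=None)
        assert 1.0 / fit.theta < 0.01

    def test_underdetermined_design_rejected(self):
        with pytest.raises(ValueError):
            fit_nb_glm(np.ones(3), np.ones((3, 4)), theta=1.0)


class TestLodFromLr:
    @pytest.mark.parametrize("lr,expected", [
        (4.60517, 1.0), (0.0, 0.0), (46.0517, 10.0)])
    def test_values(self, lr, expected):
        assert lod_from_lr(lr) == pytest.approx(expected, abs=1e-4)

    def test_negative_clamped(self):
        assert lod_from_lr(-0.5) == 0.0


class TestPruneMarkers:
    def test_identical_column_dropped(self):
        rng = np.random.default_rng(0)
        a = rng.integers(0, 2, 100).astype(float)
        G = np.column_stack([a, a, rng.integers(0, 2, 100)])
        markers = pd.DataFrame({"chrom": ["chrI"] * 3, "pos": [1, 2, 3]})
        kept = eqtl_scan.prune_markers(G, markers)
        assert list(kept) == [0, 2]

    def test_independent_markers_all_kept(self):
        rng = np.random.default_rng(1)
        G = rng.integers(0, 2, size=(200, 5)).astype(float)
        markers = pd.DataFrame({"chrom": ["chrI"] * 5, "pos": range(5)})
        kept = eqtl_scan.prune_markers(G, markers)
        assert len(kept) == 5

    def test_posterior_pruning_spacing_on_dense_map(self):
        """HMM posteriors on a dense (0.5 cM) map are locally near-identical,
        so r>0.999 pruning thins them to a few-cM effective grid."""
        gmap = simdata.simulate_map(1, 161, 80.0, 1_000_000)  # 0.5 cM steps
        models = simdata.random_transcript_models(gmap, 3, seed=0)
        design = simdata.SimDesign(
            genetic_map=gmap, transcript_models=models,
            n_segregants=100, n_cells=500, seed=5)
        ds = simdata.simulate_experiment(design)
        gp = genotyping.infer_genotypes(
            genotyping.filter_sites(ds.allele_counts), gmap)
        kept = eqtl_scan.prune_markers(gp.p_a, gmap.markers)
        assert len(kept) < 161
        spacing = np.diff(gmap.markers["cM"].to_numpy()[kept])
        assert 0.5 < np.median(spacing) < 10.0


class TestFilterTranscripts:
    def test_detection_boundary(self, small_map):
        import scipy.sparse as sp
        from onepot.io_formats import ExpressionMatrix
        counts = np.zeros((200, 3), dtype=int)
        counts[:127, 0] = 1
        counts[:128, 1] = 1
        expr = ExpressionMatrix(
            cells=np.array([f"c{i}" for i in range(200)]),
            transcripts=pd.DataFrame({"name": ["a", "b", "c"],
                                      "chrom": "chrI", "pos": [1, 2, 3]}),
            counts=sp.csr_matrix(counts),
            cell_meta=pd.DataFrame({"batch": ["b0"] * 200}))
        kept = eqtl_scan.filter_transcripts(expr, min_cells=128)
        assert list(kept) == [1]

    def test_empty_result_is_error(self, small_dataset):
        with pytest.raises(ValueError):
            eqtl_scan.filter_transcripts(small_dataset.expr,
                                         min_cells=10 ** 6)


class TestFindPeaks:
    def test_sharp_peak_hand_case(self):
        lod = np.array([0.0, 1.0, 3.0, 1.0, 0.0])
        chrom = np.repeat("chrI", 5)
        [(c, pk, lo, hi)] = find_peaks(lod, chrom)
        assert (pk, lo, hi) == (2, 2, 2)

    def test_flat_vector_leftmost_peak_full_ci(self):
        lod = np.ones(4)
        [(c, pk, lo, hi)] = find_peaks(lod, np.repeat("chrI", 4))
        assert (pk, lo, hi) == (0, 0, 3)

    def test_monotone_vector_clips_at_end(self):
        lod = np.arange(5, dtype=float)
        [(c, pk, lo, hi)] = find_peaks(lod, np.repeat("chrI", 5))
        assert pk == 4
        assert hi == 4
        assert lo == 3  # lod 3 >= 4 - 1.5 fails for 2.5>... 3 >= 2.5 holds

    def test_wide_shoulder_ci(self):
        lod = np.array([0.0, 2.6, 2.8, 4.0, 2.9, 0.5])
        [(c, pk, lo, hi)] = find_peaks(lod, np.repeat("chrI", 6))
        assert (pk, lo, hi) == (3, 1, 4)

    def test_per_chromosome_peaks(self):
        lod = np.array([1.0, 5.0, 0.0, 3.0])
        chrom = np.array(["chrI", "chrI", "chrII", "chrII"])
        peaks = find_peaks(lod, chrom)
        assert peaks[0][:2] == ("chrI", 1)
        assert peaks[1][:2] == ("chrII", 3)


class TestPermutationFdr:
    def test_toy_hand_evaluation(self):
        fdr = permutation_fdr(np.array([1.0, 2.0, 3.0, 4.0]),
                              np.array([[1.0, 1.0, 1.0, 1.0]]))
        assert fdr.adjust(np.array([2.5]))[0] == pytest.approx(0.0)
        assert fdr.adjust(np.array([0.5]))[0] == pytest.approx(1.0)

    def test_null_data_gives_fdr_one(self):
        rng = np.random.default_rng(0)
        obs = rng.exponential(1.0, 100)
        perm = rng.exponential(1.0, (5, 100))
        fdr = permutation_fdr(obs, perm)
        assert fdr.adjust(np.array([0.2]))[0] > 0.5

    def test_separated_data_gives_fdr_zero(self):
        obs = np.full(50, 10.0)
        perm = np.full((5, 50), 1.0)
        fdr = permutation_fdr(obs, perm)
        assert fdr.adjust(np.array([9.0]))[0] == 0.0

    def test_map_is_monotone_and_bounded(self):
        rng = np.random.default_rng(1)
        fdr = permutation_fdr(rng.exponential(1, 200),
                              rng.exponential(1, (3, 200)))
        assert (np.diff(fdr.fdr) <= 1e-12).all()
        assert (fdr.fdr >= 0).all() and (fdr.fdr <= 1).all()


class TestInteractionTest:
    def test_z_statistic_value(self):
        res = eqtl_scan.interaction_test(1.0, 0.5, 0.0, 0.5)
        assert res["z"].iloc[0] == pytest.approx(1.41421, abs=1e-5)

    def test_equal_betas_p_one(self):
        res = eqtl_scan.interaction_test(0.7, 0.1, 0.7, 0.2)
        assert res["p"].iloc[0] == pytest.approx(1.0)

    def test_z_196_gives_p_005(self):
        res = eqtl_scan.interaction_test(1.96, 1 / np.sqrt(2),
                                         0.0, 1 / np.sqrt(2))
        assert res["p"].iloc[0] == pytest.approx(0.0500, abs=5e-4)

    def test_zero_se_rejected(self):
        with pytest.raises(ValueError):
            eqtl_scan.interaction_test(1.0, 0.0, 0.0, 0.5)


@pytest.fixture(scope="module")
def planted_scan_data(small_map):
    """60 transcripts (15 with local eQTL, log-FC 0.5), 2000 cells."""
    models = simdata.random_transcript_models(
        small_map, 60, seed=50, n_local_eqtl=15, local_effect=0.5)
    design = simdata.SimDesign(
        genetic_map=small_map, transcript_models=models,
        n_segregants=150, n_cells=2000, seed=51,
        batches=[("b0", 0.5), ("b1", 0.5)])
    ds = simdata.simulate_experiment(design)
    X = standardize_genotypes(ds.cell_genotypes.astype(float))
    return ds, X


class TestLocalScan:
    def test_planted_effects_detected_with_correct_sign(
            self, planted_scan_data, small_map):
        ds, X = planted_scan_data
        tidx = eqtl_scan.filter_transcripts(ds.expr, min_cells=64)
        res = eqtl_scan.local_scan(
            ds.expr, X, small_map.markers, tidx,
            seg_of_cell=ds.cell_segregant, n_perm=3, seed=1)
        res = res.set_index("transcript")
        planted = ds.truth_eqtl.set_index("transcript")
        hits = res.index.intersection(planted.index)
        calls = res.loc[hits, "p_fdr"] < 0.05
        assert calls.mean() >= 0.80
        sig = res.loc[hits][calls]
        assert (np.sign(sig["beta"]) == 1).mean() >= 0.95


class TestGenomeScan:
    def test_matches_local_scan_at_closest_marker(
            self, planted_scan_data, small_map):
        ds, X = planted_scan_data
        tidx = np.arange(3)
        res = eqtl_scan.local_scan(ds.expr, X, small_map.markers, tidx,
                                   n_perm=1, seed=0)
        thetas = {int(t): float(th)
                  for t, th in zip(tidx, res["theta"])}
        scan = eqtl_scan.genome_scan(ds.expr, X, small_map.markers,
                                     tidx, thetas)
        for i, row in res.iterrows():
            assert scan.lod[i, row["marker"]] == pytest.approx(
                row["lr"] / (2 * np.log(10)), abs=1e-9)

    def test_invariant_to_batch_relabeling(self, planted_scan_data,
                                           small_map):
        ds, X = planted_scan_data
        tidx = np.arange(2)
        thetas = {0: 5.0, 1: 5.0}
        scan1 = eqtl_scan.genome_scan(ds.expr, X, small_map.markers,
                                      tidx, thetas)
        relabeled = ds.expr.cell_meta.copy()
        relabeled["batch"] = relabeled["batch"].map({"b0": "zz", "b1": "aa"})
        from onepot.io_formats import ExpressionMatrix
        expr2 = ExpressionMatrix(cells=ds.expr.cells,
                                 transcripts=ds.expr.transcripts,
                                 counts=ds.expr.counts, cell_meta=relabeled)
        scan2 = eqtl_scan.genome_scan(expr2, X, small_map.markers,
                                      tidx, thetas)
        assert np.allclose(scan1.lod, scan2.lod, atol=1e-7)

    def test_peak_near_planted_marker(self, planted_scan_data, small_map):
        ds, X = planted_scan_data
        planted = ds.truth_eqtl
        name_to_idx = {n: i for i, n in
                       enumerate(ds.expr.transcripts["name"])}
        tidx = np.array([name_to_idx[n] for n in planted["transcript"]])
        thetas = {int(t): 5.0 for t in tidx}
        scan = eqtl_scan.genome_scan(ds.expr, X, small_map.markers,
                                     tidx, thetas)
        ok = 0
        for i, (_, row) in enumerate(planted.iterrows()):
            peaks = find_peaks(scan.lod[i], scan.chrom_of_marker)
            best = max(peaks, key=lambda p: scan.lod[i, p[1]])
            ok += abs(best[1] - row["marker"]) <= 2
        assert ok / len(planted) >= 0.80


class TestCombinedStageScan:
    def test_single_stage_is_identity(self, planted_scan_data, small_map):
        ds, X = planted_scan_data
        tidx = np.arange(2)
        thetas = {0: 5.0, 1: 5.0}
        scan = eqtl_scan.genome_scan(ds.expr, X, small_map.markers,
                                     tidx, thetas)
        perm = eqtl_scan.genome_scan(ds.expr, X[::-1], small_map.markers,
                                     tidx, thetas)
        comb, pcomb = eqtl_scan.combined_stage_scan(
            {"G1": scan}, {"G1": [perm]})
        assert np.array_equal(comb.lod, scan.lod)
        assert np.array_equal(pcomb[0].lod, perm.lod)

    def test_mismatched_grids_rejected(self, planted_scan_data, small_map):
        ds, X = planted_scan_data
        thetas = {0: 5.0}
        scan = eqtl_scan.genome_scan(ds.expr, X, small_map.markers,
                                     np.arange(1), thetas)
        other_markers = small_map.markers.iloc[:-1].reset_index(drop=True)
        scan2 = eqtl_scan.genome_scan(ds.expr, X[:, :-1], other_markers,
                                      np.arange(1), thetas)
        with pytest.raises(ValueError):
            eqtl_scan.combined_stage_scan({"a": scan, "b": scan2},
                                          {"a": [scan], "b": [scan2]})


class TestPermuteGenotypeRows:
    def test_cells_of_a_segregant_move_together(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(12, 4))
        seg = np.repeat([0, 1, 2, 3], 3)
        # make within-segregant rows identical so moves are visible
        for s in range(4):
            X[seg == s] = X[seg == s][0]
        batch = np.repeat("b0", 12)
        Xp = eqtl_scan.permute_genotype_rows(X, seg, batch,
                                             np.random.default_rng(1))
        for s in range(4):
            rows = Xp[seg == s]
            assert np.allclose(rows, rows[0])

    def test_permutation_preserves_row_multiset_within_batch(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(10, 3))
        seg = np.arange(10)
        batch = np.array(["a"] * 5 + ["b"] * 5)
        Xp = eqtl_scan.permute_genotype_rows(X, seg, batch,
                                             np.random.default_rng(3))
        for b in ["a", "b"]:
            orig = np.sort(X[batch == b], axis=0)
            perm = np.sort(Xp[batch == b], axis=0)
            assert np.allclose(orig, perm)
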