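import numpy as np
import pytest

from onepot import simdata


@pytest.fixture(scope="session")
def small_map():
    """Two chromosomes, 10 markers each, 80 cM / 1 Mb per chromosome."""
    return simdata.simulate_map(2, 10, 80.0, 1_000_000)


@pytest.fixture(scope="session")
def small_dataset(small_map):
    """A modest one-pot simulation reused across read-only tests."""
    models = simdata.random_transcript_models(
        small_map, 30, seed=11, n_local_eqtl=8, local_effect=0.5)
    design = simdata.SimDesign(
        genetic_map=small_map, transcript_models=models,
        n_segregants=60, n_cells=800, seed=12,
        batches=[("b0", 0.5), ("b1", 0.5)])
    return simdata.simulate_experiment(design)


def brute_force_posterior(rA, D, cm, e=0.005, prior=0.5,
                          map_function="haldane"):
    """Exhaustive-path genotype posterior for one cell on one chromosome.

    Enumerates all 2^k genotype paths with prior 0.5 per chromosome
    start, Haldane-derived switch probabilities between adjacent markers
    and binomial emissions; independent of the forward-backward code.
    """
    from onepot._mapfun import MAP_FUNCTIONS
    from onepot.genotyping import emission_probs

    k = len(rA)
    rfrac = MAP_FUNCTIONS[map_function](np.diff(np.asarray(cm, float)))
    post_num = np.zeros(k)
    total = 0.0
    for mask in range(2 ** k):
        path = [(mask >> j) & 1 for j in range(k)]  # 1 = parent A
        p = prior if path[0] == 1 else 1 - prior
        for j in range(1, k):
            r = rfrac[j - 1]
            p *= r if path[j] != path[j - 1] else 1 - r
        for j in range(k):
            pA, pB = emission_probs(int(rA[j]), int(D[j]), e)
            p *= pA if path[j] == 1 else pB
        total += p
        for j in range(k):
            if path[j] == 1:
                post_num[j] += p
    return post_num / total
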