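"""Genetic map functions: cM distance -> recombination fraction.

The simulator and the genotyping HMM share these so that the generative
model and the inference model are self-consistent.
"""

from __future__ import annotations

import numpy as np


def haldane(d_cM):
    """Haldane map function, r = 0.5 * (1 - exp(-2 d / 100)).

    Assumes no crossover interference; ``d_cM`` may be scalar or array.
    """
    d = np.asarray(d_cM, float)
    if np.any(d < 0):
        raise ValueError("genetic distance must be non-negative")
    return 0.5 * (1.0 - np.exp(-2.0 * d / 100.0))


def kosambi(d_cM):
    """Kosambi map function, r = 0.5 * tanh(2 d / 100)."""
    d = np.asarray(d_cM, float)
    if np.any(d < 0):
        raise ValueError("genetic distance must be non-negative")
    return 0.5 * np.tanh(2.0 * d / 100.0)


MAP_FUNCTIONS = {"haldane": haldane, "kosambi": kosambi}
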