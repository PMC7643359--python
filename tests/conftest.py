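"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest


def naive_match_counts(V: np.ndarray, r: float) -> np.ndarray:
    """Brute-force double-loop Chebyshev match counting (self excluded).

    Deliberately independent of the package implementation: plain
    Python loops over all ordered pairs.
    """
    V = np.atleast_2d(V)
    n = len(V)
    counts = np.zeros(n, dtype=int)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            if max(abs(a - b) for a, b in zip(V[i], V[j])) <= r:
                counts[i] += 1
    return counts


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_feature_table():
    """A 20-subject feature table with a known single strong predictor."""
    from neurocx.synthetic import CohortSpec, generate_feature_table

    beta = {"AvgEnt_FL-FR": 0.8}
    spec = CohortSpec(n_subjects=20, true_beta=beta, noise_sd=0.3, seed=7)
    return generate_feature_table(spec)
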