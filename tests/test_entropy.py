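"""Unit and property tests of the mMSE engine."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import norm

from neurocx.entropy import (
    MMSEParams,
    build_cdvs,
    coarse_grain,
    extend_cdvs,
    match_counts,
    mmse_profile,
    mv_sample_entropy,
    normalize_channels,
    similarity_fraction,
    subject_profile,
)
from neurocx.exceptions import (
    DegenerateChannelError,
    InsufficientSamplesError,
    UndefinedSimilarityError,
)

from conftest import naive_match_counts


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------


def test_normalize_gives_unit_variance(rng):
    X = rng.normal(5.0, 3.0, size=(3, 200))
    Z = normalize_channels(X)
    assert np.allclose(Z.mean(axis=1), 0, atol=1e-12)
    assert np.allclose(Z.std(axis=1, ddof=1), 1, atol=1e-12)
    # idempotence
    assert np.allclose(normalize_channels(Z), Z, atol=1e-12)


def test_normalize_rejects_constant_channel():
    X = np.vstack([np.ones(50), np.arange(50.0)])
    with pytest.raises(DegenerateChannelError):
        normalize_channels(X)


# ---------------------------------------------------------------------------
# coarse-graining
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "x, eps, expected",
    [
        ([1, 2, 3, 4, 5, 6], 1, [1, 2, 3, 4, 5, 6]),
        ([1, 2, 3, 4, 5, 6], 2, [1.5, 3.5, 5.5]),
        ([1, 2, 3, 4, 5], 2, [1.5, 3.5]),  # remainder dropped
        ([1, 2, 3, 4, 5, 6], 3, [2.0, 5.0]),
    ],
)
def test_coarse_grain_examples(x, eps, expected):
    assert np.allclose(coarse_grain(np.array(x, float), eps), expected)


def test_coarse_grain_too_large_scale():
    with pytest.raises(InsufficientSamplesError):
        coarse_grain(np.arange(3.0), 5)


@settings(max_examples=30, deadline=None, derandomize=True)
@given(
    a=st.integers(min_value=1, max_value=4),
    b=st.integers(min_value=1, max_value=4),
    reps=st.integers(min_value=1, max_value=6),
)
def test_coarse_grain_composes(a, b, reps):
    """coarse_grain(x, a*b) == coarse_grain(coarse_grain(x, a), b) when
    the lengths divide evenly."""
    n = a * b * reps
    x = np.sin(np.arange(n, dtype=float)) + np.arange(n, dtype=float) * 0.1
    assert np.allclose(
        coarse_grain(x, a * b), coarse_grain(coarse_grain(x, a), b), atol=1e-12
    )


# ---------------------------------------------------------------------------
# composite delay vectors
# ---------------------------------------------------------------------------


def test_cdv_worked_example_shapes():
    """p=2, N=10, M=[3,2], tau=[2,1]: N-n = 10-3*2 = 4 vectors of
    length m = 3+2 = 5."""
    X = np.arange(20.0).reshape(2, 10)
    V = build_cdvs(X, [3, 2], [2, 1])
    assert V.shape == (4, 5)
    # row 0 layout: x1[0], x1[2], x1[4] then x2[0], x2[1]
    assert np.allclose(V[0], [0, 2, 4, 10, 11])
    assert np.allclose(V[3], [3, 5, 7, 13, 14])


def test_cdv_univariate():
    x = np.arange(5.0)[None, :]
    V = build_cdvs(x, [2], [1])
    assert V.shape == (3, 2)
    assert np.allclose(V, [[0, 1], [1, 2], [2, 3]])


def test_cdv_constant_rows_identical():
    V = build_cdvs(np.ones((2, 12)), [2, 2], [1, 1])
    assert np.allclose(V, V[0])


def test_cdv_insufficient_samples():
    with pytest.raises(InsufficientSamplesError):
        build_cdvs(np.ones((1, 4)), [2], [2])


def test_extension_lengths_worked_example():
    X = np.arange(20.0).reshape(2, 10)
    sim = extend_cdvs(X, [3, 2], [2, 1], "simultaneous")
    assert sim.shape == (4, 7)  # length grows by p = 2
    pc = extend_cdvs(X, [3, 2], [2, 1], "per_channel")
    assert pc.shape == (8, 6)  # pooled p*(N-n) vectors of length m+1
    # channel-1 extension of row 0 inserts x1[6] inside the first block
    assert np.allclose(pc[0], [0, 2, 4, 6, 10, 11])
    # channel-2 extension of row 0 appends x2[2] after the second block
    assert np.allclose(pc[4], [0, 2, 4, 10, 11, 12])


def test_extension_variants_agree_for_single_channel(rng):
    x = rng.standard_normal((1, 60))
    a = extend_cdvs(x, [2], [1], "simultaneous")
    b = extend_cdvs(x, [2], [1], "per_channel")
    assert np.array_equal(a, b)


# ---------------------------------------------------------------------------
# similarity counting
# ---------------------------------------------------------------------------


def test_similarity_hand_example():
    V = np.array([[0.0], [0.1], [0.3]])
    B_i, B = similarity_fraction(V, r=0.15)
    assert np.allclose(B_i, [0.5, 0.5, 0.0])
    assert B == pytest.approx(1 / 3)


def test_similarity_extremes(rng):
    same = np.ones((5, 3))
    B_i, B = similarity_fraction(same, r=0.1)
    assert np.all(B_i == 1) and B == 1
    far = np.repeat(np.arange(4.0)[:, None] * 10, 2, axis=1)
    _, B = similarity_fraction(far, r=0.5)
    assert B == 0


def test_similarity_needs_two_vectors():
    with pytest.raises(UndefinedSimilarityError):
        similarity_fraction(np.ones((1, 2)), r=0.1)


def test_tie_at_exactly_r_is_a_match():
    V = np.array([[0.0], [0.15]])
    _, B = similarity_fraction(V, r=0.15)
    assert B == 1.0


@pytest.mark.parametrize("method", ["sorted", "blocked"])
def test_match_counting_equals_naive_oracle(method, rng):
    """Both exact counting paths reproduce the brute-force double loop."""
    for _ in range(15):
        n = int(rng.integers(5, 60))
        d = int(rng.integers(1, 6))
        V = rng.standard_normal((n, d))
        r = float(rng.uniform(0.05, 1.5))
        got = match_counts(V, r, method=method, block_size=7)
        assert np.array_equal(got, naive_match_counts(V, r))


# ---------------------------------------------------------------------------
# entropy
# ---------------------------------------------------------------------------


def test_constant_signal_has_zero_entropy():
    # all base and extended vectors identical -> B^m = B^{m+1} = 1
    X = np.vstack([np.ones(40), np.ones(40)])
    value = mv_sample_entropy(X, MMSEParams(r=0.2))
    assert value == pytest.approx(0.0, abs=1e-12)


def test_entropy_matches_brute_force_oracle(rng):
    """-ln(B^{m+1}/B^m) recomputed from naive counts, p=2, N=60."""
    X = normalize_channels(rng.standard_normal((2, 60)))
    params = MMSEParams(r=0.4)
    got = mv_sample_entropy(X, params)
    base = build_cdvs(X, [2, 2], [1, 1])
    ext = extend_cdvs(X, [2, 2], [1, 1], "per_channel")
    cb = naive_match_counts(base, 0.4)
    ce = naive_match_counts(ext, 0.4)
    B_m = cb.mean() / (len(base) - 1)
    B_m1 = ce.mean() / (len(ext) - 1)
    assert got == pytest.approx(-np.log(B_m1 / B_m), rel=1e-12)


def test_iid_gaussian_closed_form_sanity(rng):
    """Univariate SampEn of iid normals approaches -ln(2*Phi(r/sqrt(2))-1)."""
    expected = -np.log(2 * norm.cdf(0.15 / np.sqrt(2)) - 1)
    x = normalize_channels(rng.standard_normal((1, 30_000)))
    got = mv_sample_entropy(x, MMSEParams(r=0.15))
    assert got == pytest.approx(expected, abs=0.1)


def test_entropy_invariant_to_channel_rescaling(rng):
    X = rng.standard_normal((2, 300))
    params = MMSEParams(r=0.4, eps_max=3)
    p1 = mmse_profile(X, params).values
    Y = X * np.array([[5.0], [0.2]]) + np.array([[3.0], [-1.0]])
    p2 = mmse_profile(Y, params).values
    assert np.allclose(p1, p2, atol=1e-12)


def test_variants_equal_for_single_channel(rng):
    x = rng.standard_normal((1, 500))
    a = mv_sample_entropy(normalize_channels(x), MMSEParams(r=0.3, variant="per_channel"))
    b = mv_sample_entropy(normalize_channels(x), MMSEParams(r=0.3, variant="simultaneous"))
    assert a == pytest.approx(b, rel=1e-12)


def test_per_channel_entropy_nonnegative_on_random_data(rng):
    for _ in range(10):
        p = int(rng.integers(1, 4))
        X = normalize_channels(rng.standard_normal((p, 120)))
        v = mv_sample_entropy(X, MMSEParams(r=0.8))
        assert np.isnan(v) or v >= 0


def test_undefined_entropy_is_nan(rng):
    # far-apart vectors at tiny r: zero matches
    x = np.arange(30.0)[None, :]
    v = mv_sample_entropy(x, MMSEParams(r=1e-6))
    assert np.isnan(v)


# ---------------------------------------------------------------------------
# profiles
# ---------------------------------------------------------------------------


def test_profile_single_scale_equals_entropy(rng):
    X = rng.standard_normal((2, 400))
    params = MMSEParams(r=0.4, eps_max=1)
    prof = mmse_profile(X, params)
    assert len(prof) == 1
    assert prof.values[0] == pytest.approx(
        mv_sample_entropy(normalize_channels(X), params)
    )


def test_profile_default_length_is_twelve(rng):
    prof = mmse_profile(rng.standard_normal((2, 6000)), MMSEParams(r=0.5))
    assert len(prof) == 12


def test_profile_warns_when_sample_guideline_violated(rng):
    with pytest.warns(UserWarning, match="recommended minimum"):
        mmse_profile(rng.standard_normal((4, 3000)), MMSEParams(r=0.5))


def test_subject_profile_aggregates_epochs(rng):
    params = MMSEParams(r=0.5, eps_max=3)
    e1 = rng.standard_normal((2, 600))
    e2 = rng.standard_normal((2, 600))
    single = subject_profile([e1], params)
    assert np.allclose(single.values, mmse_profile(e1, params).values)
    both = subject_profile([e1, e2], params)
    expected = (mmse_profile(e1, params).values + mmse_profile(e2, params).values) / 2
    assert np.allclose(both.values, expected)
    assert np.all(both.n_epochs == 2)
    # two identical epochs average to the single-epoch profile
    dup = subject_profile([e1, e1], params)
    assert np.allclose(dup.values, single.values)


def test_subject_profile_requires_epochs():
    with pytest.raises(ValueError):
        subject_profile([], MMSEParams())
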