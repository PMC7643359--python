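"""Multivariate multiscale sample entropy (mMSE).

Sample entropy of a p-channel series is the negative log of the
conditional probability that composite delay vectors (concatenated
time-delay embeddings of all channels) which match within a Chebyshev
tolerance ``r`` in the m-dimensional space also match after the
embedding is extended by one sample.  Repeating the computation on
coarse-grained (block-averaged) copies of the signal yields a profile
over timescales: the mMSE vector.

Conventions
-----------
* Channels are normalized to zero mean / unit variance **once**, on the
  original (scale-1) series; coarse-grained copies are *not*
  re-standardized, so ``r`` is an absolute tolerance on that common
  scale (Costa-style multiscale convention).
* Similarity is non-strict: Chebyshev distance ``<= r`` is a match; ties
  at exactly ``r`` count.  Self-matches are always excluded.
* Two extension variants are provided.  ``per_channel`` (default,
  Ahmed-Mandic convention): the embedding of one channel at a time is
  grown by one sample, pooling ``p * (N - n)`` vectors of length
  ``m + 1``; the extra sample is inserted at the end of that channel's
  block, so vectors from different channel-extensions are compared on
  genuinely shifted coordinates.  ``simultaneous``: every channel gains
  its next sample, giving ``N - n`` vectors of length ``m + p``.
* Undefined entropies (zero match counts) propagate as NaN, never as
  infinities; profile aggregation skips them and records counts.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from .exceptions import (
    DegenerateChannelError,
    InsufficientSamplesError,
    UndefinedEntropyError,
    UndefinedSimilarityError,
)

logger = logging.getLogger(__name__)

Variant = Literal["per_channel", "simultaneous"]

try:  # compiled sliding-window counting kernel
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is a hard dependency
    _HAVE_NUMBA = False


# ---------------------------------------------------------------------------
# parameters / profile containers
# ---------------------------------------------------------------------------


def _as_int_tuple(value, p: int, name: str) -> tuple[int, ...]:
    if np.isscalar(value):
        out = (int(value),) * p
    else:
        out = tuple(int(v) for v in value)
    if len(out) != p:
        raise ValueError(f"{name} must have one entry per channel ({p}), got {len(out)}")
    if any(v < 1 for v in out):
        raise ValueError(f"all {name} entries must be >= 1, got {out}")
    return out


@dataclass(frozen=True)
class MMSEParams:
    """Parameters of the mMSE computation.

    Attributes
    ----------
    M : embedding vector, one dimension per channel (default all 2).
    tau : time-lag vector (default all 1).
    r : similarity threshold, absolute on unit-variance data (default .15).
    eps_max : largest coarse-graining scale (default 12).
    variant : composite-delay-vector extension rule (see module docstring).
    """

    M: int | Sequence[int] = 2
    tau: int | Sequence[int] = 1
    r: float = 0.15
    eps_max: int = 12
    variant: Variant = "per_channel"

    def __post_init__(self):
        if self.r <= 0:
            raise ValueError(f"similarity threshold r must be > 0, got {self.r}")
        if self.eps_max < 1:
            raise ValueError(f"eps_max must be >= 1, got {self.eps_max}")
        if self.variant not in ("per_channel", "simultaneous"):
            raise ValueError(f"unknown extension variant {self.variant!r}")

    def resolve(self, p: int) -> tuple[tuple[int, ...], tuple[int, ...]]:
        """Per-channel embedding and lag vectors for ``p`` channels."""
        return _as_int_tuple(self.M, p, "M"), _as_int_tuple(self.tau, p, "tau")

    def m_total(self, p: int) -> int:
        M, _ = self.resolve(p)
        return sum(M)

    def n_offset(self, p: int) -> int:
        """n = max(M) * max(tau): samples consumed by one delay vector."""
        M, tau = self.resolve(p)
        return max(M) * max(tau)


@dataclass
class MMSEProfile:
    """mMSE values over scales 1..eps_max for one (subject, channel set).

    Undefined scales are NaN.  ``n_epochs`` records, per scale, how many
    epochs contributed when the profile is an across-epoch average.
    """

    values: np.ndarray
    params: MMSEParams
    channel_set: str | None = None
    subject_id: str | None = None
    n_epochs: np.ndarray | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)

    def __len__(self) -> int:
        return len(self.values)

    @property
    def defined(self) -> np.ndarray:
        return ~np.isnan(self.values)


# ---------------------------------------------------------------------------
# elementary operations
# ---------------------------------------------------------------------------


def normalize_channels(X: np.ndarray) -> np.ndarray:
    """Center each channel to mean 0 and scale to sample SD 1 (ddof=1)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    sd = X.std(axis=1, ddof=1)
    if np.any(sd == 0) or not np.all(np.isfinite(sd)):
        bad = np.flatnonzero(~np.isfinite(sd) | (sd == 0))
        raise DegenerateChannelError(
            f"channel(s) {bad.tolist()} have zero or non-finite variance"
        )
    return (X - X.mean(axis=1, keepdims=True)) / sd[:, None]


def coarse_grain(x: np.ndarray, eps: int) -> np.ndarray:
    """Average ``x`` over disjoint windows of length ``eps``.

    The output has length floor(N / eps); trailing remainder samples are
    dropped.  ``eps=1`` is the identity.
    """
    x = np.asarray(x, dtype=float)
    eps = int(eps)
    if eps < 1:
        raise ValueError(f"scale factor must be >= 1, got {eps}")
    n_out = x.shape[-1] // eps
    if n_out == 0:
        raise InsufficientSamplesError(
            f"scale {eps} exceeds series length {x.shape[-1]}"
        )
    if eps == 1:
        return x.copy()
    return x[..., : n_out * eps].reshape(*x.shape[:-1], n_out, eps).mean(axis=-1)


def build_cdvs(
    X: np.ndarray,
    M: Sequence[int],
    tau: Sequence[int],
    extend_channel: int | Literal["all"] | None = None,
) -> np.ndarray:
    """Composite delay vectors of a p x N matrix.

    Row ``i`` (``i = 0..N-n-1``, ``n = max(M)*max(tau)``) concatenates,
    channel by channel, the lagged samples ``x_k[i + j*tau_k]`` for
    ``j = 0..m_k-1``.  With ``extend_channel=k`` the k-th block is one
    sample longer (the extended vectors of the sample-entropy
    conditional); ``extend_channel="all"`` lengthens every block.  The
    number of rows is always ``N - n`` with ``n`` computed from the base
    embedding: extension reaches at most sample ``i + m_k*tau_k <= N-1``,
    so no rows are lost.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    p, N = X.shape
    M = _as_int_tuple(M, p, "M")
    tau = _as_int_tuple(tau, p, "tau")
    n = max(M) * max(tau)
    rows = N - n
    if rows <= 0:
        raise InsufficientSamplesError(
            f"need N > max(M)*max(tau) = {n}, got N = {N}"
        )
    cols = []
    for k in range(p):
        extra = 1 if (extend_channel == "all" or k == extend_channel) else 0
        for j in range(M[k] + extra):
            start = j * tau[k]
            if start + rows > N:
                raise InsufficientSamplesError(
                    f"extension of channel {k} exceeds the series length"
                )
            cols.append(X[k, start : start + rows])
    return np.column_stack(cols)


# -- pairwise Chebyshev match counting --------------------------------------

if _HAVE_NUMBA:

    @njit(cache=True)
    def _count_sorted_kernel(V, r):  # pragma: no cover - compiled
        n, d = V.shape
        counts = np.zeros(n, np.int64)
        for i in range(n):
            j = i + 1
            while j < n and V[j, 0] - V[i, 0] <= r:
                ok = True
                for c in range(1, d):
                    if abs(V[i, c] - V[j, c]) > r:
                        ok = False
                        break
                if ok:
                    counts[i] += 1
                    counts[j] += 1
                j += 1
        return counts


def _match_counts_sorted(V: np.ndarray, r: float) -> np.ndarray:
    """Per-vector match counts via sort on the first coordinate plus a
    sliding window; candidate pairs are pruned to ``|v_i0 - v_j0| <= r``."""
    order = np.argsort(V[:, 0], kind="stable")
    counts = _count_sorted_kernel(np.ascontiguousarray(V[order]), float(r))
    out = np.empty(len(V), dtype=np.int64)
    out[order] = counts
    return out


def _match_counts_blocked(V: np.ndarray, r: float, block_size: int = 1024) -> np.ndarray:
    """Exact per-vector match counts by blocked vectorized Chebyshev
    distances; memory bounded by ``block_size * len(V)`` floats."""
    n, d = V.shape
    counts = np.zeros(n, dtype=np.int64)
    for start in range(0, n, block_size):
        stop = min(start + block_size, n)
        block = V[start:stop]
        dist = np.abs(block[:, None, 0] - V[None, :, 0])
        for c in range(1, d):
            np.maximum(dist, np.abs(block[:, None, c] - V[None, :, c]), out=dist)
        hits = dist <= r
        counts[start:stop] += hits.sum(axis=1)
    counts -= 1  # remove self-matches
    return counts


def match_counts(
    V: np.ndarray,
    r: float,
    method: Literal["auto", "sorted", "blocked"] = "auto",
    block_size: int = 1024,
) -> np.ndarray:
    """Number of other vectors within Chebyshev distance ``r`` of each
    vector (self-matches excluded).  All methods are exact."""
    V = np.atleast_2d(np.asarray(V, dtype=float))
    if method == "auto":
        method = "sorted" if _HAVE_NUMBA else "blocked"
    if method == "sorted":
        return _match_counts_sorted(V, r)
    if method == "blocked":
        return _match_counts_blocked(V, r, block_size=block_size)
    raise ValueError(f"unknown counting method {method!r}")


def similarity_fraction(
    V: np.ndarray,
    r: float,
    method: Literal["auto", "sorted", "blocked"] = "auto",
    block_size: int = 1024,
) -> tuple[np.ndarray, float]:
    """Per-vector similarity fractions and their mean.

    ``B_i = P_i / (count - 1)`` where ``P_i`` counts vectors ``j != i``
    with Chebyshev distance at most ``r``; the similarity coefficient
    ``B`` is the mean over ``i``.
    """
    V = np.atleast_2d(np.asarray(V, dtype=float))
    if len(V) < 2:
        raise UndefinedSimilarityError(
            f"similarity needs at least 2 vectors, got {len(V)}"
        )
    if r <= 0:
        raise ValueError(f"similarity threshold must be > 0, got {r}")
    counts = match_counts(V, r, method=method, block_size=block_size)
    B_i = counts / (len(V) - 1)
    return B_i, float(B_i.mean())


def extend_cdvs(
    X: np.ndarray,
    M: Sequence[int],
    tau: Sequence[int],
    variant: Variant = "per_channel",
) -> np.ndarray:
    """Extended composite delay vectors.

    ``per_channel``: for each channel k the embedding of channel k alone
    grows by one sample; the p stacks are pooled into ``p * (N - n)``
    vectors of length ``m + 1``.  ``simultaneous``: each of the
    ``N - n`` vectors gains one next sample per channel (length
    ``m + p``).  For p = 1 the two variants coincide.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    p = X.shape[0]
    if variant == "simultaneous":
        return build_cdvs(X, M, tau, extend_channel="all")
    if variant == "per_channel":
        stacks = [build_cdvs(X, M, tau, extend_channel=k) for k in range(p)]
        return np.vstack(stacks)
    raise ValueError(f"unknown extension variant {variant!r}")


def mv_sample_entropy(
    X: np.ndarray,
    params: MMSEParams,
    method: Literal["auto", "sorted", "blocked"] = "auto",
) -> float:
    """Multivariate sample entropy ``-ln(B^{m+1} / B^m)`` of one matrix.

    Returns NaN (with a log entry) when either match count is zero.  The
    input is assumed already normalized; see :func:`mmse_profile` for
    the full multiscale pipeline.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    p = X.shape[0]
    M, tau = params.resolve(p)

    base = build_cdvs(X, M, tau)
    _, B_m = similarity_fraction(base, params.r, method=method)
    if B_m == 0.0:
        logger.info("undefined entropy: zero matches among base vectors")
        return float("nan")

    # For the simultaneous variant the extended vectors reach one step
    # further into the series; guard the boundary explicitly.
    ext = extend_cdvs(X, M, tau, variant=params.variant)
    _, B_m1 = similarity_fraction(ext, params.r, method=method)
    if B_m1 == 0.0:
        logger.info("undefined entropy: zero matches among extended vectors")
        return float("nan")
    return float(-np.log(B_m1 / B_m))


def mmse_profile(
    X: np.ndarray,
    params: MMSEParams | None = None,
    method: Literal["auto", "sorted", "blocked"] = "auto",
    channel_set: str | None = None,
    subject_id: str | None = None,
) -> MMSEProfile:
    """mMSE vector of a p x N matrix over scales 1..eps_max.

    Channels are normalized to unit variance once (on the scale-1
    series); each scale coarse-grains every channel by ``eps`` and
    computes :func:`mv_sample_entropy` on the shortened matrix.  Scales
    with zero match counts yield NaN entries; a profile that is NaN at
    every scale raises :class:`UndefinedEntropyError`.
    """
    params = params or MMSEParams()
    X = normalize_channels(X)
    p, N = X.shape
    M, _ = params.resolve(p)

    n_coarse = N // params.eps_max
    recommended = p * 10 ** max(M)
    if n_coarse <= params.n_offset(p) or n_coarse < recommended:
        warnings.warn(
            f"only {n_coarse} samples at scale {params.eps_max}; "
            f"recommended minimum is p*10^max(M) = {recommended}",
            stacklevel=2,
        )

    values = np.empty(params.eps_max)
    for eps in range(1, params.eps_max + 1):
        Xc = coarse_grain(X, eps)
        values[eps - 1] = mv_sample_entropy(Xc, params, method=method)
    if np.all(np.isnan(values)):
        raise UndefinedEntropyError("entropy undefined at every scale")
    return MMSEProfile(values, params, channel_set=channel_set, subject_id=subject_id)


def subject_profile(
    epochs: Sequence[np.ndarray],
    params: MMSEParams | None = None,
    method: Literal["auto", "sorted", "blocked"] = "auto",
    channel_set: str | None = None,
    subject_id: str | None = None,
) -> MMSEProfile:
    """Element-wise mean of per-epoch mMSE profiles.

    Undefined (NaN) entries are skipped per scale; the number of epochs
    that contributed to each scale is recorded on the result.
    """
    params = params or MMSEParams()
    if len(epochs) == 0:
        raise ValueError("subject_profile requires at least one epoch")
    per_epoch = np.vstack(
        [mmse_profile(ep, params, method=method).values for ep in epochs]
    )
    counts = np.sum(~np.isnan(per_epoch), axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        values = np.nanmean(per_epoch, axis=0)
    if np.any(counts < len(epochs)):
        logger.info(
            "undefined entries skipped; epochs used per scale: %s", counts.tolist()
        )
    return MMSEProfile(
        values,
        params,
        channel_set=channel_set,
        subject_id=subject_id,
        n_epochs=counts,
    )
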