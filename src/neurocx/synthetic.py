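"""Seeded synthetic cohorts with known ground truth.

Two generation paths serve different test depths:

* **signal level** — multichannel noise mixtures whose mMSE profiles
  reproduce the qualitative shapes seen in resting EEG (white-dominated
  signals decay across scales, 1/f-dominated signals keep a flatter,
  higher coarse-scale tail), with a controllable pink/white balance and
  an optional 10 Hz oscillation shared across channels;
* **feature level** — 45-column predictor tables drawn from a known
  multivariate normal with ``gf`` a known sparse linear function of the
  features, for fast calibration of the inference stage.

Everything is deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import ConsistencyError, InvalidSpecError
from .io import MultichannelRecording, write_recording
from .schema import (
    ALL_SET_CHANNELS,
    FEATURE_COLUMNS,
    SEX_CODES,
    TEST_NAMES,
    TEST_SCALES,
)

ALPHA_FREQ_HZ = 10.0

#: Default factor loadings: equal loadings lambda with
#: 1 + 5*lambda^2 = 3.706, i.e. a first factor carrying ~61.8% of the
#: variance of six tests, the structure typical of fluid-intelligence
#: batteries.
DEFAULT_LOADING = 0.7356


# ---------------------------------------------------------------------------
# specs
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SignalSpec:
    """Parameters of one subject's synthetic multichannel signal.

    Each channel is ``pink_weight * pink + (1 - pink_weight) * white +
    alpha_amp * sin(2*pi*10*t + phase)`` with channel-wise independent
    unit-variance noise draws and an alpha phase shared across channels.
    """

    n_channels: int = 4
    n_samples: int = 10_240
    sampling_rate: float = 256.0
    pink_weight: float = 0.5
    alpha_amp: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_channels < 1 or self.n_samples < 1:
            raise InvalidSpecError(
                f"n_channels and n_samples must be >= 1, got "
                f"{self.n_channels}, {self.n_samples}"
            )
        if not 0.0 <= self.pink_weight <= 1.0:
            raise InvalidSpecError(f"pink_weight must be in [0, 1], got {self.pink_weight}")
        if self.sampling_rate <= 0:
            raise InvalidSpecError(f"sampling_rate must be > 0, got {self.sampling_rate}")


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of a feature-level synthetic cohort.

    ``true_beta`` is the effect of each of the 45 predictors on ``gf``;
    the residual is Normal(0, noise_sd^2).  ``feature_cov`` must be a
    symmetric PSD 45 x 45 matrix (identity by default).
    ``factor_loadings`` drive the six-test score battery.
    """

    n_subjects: int = 119
    true_beta: np.ndarray | Mapping[str, float] | None = None
    noise_sd: float = 1.0
    feature_cov: np.ndarray | None = None
    factor_loadings: Sequence[float] = field(default=(DEFAULT_LOADING,) * 6)
    seed: int = 0

    def __post_init__(self):
        if self.n_subjects < 3:
            raise InvalidSpecError(f"n_subjects must be >= 3, got {self.n_subjects}")
        if self.noise_sd < 0:
            raise InvalidSpecError(f"noise_sd must be >= 0, got {self.noise_sd}")
        if len(self.factor_loadings) != 6:
            raise InvalidSpecError("factor_loadings must have 6 entries")
        if not all(0 < l < 1 for l in self.factor_loadings):
            raise InvalidSpecError("factor loadings must lie in the open interval (0, 1)")

    def resolved_beta(self) -> np.ndarray:
        q = len(FEATURE_COLUMNS)
        if self.true_beta is None:
            return np.zeros(q)
        if isinstance(self.true_beta, Mapping):
            beta = np.zeros(q)
            for name, value in self.true_beta.items():
                if name not in FEATURE_COLUMNS:
                    raise InvalidSpecError(f"unknown feature name in true_beta: {name}")
                beta[FEATURE_COLUMNS.index(name)] = float(value)
            return beta
        beta = np.asarray(self.true_beta, dtype=float)
        if beta.shape != (q,):
            raise InvalidSpecError(f"true_beta must have shape ({q},), got {beta.shape}")
        return beta

    def resolved_cov(self) -> np.ndarray:
        q = len(FEATURE_COLUMNS)
        if self.feature_cov is None:
            return np.eye(q)
        cov = np.asarray(self.feature_cov, dtype=float)
        if cov.shape != (q, q):
            raise InvalidSpecError(f"feature_cov must be {q} x {q}, got {cov.shape}")
        if not np.allclose(cov, cov.T, atol=1e-10):
            raise InvalidSpecError("feature_cov must be symmetric")
        eigs = np.linalg.eigvalsh(cov)
        if eigs.min() < -1e-8 * max(1.0, eigs.max()):
            raise InvalidSpecError("feature_cov must be positive semidefinite")
        return cov


# ---------------------------------------------------------------------------
# signal-level generation
# ---------------------------------------------------------------------------


def pink_noise(n_samples: int, rng: np.random.Generator, n_channels: int = 1) -> np.ndarray:
    """Gaussian 1/f noise by spectral shaping.

    The rFFT of white noise is weighted by 1/sqrt(f) (DC bin zeroed) and
    inverted; each channel is scaled to unit sample variance.
    """
    freqs = np.fft.rfftfreq(n_samples)
    amp = np.zeros_like(freqs)
    amp[1:] = 1.0 / np.sqrt(freqs[1:])
    z = rng.standard_normal((n_channels, freqs.size)) + 1j * rng.standard_normal(
        (n_channels, freqs.size)
    )
    x = np.fft.irfft(z * amp, n=n_samples)
    sd = x.std(axis=1, ddof=1, keepdims=True)
    sd[sd == 0] = 1.0
    return x / sd


def generate_subject_signal(spec: SignalSpec) -> MultichannelRecording:
    """Generate one subject's multichannel recording from its spec."""
    rng = np.random.default_rng(spec.seed)
    t = np.arange(spec.n_samples) / spec.sampling_rate
    phase = rng.uniform(0, 2 * np.pi)  # alpha phase shared across channels
    pink = pink_noise(spec.n_samples, rng, spec.n_channels)
    white = rng.standard_normal((spec.n_channels, spec.n_samples))
    data = (
        spec.pink_weight * pink
        + (1.0 - spec.pink_weight) * white
        + spec.alpha_amp * np.sin(2 * np.pi * ALPHA_FREQ_HZ * t + phase)
    )
    labels = [
        ALL_SET_CHANNELS[i] if i < len(ALL_SET_CHANNELS) else f"CH{i}"
        for i in range(spec.n_channels)
    ]
    return MultichannelRecording(
        data,
        labels,
        sampling_rate=spec.sampling_rate,
        subject_id=f"sim{spec.seed:05d}",
    )


# ---------------------------------------------------------------------------
# feature-level generation
# ---------------------------------------------------------------------------


def _sex_labels(n: int) -> list[str]:
    return [SEX_CODES[i % 2] for i in range(n)]


def generate_feature_table(spec: CohortSpec) -> pd.DataFrame:
    """Draw a feature table with a known linear feature -> gf map.

    Rows are MVN(0, feature_cov); ``gf = features @ true_beta +
    Normal(0, noise_sd^2)``; sex alternates M/W.  Note the 45 columns are
    free draws here: the between-set difference columns are *not*
    constrained to equal the corresponding per-set differences (that
    identity is guaranteed only for tables assembled from profiles).
    """
    rng = np.random.default_rng(spec.seed)
    beta = spec.resolved_beta()
    cov = spec.resolved_cov()
    chol_cov = np.linalg.cholesky(cov + 1e-12 * np.eye(cov.shape[0]))
    X = rng.standard_normal((spec.n_subjects, cov.shape[0])) @ chol_cov.T
    gf = X @ beta + rng.normal(0.0, spec.noise_sd, size=spec.n_subjects)
    table = pd.DataFrame(X, columns=list(FEATURE_COLUMNS))
    table.insert(0, "gf", gf)
    table.insert(0, "sex", _sex_labels(spec.n_subjects))
    table.insert(0, "subject_id", [f"S{i:04d}" for i in range(spec.n_subjects)])
    return table


def generate_test_scores(
    gf: np.ndarray | pd.Series,
    loadings: Sequence[float] = (DEFAULT_LOADING,) * 6,
    seed: int = 0,
) -> pd.DataFrame:
    """Six test-score columns with a single-factor structure.

    ``score_j = loading_j * gf + sqrt(1 - loading_j^2) * noise`` on the
    standardized scale, then mapped affinely onto each test's plausible
    raw range.  Loadings must lie in the open interval (0, 1).
    """
    if len(loadings) != 6:
        raise InvalidSpecError("exactly six loadings are required")
    if not all(0 < l < 1 for l in loadings):
        raise InvalidSpecError("loadings must lie in the open interval (0, 1)")
    gf = np.asarray(gf, dtype=float)
    rng = np.random.default_rng(seed)
    cols = {}
    for name, lam in zip(TEST_NAMES, loadings):
        std_score = lam * gf + np.sqrt(1.0 - lam**2) * rng.standard_normal(gf.size)
        mean, sd = TEST_SCALES[name]
        cols[name] = mean + sd * std_score
    return pd.DataFrame(cols)


# ---------------------------------------------------------------------------
# end-to-end cohorts
# ---------------------------------------------------------------------------


def linked_signal_specs(
    n_subjects: int,
    pink_range: tuple[float, float] = (0.0, 0.4),
    n_channels: int = len(ALL_SET_CHANNELS),
    n_samples: int = 10_240,
    alpha_amp: float = 0.0,
    seed: int = 0,
) -> dict[str, SignalSpec]:
    """Per-subject specs whose pink/white balance increases across the
    cohort — the complexity-driving parameter later linked to gf."""
    lo, hi = pink_range
    weights = np.linspace(lo, hi, n_subjects)
    return {
        f"S{i:04d}": SignalSpec(
            n_channels=n_channels,
            n_samples=n_samples,
            pink_weight=float(w),
            alpha_amp=alpha_amp,
            seed=seed * 100_003 + i,
        )
        for i, w in enumerate(weights)
    }


def generate_end_to_end_cohort(
    cohort_spec: CohortSpec,
    signal_spec_map: Mapping[str, SignalSpec],
) -> tuple[dict[str, MultichannelRecording], pd.Series]:
    """Recordings plus gf scores tied linearly to each subject's
    pink/white balance.

    gf is the standardized pink_weight plus Normal(0, noise_sd^2) noise,
    so subjects with more 1/f character in their signals systematically
    score higher — the ground truth for end-to-end recovery tests.
    """
    if not signal_spec_map:
        raise ConsistencyError("signal_spec_map is empty")
    if len(signal_spec_map) != cohort_spec.n_subjects:
        raise ConsistencyError(
            f"cohort_spec.n_subjects = {cohort_spec.n_subjects} but "
            f"{len(signal_spec_map)} signal specs were provided"
        )
    subjects = sorted(signal_spec_map)
    weights = np.array([signal_spec_map[s].pink_weight for s in subjects])
    if np.ptp(weights) == 0:
        raise ConsistencyError(
            "signal specs must vary pink_weight across subjects"
        )
    rng = np.random.default_rng(cohort_spec.seed)
    gf_raw = (weights - weights.mean()) / weights.std(ddof=1)
    gf = gf_raw + rng.normal(0.0, cohort_spec.noise_sd, size=len(subjects))
    recordings = {}
    for s in subjects:
        rec = generate_subject_signal(signal_spec_map[s])
        rec.subject_id = s
        recordings[s] = rec
    return recordings, pd.Series(gf, index=subjects, name="gf")


def write_cohort(
    recordings: Mapping[str, MultichannelRecording],
    cohort: pd.DataFrame,
    out_dir: str | Path,
) -> Path:
    """Write per-subject delimited signal files plus a cohort CSV."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for subject, rec in recordings.items():
        write_recording(rec, out_dir / f"{subject}.csv")
    cohort.to_csv(out_dir / "cohort.csv", index=False, float_format="%.12g")
    return out_dir
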