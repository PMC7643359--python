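"""Scalar complexity features of mMSE profiles and the predictor table.

Each 12-scale profile is reduced to three summaries: AUC (trapezoidal
area over the scale index — overall complexity), MaxSlope (maximum
pairwise slope among scales 1-4 — fine-scale complexity change, signed)
and AvgEnt (mean of scales 9-12 — coarse-scale baseline entropy).  The
full predictor table has 27 per-set features plus 18 between-set
differences (first-named minus second-named set).
"""

from __future__ import annotations

import itertools
import logging
from typing import Mapping

import numpy as np
import pandas as pd

from .entropy import MMSEProfile
from .schema import (
    DIFF_PAIRS,
    FEATURE_COLUMNS,
    ID_COLUMNS,
    PROFILE_FEATURES,
    SET_NAMES,
)

logger = logging.getLogger(__name__)


def _values(profile) -> np.ndarray:
    if isinstance(profile, MMSEProfile):
        return profile.values
    return np.asarray(profile, dtype=float)


def _require_defined(v: np.ndarray, what: str) -> None:
    if np.any(np.isnan(v)):
        raise ValueError(f"{what} undefined: profile has NaN entries")


def auc(profile) -> float:
    """Trapezoidal area under the profile with unit scale spacing."""
    v = _values(profile)
    if len(v) < 2:
        raise ValueError("AUC needs a profile of length >= 2")
    _require_defined(v, "AUC")
    return float(np.trapezoid(v))


def max_slope(profile) -> float:
    """Signed maximum pairwise slope among the first four scales.

    ``max over 1 <= i < j <= 4 of (v_j - v_i) / (j - i)``; negative when
    the fine-scale profile only falls.
    """
    v = _values(profile)
    if len(v) < 4:
        raise ValueError("MaxSlope needs a profile of length >= 4")
    head = v[:4]
    _require_defined(head, "MaxSlope")
    slopes = [
        (head[j] - head[i]) / (j - i)
        for i, j in itertools.combinations(range(4), 2)
    ]
    return float(max(slopes))


def avg_ent(profile) -> float:
    """Mean of the last four (coarse) scales, 9-12 of a 12-scale profile."""
    v = _values(profile)
    if len(v) < 4:
        raise ValueError("AvgEnt needs a profile of length >= 4")
    tail = v[-4:]
    _require_defined(tail, "AvgEnt")
    return float(tail.mean())


_FEATURE_FUNCS = {"AUC": auc, "MaxSlope": max_slope, "AvgEnt": avg_ent}


def profile_features(profile) -> dict[str, float]:
    """All three scalar features of one profile."""
    return {name: fn(profile) for name, fn in _FEATURE_FUNCS.items()}


def assemble_features(
    profiles: Mapping[str, Mapping[str, MMSEProfile | np.ndarray]],
    gf: Mapping[str, float] | pd.Series,
    sex: Mapping[str, str] | pd.Series,
) -> pd.DataFrame:
    """Build the 45-predictor feature table from per-subject profiles.

    Parameters
    ----------
    profiles : mapping subject_id -> {set name -> profile}; all nine sets
        must be present, otherwise the subject is excluded with a log
        entry.
    gf, sex : per-subject factor score and sex code ("M"/"W").

    Returns
    -------
    DataFrame with columns ``subject_id, sex, gf`` plus the 45 feature
    columns, rows sorted by subject_id.  Difference columns equal the
    first-named minus the second-named set feature.
    """
    rows = []
    for subject in sorted(profiles):
        per_set = profiles[subject]
        missing = [s for s in SET_NAMES if s not in per_set]
        if missing:
            logger.warning(
                "subject %s excluded: missing channel sets %s", subject, missing
            )
            continue
        try:
            feats = {
                f"{feat}_{s}": _FEATURE_FUNCS[feat](per_set[s])
                for feat in PROFILE_FEATURES
                for s in SET_NAMES
            }
        except ValueError as exc:
            logger.warning("subject %s excluded: %s", subject, exc)
            continue
        for feat in PROFILE_FEATURES:
            for a, b in DIFF_PAIRS:
                feats[f"{feat}_{a}-{b}"] = feats[f"{feat}_{a}"] - feats[f"{feat}_{b}"]
        rows.append(
            {
                "subject_id": str(subject),
                "sex": sex[subject],
                "gf": float(gf[subject]),
                **feats,
            }
        )
    table = pd.DataFrame(rows, columns=list(ID_COLUMNS) + list(FEATURE_COLUMNS))
    return table.sort_values("subject_id", ignore_index=True)


def rename_external_columns(
    table: pd.DataFrame, mapping: Mapping[str, str]
) -> pd.DataFrame:
    """Map externally named feature columns onto the package schema.

    ``mapping`` sends external names to the canonical names in
    :data:`~neurocx.schema.FEATURE_COLUMNS`; useful when loading
    deposited feature files with different column spellings.
    """
    renamed = table.rename(columns=dict(mapping))
    unknown = [
        c
        for c in renamed.columns
        if c not in FEATURE_COLUMNS and c not in ID_COLUMNS
    ]
    if unknown:
        logger.warning("columns left unmapped: %s", unknown)
    return renamed
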