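"""Shared naming schema: channel sets, feature columns, test battery.

The nine 4-electrode scalp sets cover frontal, central, parietal and
middle (temporo-central) regions of the 10-20 montage.  Complexity
features are one row per subject: three profile summaries (AUC, MaxSlope,
AvgEnt) per channel set plus their differences over six set pairs that
contrast frontal vs parietal and left vs right hemispheres.
"""

from __future__ import annotations

# Nine named 4-channel scalp sets (10-20 labels, upper-case normalized).
CHANNEL_SETS: dict[str, tuple[str, str, str, str]] = {
    "F": ("F7", "F8", "F3", "F4"),
    "FL": ("FP1", "F7", "F3", "FC3"),
    "FR": ("FP2", "F8", "F4", "FC4"),
    "C": ("FZ", "CZ", "PZ", "OZ"),
    "P": ("P3", "P4", "P7", "P8"),
    "PL": ("P7", "P3", "O1", "PO3"),
    "PR": ("P8", "P4", "O2", "PO4"),
    "ML": ("T7", "C3", "CP5", "CP1"),
    "MR": ("T8", "C4", "CP6", "CP2"),
}

SET_NAMES: tuple[str, ...] = tuple(CHANNEL_SETS)

#: Set pairs whose feature differences (first minus second) are predictors.
DIFF_PAIRS: tuple[tuple[str, str], ...] = (
    ("F", "P"),
    ("FL", "PL"),
    ("FR", "PR"),
    ("FL", "FR"),
    ("PL", "PR"),
    ("ML", "MR"),
)

PROFILE_FEATURES: tuple[str, ...] = ("AUC", "MaxSlope", "AvgEnt")

#: 27 per-set columns, in feature-major order.
SET_FEATURE_COLUMNS: tuple[str, ...] = tuple(
    f"{feat}_{s}" for feat in PROFILE_FEATURES for s in SET_NAMES
)

#: 18 difference columns named ``<feat>_<A>-<B>``.
DIFF_FEATURE_COLUMNS: tuple[str, ...] = tuple(
    f"{feat}_{a}-{b}" for feat in PROFILE_FEATURES for a, b in DIFF_PAIRS
)

#: The 45 predictor columns of a feature table.
FEATURE_COLUMNS: tuple[str, ...] = SET_FEATURE_COLUMNS + DIFF_FEATURE_COLUMNS

#: Non-predictor columns of a feature table.
ID_COLUMNS: tuple[str, ...] = ("subject_id", "sex", "gf")

SEX_CODES: tuple[str, str] = ("M", "W")

#: The six reasoning tests whose scores carry the fluid-intelligence factor.
TEST_NAMES: tuple[str, ...] = (
    "RAPM",
    "CFT3",
    "Paper",
    "Analogies",
    "Number",
    "Pattern",
)

#: Plausible raw-score scales (mean, SD) used to map standardized
#: synthetic scores onto each test's range.
TEST_SCALES: dict[str, tuple[float, float]] = {
    "RAPM": (21.03, 4.18),
    "CFT3": (29.02, 4.92),
    "Paper": (10.45, 3.31),
    "Analogies": (21.76, 3.99),
    "Number": (10.72, 3.22),
    "Pattern": (9.42, 2.83),
}

#: Union of channels needed to compute every channel set.
ALL_SET_CHANNELS: tuple[str, ...] = tuple(
    dict.fromkeys(label for labels in CHANNEL_SETS.values() for label in labels)
)
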