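"""Recording and table IO, epoch extraction, channel-set selection.

Disk formats are deliberately plain: delimited text matrices with a
channel-label header for signals (EDF is also read), CSV for feature
tables.  Epoching takes disjoint, contiguous fixed-length windows from
sample 0 and applies a final absolute-amplitude rejection, mirroring the
last QC pass of a conventional EEG cleaning chain (the earlier
filter/ICA stages belong to upstream tools and are out of scope here).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import (
    FormatError,
    MissingChannelError,
    NoUsableEpochsError,
    SchemaError,
)
from .schema import CHANNEL_SETS, FEATURE_COLUMNS, ID_COLUMNS

logger = logging.getLogger(__name__)

DEFAULT_EPOCH_LENGTH = 10_240  # 40 s at 256 Hz
DEFAULT_AMP_THRESHOLD = 111.0  # uV, final-pass rejection
STANDARD_SAMPLING_RATE = 256.0


@dataclass
class MultichannelRecording:
    """Labeled multichannel time series (channels x samples)."""

    data: np.ndarray
    channel_labels: list[str]
    sampling_rate: float = STANDARD_SAMPLING_RATE
    subject_id: str = ""

    def __post_init__(self):
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        self.channel_labels = [str(l).upper() for l in self.channel_labels]
        if len(self.channel_labels) != self.data.shape[0]:
            raise SchemaError(
                f"{len(self.channel_labels)} labels for {self.data.shape[0]} channel rows"
            )
        if self.sampling_rate <= 0:
            raise SchemaError(f"sampling_rate must be > 0, got {self.sampling_rate}")
        if not np.all(np.isfinite(self.data)):
            raise SchemaError("recording contains non-finite values")
        if self.sampling_rate != STANDARD_SAMPLING_RATE:
            logger.warning(
                "sampling rate %.6g Hz differs from the standard %.6g Hz; "
                "the pipeline operates on sample counts",
                self.sampling_rate,
                STANDARD_SAMPLING_RATE,
            )

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


@dataclass
class Epoch:
    """One fixed-length window of a recording (channels x epoch_length)."""

    data: np.ndarray
    index: int


@dataclass(frozen=True)
class ChannelSetDef:
    """A named 4-channel scalp set."""

    name: str
    labels: tuple[str, str, str, str]

    def __post_init__(self):
        if len(self.labels) != 4:
            raise SchemaError(f"channel set {self.name} must have 4 labels")


#: The nine built-in channel sets.
BUILTIN_SETS: dict[str, ChannelSetDef] = {
    name: ChannelSetDef(name, labels) for name, labels in CHANNEL_SETS.items()
}


# ---------------------------------------------------------------------------
# recordings
# ---------------------------------------------------------------------------


def _read_delimited(path: Path, delimiter: str | None) -> tuple[np.ndarray, list[str]]:
    df = pd.read_csv(path, sep=delimiter, header=None, engine="python")
    first_row = df.iloc[0]
    first_col = df.iloc[:, 0]

    def _numeric(s) -> bool:
        try:
            float(s)
            return True
        except (TypeError, ValueError):
            return False

    if not any(_numeric(v) for v in first_row):
        # header row of channel labels; data rows are samples
        labels = [str(v) for v in first_row]
        data = df.iloc[1:].to_numpy(dtype=float).T
    elif not _numeric(first_col.iloc[0]):
        # channels as rows, label in the first field
        labels = [str(v) for v in first_col]
        data = df.iloc[:, 1:].to_numpy(dtype=float)
    else:
        raise SchemaError(
            f"{path}: no channel labels found (expected a header row or a label column)"
        )
    return data, labels


def read_recording(
    path: str | Path,
    format: str = "auto",
    subject_id: str | None = None,
    delimiter: str | None = None,
) -> MultichannelRecording:
    """Read a recording from EDF, delimited text, or an .npz matrix.

    Delimited files may be oriented either way: a header row of channel
    labels over sample rows, or one row per channel with the label in
    the first field.  Labels are upper-cased on read.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "auto":
        suffix = path.suffix.lower()
        format = {
            ".edf": "edf",
            ".npz": "binary",
            ".csv": "delimited",
            ".tsv": "delimited",
            ".txt": "delimited",
            ".dat": "delimited",
        }.get(suffix, "")
        if not format:
            raise FormatError(f"cannot infer format from suffix {suffix!r}")

    if format == "edf":
        import mne

        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
        data = raw.get_data() * 1e6  # volts -> microvolts
        labels = list(raw.ch_names)
        rate = float(raw.info["sfreq"])
    elif format == "delimited":
        data, labels = _read_delimited(path, delimiter)
        rate = STANDARD_SAMPLING_RATE
    elif format == "binary":
        with np.load(path, allow_pickle=False) as npz:
            data = npz["data"]
            labels = [str(l) for l in npz["labels"]]
            rate = float(npz["sampling_rate"]) if "sampling_rate" in npz else STANDARD_SAMPLING_RATE
    else:
        raise FormatError(f"unknown recording format {format!r}")

    return MultichannelRecording(
        data, labels, sampling_rate=rate, subject_id=subject_id or path.stem
    )


def write_recording(rec: MultichannelRecording, path: str | Path) -> Path:
    """Write a recording as delimited text: header row of channel labels,
    one row per sample."""
    path = Path(path)
    df = pd.DataFrame(rec.data.T, columns=rec.channel_labels)
    df.to_csv(path, index=False, float_format="%.12g")
    return path


# ---------------------------------------------------------------------------
# epochs and channel sets
# ---------------------------------------------------------------------------


def extract_epochs(
    rec: MultichannelRecording,
    epoch_length: int = DEFAULT_EPOCH_LENGTH,
    amp_threshold: float | None = DEFAULT_AMP_THRESHOLD,
) -> list[Epoch]:
    """Cut disjoint contiguous epochs from sample 0 and reject on amplitude.

    floor(N / epoch_length) candidates are taken; any epoch in which any
    channel sample satisfies ``|x| > amp_threshold`` is dropped.  Order
    is preserved.  ``amp_threshold=None`` disables rejection.
    """
    if epoch_length < 1:
        raise ValueError(f"epoch_length must be >= 1, got {epoch_length}")
    if rec.n_samples < epoch_length:
        raise NoUsableEpochsError(
            f"recording has {rec.n_samples} samples, epoch length is {epoch_length}"
        )
    n_cand = rec.n_samples // epoch_length
    epochs: list[Epoch] = []
    n_dropped = 0
    for i in range(n_cand):
        window = rec.data[:, i * epoch_length : (i + 1) * epoch_length]
        if amp_threshold is not None and np.any(np.abs(window) > amp_threshold):
            n_dropped += 1
            continue
        epochs.append(Epoch(window, index=i))
    if n_dropped:
        logger.info(
            "subject %s: dropped %d/%d epochs over |amplitude| > %s",
            rec.subject_id,
            n_dropped,
            n_cand,
            amp_threshold,
        )
    if not epochs:
        raise NoUsableEpochsError(
            f"no usable epochs: all {n_cand} candidates exceeded "
            f"|amplitude| > {amp_threshold}"
        )
    return epochs


def select_channel_set(
    data: np.ndarray | Epoch,
    set_def: ChannelSetDef | str,
    labels: list[str] | None = None,
) -> np.ndarray:
    """Project a channels x samples matrix onto one 4-channel set.

    Rows are returned in the order of the set definition.  Matching is
    case-insensitive; if a label occurs twice in the recording the first
    occurrence is used (with a warning).
    """
    if isinstance(set_def, str):
        set_def = BUILTIN_SETS[set_def]
    matrix = data.data if isinstance(data, Epoch) else np.asarray(data, dtype=float)
    if labels is None:
        raise ValueError("channel labels are required to select a set")
    norm = [str(l).upper() for l in labels]
    index: dict[str, int] = {}
    for i, label in enumerate(norm):
        if label in index:
            logger.warning("duplicate channel label %s: first occurrence used", label)
        else:
            index[label] = i
    rows = []
    for label in set_def.labels:
        key = label.upper()
        if key not in index:
            raise MissingChannelError(
                f"channel {label} (set {set_def.name}) absent from recording"
            )
        rows.append(index[key])
    return matrix[rows]


# ---------------------------------------------------------------------------
# feature tables
# ---------------------------------------------------------------------------


def write_feature_table(table: pd.DataFrame, path: str | Path) -> Path:
    """Write a feature table as CSV, lossless to 12 significant digits."""
    missing = [c for c in ID_COLUMNS + FEATURE_COLUMNS if c not in table.columns]
    if missing:
        raise SchemaError(f"feature table is missing columns: {missing}")
    path = Path(path)
    cols = list(ID_COLUMNS) + list(FEATURE_COLUMNS)
    table[cols].to_csv(path, index=False, float_format="%.12g")
    return path


def read_feature_table(path: str | Path) -> pd.DataFrame:
    """Read and validate a feature-table CSV."""
    df = pd.read_csv(path)
    expected = set(ID_COLUMNS + FEATURE_COLUMNS)
    unknown = [c for c in df.columns if c not in expected]
    if unknown:
        raise SchemaError(f"unknown feature-table columns: {unknown}")
    missing = [c for c in ID_COLUMNS + FEATURE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"feature table is missing columns: {missing}")
    df["subject_id"] = df["subject_id"].astype(str)
    return df[list(ID_COLUMNS) + list(FEATURE_COLUMNS)]
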