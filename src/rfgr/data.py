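"""Domain types and I/O for single-channel EEG segment data.

The dataset dialect is the public "epileptic seizure recognition" CSV: one
row per one-second segment, columns ``X1..X178`` of signal amplitudes and an
integer class label ``y`` in 1..5.  Longer single-subject recordings of
4,097 samples (~23.6 s) are chunked into 23 such segments.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

#: samples per segment (one second of recording)
SEGMENT_LENGTH = 178
#: samples per subject recording
RECORDING_LENGTH = 4097
#: segments obtained from one recording
CHUNKS_PER_RECORDING = RECORDING_LENGTH // SEGMENT_LENGTH  # 23
#: minimum trace length that still tiles into 23 chunks exactly
MIN_RECORDING_LENGTH = CHUNKS_PER_RECORDING * SEGMENT_LENGTH  # 4094

FEATURE_COLUMNS = [f"X{i}" for i in range(1, SEGMENT_LENGTH + 1)]
LABEL_COLUMN = "y"


class FormatError(ValueError):
    """Malformed input file (wrong columns, non-numeric cells)."""


class LabelError(ValueError):
    """Unknown class-label code."""


@dataclass(frozen=True, order=True)
class ClassLabel:
    """One of the five brain-activity classes.

    The code convention follows the public dataset: 1 = epileptic seizure,
    2 = tumor brain area, 3 = healthy brain area, 4 = eyes closed,
    5 = eyes open.  An alternate coding can be declared by constructing
    labels directly; :func:`class_labels` returns the default set.
    """

    code: int
    name: str = field(compare=False)

    def __post_init__(self) -> None:
        if not isinstance(self.code, (int, np.integer)) or isinstance(self.code, bool):
            raise LabelError(f"label code must be an integer, got {self.code!r}")


_DEFAULT_NAMES = {
    1: "epileptic seizure",
    2: "tumor brain area",
    3: "healthy brain area",
    4: "eyes closed",
    5: "eyes open",
}


def class_labels() -> list[ClassLabel]:
    """The five default labels, in ascending code order."""
    return [ClassLabel(code, name) for code, name in sorted(_DEFAULT_NAMES.items())]


def label_from_code(code: int) -> ClassLabel:
    try:
        return ClassLabel(int(code), _DEFAULT_NAMES[int(code)])
    except (KeyError, TypeError, ValueError):
        raise LabelError(
            f"unknown label code {code!r}; expected one of {sorted(_DEFAULT_NAMES)}"
        ) from None


@dataclass(frozen=True)
class EEGRecording:
    """One subject's single-channel trace, nominally 4,097 samples / 23.6 s."""

    subject_id: str
    amplitudes: np.ndarray
    label: ClassLabel
    nominal_duration_s: float = 23.6

    def __post_init__(self) -> None:
        amp = np.asarray(self.amplitudes, dtype=float)
        object.__setattr__(self, "amplitudes", amp)
        if amp.ndim != 1 or amp.size < MIN_RECORDING_LENGTH:
            raise ValueError(
                f"recording needs at least {MIN_RECORDING_LENGTH} samples, "
                f"got shape {amp.shape}"
            )
        if not np.all(np.isfinite(amp)):
            raise ValueError("recording contains non-finite amplitudes")


@dataclass(frozen=True)
class EEGSegment:
    """One 178-sample labeled observation (a single dataset row)."""

    amplitudes: np.ndarray
    label: ClassLabel
    source_subject: str = ""
    chunk_index: int = 0

    def __post_init__(self) -> None:
        amp = np.asarray(self.amplitudes, dtype=float)
        object.__setattr__(self, "amplitudes", amp)
        if amp.shape != (SEGMENT_LENGTH,):
            raise ValueError(f"segment must have {SEGMENT_LENGTH} samples, got {amp.shape}")
        if not np.all(np.isfinite(amp)):
            raise ValueError("segment contains non-finite amplitudes")


class SegmentDataset:
    """An ordered collection of labeled segments.

    Stores the n x 178 amplitude matrix, the integer label codes, and
    per-row provenance (source subject, chunk index) side by side.
    """

    def __init__(
        self,
        X: np.ndarray,
        label_codes: Sequence[int],
        sources: Sequence[str] | None = None,
        chunk_indices: Sequence[int] | None = None,
    ) -> None:
        X = np.asarray(X, dtype=float).reshape(-1, SEGMENT_LENGTH) if np.size(X) else np.empty((0, SEGMENT_LENGTH))
        y = np.asarray(label_codes, dtype=int)
        if X.shape[0] != y.shape[0]:
            raise ValueError("row count of X and labels differ")
        for code in np.unique(y):
            label_from_code(code)  # raises LabelError on unknown codes
        self.X = X
        self.y = y
        self.sources = list(sources) if sources is not None else [""] * len(y)
        self.chunk_indices = (
            list(chunk_indices) if chunk_indices is not None else [0] * len(y)
        )

    # -- construction ------------------------------------------------------
    @classmethod
    def from_segments(cls, segments: Sequence[EEGSegment]) -> "SegmentDataset":
        if not segments:
            return cls(np.empty((0, SEGMENT_LENGTH)), [])
        X = np.stack([s.amplitudes for s in segments])
        return cls(
            X,
            [s.label.code for s in segments],
            [s.source_subject for s in segments],
            [s.chunk_index for s in segments],
        )

    # -- container protocol ------------------------------------------------
    def __len__(self) -> int:
        return self.X.shape[0]

    def __getitem__(self, i: int) -> EEGSegment:
        return EEGSegment(
            self.X[i], label_from_code(self.y[i]), self.sources[i], self.chunk_indices[i]
        )

    def __iter__(self) -> Iterator[EEGSegment]:
        return (self[i] for i in range(len(self)))

    def subset(self, idx: Sequence[int]) -> "SegmentDataset":
        idx = np.asarray(idx, dtype=int)
        return SegmentDataset(
            self.X[idx],
            self.y[idx],
            [self.sources[i] for i in idx],
            [self.chunk_indices[i] for i in idx],
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.X, columns=FEATURE_COLUMNS)
        df[LABEL_COLUMN] = self.y
        return df


# ---------------------------------------------------------------------------
# CSV dialect
# ---------------------------------------------------------------------------

def read_segments_csv(path: str | Path) -> SegmentDataset:
    """Read a segment CSV (header ``X1..X178,y``).

    An optional leading unnamed identifier column is retained as the
    per-row source tag.  Raises :class:`FormatError` for missing/extra
    feature columns or non-numeric cells and :class:`LabelError` for
    unknown label codes.
    """
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    cols = list(df.columns)
    sources: list[str] | None = None
    if cols and cols[0] not in FEATURE_COLUMNS + [LABEL_COLUMN]:
        sources = df[cols[0]].astype(str).tolist()
        df = df.drop(columns=cols[0])
        cols = cols[1:]

    missing = [c for c in FEATURE_COLUMNS + [LABEL_COLUMN] if c not in cols]
    if missing:
        raise FormatError(f"{path}: missing column {missing[0]!r}")
    extra = [c for c in cols if c not in FEATURE_COLUMNS + [LABEL_COLUMN]]
    if extra:
        raise FormatError(f"{path}: unexpected column {extra[0]!r}")

    feats = df[FEATURE_COLUMNS]
    numeric = feats.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & ~feats.isna()
    if bad.any().any():
        row = int(np.nonzero(bad.any(axis=1).to_numpy())[0][0])
        raise FormatError(f"{path}: non-numeric cell in data row {row}")
    if numeric.isna().any().any():
        row = int(np.nonzero(numeric.isna().any(axis=1).to_numpy())[0][0])
        raise FormatError(f"{path}: missing value in data row {row}")

    labels = pd.to_numeric(df[LABEL_COLUMN], errors="coerce")
    if labels.isna().any():
        row = int(np.nonzero(labels.isna().to_numpy())[0][0])
        raise FormatError(f"{path}: non-numeric label in data row {row}")
    return SegmentDataset(
        numeric.to_numpy(dtype=float),
        labels.astype(int).to_numpy(),
        sources=sources,
    )


def write_segments_csv(dataset: SegmentDataset, path: str | Path) -> Path:
    """Write the dataset as ``X1..X178,y`` at full float precision."""
    path = Path(path)
    dataset.to_frame().to_csv(path, index=False)
    return path


# ---------------------------------------------------------------------------
# Chunking
# ---------------------------------------------------------------------------

def chunk_recording(recording: EEGRecording) -> list[EEGSegment]:
    """Cut a recording into 23 contiguous non-overlapping 178-sample segments.

    Windows are anchored at sample 0 (half-open ``[k*178, (k+1)*178)``);
    the trailing ``len - 23*178`` samples (3 for a canonical 4,097-sample
    trace) are discarded.  Every segment inherits the recording's label.
    """
    amp = recording.amplitudes
    if amp.size < MIN_RECORDING_LENGTH:
        raise ValueError(
            f"recording too short to chunk: {amp.size} < {MIN_RECORDING_LENGTH}"
        )
    return [
        EEGSegment(
            amp[k * SEGMENT_LENGTH : (k + 1) * SEGMENT_LENGTH],
            recording.label,
            recording.subject_id,
            k,
        )
        for k in range(CHUNKS_PER_RECORDING)
    ]


def class_distribution(dataset: SegmentDataset) -> dict[ClassLabel, int]:
    """Per-class segment counts; every default class appears (possibly 0)."""
    counts = Counter(int(c) for c in dataset.y)
    return {lab: counts.get(lab.code, 0) for lab in class_labels()}
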