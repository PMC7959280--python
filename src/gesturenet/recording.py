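"""Recordings, gesture annotations and epoch extraction.

A :class:`Recording` holds a multichannel EEG signal block (channels x
samples, microvolts) with its sampling rate and ordered channel labels.
Gesture annotations are rows of (label, hand, start_s, end_s) referring to
times within a recording; :func:`extract_epochs` slices the annotated
portions out as :class:`GestureEpoch` objects, the unit every downstream
stage (connectivity, community detection, feature extraction) operates on.

On-disk formats are deliberately plain: recordings as matrix text (CSV,
channels as rows, header line of channel labels, JSON sidecar with the
sampling rate), annotations as CSV, EDF supported read-only through mne.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: The nine-gesture vocabulary, and which hand may perform each.
GESTURE_HANDS: dict[str, frozenset[str]] = {
    "Bipolar Cautery": frozenset({"dominant"}),
    "Monopolar Cautery": frozenset({"dominant"}),
    "Blunt Dissection": frozenset({"dominant"}),
    "Tissue Grasping": frozenset({"non-dominant"}),
    "Retraction": frozenset({"dominant", "non-dominant"}),
    "Suturing": frozenset({"dominant", "non-dominant"}),
    "Needle Insertion": frozenset({"dominant", "non-dominant"}),
    "Surgical Thread Grasping": frozenset({"dominant", "non-dominant"}),
    "Idle": frozenset({"dominant", "non-dominant"}),
}

DOMINANT_GESTURES: tuple[str, ...] = tuple(
    g for g, h in GESTURE_HANDS.items() if "dominant" in h
)
NONDOMINANT_GESTURES: tuple[str, ...] = tuple(
    g for g, h in GESTURE_HANDS.items() if "non-dominant" in h
)

HANDS = ("dominant", "non-dominant")

#: Minimum epoch duration: two 1-second network layers.
MIN_EPOCH_S = 2.0


@dataclass
class Recording:
    """Channels x samples voltage block (microvolts) with metadata."""

    data: np.ndarray
    fs: float
    labels: list[str]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        self.labels = [str(x) for x in self.labels]
        if len(self.labels) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.labels)} labels for {self.data.shape[0]} channels"
            )
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("duplicate labels")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_samples / self.fs

    def copy_with(self, data: np.ndarray) -> "Recording":
        return Recording(data=np.asarray(data, dtype=float), fs=self.fs,
                         labels=list(self.labels))


@dataclass
class AnnotationTable:
    """Validated gesture annotations: label, hand, start_s, end_s."""

    rows: pd.DataFrame

    COLUMNS = ("label", "hand", "start_s", "end_s")

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.rows, columns=list(self.COLUMNS))
        for _, r in df.iterrows():
            _validate_annotation(r["label"], r["hand"], r["start_s"], r["end_s"])
        self.rows = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.rows)


def _validate_annotation(label: str, hand: str, start: float, end: float) -> None:
    if label not in GESTURE_HANDS:
        raise ValueError(f"unknown gesture label {label!r}")
    if hand not in HANDS:
        raise ValueError(f"unknown hand {hand!r}")
    if hand not in GESTURE_HANDS[label]:
        raise ValueError(f"gesture {label!r} is not performed by the {hand} hand")
    if not float(start) < float(end):
        raise ValueError(f"start {start} must be < end {end}")


@dataclass
class GestureEpoch:
    """One annotated gesture instance: a labelled slice of a Recording."""

    label: str
    hand: str
    recording: Recording
    subject: str = "S0"
    session: str = "R0"
    start_s: float = 0.0

    @property
    def duration(self) -> float:
        return self.recording.duration


# ---------------------------------------------------------------------------
# Recording I/O

def read_recording(path: str | Path, format: str = "matrix-text",
                   fs: float | None = None) -> Recording:
    """Read a recording from ``matrix-text`` (CSV) or ``edf``.

    Matrix text is channels-as-rows CSV whose header row holds channel
    labels; the sampling rate comes from the ``<path>.meta.json`` sidecar or
    the ``fs`` argument. No resampling is performed.
    """
    path = Path(path)
    if format == "matrix-text":
        with open(path) as fh:
            labels = [s.strip() for s in fh.readline().strip().split(",")]
            data = np.loadtxt(fh, delimiter=",", ndmin=2)
        if data.shape[0] != len(labels):
            raise ValueError(
                f"expected {len(labels)} channel rows, found {data.shape[0]}"
            )
        if fs is None:
            sidecar = path.with_name(path.name + ".meta.json")
            if not sidecar.exists():
                raise ValueError("sampling rate missing: no fs given, no sidecar")
            fs = float(json.loads(sidecar.read_text())["fs"])
        return Recording(data=data, fs=fs, labels=labels)
    if format == "edf":
        import mne  # optional dependency, EDF only

        raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
        return Recording(data=raw.get_data() * 1e6,  # volts -> microvolts
                         fs=float(raw.info["sfreq"]),
                         labels=list(raw.ch_names))
    raise ValueError(f"unknown format {format!r}")


def write_recording(recording: Recording, path: str | Path) -> None:
    """Write matrix-text CSV (labels header, channels as rows) + fs sidecar."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(",".join(recording.labels) + "\n")
        np.savetxt(fh, recording.data, delimiter=",", fmt="%.17g")
    sidecar = path.with_name(path.name + ".meta.json")
    sidecar.write_text(json.dumps({"fs": recording.fs}))


# ---------------------------------------------------------------------------
# Annotation I/O

def read_annotations(path: str | Path) -> AnnotationTable:
    """Read a gesture annotation CSV with header label,hand,start_s,end_s."""
    df = pd.read_csv(path)
    missing = set(AnnotationTable.COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"annotation file missing columns {sorted(missing)}")
    return AnnotationTable(rows=df[list(AnnotationTable.COLUMNS)])


def write_annotations(table: AnnotationTable, path: str | Path) -> None:
    table.rows.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Epoch extraction

def extract_epochs(recording: Recording, annotations: AnnotationTable,
                   subject: str = "S0", session: str = "R0") -> list[GestureEpoch]:
    """Slice the recording into one epoch per annotation row.

    Annotation times are half-open second intervals [start, end); the sample
    range is floor(start*fs) to floor(end*fs). Rows shorter than 2 s cannot
    support the two network layers the dynamic features need and are skipped
    with a log message; rows extending past the recording are an error.
    """
    epochs: list[GestureEpoch] = []
    for _, row in annotations.rows.iterrows():
        start, end = float(row["start_s"]), float(row["end_s"])
        if end > recording.duration + 1e-9:
            raise ValueError(
                f"annotation end {end} s exceeds recording "
                f"length {recording.duration} s"
            )
        if end - start < MIN_EPOCH_S:
            logger.info("skipping %.2f s annotation %r (< %g s)",
                        end - start, row["label"], MIN_EPOCH_S)
            continue
        i0 = int(np.floor(start * recording.fs))
        i1 = int(np.floor(end * recording.fs))
        sl = recording.copy_with(recording.data[:, i0:i1])
        epochs.append(GestureEpoch(label=row["label"], hand=row["hand"],
                                   recording=sl, subject=subject,
                                   session=session, start_s=start))
    return epochs
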