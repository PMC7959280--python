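"""Signal conditioning: DC removal, notch, band-pass, artifact projection,
surface Laplacian.

The chain mirrors standard operating-room EEG conditioning at 500 Hz:
per-channel DC offset subtraction, a 60 Hz line-noise notch, a 0.2-250 Hz
band-pass with 24 dB/octave steepness (4th-order Butterworth; a 250 Hz edge
equals Nyquist at fs=500 so the filter reduces to the 0.2 Hz high-pass),
topographic-PCA projection of user-marked artifact intervals, and a
nearest-neighbor surface Laplacian. All filters are applied forward-backward
(zero phase); the whole chain is deterministic.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal

from .montage import Montage
from .recording import Recording


@dataclass
class PreprocessConfig:
    notch_hz: float = 60.0
    notch_q: float = 30.0                 # quality factor of the line-noise notch
    band_hz: tuple[float, float] = (0.2, 250.0)
    slope_db_per_octave: int = 24         # 24 dB/octave -> 4th-order Butterworth
    artifact_corr_threshold: float = 0.9  # |corr| with artifact topography
    artifact_max_amplitude: float = 100.0 # uV RMS a brain component may reach
    artifact_max_components: int = 3
    laplacian_k: int = 4                  # nearest neighbors ("small" Laplacian)

    def __post_init__(self) -> None:
        lo, hi = self.band_hz
        if not 0 < lo < hi:
            raise ValueError("band edges must satisfy 0 < low < high")
        if self.slope_db_per_octave <= 0 or self.slope_db_per_octave % 6:
            raise ValueError("slope must be a positive multiple of 6 dB/octave")

    @property
    def butter_order(self) -> int:
        return self.slope_db_per_octave // 6

    @classmethod
    def from_json(cls, path: str | Path) -> "PreprocessConfig":
        doc = json.loads(Path(path).read_text())
        if "band_hz" in doc:
            doc["band_hz"] = tuple(doc["band_hz"])
        return cls(**doc)


def remove_dc(recording: Recording) -> Recording:
    """Subtract each channel's mean (running DC offset compensation)."""
    if recording.n_samples == 0:
        raise ValueError("empty recording")
    return recording.copy_with(
        recording.data - recording.data.mean(axis=1, keepdims=True))


def notch_filter(recording: Recording, config: PreprocessConfig | None = None) -> Recording:
    """Zero-phase IIR notch at the line frequency (default 60 Hz, Q=30)."""
    config = config or PreprocessConfig()
    nyq = recording.fs / 2
    if config.notch_hz >= nyq:
        raise ValueError(f"notch {config.notch_hz} Hz >= Nyquist {nyq} Hz")
    b, a = signal.iirnotch(config.notch_hz, config.notch_q, fs=recording.fs)
    return recording.copy_with(signal.filtfilt(b, a, recording.data, axis=1))


def bandpass_filter(recording: Recording, config: PreprocessConfig | None = None) -> Recording:
    """Zero-phase Butterworth band-pass; a high edge at/above Nyquist makes
    it a pure high-pass (the anti-aliasing role is already played by the
    acquisition hardware)."""
    config = config or PreprocessConfig()
    lo, hi = config.band_hz
    if lo <= 0:
        raise ValueError("low edge must be > 0")
    nyq = recording.fs / 2
    if hi >= nyq:
        sos = signal.butter(config.butter_order, lo, btype="highpass",
                            fs=recording.fs, output="sos")
    else:
        sos = signal.butter(config.butter_order, [lo, hi], btype="bandpass",
                            fs=recording.fs, output="sos")
    # the 0.2 Hz pole has a multi-second transient: pad generously so the
    # forward-backward pass stays symmetric away from the edges
    padlen = min(recording.n_samples - 2, int(3 * recording.fs / lo))
    return recording.copy_with(
        signal.sosfiltfilt(sos, recording.data, axis=1, padlen=padlen))


def read_artifact_intervals(path: str | Path) -> list[tuple[float, float]]:
    """CSV of visually marked artifact intervals (start_s, end_s)."""
    df = pd.read_csv(path)
    return [(float(r["start_s"]), float(r["end_s"])) for _, r in df.iterrows()]


def spatial_pca_artifact_removal(
    recording: Recording,
    artifact_intervals: list[tuple[float, float]],
    config: PreprocessConfig | None = None,
) -> Recording:
    """Project artifact topographies out of the whole recording.

    Spatial principal components are fitted on the concatenated user-marked
    intervals. The artifact topography is estimated from the channel vectors
    at the highest-amplitude moments of those intervals; components whose
    spatial correlation with it exceeds ``artifact_corr_threshold``, or
    whose RMS amplitude within the intervals exceeds
    ``artifact_max_amplitude``, are removed (up to
    ``artifact_max_components``, strongest first). Each removed component
    lowers the signal rank by one.
    """
    config = config or PreprocessConfig()
    if not artifact_intervals:
        return recording.copy_with(recording.data.copy())
    fs = recording.fs
    segs = []
    for start, end in artifact_intervals:
        if start < 0 or end > recording.duration + 1e-9 or start >= end:
            raise ValueError(f"artifact interval ({start}, {end}) outside recording")
        segs.append(recording.data[:, int(start * fs):int(end * fs)])
    art = np.concatenate(segs, axis=1)
    art = art - art.mean(axis=1, keepdims=True)

    # spatial PCA of the marked intervals
    u, s, _ = np.linalg.svd(art, full_matrices=False)
    rms = s / np.sqrt(max(art.shape[1], 1))

    # artifact topography: mean channel vector at the strongest samples
    amp = np.abs(art).max(axis=0)
    top_idx = np.argsort(amp)[-max(1, art.shape[1] // 20):]
    topo = art[:, top_idx].mean(axis=1)
    n = np.linalg.norm(topo)
    topo = topo / n if n > 0 else topo

    remove = []
    for k in range(u.shape[1]):
        if len(remove) >= config.artifact_max_components:
            break
        corr = abs(float(u[:, k] @ topo))
        if corr > config.artifact_corr_threshold or rms[k] > config.artifact_max_amplitude:
            remove.append(k)
    if not remove:
        return recording.copy_with(recording.data.copy())
    basis = u[:, remove]                       # channels x n_removed
    proj = np.eye(recording.n_channels) - basis @ basis.T
    return recording.copy_with(proj @ recording.data)


def surface_laplacian(recording: Recording, montage: Montage,
                      config: PreprocessConfig | None = None) -> Recording:
    """Nearest-neighbor surface Laplacian re-reference.

    Each channel is replaced by its value minus the mean of its k nearest
    montage neighbors — a spatial high-pass that removes activity common to
    a neighborhood and sharpens topography.
    """
    config = config or PreprocessConfig()
    k = config.laplacian_k
    n = recording.n_channels
    if k >= n:
        raise ValueError(f"laplacian_k={k} must be < channel count {n}")
    pos = montage.positions
    if pos.shape[0] != n:
        raise ValueError("montage channel count does not match recording")
    d = np.linalg.norm(pos[:, None, :] - pos[None, :, :], axis=2)
    np.fill_diagonal(d, np.inf)
    out = recording.data.copy()
    for i in range(n):
        nbrs = np.argsort(d[i])[:k]
        out[i] = recording.data[i] - recording.data[nbrs].mean(axis=0)
    return recording.copy_with(out)


def preprocess_chain(recording: Recording, montage: Montage | None = None,
                     artifact_intervals: list[tuple[float, float]] | None = None,
                     config: PreprocessConfig | None = None) -> Recording:
    """Full conditioning chain in study order: DC -> notch -> band-pass ->
    artifact projection -> surface Laplacian (Laplacian needs a montage)."""
    config = config or PreprocessConfig()
    rec = remove_dc(recording)
    rec = notch_filter(rec, config)
    rec = bandpass_filter(rec, config)
    rec = spatial_pca_artifact_removal(rec, artifact_intervals or [], config)
    if montage is not None:
        rec = surface_laplacian(rec, montage, config)
    return rec
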