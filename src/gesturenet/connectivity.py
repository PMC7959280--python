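"""Windowed coherence networks.

Each gesture epoch is cut into non-overlapping 1-second windows; within a
window, the magnitude-squared coherence

    C_ij(f) = |S_ij(f)|^2 / (S_ii(f) S_jj(f))

is estimated from Welch-averaged cross-spectra (Hann-tapered sub-segments
with 50% overlap) and averaged over the aggregation band to give one
weighted, undirected adjacency matrix Gamma per window — a network layer.
The stack of layers is the epoch's adjacency tensor, the input to
multilayer community detection and to every weighted-graph feature.

A single segment per window would make coherence identically 1; the
default (125-sample Hann sub-segments at 50% overlap, 7 per 1-s window at
fs=500) keeps the estimator non-degenerate with an acceptable bias floor
while resolving the physiological bands.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .recording import GestureEpoch, Recording


@dataclass
class ConnectivityConfig:
    window_s: float = 1.0
    subsegment_samples: int = 125
    subsegment_overlap: float = 0.5
    band_hz: tuple[float, float] = (1.0, 50.0)  # aggregation band for the mean

    def __post_init__(self) -> None:
        if not 0 <= self.subsegment_overlap < 1:
            raise ValueError("overlap must be in [0, 1)")
        lo, hi = self.band_hz
        if not 0 <= lo < hi:
            raise ValueError("aggregation band must satisfy 0 <= low < high")


@dataclass
class AdjacencyTensor:
    """N x N x T stack of per-window coherence matrices for one epoch."""

    values: np.ndarray
    labels: list[str]
    layer_s: float = 1.0
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 3 or v.shape[0] != v.shape[1]:
            raise ValueError("values must be N x N x T")
        if v.shape[2] < 2:
            raise ValueError("tensor needs at least 2 layers")
        self.values = v

    @property
    def n_nodes(self) -> int:
        return self.values.shape[0]

    @property
    def n_layers(self) -> int:
        return self.values.shape[2]

    def layer(self, r: int) -> np.ndarray:
        return self.values[:, :, r]


def window_epoch(epoch: GestureEpoch, config: ConnectivityConfig | None = None
                 ) -> list[np.ndarray]:
    """Cut the epoch into consecutive non-overlapping windows.

    The trailing remainder shorter than one window is discarded; an epoch
    yielding fewer than 2 windows is an error (no dynamics to measure).
    """
    config = config or ConnectivityConfig()
    n_win = int(config.window_s * epoch.recording.fs)
    data = epoch.recording.data
    t = data.shape[1] // n_win
    if t < 2:
        raise ValueError(
            f"epoch of {data.shape[1]} samples gives {t} windows (< 2)")
    return [data[:, r * n_win:(r + 1) * n_win] for r in range(t)]


def _welch_spectra(window: np.ndarray, fs: float, config: ConnectivityConfig
                   ) -> tuple[np.ndarray, np.ndarray]:
    """All-pairs Welch cross-spectra of one window.

    Returns (freqs, S) with S of shape (F, N, N); S[f] is the averaged
    cross-spectral matrix at frequency f. One FFT per (channel, segment),
    then an einsum over segments — algebraically identical to per-pair
    scipy.signal.csd with the same segmentation and taper.
    """
    n_ch, n_samp = window.shape
    nper = config.subsegment_samples
    step = max(1, int(round(nper * (1 - config.subsegment_overlap))))
    if n_samp < nper + step:
        raise ValueError("window too short for >= 2 spectral sub-segments")
    starts = range(0, n_samp - nper + 1, step)
    taper = sps.get_window("hann", nper)
    segs = np.stack([window[:, s:s + nper] for s in starts])   # (K, N, nper)
    segs = segs - segs.mean(axis=2, keepdims=True)
    fx = np.fft.rfft(segs * taper, axis=2)                     # (K, N, F)
    s = np.einsum("knf,kmf->fnm", fx, np.conj(fx)) / len(segs)
    freqs = np.fft.rfftfreq(nper, d=1 / fs)
    return freqs, s


def coherence_matrix(window: np.ndarray, fs: float,
                     config: ConnectivityConfig | None = None) -> np.ndarray:
    """Band-averaged magnitude-squared coherence adjacency of one window.

    Zero-variance channels leave coherence undefined; their rows/columns are
    set to 0 (diagonal stays 1). Output is symmetric with entries in [0, 1].
    """
    config = config or ConnectivityConfig()
    freqs, s = _welch_spectra(np.asarray(window, dtype=float), fs, config)
    auto = np.real(np.einsum("fnn->fn", s))                    # (F, N)
    dead = auto.max(axis=0) <= 0
    denom = auto[:, :, None] * auto[:, None, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        coh = np.abs(s) ** 2 / denom
    coh[~np.isfinite(coh)] = 0.0
    lo, hi = config.band_hz
    in_band = (freqs >= lo) & (freqs <= hi)
    c = coh[in_band].mean(axis=0)
    c = np.clip((c + c.T) / 2, 0.0, 1.0)
    c[dead, :] = 0.0
    c[:, dead] = 0.0
    np.fill_diagonal(c, 1.0)
    return c


def write_tensor(tensor: AdjacencyTensor, directory) -> None:
    """Serialize as one CSV per layer plus a JSON index (text-only format)."""
    import json
    from pathlib import Path

    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    for r in range(tensor.n_layers):
        np.savetxt(d / f"layer_{r:04d}.csv", tensor.layer(r),
                   delimiter=",", fmt="%.17g")
    (d / "index.json").write_text(json.dumps({
        "n_nodes": tensor.n_nodes, "n_layers": tensor.n_layers,
        "labels": tensor.labels, "layer_s": tensor.layer_s,
        "provenance": tensor.provenance}))


def read_tensor(directory) -> AdjacencyTensor:
    import json
    from pathlib import Path

    d = Path(directory)
    idx = json.loads((d / "index.json").read_text())
    layers = [np.loadtxt(d / f"layer_{r:04d}.csv", delimiter=",", ndmin=2)
              for r in range(idx["n_layers"])]
    return AdjacencyTensor(values=np.stack(layers, axis=2),
                           labels=idx["labels"], layer_s=idx["layer_s"],
                           provenance=idx.get("provenance", {}))


def build_tensor(epoch: GestureEpoch, config: ConnectivityConfig | None = None
                 ) -> AdjacencyTensor:
    """Coherence adjacency tensor of an epoch, layers in time order."""
    config = config or ConnectivityConfig()
    windows = window_epoch(epoch, config)
    fs = epoch.recording.fs
    layers = [coherence_matrix(w, fs, config) for w in windows]
    return AdjacencyTensor(
        values=np.stack(layers, axis=2),
        labels=list(epoch.recording.labels),
        layer_s=config.window_s,
        provenance={"label": epoch.label, "hand": epoch.hand,
                    "subject": epoch.subject, "session": epoch.session,
                    "band_hz": list(config.band_hz)},
    )
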