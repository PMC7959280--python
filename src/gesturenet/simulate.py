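"""Synthetic EEG-like recordings with planted connectivity and power.

The study's operating-room recordings are not public, so every downstream
stage is exercised on simulated data with a known ground truth. Each
gesture class plants (a) a coherence structure — channels in the same
coupling group share a band-limited latent oscillator, mixed with
independent noise according to a coupling strength in [0, 1] — and (b) a
class-specific broadband amplitude gain. Latents are band-pass-filtered
Gaussian noise rather than sinusoids, so in-band coherence is high but
below 1, as in real EEG. Epochs of variable duration are laid end-to-end
with idle noise gaps; class counts may be imbalanced, mirroring the uneven
gesture inventories of real surgeries. All randomness flows from a single
seed through per-epoch substreams, so a configuration is a reproducible
dataset.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal as sps

from .communities import PartitionMatrix
from .montage import Montage, simulated_montage
from .recording import AnnotationTable, Recording


@dataclass
class ClassSpec:
    """Planted structure of one gesture class."""

    label: str
    hand: str
    count: int
    groups: list[list[int]] = field(default_factory=list)
    band_hz: tuple[float, float] = (8.0, 12.0)
    coupling: float = 0.0        # in [0, 1]; 0 = independent channels
    power_gain: float = 1.0      # amplitude multiplier for the epoch

    def __post_init__(self) -> None:
        if not 0 <= self.coupling <= 1:
            raise ValueError("coupling must be in [0, 1]")
        if self.count < 1:
            raise ValueError("class count must be >= 1")
        flat = [i for g in self.groups for i in g]
        if len(flat) != len(set(flat)):
            raise ValueError(
                f"class {self.label!r}: overlapping coupling groups")


@dataclass
class SimulationConfig:
    n_channels: int
    classes: list[ClassSpec]
    fs: float = 500.0
    duration_range_s: tuple[float, float] = (2.0, 5.0)
    gap_range_s: tuple[float, float] = (0.5, 1.5)
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.duration_range_s
        if lo < 2.0:
            raise ValueError("minimum epoch duration is 2 s (two layers)")
        if hi < lo:
            raise ValueError("duration range inverted")
        for c in self.classes:
            for g in c.groups:
                if any(i < 0 or i >= self.n_channels for i in g):
                    raise ValueError(f"group channel index out of range in "
                                     f"class {c.label!r}")


def _bandlimited_noise(rng: np.random.Generator, n: int, fs: float,
                       band: tuple[float, float]) -> np.ndarray:
    """Unit-variance band-pass-filtered white noise."""
    x = rng.standard_normal(n + int(fs))  # pad to absorb filter transients
    lo, hi = band
    hi = min(hi, fs / 2 * 0.99)
    sos = sps.butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")
    y = sps.sosfiltfilt(sos, x)[int(fs) // 2:int(fs) // 2 + n]
    sd = y.std()
    return y / sd if sd > 0 else y


def _epoch_signal(spec: ClassSpec, n_channels: int, n_samples: int, fs: float,
                  noise_sd: float, rng: np.random.Generator) -> np.ndarray:
    data = rng.standard_normal((n_channels, n_samples))
    for group in spec.groups:
        latent = _bandlimited_noise(rng, n_samples, fs, spec.band_hz)
        c = spec.coupling
        for ch in group:
            own = _bandlimited_noise(rng, n_samples, fs, spec.band_hz)
            data[ch] = (rng.standard_normal(n_samples) * 0.5
                        + np.sqrt(c) * latent + np.sqrt(1 - c) * own)
    return data * (noise_sd * spec.power_gain)


def generate_dataset(config: SimulationConfig
                     ) -> tuple[Recording, AnnotationTable]:
    """One continuous recording plus its gesture annotation table.

    Epoch order is shuffled across classes; durations are uniform in the
    configured range; idle gaps of plain noise separate epochs. Identical
    configs (including seed) produce bit-identical output.
    """
    root = np.random.SeedSequence(config.seed)
    epoch_specs = [(spec, k) for spec in config.classes
                   for k in range(spec.count)]
    order_rng = np.random.default_rng(root.spawn(1)[0])
    order = order_rng.permutation(len(epoch_specs))
    streams = root.spawn(len(epoch_specs) + 1)[1:]

    labels = [f"CH{i + 1:03d}" for i in range(config.n_channels)]
    blocks: list[np.ndarray] = []
    rows = []
    t = 0.0
    lo_d, hi_d = config.duration_range_s
    lo_g, hi_g = config.gap_range_s
    for pos, idx in enumerate(order):
        spec, _ = epoch_specs[idx]
        rng = np.random.default_rng(streams[idx])
        dur = float(rng.uniform(lo_d, hi_d))
        n = int(round(dur * config.fs))
        gap_n = int(round(float(rng.uniform(lo_g, hi_g)) * config.fs))
        blocks.append(rng.standard_normal((config.n_channels, gap_n))
                      * config.noise_sd)
        t += gap_n / config.fs
        blocks.append(_epoch_signal(spec, config.n_channels, n, config.fs,
                                    config.noise_sd, rng))
        rows.append({"label": spec.label, "hand": spec.hand,
                     "start_s": t, "end_s": t + n / config.fs})
        t += n / config.fs
    data = np.concatenate(blocks, axis=1) if blocks else \
        np.zeros((config.n_channels, 0))
    rec = Recording(data=data, fs=config.fs, labels=labels)
    return rec, AnnotationTable(rows=pd.DataFrame(rows))


def planted_partition(config: SimulationConfig, label: str,
                      n_layers: int = 2) -> PartitionMatrix:
    """Ground-truth community structure of a class, constant across layers.

    Coupling groups become communities; channels outside any group are
    singletons. Useful as the reference in community-recovery experiments.
    """
    spec = next((c for c in config.classes if c.label == label), None)
    if spec is None:
        raise ValueError(f"no class labelled {label!r}")
    assign = np.zeros(config.n_channels, dtype=int)
    nxt = 1
    for group in spec.groups:
        for ch in group:
            assign[ch] = nxt
        nxt += 1
    for ch in range(config.n_channels):
        if assign[ch] == 0:
            assign[ch] = nxt
            nxt += 1
    return PartitionMatrix(
        assignments=np.tile(assign[:, None], (1, n_layers)),
        provenance={"planted": True, "label": label})


# ---------------------------------------------------------------------------
# Ready-made study-scale scenarios

def cortex_group_specs(montage: Montage, labels_hands: list[tuple[str, str]],
                       counts: list[int], coupling: float = 0.9,
                       power_step: float = 0.15) -> list[ClassSpec]:
    """Class specs that differ in which cortex-hemisphere blocks they couple.

    Class k couples a distinct pair of (cortex, hemisphere) channel blocks
    with an alpha-beta band that shifts per class, and carries a small
    class-specific amplitude gain — class-conditional structure in both
    connectivity and power, as the classifier expects of real gestures.
    """
    blocks = [montage.scope_members(cortex, hemi).tolist()
              for cortex in ("motor", "cognition", "perception")
              for hemi in ("left", "right")]
    blocks = [b for b in blocks if len(b) >= 2]
    specs = []
    for k, ((label, hand), count) in enumerate(zip(labels_hands, counts)):
        g1 = blocks[k % len(blocks)]
        g2 = blocks[(k + 3) % len(blocks)]
        groups = [g1] if g1 is g2 else [g1, [c for c in g2 if c not in g1]]
        lo = 6.0 + 3.0 * k
        specs.append(ClassSpec(
            label=label, hand=hand, count=count, groups=groups,
            band_hz=(lo, lo + 4.0), coupling=coupling,
            power_gain=1.0 + power_step * k))
    return specs


def save_ground_truth(config: SimulationConfig, path: str | Path) -> None:
    """Planted partitions and class effects, for recovery experiments."""
    doc = {
        "n_channels": config.n_channels,
        "seed": config.seed,
        "classes": [
            {"label": c.label, "hand": c.hand, "count": c.count,
             "groups": c.groups, "band_hz": list(c.band_hz),
             "coupling": c.coupling, "power_gain": c.power_gain,
             "partition": planted_partition(config, c.label)
             .assignments[:, 0].tolist()}
            for c in config.classes
        ],
    }
    Path(path).write_text(json.dumps(doc, indent=1))
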