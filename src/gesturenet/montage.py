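"""Electrode montage and cortex mapping.

The montage assigns every analysis channel to exactly one functional cortex
(motor, cognition or perception) and one hemisphere (left, right or
midline). The default layout models a 128-electrode headset: 119 analysis
channels (70 motor, 37 cognition, 12 perception), 7 excluded channels
(I1, Iz, I2, CPz, PO5, PO6, Oz) and 2 mastoid references. Electrode
positions are generated on a unit sphere; they are used only for surface
Laplacian neighborhoods and artifact topographies, where relative distance,
not exact scalp geometry, is what matters.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

CORTICES = ("motor", "cognition", "perception")
HEMISPHERES = ("left", "right", "midline")

#: Analysis-channel counts per functional cortex in the default montage.
DEFAULT_CORTEX_SIZES = {"motor": 70, "cognition": 37, "perception": 12}
DEFAULT_EXCLUDED = ("I1", "Iz", "I2", "CPz", "PO5", "PO6", "Oz")
DEFAULT_REFERENCES = ("M1", "M2")


@dataclass
class ChannelRecord:
    name: str
    position: np.ndarray  # 3-vector, arbitrary units
    cortex: str           # motor | cognition | perception | other
    hemisphere: str       # left | right | midline

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float).reshape(3)
        if self.cortex not in CORTICES + ("other",):
            raise ValueError(f"unknown cortex {self.cortex!r}")
        if self.hemisphere not in HEMISPHERES:
            raise ValueError(f"unknown hemisphere {self.hemisphere!r}")


@dataclass
class Montage:
    """Channel records plus excluded- and reference-channel lists."""

    channels: list[ChannelRecord]
    excluded: list[str] = field(default_factory=list)
    references: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [c.name for c in self.channels]
        if len(set(names)) != len(names):
            raise ValueError("duplicate channel names in montage")
        bad = set(names) & set(self.excluded)
        if bad:
            raise ValueError(f"analysis channels in excluded list: {sorted(bad)}")

    @property
    def labels(self) -> list[str]:
        return [c.name for c in self.channels]

    @property
    def n_channels(self) -> int:
        return len(self.channels)

    @property
    def positions(self) -> np.ndarray:
        return np.stack([c.position for c in self.channels])

    def cortex_members(self, cortex: str) -> np.ndarray:
        """Indices of analysis channels in the given cortex."""
        return np.array([i for i, c in enumerate(self.channels)
                         if c.cortex == cortex], dtype=int)

    def scope_members(self, cortex: str, hemisphere: str = "whole") -> np.ndarray:
        """Indices for a (cortex, hemisphere-scope) feature mask.

        ``hemisphere='whole'`` pools left, right and midline channels of the
        cortex; otherwise only the named hemisphere.
        """
        idx = []
        for i, c in enumerate(self.channels):
            if c.cortex != cortex:
                continue
            if hemisphere == "whole" or c.hemisphere == hemisphere:
                idx.append(i)
        return np.array(idx, dtype=int)

    def cortex_sizes(self) -> dict[str, int]:
        return {k: len(self.cortex_members(k)) for k in CORTICES}


def save_montage(montage: Montage, path: str | Path) -> None:
    doc = {
        "channels": [
            {"name": c.name, "position": c.position.tolist(),
             "cortex": c.cortex, "hemisphere": c.hemisphere}
            for c in montage.channels
        ],
        "excluded": list(montage.excluded),
        "references": list(montage.references),
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def load_montage(path: str | Path) -> Montage:
    """Load and validate a montage JSON config.

    Each channel entry must carry exactly one ``cortex`` string; a list (a
    channel mapped to two cortices) or a missing key is an error, as is any
    analysis channel that also appears in the excluded list.
    """
    doc = json.loads(Path(path).read_text())
    channels = []
    for entry in doc["channels"]:
        cortex = entry.get("cortex")
        if cortex is None:
            raise ValueError(f"channel {entry.get('name')!r} mapped to no cortex")
        if not isinstance(cortex, str):
            raise ValueError(
                f"channel {entry.get('name')!r} mapped to multiple cortices: {cortex}"
            )
        channels.append(ChannelRecord(
            name=entry["name"], position=np.asarray(entry["position"]),
            cortex=cortex, hemisphere=entry["hemisphere"]))
    return Montage(channels=channels, excluded=list(doc.get("excluded", [])),
                   references=list(doc.get("references", [])))


def _fibonacci_sphere(n: int) -> np.ndarray:
    """n roughly uniform points on the upper unit hemisphere (scalp-like)."""
    k = np.arange(n)
    golden = (1 + 5 ** 0.5) / 2
    theta = 2 * np.pi * k / golden
    # z in (0, 1]: electrodes sit on the upper half of the head sphere
    z = (k + 0.5) / n
    r = np.sqrt(1 - z ** 2)
    return np.stack([r * np.cos(theta), r * np.sin(theta), z], axis=1)


def _split_hemispheres(count: int) -> list[str]:
    """left/right split of a cortex; odd counts place one channel midline."""
    half = count // 2
    out = ["left"] * half + ["right"] * half
    if count % 2:
        out.append("midline")
    return out


def default_montage() -> Montage:
    """The shipped 128-position layout reproducing the study's channel counts.

    119 analysis channels split 70/37/12 across motor, cognition and
    perception; position hemisphere (sign of x) is made consistent with the
    assigned hemisphere label. The grouping into cortices is an
    approximation: only the group sizes, not the identity of individual
    electrodes, are constrained.
    """
    sizes = DEFAULT_CORTEX_SIZES
    n_total = sum(sizes.values()) + len(DEFAULT_EXCLUDED) + len(DEFAULT_REFERENCES)
    pos = _fibonacci_sphere(n_total)
    channels: list[ChannelRecord] = []
    prefix = {"motor": "MO", "cognition": "CO", "perception": "PE"}
    i_pos = 0
    for cortex in CORTICES:
        hemis = _split_hemispheres(sizes[cortex])
        for j, hemi in enumerate(hemis):
            p = pos[i_pos].copy()
            i_pos += 1
            # align geometric side with the assigned hemisphere
            if hemi == "left":
                p[0] = -abs(p[0]) - 1e-3
            elif hemi == "right":
                p[0] = abs(p[0]) + 1e-3
            else:
                p[0] = 0.0
            channels.append(ChannelRecord(
                name=f"{prefix[cortex]}{j + 1:03d}", position=p,
                cortex=cortex, hemisphere=hemi))
    return Montage(channels=channels, excluded=list(DEFAULT_EXCLUDED),
                   references=list(DEFAULT_REFERENCES))


def simulated_montage(n_motor: int = 8, n_cognition: int = 6,
                      n_perception: int = 4) -> Montage:
    """A small montage with the same cortex structure, for simulations."""
    sizes = {"motor": n_motor, "cognition": n_cognition, "perception": n_perception}
    pos = _fibonacci_sphere(sum(sizes.values()))
    channels = []
    prefix = {"motor": "MO", "cognition": "CO", "perception": "PE"}
    i_pos = 0
    for cortex in CORTICES:
        hemis = _split_hemispheres(sizes[cortex])
        for j, hemi in enumerate(hemis):
            p = pos[i_pos].copy()
            i_pos += 1
            if hemi == "left":
                p[0] = -abs(p[0]) - 1e-3
            elif hemi == "right":
                p[0] = abs(p[0]) + 1e-3
            else:
                p[0] = 0.0
            channels.append(ChannelRecord(
                name=f"{prefix[cortex]}{j + 1:03d}", position=p,
                cortex=cortex, hemisphere=hemi))
    return Montage(channels=channels)
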