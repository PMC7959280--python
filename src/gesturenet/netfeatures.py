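"""The 60-feature vector: 57 functional-brain-network + 3 spectral-power
features per gesture epoch.

Six feature families are evaluated per (cortex x hemisphere-scope) mask —
motor/cognition/perception crossed with left/right/whole — giving 9 values
each:

* flexibility          — fraction of successive-layer community changes,
                         f_i = 1 - (1/(T-1)) sum_r d(A_{i,r}, A_{i,r+1})
* integration          — mean allegiance P_ij to channels outside the cortex
* recruitment          — mean allegiance P_ij to other channels of the cortex
* search_information   — bits to follow the shortest path, -log2 of the
                         product of random-walk step probabilities along it
* strength             — total communication weight s_i = sum_j w_ij
* diffusion_efficiency — inverse mean-first-passage time of a random walk

Three whole-brain scalars (weighted transitivity, global efficiency with
edge lengths L_ij = 1/w_ij, mean global diffusion efficiency) and the mean
spectral power of each cortex (Welch PSD, 1-s Kaiser windows, 50% overlap)
complete the vector. Per-layer graph quantities are averaged over the
epoch's T layers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy.sparse import csgraph

from .communities import ModuleAllegianceMatrix, PartitionMatrix
from .connectivity import AdjacencyTensor
from .montage import CORTICES, Montage
from .recording import GestureEpoch

logger = logging.getLogger(__name__)

SCOPED_FAMILIES = ("flexibility", "integration", "recruitment",
                   "search_information", "strength", "diffusion_efficiency")
HEMI_SCOPES = ("left", "right", "whole")
GLOBAL_FEATURES = ("transitivity", "global_efficiency",
                   "mean_global_diffusion_efficiency")


def feature_names() -> list[str]:
    """The canonical, ordered 60 feature names."""
    names = [f"{fam}.{cortex}.{hemi}"
             for fam in SCOPED_FAMILIES
             for cortex in CORTICES
             for hemi in HEMI_SCOPES]
    names += list(GLOBAL_FEATURES)
    names += [f"power.{cortex}" for cortex in CORTICES]
    return names


@dataclass
class FeatureConfig:
    layer_aggregate: str = "mean"    # or "median", across the T layers
    kaiser_beta: float = 14.0        # PSD taper shape
    psd_band_hz: tuple[float, float] | None = None  # None = full passband
    time_averaged_gamma: bool = False  # one mean adjacency instead of per-layer

    def __post_init__(self) -> None:
        if self.layer_aggregate not in ("mean", "median"):
            raise ValueError("layer_aggregate must be 'mean' or 'median'")


# ---------------------------------------------------------------------------
# Dynamic (partition / allegiance) features

def flexibility(partition: PartitionMatrix | np.ndarray) -> np.ndarray:
    """Per-node flexibility f_i in [0, 1]; requires >= 2 layers."""
    a = partition.assignments if isinstance(partition, PartitionMatrix) \
        else np.asarray(partition, dtype=int)
    if a.ndim != 2 or a.shape[1] < 2:
        raise ValueError("flexibility needs an N x T partition with T >= 2")
    same = a[:, 1:] == a[:, :-1]
    return 1.0 - same.mean(axis=1)


def integration(mam: ModuleAllegianceMatrix | np.ndarray, members: np.ndarray,
                cortex_members: np.ndarray) -> float:
    """Mean allegiance of scope members to channels outside their cortex."""
    p = mam.values if isinstance(mam, ModuleAllegianceMatrix) else np.asarray(mam)
    n = p.shape[0]
    outside = np.setdiff1d(np.arange(n), cortex_members)
    if len(members) == 0 or len(outside) == 0:
        raise ValueError("integration needs non-empty scope and complement")
    return float(p[np.ix_(members, outside)].mean(axis=1).mean())


def recruitment(mam: ModuleAllegianceMatrix | np.ndarray, members: np.ndarray,
                cortex_members: np.ndarray) -> float:
    """Mean allegiance of scope members to the other channels of their cortex."""
    p = mam.values if isinstance(mam, ModuleAllegianceMatrix) else np.asarray(mam)
    if len(cortex_members) < 2:
        raise ValueError("recruitment needs a cortex with >= 2 channels")
    vals = []
    cset = set(cortex_members.tolist())
    for i in members:
        others = np.array(sorted(cset - {int(i)}), dtype=int)
        vals.append(p[i, others].mean())
    if not vals:
        raise ValueError("empty scope")
    return float(np.mean(vals))


# ---------------------------------------------------------------------------
# Weighted-graph features (per layer)

def _offdiag(g: np.ndarray) -> np.ndarray:
    a = np.asarray(g, dtype=float).copy()
    np.fill_diagonal(a, 0.0)
    return a


def _length_graph(a: np.ndarray) -> np.ndarray:
    """Connection-length matrix L_ij = 1/w_ij (0 encodes 'no edge')."""
    with np.errstate(divide="ignore"):
        l = np.where(a > 0, 1.0 / np.where(a > 0, a, 1.0), 0.0)
    return l


def shortest_paths(g: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """All-pairs shortest-path distances and predecessors under L = 1/w."""
    a = _offdiag(g)
    l = csgraph.csgraph_from_dense(_length_graph(a), null_value=0)
    dist, pred = csgraph.dijkstra(l, directed=False, return_predecessors=True)
    return dist, pred


def node_strengths(g: np.ndarray) -> np.ndarray:
    """s_i = sum_{j != i} w_ij."""
    return _offdiag(g).sum(axis=1)


def strength_scope(g: np.ndarray, members: np.ndarray) -> float:
    return float(node_strengths(g)[members].mean())


def search_information_matrix(g: np.ndarray) -> np.ndarray:
    """SI(i -> j) in bits for all ordered pairs; inf where no path.

    The walker follows the (unique scipy-reconstructed) shortest path under
    lengths 1/w; each step u -> v costs -log2(w_uv / s_u).
    """
    a = _offdiag(g)
    n = a.shape[0]
    s = a.sum(axis=1)
    dist, pred = shortest_paths(g)
    with np.errstate(divide="ignore", invalid="ignore"):
        logp = np.where(a > 0, np.log2(a / np.where(s[:, None] > 0,
                                                    s[:, None], 1.0)), -np.inf)
    si = np.full((n, n), np.inf)
    np.fill_diagonal(si, 0.0)
    for i in range(n):
        for j in range(n):
            if i == j or not np.isfinite(dist[i, j]):
                continue
            bits = 0.0
            v = j
            while v != i:
                u = pred[i, v]
                bits -= logp[u, v]
                v = u
            si[i, j] = bits
    return si


def search_information_scope(g: np.ndarray, members: np.ndarray,
                             si: np.ndarray | None = None) -> float:
    """Mean SI over ordered member pairs; unreachable pairs are excluded."""
    si = search_information_matrix(g) if si is None else si
    sub = si[np.ix_(members, members)]
    mask = ~np.eye(len(members), dtype=bool)
    vals = sub[mask]
    finite = vals[np.isfinite(vals)]
    n_inf = vals.size - finite.size
    if n_inf:
        logger.info("search information: %d unreachable pairs excluded", n_inf)
    return float(finite.mean()) if finite.size else 0.0


def mfpt_matrix(g: np.ndarray) -> np.ndarray:
    """Mean first passage times of the weighted random walk (inf across
    disconnected components), via the fundamental matrix per component."""
    a = _offdiag(g)
    n = a.shape[0]
    m = np.full((n, n), np.inf)
    np.fill_diagonal(m, 0.0)
    n_comp, comp = csgraph.connected_components(
        csgraph.csgraph_from_dense(a, null_value=0), directed=False)
    for c in range(n_comp):
        idx = np.flatnonzero(comp == c)
        if len(idx) < 2:
            continue
        sub = a[np.ix_(idx, idx)]
        s = sub.sum(axis=1)
        p = sub / s[:, None]
        pi = s / s.sum()
        z = np.linalg.inv(np.eye(len(idx)) - p + np.outer(np.ones(len(idx)), pi))
        mf = (np.diag(z)[None, :] - z) / pi[None, :]
        np.fill_diagonal(mf, 0.0)
        m[np.ix_(idx, idx)] = mf
    return m


def diffusion_efficiency_matrix(g: np.ndarray) -> np.ndarray:
    """E_diff(i, j) = 1 / MFPT(i, j); 0 for unreachable pairs, diag 0."""
    m = mfpt_matrix(g)
    with np.errstate(divide="ignore"):
        e = np.where(m > 0, 1.0 / m, 0.0)
    e[~np.isfinite(m)] = 0.0
    np.fill_diagonal(e, 0.0)
    return e


def diffusion_efficiency_scope(g: np.ndarray, members: np.ndarray,
                               e: np.ndarray | None = None) -> float:
    """Mean diffusion efficiency over ordered member pairs."""
    e = diffusion_efficiency_matrix(g) if e is None else e
    sub = e[np.ix_(members, members)]
    mask = ~np.eye(len(members), dtype=bool)
    return float(sub[mask].mean()) if mask.any() else 0.0


def transitivity(g: np.ndarray) -> float:
    """Weighted transitivity: closed triplets (geometric-mean weights,
    normalized by the maximum weight) over possible triplets."""
    a = _offdiag(g)
    if a.shape[0] < 3:
        raise ValueError("transitivity needs >= 3 nodes")
    w_max = a.max()
    if w_max <= 0:
        return 0.0
    cube = np.cbrt(a / w_max)
    t_i = np.diag(cube @ cube @ cube) / 2.0
    k = (a > 0).sum(axis=1)
    denom = (k * (k - 1)).sum()
    return float(2.0 * t_i.sum() / denom) if denom > 0 else 0.0


def global_efficiency(g: np.ndarray, dist: np.ndarray | None = None) -> float:
    """Mean inverse shortest-path length; unreachable pairs contribute 0."""
    n = np.asarray(g).shape[0]
    if n < 2:
        raise ValueError("global efficiency needs >= 2 nodes")
    if dist is None:
        dist, _ = shortest_paths(g)
    with np.errstate(divide="ignore"):
        inv = np.where(np.isfinite(dist) & (dist > 0), 1.0 / dist, 0.0)
    np.fill_diagonal(inv, 0.0)
    return float(inv.sum() / (n * (n - 1)))


# ---------------------------------------------------------------------------
# Spectral power

def psd_power(epoch: GestureEpoch, montage: Montage,
              config: FeatureConfig | None = None) -> dict[str, float]:
    """Mean signal power per cortex from 1-s Kaiser-windowed Welch PSD.

    Per channel, the PSD is integrated over frequency (optionally limited to
    ``psd_band_hz``), recovering the band-limited signal variance in uV^2;
    the cortex feature pools its member channels.
    """
    config = config or FeatureConfig()
    fs = epoch.recording.fs
    nper = int(fs)
    data = epoch.recording.data
    if data.shape[1] < nper:
        raise ValueError("epoch shorter than one PSD window")
    freqs, pxx = sps.welch(data, fs=fs, window=("kaiser", config.kaiser_beta),
                           nperseg=nper, noverlap=nper // 2, axis=1)
    if config.psd_band_hz is not None:
        lo, hi = config.psd_band_hz
        sel = (freqs >= lo) & (freqs <= hi)
        freqs, pxx = freqs[sel], pxx[:, sel]
    power = np.trapezoid(pxx, freqs, axis=1)
    return {f"power.{cortex}": float(power[montage.cortex_members(cortex)].mean())
            for cortex in CORTICES}


# ---------------------------------------------------------------------------
# Assembly

def _aggregate_layers(values: list[float], how: str) -> float:
    return float(np.median(values)) if how == "median" else float(np.mean(values))


def assemble_features(epoch: GestureEpoch, tensor: AdjacencyTensor,
                      partition: PartitionMatrix,
                      mam: ModuleAllegianceMatrix, montage: Montage,
                      config: FeatureConfig | None = None) -> dict[str, float]:
    """The full 60-value named feature vector for one epoch.

    Graph-family features are computed per layer and aggregated across the
    epoch's T layers (or once on the time-averaged adjacency when
    ``time_averaged_gamma`` is set). Any non-finite value is an error naming
    the offending feature.
    """
    config = config or FeatureConfig()
    scopes = {(cortex, hemi): montage.scope_members(cortex, hemi)
              for cortex in CORTICES for hemi in HEMI_SCOPES}
    cortex_all = {cortex: montage.cortex_members(cortex) for cortex in CORTICES}

    out: dict[str, float] = {}
    flex = flexibility(partition)
    for cortex in CORTICES:
        for hemi in HEMI_SCOPES:
            out[f"flexibility.{cortex}.{hemi}"] = float(
                flex[scopes[(cortex, hemi)]].mean())
    for cortex in CORTICES:
        for hemi in HEMI_SCOPES:
            out[f"integration.{cortex}.{hemi}"] = integration(
                mam, scopes[(cortex, hemi)], cortex_all[cortex])
    for cortex in CORTICES:
        for hemi in HEMI_SCOPES:
            out[f"recruitment.{cortex}.{hemi}"] = recruitment(
                mam, scopes[(cortex, hemi)], cortex_all[cortex])

    if config.time_averaged_gamma:
        layers = [tensor.values.mean(axis=2)]
    else:
        layers = [tensor.layer(r) for r in range(tensor.n_layers)]

    per_layer: dict[str, list[float]] = {}
    all_nodes = np.arange(tensor.n_nodes)
    for g in layers:
        si = search_information_matrix(g)
        ediff = diffusion_efficiency_matrix(g)
        dist, _ = shortest_paths(g)
        for cortex in CORTICES:
            for hemi in HEMI_SCOPES:
                mem = scopes[(cortex, hemi)]
                per_layer.setdefault(
                    f"search_information.{cortex}.{hemi}", []).append(
                    search_information_scope(g, mem, si=si))
                per_layer.setdefault(
                    f"strength.{cortex}.{hemi}", []).append(
                    strength_scope(g, mem))
                per_layer.setdefault(
                    f"diffusion_efficiency.{cortex}.{hemi}", []).append(
                    diffusion_efficiency_scope(g, mem, e=ediff))
        per_layer.setdefault("transitivity", []).append(transitivity(g))
        per_layer.setdefault("global_efficiency", []).append(
            global_efficiency(g, dist=dist))
        per_layer.setdefault("mean_global_diffusion_efficiency", []).append(
            diffusion_efficiency_scope(g, all_nodes, e=ediff))
    for name, vals in per_layer.items():
        out[name] = _aggregate_layers(vals, config.layer_aggregate)

    out.update(psd_power(epoch, montage, config))

    ordered = {name: out[name] for name in feature_names()}
    for name, val in ordered.items():
        if not np.isfinite(val):
            raise ValueError(f"non-finite feature {name!r} = {val}")
    return ordered


# ---------------------------------------------------------------------------
# Feature-table I/O

META_COLUMNS = ("label", "hand", "subject")


def write_feature_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False)


def read_feature_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in list(feature_names()) + list(META_COLUMNS)
               if c not in df.columns]
    if missing:
        raise ValueError(f"feature table missing columns {missing[:5]} ...")
    return df
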