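"""Multilayer community detection on coherence tensors.

A gesture epoch's adjacency tensor is treated as a multilayer network: each
1-s coherence matrix is a layer, and copies of the same channel in
different layers are coupled with strength omega (categorical topology —
all layer pairs — by default, ordinal — consecutive layers — as an
option). Partitions are found by greedily optimizing the multilayer
modularity

    Q = (1/2mu) sum_{ijlr} [ (Gamma_ijl - gamma_l k_il k_jl / (2m_l)) d_lr
                              + d_ij omega_jlr ] d(g_il, g_jr)

with a Newman-Girvan null per layer, using a Louvain-like locally greedy
algorithm. Because the optimizer is stochastic and modularity landscapes
are nearly degenerate, optimization is repeated (default 100 runs) and a
single representative partition is extracted by an iterative consensus
procedure thresholded against a permutation null. The module-allegiance
matrix (the probability that two channels share a community across runs
and layers) feeds the integration and recruitment features; the partition
matrix feeds flexibility.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .connectivity import AdjacencyTensor


@dataclass
class CommunityConfig:
    gamma: float = 1.0            # resolution of the Newman-Girvan null
    omega: float = 1.0            # inter-layer coupling strength
    topology: str = "categorical" # or "ordinal"
    repetitions: int = 100        # independent optimization runs
    consensus_max_iter: int = 20
    null_permutations: int = 100  # surrogates for the consensus threshold
    seed: int = 0

    def __post_init__(self) -> None:
        if self.gamma <= 0:
            raise ValueError("gamma must be > 0")
        if self.omega < 0:
            raise ValueError("omega must be >= 0")
        if self.repetitions < 1:
            raise ValueError("repetitions must be >= 1")
        if self.topology not in ("categorical", "ordinal"):
            raise ValueError(f"unknown coupling topology {self.topology!r}")


@dataclass
class PartitionMatrix:
    """N x T community labels (contiguous integers from 1)."""

    assignments: np.ndarray
    provenance: dict = field(default_factory=dict)
    converged: bool = True

    def __post_init__(self) -> None:
        a = np.asarray(self.assignments, dtype=int)
        if a.ndim != 2:
            raise ValueError("assignments must be N x T")
        self.assignments = _canonicalize(a)

    @property
    def n_nodes(self) -> int:
        return self.assignments.shape[0]

    @property
    def n_layers(self) -> int:
        return self.assignments.shape[1]


@dataclass
class ModuleAllegianceMatrix:
    """P_ij: probability that i and j share a community (symmetric, diag 1)."""

    values: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("values must be square")
        self.values = v


def _canonicalize(assign: np.ndarray) -> np.ndarray:
    """Relabel communities 1..K by first appearance in layer-major order."""
    flat = assign.flatten(order="F")
    mapping: dict[int, int] = {}
    out = np.empty_like(flat)
    for i, g in enumerate(flat):
        if g not in mapping:
            mapping[g] = len(mapping) + 1
        out[i] = mapping[g]
    return out.reshape(assign.shape, order="F")


def _tensor_values(tensor) -> np.ndarray:
    """Accept an AdjacencyTensor or a bare N x N x T (or N x N) array."""
    if isinstance(tensor, AdjacencyTensor):
        return tensor.values
    v = np.asarray(tensor, dtype=float)
    if v.ndim == 2:
        v = v[:, :, None]
    return v


def supra_modularity_matrix(tensor, config: CommunityConfig
                            ) -> tuple[np.ndarray, float]:
    """Dense NT x NT multilayer modularity matrix B and normalization 2mu.

    Self-loops are excluded from each layer (the unit coherence diagonal is
    a convention, not an edge). Supra-node (i, l) sits at index l*N + i.
    """
    v = _tensor_values(tensor)
    n, _, t = v.shape
    big = np.zeros((n * t, n * t))
    two_mu = 0.0
    for l in range(t):
        a = v[:, :, l].copy()
        np.fill_diagonal(a, 0.0)
        k = a.sum(axis=1)
        two_m = k.sum()
        null = np.outer(k, k) / two_m if two_m > 0 else np.zeros((n, n))
        big[l * n:(l + 1) * n, l * n:(l + 1) * n] = a - config.gamma * null
        two_mu += two_m
    if config.omega > 0 and t > 1:
        idx = np.arange(n)
        for l in range(t):
            for r in range(t):
                if l == r:
                    continue
                if config.topology == "ordinal" and abs(l - r) != 1:
                    continue
                big[l * n + idx, r * n + idx] += config.omega
                two_mu += config.omega * n
    return big, two_mu


def multilayer_modularity(tensor, partition: PartitionMatrix | np.ndarray,
                          config: CommunityConfig | None = None) -> float:
    """Modularity Q of a partition of the multilayer network."""
    config = config or CommunityConfig()
    v = _tensor_values(tensor)
    assign = partition.assignments if isinstance(partition, PartitionMatrix) \
        else np.asarray(partition, dtype=int)
    if assign.ndim == 1:
        assign = assign[:, None]
    if assign.shape != v.shape[::2][:1] + (v.shape[2],) and \
       assign.shape != (v.shape[0], v.shape[2]):
        raise ValueError(
            f"partition shape {assign.shape} does not match tensor "
            f"{(v.shape[0], v.shape[2])}")
    big, two_mu = supra_modularity_matrix(v, config)
    if two_mu == 0:
        return 0.0
    g = assign.flatten(order="F")
    same = g[:, None] == g[None, :]
    return float(big[same].sum() / two_mu)


# ---------------------------------------------------------------------------
# Generalized Louvain on a dense modularity matrix

def _louvain_one_level(big: np.ndarray, rng: np.random.Generator,
                       tol: float = 1e-12) -> tuple[np.ndarray, bool]:
    """Greedy node moves until no move improves the quality sum_same B."""
    n = big.shape[0]
    labels = np.arange(n)
    improved = False
    while True:
        moved = False
        for v in rng.permutation(n):
            row = big[v].copy()
            row[v] = 0.0
            # gain of belonging to community c: sum_{j in c} B_vj
            gains = np.zeros(n)
            np.add.at(gains, labels, row)
            cur = labels[v]
            best = int(np.argmax(gains))
            if gains[best] > gains[cur] + tol and best != cur:
                labels[v] = best
                moved = True
                improved = True
        if not moved:
            break
    return labels, improved


def _aggregate(big: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    uniq, inv = np.unique(labels, return_inverse=True)
    k = len(uniq)
    ind = np.zeros((big.shape[0], k))
    ind[np.arange(big.shape[0]), inv] = 1.0
    return ind.T @ big @ ind, inv


def louvain_on_matrix(big: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Multi-level greedy optimization of sum_{same community} B_ij."""
    n = big.shape[0]
    membership = np.arange(n)
    cur = big
    while True:
        labels, improved = _louvain_one_level(cur, rng)
        if not improved:
            break
        agg, inv = _aggregate(cur, labels)
        membership = inv[membership]
        if agg.shape[0] == cur.shape[0]:  # no merge: nothing left to gain
            break
        cur = agg
    return membership


def louvain_multilayer(tensor, config: CommunityConfig | None = None,
                       seed: int | None = None) -> PartitionMatrix:
    """One seeded run of multilayer Louvain; deterministic given the seed."""
    config = config or CommunityConfig()
    v = _tensor_values(tensor)
    n, _, t = v.shape
    big, _ = supra_modularity_matrix(v, config)
    rng = np.random.default_rng(config.seed if seed is None else seed)
    labels = louvain_on_matrix(big, rng)
    assign = labels.reshape((t, n)).T + 1
    return PartitionMatrix(assignments=assign,
                           provenance={"gamma": config.gamma,
                                       "omega": config.omega,
                                       "topology": config.topology,
                                       "seed": int(config.seed if seed is None
                                                   else seed)})


def run_louvain_ensemble(tensor, config: CommunityConfig | None = None
                         ) -> list[PartitionMatrix]:
    """The configured number of independent optimization runs."""
    config = config or CommunityConfig()
    seeds = np.random.SeedSequence(config.seed).generate_state(config.repetitions)
    return [louvain_multilayer(tensor, config, seed=int(s % (2 ** 31)))
            for s in seeds]


# ---------------------------------------------------------------------------
# Consensus and module allegiance

def _coassignment(flats: list[np.ndarray]) -> np.ndarray:
    nt = flats[0].size
    d = np.zeros((nt, nt))
    for f in flats:
        d += f[:, None] == f[None, :]
    return d / len(flats)


def consensus_partition(partitions: list[PartitionMatrix],
                        config: CommunityConfig | None = None
                        ) -> PartitionMatrix:
    """Representative partition of an ensemble of optimization runs.

    The runs' co-assignment matrix is thresholded at the maximum
    off-diagonal co-assignment observed in permuted surrogate ensembles
    (assignment vectors shuffled across supra-nodes, preserving community
    sizes) and re-clustered; iterate until all re-clustering runs agree or
    the iteration cap is hit (then the modal partition is returned with
    ``converged=False``).
    """
    config = config or CommunityConfig()
    if not partitions:
        raise ValueError("need at least one partition")
    shape = partitions[0].assignments.shape
    for p in partitions:
        if p.assignments.shape != shape:
            raise ValueError("partition shapes differ")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0xC0]))
    flats = [p.assignments.flatten(order="F") for p in partitions]
    n_reclust = max(len(flats), 2)
    for _ in range(config.consensus_max_iter):
        if all(np.array_equal(flats[0], f) for f in flats[1:]):
            return PartitionMatrix(
                assignments=flats[0].reshape((shape[1], shape[0])).T,
                provenance={"consensus": True, "runs": len(partitions),
                            "gamma": config.gamma, "omega": config.omega},
                converged=True)
        d = _coassignment(flats)
        thr = 0.0
        for _ in range(config.null_permutations):
            perm = [f[rng.permutation(f.size)] for f in flats]
            dp = _coassignment(perm)
            np.fill_diagonal(dp, 0.0)
            thr = max(thr, float(dp.max()))
        dt = np.where(d >= max(thr, 1e-12), d, 0.0)
        np.fill_diagonal(dt, 0.0)
        k = dt.sum(axis=1)
        two_m = k.sum()
        null = np.outer(k, k) / two_m if two_m > 0 else np.zeros_like(dt)
        big = dt - null
        flats = [louvain_on_matrix(big, rng) for _ in range(n_reclust)]
    # non-convergence: return the modal partition with a warning flag
    keys = [tuple(f) for f in flats]
    modal = np.array(max(set(keys), key=keys.count))
    return PartitionMatrix(assignments=modal.reshape((shape[1], shape[0])).T,
                           provenance={"consensus": True,
                                       "runs": len(partitions)},
                           converged=False)


def module_allegiance(partitions: list[PartitionMatrix]
                      ) -> ModuleAllegianceMatrix:
    """P_ij = fraction of (run, layer) pairs in which i and j co-assign."""
    if not partitions:
        raise ValueError("need at least one partition")
    shape = partitions[0].assignments.shape
    n, t = shape
    acc = np.zeros((n, n))
    count = 0
    for p in partitions:
        if p.assignments.shape != shape:
            raise ValueError("partition shapes differ")
        for r in range(t):
            col = p.assignments[:, r]
            acc += col[:, None] == col[None, :]
            count += 1
    p_mat = acc / count
    p_mat = (p_mat + p_mat.T) / 2
    np.fill_diagonal(p_mat, 1.0)
    return ModuleAllegianceMatrix(values=p_mat,
                                  provenance={"runs": len(partitions),
                                              "layers": t})


def write_partition(partition: PartitionMatrix, path,
                    labels: list[str] | None = None) -> None:
    """Partition CSV (channels x layers, channel-label index) + provenance
    JSON sidecar."""
    import json
    from pathlib import Path

    import pandas as pd

    n, t = partition.assignments.shape
    idx = labels if labels is not None else [f"CH{i + 1:03d}" for i in range(n)]
    pd.DataFrame(partition.assignments, index=idx,
                 columns=[f"layer_{r}" for r in range(t)]).to_csv(path)
    Path(str(path) + ".meta.json").write_text(json.dumps(
        {"provenance": partition.provenance,
         "converged": partition.converged}))


def write_allegiance(mam: ModuleAllegianceMatrix, path,
                     labels: list[str] | None = None) -> None:
    import json
    from pathlib import Path

    import pandas as pd

    n = mam.values.shape[0]
    idx = labels if labels is not None else [f"CH{i + 1:03d}" for i in range(n)]
    pd.DataFrame(mam.values, index=idx, columns=idx).to_csv(path)
    Path(str(path) + ".meta.json").write_text(
        json.dumps({"provenance": mam.provenance}))


def detect_communities(tensor, config: CommunityConfig | None = None
                       ) -> tuple[PartitionMatrix, ModuleAllegianceMatrix,
                                  list[PartitionMatrix]]:
    """Full pipeline for one epoch: ensemble -> consensus + allegiance."""
    config = config or CommunityConfig()
    runs = run_louvain_ensemble(tensor, config)
    return consensus_partition(runs, config), module_allegiance(runs), runs
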