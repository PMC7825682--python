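"""Modularity, community detection, and force-directed layout.

Modularity of a partition A = {C_1..C_m} of graph G is

    M(A) = sum_C [ W_C / W - (s_C / 2W)^2 ]

with W the total edge weight, W_C the intra-community weight and s_C
the summed node strength of C (edge counts and degrees in the
unweighted case). Maximization is Louvain-style local moves with
multiple seeded restarts and a greedy community-merge refinement; an
exhaustive set-partition oracle is available for graphs of at most
ten nodes.

The force-directed layout follows the (attraction, repulsion)
exponent family: adjacent nodes attract with force |d|^a and all
pairs repel with |d|^r. For exponents greater than -1 the energy
minima of this family place modularity communities in spatial
clusters, which the agreement diagnostic quantifies.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Union

import networkx as nx
import numpy as np

__all__ = [
    "CommunityPartition",
    "LayoutResult",
    "modularity",
    "detect_communities",
    "exhaustive_modularity_oracle",
    "force_layout",
    "layout_community_agreement",
]

PartitionLike = Union["CommunityPartition", Mapping, Iterable]


@dataclass(frozen=True)
class CommunityPartition:
    """A node -> community assignment with its modularity."""

    assignment: dict
    modularity: float
    m: int

    def communities(self) -> list[set]:
        groups: dict = {}
        for node, c in self.assignment.items():
            groups.setdefault(c, set()).add(node)
        return [groups[c] for c in sorted(groups)]


def _as_assignment(partition: PartitionLike) -> dict:
    if isinstance(partition, CommunityPartition):
        return dict(partition.assignment)
    if isinstance(partition, Mapping):
        return dict(partition)
    assign = {}
    for ci, group in enumerate(partition):
        for node in group:
            assign[node] = ci
    return assign


def modularity(G: nx.Graph, partition: PartitionLike, weighted: bool = True) -> float:
    """Modularity of *partition* on *G* (edge-weight aware when *weighted*).

    The partition must cover exactly the node set. An empty edge set is
    degenerate: modularity is defined as 0 with a warning.
    """
    assign = _as_assignment(partition)
    if set(assign) != set(G.nodes):
        raise ValueError("partition must cover exactly the node set of the graph")
    w_total = 0.0
    intra: dict = {}
    strength: dict = {}
    for u, v, data in G.edges(data=True):
        w = float(data.get("weight", 1.0)) if weighted else 1.0
        w_total += w
        strength[assign[u]] = strength.get(assign[u], 0.0) + w
        strength[assign[v]] = strength.get(assign[v], 0.0) + w
        if assign[u] == assign[v]:
            intra[assign[u]] = intra.get(assign[u], 0.0) + w
    if w_total == 0.0:
        warnings.warn("modularity of a graph with no edges is degenerate; returning 0")
        return 0.0
    return sum(
        intra.get(c, 0.0) / w_total - (strength.get(c, 0.0) / (2.0 * w_total)) ** 2
        for c in set(assign.values())
    )


def _canonical_copy(G: nx.Graph) -> nx.Graph:
    """Rebuild with sorted node/edge insertion so results are independent
    of the caller's construction order (up to community relabeling)."""
    H = nx.Graph()
    H.add_nodes_from(sorted(G.nodes))
    H.add_edges_from(
        (u, v, {"weight": float(d.get("weight", 1.0))})
        for u, v, d in sorted(
            ((min(u, v), max(u, v), d) for u, v, d in G.edges(data=True)),
            key=lambda t: (t[0], t[1]),
        )
    )
    return H


def _local_move_refine(G: nx.Graph, comms: list[set], weighted: bool) -> list[set]:
    """Steepest single-node moves (including to a fresh singleton) on the
    flat graph until no move increases modularity. Deterministic: nodes
    in sorted order, ties to the smallest community id."""
    comms = [set(c) for c in comms if c]
    label = {v: i for i, c in enumerate(comms) for v in c}
    W = 0.0
    strength: dict = {}
    for u, v, data in G.edges(data=True):
        w = float(data.get("weight", 1.0)) if weighted else 1.0
        W += w
        strength[u] = strength.get(u, 0.0) + w
        strength[v] = strength.get(v, 0.0) + w
    if W == 0.0:
        return comms
    S = [sum(strength.get(v, 0.0) for v in c) for c in comms]
    improved = True
    while improved:
        improved = False
        for v in sorted(G.nodes):
            c = label[v]
            s_v = strength.get(v, 0.0)
            w_to: dict = {}
            for u in G[v]:
                w = float(G[v][u].get("weight", 1.0)) if weighted else 1.0
                w_to[label[u]] = w_to.get(label[u], 0.0) + w
            base = -w_to.get(c, 0.0) / W + s_v * (S[c] - s_v) / (2.0 * W * W)
            best_gain, best_d = 1e-12, None
            for d in sorted(set(w_to) | {len(comms)}):
                if d == c:
                    continue
                S_d = S[d] if d < len(comms) else 0.0
                gain = base + w_to.get(d, 0.0) / W - s_v * S_d / (2.0 * W * W)
                if gain > best_gain:
                    best_gain, best_d = gain, d
            if best_d is not None:
                comms[c].discard(v)
                S[c] -= s_v
                if best_d == len(comms):
                    comms.append(set())
                    S.append(0.0)
                comms[best_d].add(v)
                S[best_d] += s_v
                label[v] = best_d
                improved = True
    return [c for c in comms if c]


def _merge_refine(G: nx.Graph, comms: list[set], weighted: bool) -> list[set]:
    """Greedily merge community pairs while any merge increases modularity.

    The merge gain for communities c, d is B_cd / W - s_c s_d / (2 W^2)
    with B_cd the between-community weight.
    """
    comms = [set(c) for c in comms]
    if len(comms) <= 1:
        return comms
    label = {}
    for ci, c in enumerate(comms):
        for v in c:
            label[v] = ci
    W = 0.0
    strength = [0.0] * len(comms)
    between: dict[tuple[int, int], float] = {}
    for u, v, data in G.edges(data=True):
        w = float(data.get("weight", 1.0)) if weighted else 1.0
        W += w
        cu, cv = label[u], label[v]
        strength[cu] += w
        strength[cv] += w
        if cu != cv:
            key = (min(cu, cv), max(cu, cv))
            between[key] = between.get(key, 0.0) + w
    if W == 0.0:
        return comms
    alive = set(range(len(comms)))
    while len(alive) > 1:
        best_gain, best_pair = 1e-12, None
        for (c, d), b in between.items():
            if c in alive and d in alive:
                gain = b / W - strength[c] * strength[d] / (2.0 * W * W)
                if gain > best_gain:
                    best_gain, best_pair = gain, (c, d)
        if best_pair is None:
            break
        c, d = best_pair
        comms[c] |= comms[d]
        comms[d] = set()
        strength[c] += strength[d]
        alive.discard(d)
        for e in list(alive):
            if e == c:
                continue
            key_d = (min(d, e), max(d, e))
            if key_d in between:
                key_c = (min(c, e), max(c, e))
                between[key_c] = between.get(key_c, 0.0) + between.pop(key_d)
        between.pop((min(c, d), max(c, d)), None)
    return [c for c in comms if c]


def detect_communities(
    G: nx.Graph,
    seed: int = 0,
    weighted: bool = True,
    n_restarts: int = 8,
    resolution: float = 1.0,
) -> CommunityPartition:
    """Maximize modularity by seeded Louvain restarts plus merge refinement.

    Deterministic given *seed*: the graph is canonicalized to sorted
    node order before the local moves, so the result does not depend
    on input construction order. The best restart by (this module's)
    modularity is returned; community ids are 0..m-1 ordered by
    decreasing size, ties broken by smallest member id.
    """
    if G.number_of_nodes() == 0:
        raise ValueError("cannot detect communities of an empty graph")
    H = _canonical_copy(G)
    weight_key = "weight" if weighted else None
    if H.number_of_edges() == 0:
        best = [{v} for v in H.nodes]
    else:
        best, best_m = None, -np.inf
        for rep in range(max(1, n_restarts)):
            s = (abs(seed) * 1009 + rep) % (2**31 - 1)
            comms = [
                set(c)
                for c in nx.community.louvain_communities(
                    H, weight=weight_key, seed=s, resolution=resolution
                )
            ]
            # alternate single-node moves and pair merges to a fixed point
            m_val = -np.inf
            while True:
                comms = _local_move_refine(H, comms, weighted)
                comms = _merge_refine(H, comms, weighted)
                m_new = modularity(H, comms, weighted=weighted)
                if m_new <= m_val + 1e-12:
                    break
                m_val = m_new
            if m_val > best_m + 1e-15:
                best_m, best = m_val, comms
        if best_m < 0.0:  # never worse than the single-cluster partition
            best = [set(H.nodes)]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        m_val = modularity(H, best, weighted=weighted)
    ordered = sorted(best, key=lambda c: (-len(c), min(c)))
    assign = {v: ci for ci, c in enumerate(ordered) for v in c}
    return CommunityPartition(assignment=assign, modularity=float(m_val), m=len(ordered))


def _set_partitions(nodes: list):
    """All set partitions, by recursive first-element insertion."""
    if not nodes:
        yield []
        return
    first, rest = nodes[0], nodes[1:]
    for part in _set_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [part[i] | {first}] + part[i + 1 :]
        yield [{first}] + part


def exhaustive_modularity_oracle(
    G: nx.Graph, weighted: bool = True
) -> CommunityPartition:
    """Globally optimal partition by full enumeration (<= 10 nodes).

    Enumerates every set partition of the node set (Bell-number many)
    and returns the modularity maximum. Intended as an independent
    check of the heuristic optimizer on small graphs.
    """
    n = G.number_of_nodes()
    if n == 0:
        raise ValueError("empty graph")
    if n > 10:
        raise ValueError("exhaustive enumeration is limited to graphs of <= 10 nodes")
    nodes = sorted(G.nodes)
    best, best_m = None, -np.inf
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for part in _set_partitions(nodes):
            m_val = modularity(G, part, weighted=weighted)
            if m_val > best_m:
                best_m, best = m_val, [set(c) for c in part]
    ordered = sorted(best, key=lambda c: (-len(c), min(c)))
    assign = {v: ci for ci, c in enumerate(ordered) for v in c}
    return CommunityPartition(
        assignment=assign, modularity=float(best_m), m=len(ordered)
    )


@dataclass(frozen=True)
class LayoutResult:
    """2-D node coordinates with the layout parameters that produced them."""

    coordinates: dict
    a: float
    r: float
    iterations: int
    seed: int
    energy: tuple[float, ...] = field(default=(), repr=False)


def _layout_energy(pos: np.ndarray, adj: np.ndarray, a: float, r: float) -> float:
    diff = pos[:, None, :] - pos[None, :, :]
    d = np.sqrt((diff**2).sum(-1)) + 1e-12
    iu = np.triu_indices(len(pos), k=1)
    du = d[iu]
    attraction = (du ** (a + 1.0) / (a + 1.0) * adj[iu]).sum()
    if abs(r + 1.0) < 1e-12:
        repulsion = np.log(du).sum()
    else:
        repulsion = (du ** (r + 1.0) / (r + 1.0)).sum()
    return float(attraction - repulsion)


def force_layout(
    G: nx.Graph,
    a: float = 1.0,
    r: float = -1.0,
    iterations: int = 200,
    seed: int = 0,
) -> LayoutResult:
    """Energy-minimizing force-directed layout.

    Adjacent nodes attract (exponent *a* >= 0), all node pairs repel
    (exponent *r* in [-1, 0]). Positions start from a seeded random
    configuration and follow gradient steps with backtracking, so the
    recorded energy trace is non-increasing by construction.
    """
    if a < 0:
        raise ValueError("attraction exponent a must be >= 0")
    if not (-1.0 <= r <= 0.0):
        raise ValueError("repulsion exponent r must lie in [-1, 0]")
    nodes = sorted(G.nodes)
    n = len(nodes)
    rng = np.random.default_rng(seed)
    pos = rng.uniform(-1.0, 1.0, size=(n, 2))
    if n <= 1:
        coords = {v: (float(x), float(y)) for v, (x, y) in zip(nodes, pos)}
        return LayoutResult(coords, a, r, iterations, seed, energy=())
    index = {v: i for i, v in enumerate(nodes)}
    adj = np.zeros((n, n))
    for u, v in G.edges():
        adj[index[u], index[v]] = adj[index[v], index[u]] = 1.0
    energy = [_layout_energy(pos, adj, a, r)]
    step = 0.1
    for _ in range(iterations):
        diff = pos[:, None, :] - pos[None, :, :]
        d = np.sqrt((diff**2).sum(-1)) + 1e-12
        np.fill_diagonal(d, 1.0)
        unit = diff / d[:, :, None]
        grad = ((d ** a) * adj)[:, :, None] * unit - (d ** r)[:, :, None] * unit
        np.fill_diagonal(grad[:, :, 0], 0.0)
        np.fill_diagonal(grad[:, :, 1], 0.0)
        grad = grad.sum(axis=1)
        # backtracking line search keeps the energy monotone
        while step > 1e-14:
            trial = pos - step * grad
            e_trial = _layout_energy(trial, adj, a, r)
            if np.isfinite(e_trial) and e_trial <= energy[-1]:
                pos = trial
                energy.append(e_trial)
                step = min(step * 1.5, 1.0)
                break
            step *= 0.5
        else:
            break
    if not np.isfinite(pos).all():  # pragma: no cover - guarded by line search
        raise FloatingPointError("force layout diverged to non-finite coordinates")
    coords = {v: (float(x), float(y)) for v, (x, y) in zip(nodes, pos)}
    return LayoutResult(coords, a, r, iterations, seed, energy=tuple(energy))


def layout_community_agreement(
    layout: LayoutResult, partition: PartitionLike
) -> float:
    """(mean intra-community distance) / (mean inter-community distance).

    Values below 1 mean the layout places community members closer to
    one another than to the rest of the network. Undefined (raises)
    when the partition has a single community or only singletons.
    """
    assign = _as_assignment(partition)
    if set(assign) != set(layout.coordinates):
        raise ValueError("layout and partition must cover the same node set")
    nodes = sorted(assign)
    pos = np.array([layout.coordinates[v] for v in nodes])
    labels = np.array([assign[v] for v in nodes])
    diff = pos[:, None, :] - pos[None, :, :]
    d = np.sqrt((diff**2).sum(-1))
    iu = np.triu_indices(len(nodes), k=1)
    same = labels[iu[0]] == labels[iu[1]]
    if same.all() or not same.any():
        raise ValueError(
            "agreement ratio undefined: need both intra- and inter-community pairs"
        )
    return float(d[iu][same].mean() / d[iu][~same].mean())
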