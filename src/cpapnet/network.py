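"""Risk-compatibility network construction.

Two patients are *risk compatible* when they fall in identical classes
for at least a threshold number (default 4) of the six discretized
parameters. The network is undirected; the edge weight is the number
of shared classes (an integer in 0..6), and edges below the threshold
are filtered out. All parameters carry equal weight.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence, Union

import networkx as nx
import numpy as np

from .cohort import ClassProfile

__all__ = [
    "compatibility_score",
    "build_network",
    "threshold_sweep",
    "NetworkSummary",
    "summarize_network",
]

ProfileMap = Union[Mapping[str, ClassProfile], Iterable[tuple[str, ClassProfile]]]


def compatibility_score(p: ClassProfile, q: ClassProfile) -> int:
    """Number of identical class slots between two profiles (0..6)."""
    return sum(a == b for a, b in zip(p.as_tuple(), q.as_tuple()))


def _as_items(profiles: ProfileMap) -> list[tuple[str, ClassProfile]]:
    items = list(profiles.items()) if isinstance(profiles, Mapping) else list(profiles)
    ids = [pid for pid, _ in items]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate patient ids in profile list")
    return items


def _score_matrix(items: Sequence[tuple[str, ClassProfile]]) -> np.ndarray:
    # encode the six slots as integers and count slot-wise agreements
    code = np.empty((len(items), 6), dtype=np.int64)
    for i, (_, p) in enumerate(items):
        g, a, h, o, t, s = p.as_tuple()
        code[i] = (g == "M", a, h, o, t, s)
    return (code[:, None, :] == code[None, :, :]).sum(axis=2)


def build_network(profiles: ProfileMap, threshold: int = 4) -> nx.Graph:
    """Build the weighted risk-compatibility network.

    Edge (i, j) is present iff the compatibility score is >= *threshold*
    and carries that score as its weight. Patients without compatible
    partners remain as isolated nodes. The graph-level attribute
    ``threshold`` records the filter used.
    """
    if not (1 <= threshold <= 6):
        raise ValueError("threshold must lie in 1..6")
    items = _as_items(profiles)
    G = nx.Graph(threshold=threshold)
    for pid, prof in items:
        G.add_node(
            pid,
            gender=prof.gender_class,
            age_group=prof.age_group,
            hbp=int(prof.hbp),
            obese=int(prof.obese),
            thick_neck=int(prof.thick_neck),
            sleepiness=int(prof.sleepiness),
        )
    if len(items) < 2:
        return G
    scores = _score_matrix(items)
    ids = [pid for pid, _ in items]
    ii, jj = np.nonzero(np.triu(scores >= threshold, k=1))
    G.add_weighted_edges_from(
        (ids[i], ids[j], int(scores[i, j])) for i, j in zip(ii, jj)
    )
    return G


@dataclass(frozen=True)
class NetworkSummary:
    """Size and connectivity summary of one network."""

    n_nodes: int
    n_edges: int
    density: float
    n_components: int
    giant_component_size: int
    threshold: int


def summarize_network(G: nx.Graph) -> NetworkSummary:
    n = G.number_of_nodes()
    comps = list(nx.connected_components(G)) if n else []
    return NetworkSummary(
        n_nodes=n,
        n_edges=G.number_of_edges(),
        density=nx.density(G) if n > 1 else 0.0,
        n_components=len(comps),
        giant_component_size=max((len(c) for c in comps), default=0),
        threshold=int(G.graph.get("threshold", 0)),
    )


def threshold_sweep(
    profiles: ProfileMap,
    thresholds: Sequence[int] = (1, 2, 3, 4, 5, 6),
    seed: int = 0,
    weighted: bool = True,
) -> list[tuple[NetworkSummary, int]]:
    """Network summary and community count at each compatibility threshold.

    A strict threshold fragments the graph into many small components
    while a lax one collapses it into a single dense community; the
    sweep makes that trade-off explicit. Returns one
    ``(NetworkSummary, n_communities)`` pair per threshold.
    """
    from .communities import detect_communities  # local import: avoid cycle

    items = _as_items(profiles)
    out = []
    for t in thresholds:
        G = build_network(items, threshold=int(t))
        if G.number_of_edges() == 0:
            m = G.number_of_nodes()  # all singletons
        else:
            m = detect_communities(G, seed=seed, weighted=weighted).m
        out.append((summarize_network(G), m))
    return out
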