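"""Community detection on variable graphs.

Two classic non-overlapping methods are provided:

* Girvan-Newman: repeatedly remove a maximum-edge-betweenness edge; the
  connected components at each split level are candidate partitions, and
  the returned level is either the one maximizing Newman-Girvan modularity
  or the first level with a requested number of communities.
* Clauset-Newman-Moore greedy agglomeration: start from singletons and
  merge the community pair with the largest modularity gain until no merge
  improves modularity.

All tie-breaks are lexicographic on variable names so that output is fully
deterministic.  Isolated variables become singleton communities.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import networkx as nx

from .network import VariableGraph

__all__ = [
    "CommunityPartition",
    "edge_betweenness",
    "girvan_newman",
    "modularity",
    "cnm_greedy",
    "write_partition_json",
    "read_partition_json",
]


def _as_nx(graph: VariableGraph | nx.Graph) -> nx.Graph:
    return graph.graph if isinstance(graph, VariableGraph) else graph


def _canonical(communities) -> tuple[frozenset[str], ...]:
    """Stable ordering: by size descending, then lexicographic members."""
    comms = [frozenset(c) for c in communities]
    return tuple(sorted(comms, key=lambda c: (-len(c), sorted(c))))


@dataclass(frozen=True)
class CommunityPartition:
    """A disjoint cover of the node set by communities."""

    communities: tuple[frozenset[str], ...]
    method: str  # 'girvan_newman' | 'cnm'
    modularity: float | None
    phase: str | None = None
    modularity_trace: tuple[float, ...] = field(default=(), compare=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "communities", _canonical(self.communities))
        nodes: list[str] = []
        for c in self.communities:
            nodes.extend(c)
        if len(nodes) != len(set(nodes)):
            raise ValueError("communities overlap")

    @property
    def nodes(self) -> frozenset[str]:
        return frozenset().union(*self.communities) if self.communities else frozenset()

    def __len__(self) -> int:
        return len(self.communities)

    def labels(self) -> dict[str, int]:
        """node -> community index (in the canonical order)."""
        return {n: i for i, c in enumerate(self.communities) for n in c}

    def community_of(self, name: str) -> frozenset[str]:
        for c in self.communities:
            if name in c:
                return c
        raise KeyError(name)

    def non_singleton(self) -> tuple[frozenset[str], ...]:
        return tuple(c for c in self.communities if len(c) > 1)


# --------------------------------------------------------------------------
# Edge betweenness
# --------------------------------------------------------------------------

def edge_betweenness(graph: VariableGraph | nx.Graph) -> dict[tuple[str, str], float]:
    """Raw (unnormalized) edge betweenness over unordered node pairs.

    For each edge: the sum over node pairs s != t of the fraction of
    shortest s-t paths passing through the edge.  Pairs in different
    components contribute 0.
    """
    g = _as_nx(graph)
    raw = nx.edge_betweenness_centrality(g, normalized=False)
    return {tuple(sorted((u, v))): float(b) for (u, v), b in raw.items()}


# --------------------------------------------------------------------------
# Modularity
# --------------------------------------------------------------------------

def modularity(
    graph: VariableGraph | nx.Graph, partition
) -> float | None:
    """Newman-Girvan modularity Q = sum_c (e_cc - a_c^2), unweighted.

    Returns None for an edgeless graph (Q undefined: zero total degree).
    """
    g = _as_nx(graph)
    if g.number_of_edges() == 0:
        return None
    return float(nx.community.modularity(g, [set(c) for c in partition]))


# --------------------------------------------------------------------------
# Girvan-Newman
# --------------------------------------------------------------------------

def _most_valuable_edge(g: nx.Graph) -> tuple[str, str]:
    eb = nx.edge_betweenness_centrality(g, normalized=False)
    # max betweenness; ties broken by lexicographically smallest sorted edge
    top = max(eb.values())
    candidates = [tuple(sorted(e)) for e, b in eb.items() if b >= top - 1e-12]
    return min(candidates)


def girvan_newman(
    graph: VariableGraph | nx.Graph,
    stop: str = "max_modularity",
    k: int | None = None,
    phase: str | None = None,
) -> CommunityPartition:
    """Divisive community detection by iterated edge removal.

    ``stop='max_modularity'`` evaluates every split level (including the
    initial connected components) and returns the level with the highest
    modularity, preferring fewer communities on ties.  ``stop='fixed_k'``
    returns the first level with exactly ``k`` components.
    """
    g = _as_nx(graph)
    n = g.number_of_nodes()
    if n == 0:
        raise ValueError("empty graph")
    initial = _canonical(nx.connected_components(g))
    if stop == "fixed_k":
        if k is None:
            raise ValueError("stop='fixed_k' requires k")
        if k > n:
            raise ValueError(f"k={k} exceeds node count {n}")
        if k < len(initial):
            raise ValueError(
                f"k={k} is below the number of connected components "
                f"({len(initial)}); splits can only increase the count"
            )
        if k == len(initial):
            return CommunityPartition(
                communities=initial,
                method="girvan_newman",
                modularity=modularity(g, initial),
                phase=phase,
            )
        for level in nx.community.girvan_newman(
            g, most_valuable_edge=_most_valuable_edge
        ):
            if len(level) == k:
                comms = _canonical(level)
                return CommunityPartition(
                    communities=comms,
                    method="girvan_newman",
                    modularity=modularity(g, comms),
                    phase=phase,
                )
        raise ValueError(f"no split level with exactly {k} communities")
    if stop != "max_modularity":
        raise ValueError("stop must be 'max_modularity' or 'fixed_k'")
    best = initial
    best_q = modularity(g, initial)
    if g.number_of_edges() > 0:
        for level in nx.community.girvan_newman(
            g, most_valuable_edge=_most_valuable_edge
        ):
            q = modularity(g, level)
            if best_q is None or (q is not None and q > best_q + 1e-12):
                best_q, best = q, _canonical(level)
    return CommunityPartition(
        communities=_canonical(best),
        method="girvan_newman",
        modularity=best_q,
        phase=phase,
    )


# --------------------------------------------------------------------------
# Clauset-Newman-Moore greedy agglomeration
# --------------------------------------------------------------------------

def cnm_greedy(
    graph: VariableGraph | nx.Graph, phase: str | None = None
) -> CommunityPartition:
    """Greedy modularity agglomeration from singletons.

    At each step the merge with the largest modularity gain is applied
    (ties: lexicographically smallest pair of community labels, where a
    community is labelled by its smallest member); merging stops when no
    gain is positive.  Zero-degree nodes stay singletons.  On an edgeless
    graph the result is the all-singletons partition with undefined
    modularity.
    """
    g = _as_nx(graph)
    nodes = sorted(g.nodes)
    if not nodes:
        raise ValueError("empty graph")
    m = g.number_of_edges()
    if m == 0:
        singles = _canonical([{n} for n in nodes])
        return CommunityPartition(
            communities=singles, method="cnm", modularity=None, phase=phase
        )
    # community label -> members; label = smallest member name
    members: dict[str, set[str]] = {n: {n} for n in nodes}
    # degree fraction a_c and between-community edge fractions e_{cd}
    a = {n: g.degree(n) / (2 * m) for n in nodes}
    e: dict[str, dict[str, float]] = {n: {} for n in nodes}
    for u, v in g.edges:
        e[u][v] = e[u].get(v, 0.0) + 1 / m
        e[v][u] = e[v].get(u, 0.0) + 1 / m
    q = modularity(g, members.values())
    trace = [q]
    while True:
        best_gain = 0.0
        best_pair: tuple[str, str] | None = None
        for c in sorted(e):
            for d in sorted(e[c]):
                if d <= c:
                    continue
                gain = e[c][d] - 2 * a[c] * a[d]
                if gain <= 1e-12:
                    continue
                if best_pair is None or gain > best_gain + 1e-12:
                    best_gain, best_pair = gain, (c, d)
                elif abs(gain - best_gain) <= 1e-12 and (c, d) < best_pair:
                    best_pair = (c, d)
        if best_pair is None:
            break
        c, d = best_pair  # merge d into c (c < d lexicographically)
        members[c] |= members.pop(d)
        a[c] += a.pop(d)
        for x, w in e.pop(d).items():
            if x == c:
                continue
            e[x].pop(d, None)
            e[c][x] = e[c].get(x, 0.0) + w
            e[x][c] = e[c][x]
        e[c].pop(d, None)
        q += best_gain
        trace.append(q)
    comms = _canonical(members.values())
    return CommunityPartition(
        communities=comms,
        method="cnm",
        modularity=modularity(g, comms),
        phase=phase,
        modularity_trace=tuple(trace),
    )


# --------------------------------------------------------------------------
# I/O
# --------------------------------------------------------------------------

def write_partition_json(partition: CommunityPartition, path) -> None:
    payload = {
        "phase": partition.phase,
        "method": partition.method,
        "modularity": partition.modularity,
        "communities": [sorted(c) for c in partition.communities],
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_partition_json(path) -> CommunityPartition:
    with open(path, encoding="utf-8") as fh:
        payload = json.load(fh)
    return CommunityPartition(
        communities=tuple(frozenset(c) for c in payload["communities"]),
        method=payload["method"],
        modularity=payload["modularity"],
        phase=payload.get("phase"),
    )
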