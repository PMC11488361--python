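"""Shared fixtures: tiny cohorts, the two-block matrix, small oracle graphs."""

from __future__ import annotations

import itertools

import networkx as nx
import numpy as np
import pytest

from cognet import (
    Cohort,
    Diagnosis,
    GeneratorConfig,
    Participant,
    Visit,
    default_schema,
    generate_cohort,
    select_study_sample,
    two_block_matrix,
)

CU, MCI, DEM = Diagnosis.CU, Diagnosis.MCI, Diagnosis.DEM


def make_cohort(trajectories, values_fn=None, sexes=None):
    """Build a small cohort from {pid: [diagnosis, ...]}.

    ``values_fn(pid, visit_index)`` returns the value map for a visit;
    defaults to simple increasing scores.
    """
    schema = default_schema().subset(["CDRSum", "CDRGlob", "FAQ"])
    if values_fn is None:
        def values_fn(pid, t):
            return {"CDRSum": 1.0 + t, "CDRGlob": 0.5, "FAQ": 2.0 * t}
    participants = []
    for i, (pid, dxs) in enumerate(sorted(trajectories.items())):
        visits = tuple(
            Visit(
                participant_id=pid,
                visit_index=t + 1,
                months_since_baseline=t * 15.0,
                diagnosis=dx,
                values=values_fn(pid, t),
            )
            for t, dx in enumerate(dxs)
        )
        participants.append(
            Participant(
                participant_id=pid,
                sex=(sexes or {}).get(pid, "F"),
                apoe4=False,
                age_at_baseline=80.0,
                visits=visits,
            )
        )
    return Cohort(schema=schema, participants=tuple(participants))


@pytest.fixture(scope="session")
def two_block():
    return two_block_matrix()


@pytest.fixture(scope="session")
def default_cohort():
    """The default 97-participant synthetic cohort (seed 42), post selection."""
    return select_study_sample(generate_cohort(GeneratorConfig(seed=42)))


@pytest.fixture()
def eligible_cohort():
    return make_cohort(
        {
            "P1": [CU, MCI, MCI, DEM],
            "P2": [CU, CU, MCI, MCI, MCI, DEM],
            "P3": [CU, MCI, DEM],
        }
    )


# ----------------------------------------------------------------- oracles

def set_partitions(items):
    """Enumerate all partitions of ``items`` (Bell-number many)."""
    items = list(items)
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for partition in set_partitions(rest):
        for i in range(len(partition)):
            yield partition[:i] + [[first] + partition[i]] + partition[i + 1:]
        yield [[first]] + partition


def max_modularity_bruteforce(g: nx.Graph) -> float:
    """Exhaustive-enumeration modularity optimum for graphs of <= 8 nodes."""
    assert g.number_of_nodes() <= 8
    best = -np.inf
    for partition in set_partitions(sorted(g.nodes)):
        q = nx.community.modularity(g, [set(c) for c in partition])
        best = max(best, q)
    return best


def pearson_bruteforce(x, y):
    """Textbook two-pass Pearson over paired complete observations."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    mx, my = x.mean(), y.mean()
    num = ((x - mx) * (y - my)).sum()
    den = np.sqrt(((x - mx) ** 2).sum() * ((y - my) ** 2).sum())
    return num / den


def adjusted_rand(labels_a, labels_b):
    """Adjusted Rand index from the pair-counting contingency table."""
    from scipy.special import comb

    table = {}
    for a, b in zip(labels_a, labels_b):
        table[(a, b)] = table.get((a, b), 0) + 1
    n = len(labels_a)
    count_a, count_b = {}, {}
    for a in labels_a:
        count_a[a] = count_a.get(a, 0) + 1
    for b in labels_b:
        count_b[b] = count_b.get(b, 0) + 1
    sum_ij = sum(comb(v, 2) for v in table.values())
    sum_a = sum(comb(v, 2) for v in count_a.values())
    sum_b = sum(comb(v, 2) for v in count_b.values())
    expected = sum_a * sum_b / comb(n, 2)
    maximum = (sum_a + sum_b) / 2
    if maximum == expected:
        return 1.0
    return (sum_ij - expected) / (maximum - expected)


@pytest.fixture(scope="session")
def small_graphs():
    """Named small graphs with known structure (all <= 8 nodes)."""
    star = nx.star_graph(4)
    star = nx.relabel_nodes(star, {i: f"s{i}" for i in star.nodes})
    p4 = nx.path_graph(4)
    p4 = nx.relabel_nodes(p4, {i: "abcd"[i] for i in p4.nodes})
    k3k4 = nx.disjoint_union(nx.complete_graph(3), nx.complete_graph(4))
    k3k4 = nx.relabel_nodes(k3k4, {i: "ABCDEFG"[i] for i in k3k4.nodes})
    barbell = nx.Graph(
        [("A", "B"), ("B", "C"), ("A", "C"),
         ("D", "E"), ("E", "F"), ("D", "F"), ("C", "D")]
    )
    k4e = nx.complete_graph(4)
    k4e = nx.relabel_nodes(k4e, {i: "wxyz"[i] for i in k4e.nodes})
    k4e.remove_edge("w", "x")
    return {"star": star, "p4": p4, "k3k4": k3k4, "barbell": barbell,
            "k4_minus_edge": k4e}
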