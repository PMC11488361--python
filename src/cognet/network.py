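"""Thresholded Pearson-correlation networks over clinical variables.

Variables are nodes; an undirected, unweighted edge joins two variables
whose pairwise Pearson correlation (computed over pairwise-complete visit
rows) reaches a threshold.  The working threshold is not fixed a priori:
starting from 10% it is raised in 1% steps for as long as the resulting
graph stays degree-assortative (Newman's degree-degree correlation > 0),
and the last assortative threshold is retained.  Raising the threshold
prunes weak correlations; the assortativity bound stops the pruning just
before the network's degree structure degrades.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .cohort import PhaseDataset

__all__ = [
    "CorrelationMatrix",
    "VariableGraph",
    "ThresholdTracePoint",
    "ThresholdSearchResult",
    "pearson_matrix",
    "build_graph",
    "degree_assortativity",
    "average_clustering",
    "search_threshold",
    "read_correlation_csv",
    "write_correlation_csv",
]


@dataclass(frozen=True)
class CorrelationMatrix:
    """Symmetric Pearson correlation matrix with per-pair sample sizes."""

    variables: tuple[str, ...]
    values: np.ndarray  # (p, p) floats in [-1, 1], unit diagonal
    n_pairs: np.ndarray  # (p, p) ints, observations per pair

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        n_pairs = np.asarray(self.n_pairs, dtype=int)
        p = len(self.variables)
        if values.shape != (p, p) or n_pairs.shape != (p, p):
            raise ValueError("matrix shape does not match variable count")
        if not np.allclose(values, values.T, atol=1e-12):
            raise ValueError("correlation matrix must be symmetric")
        if not np.allclose(np.diag(values), 1.0, atol=1e-12):
            raise ValueError("correlation matrix diagonal must be 1")
        if np.nanmax(np.abs(values)) > 1 + 1e-9:
            raise ValueError("correlation values must lie in [-1, 1]")
        object.__setattr__(self, "variables", tuple(self.variables))
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "n_pairs", n_pairs)

    def r(self, a: str, b: str) -> float:
        i, j = self.variables.index(a), self.variables.index(b)
        return float(self.values[i, j])


@dataclass
class VariableGraph:
    """Undirected unweighted graph over the full variable set.

    Isolated variables are kept as nodes.  ``assortativity`` is None when
    undefined (edgeless graph or zero degree variance at edge endpoints).
    """

    graph: nx.Graph
    threshold_percent: int
    edge_rule: str = "signed"
    assortativity: float | None = field(default=None)
    avg_clustering: float = field(default=0.0)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()


@dataclass(frozen=True)
class ThresholdTracePoint:
    threshold_percent: int
    assortativity: float | None
    n_edges: int
    avg_clustering: float

    @property
    def assortative(self) -> bool:
        return self.assortativity is not None and self.assortativity > 0


@dataclass(frozen=True)
class ThresholdSearchResult:
    """Outcome of the assortativity-bounded threshold grid search.

    ``t_star`` is None when the starting threshold is already
    non-assortative (no assortative threshold exists along the sweep).
    """

    t_star: int | None
    trace: tuple[ThresholdTracePoint, ...]

    @property
    def failed(self) -> bool:
        return self.t_star is None

    def at(self, t: int) -> ThresholdTracePoint:
        for point in self.trace:
            if point.threshold_percent == t:
                return point
        raise KeyError(t)


# --------------------------------------------------------------------------
# Correlation
# --------------------------------------------------------------------------

def pearson_matrix(dataset: PhaseDataset, min_pairs: int = 3) -> CorrelationMatrix:
    """Pairwise-complete Pearson correlations for one phase dataset.

    Pairs with fewer than ``min_pairs`` complete observations, and pairs
    involving a constant column, yield r = 0 with a warning (they carry no
    usable association signal but must not break the graph stage).
    """
    frame = dataset.frame
    if len(frame) < 2:
        raise ValueError(
            f"{dataset.phase.value}: need at least 2 rows to correlate, "
            f"got {len(frame)}"
        )
    names = tuple(frame.columns)
    notna = frame.notna().to_numpy(dtype=float)
    n_pairs = (notna.T @ notna).astype(int)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        corr = frame.corr(method="pearson", min_periods=min_pairs).to_numpy()
    undefined = ~np.isfinite(corr)
    np.fill_diagonal(undefined, False)
    if undefined.any():
        bad = sorted(
            {names[i] for i, j in zip(*np.nonzero(undefined))}
        )
        warnings.warn(
            "undefined correlations (constant column or fewer than "
            f"{min_pairs} complete pairs) treated as 0 for: {bad}",
            stacklevel=2,
        )
        corr = np.where(undefined, 0.0, corr)
    np.fill_diagonal(corr, 1.0)
    corr = np.clip(corr, -1.0, 1.0)
    corr = (corr + corr.T) / 2.0
    return CorrelationMatrix(variables=names, values=corr, n_pairs=n_pairs)


# --------------------------------------------------------------------------
# Graph construction and metrics
# --------------------------------------------------------------------------

def _threshold_edges(
    corr: CorrelationMatrix, threshold_percent: int, edge_rule: str
) -> list[tuple[str, str]]:
    cut = threshold_percent / 100.0
    vals = np.abs(corr.values) if edge_rule == "absolute" else corr.values
    p = len(corr.variables)
    edges = []
    for i in range(p):
        for j in range(i + 1, p):
            if vals[i, j] >= cut:
                edges.append((corr.variables[i], corr.variables[j]))
    return edges


def build_graph(
    corr: CorrelationMatrix,
    threshold_percent: int,
    edge_rule: str = "signed",
) -> VariableGraph:
    """Build the unweighted variable graph at one threshold.

    ``edge_rule='signed'`` (default) links pairs with r >= t/100;
    ``'absolute'`` links pairs with |r| >= t/100.  Ties at the cutoff are
    included.  All variables stay as nodes even when isolated.
    """
    if not 0 <= threshold_percent <= 100:
        raise ValueError("threshold_percent must lie in [0, 100]")
    if edge_rule not in ("signed", "absolute"):
        raise ValueError("edge_rule must be 'signed' or 'absolute'")
    g = nx.Graph()
    g.add_nodes_from(corr.variables)
    g.add_edges_from(_threshold_edges(corr, threshold_percent, edge_rule))
    vg = VariableGraph(
        graph=g, threshold_percent=threshold_percent, edge_rule=edge_rule
    )
    vg.assortativity = degree_assortativity(vg)
    vg.avg_clustering = average_clustering(vg)
    return vg


def _as_nx(graph: VariableGraph | nx.Graph) -> nx.Graph:
    return graph.graph if isinstance(graph, VariableGraph) else graph


def degree_assortativity(graph: VariableGraph | nx.Graph) -> float | None:
    """Newman's degree-degree Pearson correlation over edges.

    Returns None (undefined) for edgeless graphs and for graphs whose edge
    endpoint degrees have zero variance (e.g. regular graphs).
    """
    g = _as_nx(graph)
    if g.number_of_edges() == 0:
        return None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        value = nx.degree_assortativity_coefficient(g)
    if not np.isfinite(value):
        return None
    return float(value)


def average_clustering(graph: VariableGraph | nx.Graph) -> float:
    """Mean local clustering coefficient; nodes of degree < 2 contribute 0."""
    g = _as_nx(graph)
    if g.number_of_nodes() == 0:
        return 0.0
    return float(nx.average_clustering(g))


# --------------------------------------------------------------------------
# Threshold grid search
# --------------------------------------------------------------------------

def search_threshold(
    corr: CorrelationMatrix,
    t_start: int = 10,
    step: int = 1,
    t_max: int = 99,
    edge_rule: str = "signed",
) -> ThresholdSearchResult:
    """Assortativity-bounded threshold grid search.

    Starting at ``t_start`` (percent) the threshold is raised by ``step``
    while the graph remains assortative (defined assortativity > 0); the
    sweep stops at the first non-assortative threshold, and the previous
    threshold is retained as ``t_star``.  Undefined assortativity (edgeless
    or degree-regular graphs) counts as non-assortative.  When ``t_start``
    itself is non-assortative the result carries ``t_star=None`` together
    with the full trace; callers decide how to proceed.
    """
    if t_start > t_max:
        raise ValueError("t_start must not exceed t_max")
    if step < 1:
        raise ValueError("step must be a positive integer")
    trace: list[ThresholdTracePoint] = []
    t_star: int | None = None
    for t in range(t_start, t_max + 1, step):
        vg = build_graph(corr, t, edge_rule=edge_rule)
        point = ThresholdTracePoint(
            threshold_percent=t,
            assortativity=vg.assortativity,
            n_edges=vg.n_edges,
            avg_clustering=vg.avg_clustering,
        )
        trace.append(point)
        if not point.assortative:
            break
        t_star = t
    return ThresholdSearchResult(t_star=t_star, trace=tuple(trace))


# --------------------------------------------------------------------------
# I/O
# --------------------------------------------------------------------------

def write_correlation_csv(corr: CorrelationMatrix, path) -> None:
    """Square CSV with variable names as header row and column."""
    frame = pd.DataFrame(
        corr.values, index=list(corr.variables), columns=list(corr.variables)
    )
    frame.to_csv(path, index_label="variable", lineterminator="\n")


def read_correlation_csv(path) -> CorrelationMatrix:
    frame = pd.read_csv(path, index_col=0)
    if list(frame.index) != list(frame.columns):
        raise ValueError("correlation CSV must be square with matching labels")
    values = frame.to_numpy(dtype=float)
    n_pairs = np.zeros_like(values, dtype=int)  # unknown for external matrices
    return CorrelationMatrix(
        variables=tuple(frame.columns), values=values, n_pairs=n_pairs
    )
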