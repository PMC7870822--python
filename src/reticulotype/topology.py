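"""Network summary statistics and cross-network comparisons.

Topology metrics follow the conventions of the standard network-analyzer
tools: density 2E/(N(N-1)), diameter as the largest finite shortest-path
distance, characteristic path length as the mean shortest-path distance over
connected ordered pairs (disconnected pairs are ignored and the summary is
flagged when more than one component exists), and degree heterogeneity as
sqrt(population variance of degree) / mean degree.

Networks are compared with the overlap (Szymkiewicz-Simpson) coefficient
O(A, B) = |A n B| / min(|A|, |B|), applied to node sets or canonical edge
sets.  The single-outlier two-sided Grubbs test screens topology parameters
across a cohort.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .builder import Reticulotype
from .interactome import canonical_pair

logger = logging.getLogger(__name__)

__all__ = [
    "TopologySummary",
    "OverlapMatrix",
    "UniqueEdgeReport",
    "GrubbsResult",
    "summarize",
    "overlap_coefficient",
    "pairwise_overlap",
    "unique_edges",
    "unique_feature_edges",
    "grubbs_outlier",
]


@dataclass(frozen=True)
class TopologySummary:
    patient_id: str
    n_nodes: int
    n_edges: int
    density: float
    diameter: float
    characteristic_path_length: float
    heterogeneity: float
    n_components: int
    undefined: bool = False


def _as_graph(net) -> tuple[str, nx.Graph]:
    if isinstance(net, Reticulotype):
        g = nx.Graph()
        g.add_nodes_from(net.nodes)
        g.add_edges_from(net.edges)
        return net.patient_id, g
    if isinstance(net, nx.Graph):
        return str(net.graph.get("patient_id", "network")), net
    raise TypeError(f"cannot summarize {type(net).__name__}")


def summarize(net) -> TopologySummary:
    """Topology summary of one network (Reticulotype or networkx graph)."""
    pid, g = _as_graph(net)
    n, e = g.number_of_nodes(), g.number_of_edges()
    if n == 0:
        return TopologySummary(pid, 0, 0, math.nan, math.nan, math.nan, math.nan, 0, True)
    density = 2.0 * e / (n * (n - 1)) if n >= 2 else math.nan
    n_comp = nx.number_connected_components(g)
    if e == 0:
        return TopologySummary(pid, n, 0, density, math.nan, math.nan, math.nan, n_comp, True)
    dist_sum = 0
    dist_count = 0
    diameter = 0
    for _src, lengths in nx.all_pairs_shortest_path_length(g):
        for dst, d in lengths.items():
            if d > 0:
                dist_sum += d
                dist_count += 1
                diameter = max(diameter, d)
    cpl = dist_sum / dist_count
    degrees = np.array([d for _, d in g.degree()], dtype=float)
    het = math.sqrt(degrees.var()) / degrees.mean()  # population variance
    if n_comp > 1:
        logger.info(
            "network %s has %d components; path metrics cover connected pairs only",
            pid, n_comp,
        )
    return TopologySummary(pid, n, e, density, diameter, cpl, het, n_comp)


def summarize_cohort(cohort: Sequence) -> pd.DataFrame:
    rows = [summarize(net).__dict__ for net in cohort]
    return pd.DataFrame(rows)


def overlap_coefficient(A: Iterable, B: Iterable) -> float:
    """O(A, B) = |A n B| / min(|A|, |B|); 1 = containment, 0 = disjoint."""
    A, B = set(A), set(B)
    if not A or not B:
        raise ValueError("overlap coefficient undefined for empty sets")
    return len(A & B) / min(len(A), len(B))


@dataclass
class OverlapMatrix:
    """Pairwise overlap coefficients (square within a cohort, or rectangular
    between two cohorts); NaN marks networks empty in the requested mode."""

    ids: list[str]
    mode: str
    values: pd.DataFrame
    other_ids: list[str] | None = None

    def mean_off_diagonal(self) -> float:
        v = self.values.to_numpy(dtype=float)
        if self.other_ids is None:
            iu = np.triu_indices(v.shape[0], k=1)
            return float(np.nanmean(v[iu]))
        return float(np.nanmean(v))


def _mode_sets(cohort: Sequence[Reticulotype], mode: str) -> list[set]:
    if mode == "node":
        return [set(net.nodes) for net in cohort]
    if mode == "edge":
        return [{canonical_pair(*e) for e in net.edges} for net in cohort]
    raise ValueError(f"unknown overlap mode: {mode!r}")


def pairwise_overlap(
    cohort: Sequence[Reticulotype],
    mode: str = "node",
    other: Sequence[Reticulotype] | None = None,
) -> OverlapMatrix:
    """All-pairs overlap coefficients within a cohort (or across two).

    A network empty in the requested mode yields NaN for its row/column
    (overlap with an empty set is undefined).
    """
    if other is None and len(cohort) < 2:
        raise ValueError("pairwise overlap needs at least two networks")
    ids = [net.patient_id for net in cohort]
    sets_a = _mode_sets(cohort, mode)
    if other is None:
        ids_b, sets_b = ids, sets_a
    else:
        ids_b = [net.patient_id for net in other]
        sets_b = _mode_sets(other, mode)
    vals = np.full((len(sets_a), len(sets_b)), np.nan)
    for i, A in enumerate(sets_a):
        for j, B in enumerate(sets_b):
            if A and B:
                vals[i, j] = overlap_coefficient(A, B)
    frame = pd.DataFrame(vals, index=ids, columns=ids_b)
    return OverlapMatrix(
        ids=ids, mode=mode, values=frame,
        other_ids=None if other is None else ids_b,
    )


def unique_edges(cohort: Sequence[Reticulotype]) -> dict[str, set]:
    """Edges present in exactly one patient's network within the cohort."""
    if len(cohort) < 2:
        raise ValueError("unique edges need at least two networks")
    counts: dict[tuple[str, str], int] = {}
    for net in cohort:
        for e in net.edges:
            counts[e] = counts.get(e, 0) + 1
    return {
        net.patient_id: {e for e in net.edges if counts[e] == 1} for net in cohort
    }


@dataclass(frozen=True)
class UniqueEdgeReport:
    patient_id: str
    n_unique_edges: int
    n_unique_feature_edges: int
    feature_set_name: str


def unique_feature_edges(
    cohort: Sequence[Reticulotype],
    feature_set: Iterable[str],
    feature_set_name: str = "feature",
) -> list[UniqueEdgeReport]:
    """Per patient: unique edges touching at least one gene of the feature set
    (e.g. "unique fibrosis edges" when the set is a fibrosis gene list)."""
    genes = set(feature_set)
    if not genes:
        raise ValueError("feature set must be nonempty")
    uniq = unique_edges(cohort)
    return [
        UniqueEdgeReport(
            patient_id=pid,
            n_unique_edges=len(edges),
            n_unique_feature_edges=sum(
                1 for a, b in edges if a in genes or b in genes
            ),
            feature_set_name=feature_set_name,
        )
        for pid, edges in uniq.items()
    ]


@dataclass(frozen=True)
class GrubbsResult:
    index: int | None
    g: float
    critical: float
    p: float


def grubbs_outlier(values: Sequence[float], alpha: float = 0.05) -> GrubbsResult:
    """Two-sided single-outlier Grubbs test.

    G = max |x - mean| / sd (sample sd).  The critical value at level alpha is
    ((n-1)/sqrt(n)) * sqrt(t^2 / (n - 2 + t^2)) with t the upper alpha/(2n)
    quantile of Student's t with n-2 df.  Returns the flagged index when G
    exceeds it, else None.  One outlier per test, no iteration.
    """
    x = np.asarray(values, dtype=float)
    n = x.size
    if n < 3:
        raise ValueError("Grubbs test needs at least 3 values")
    sd = x.std(ddof=1)
    if sd == 0:
        logger.info("Grubbs test on constant values: no outlier")
        return GrubbsResult(None, 0.0, math.inf, 1.0)
    dev = np.abs(x - x.mean())
    idx = int(dev.argmax())
    g = dev[idx] / sd
    t_crit = stats.t.ppf(1 - alpha / (2 * n), n - 2)
    critical = (n - 1) / math.sqrt(n) * math.sqrt(t_crit**2 / (n - 2 + t_crit**2))
    # p-value by inverting the same relation
    denom = (n - 1) ** 2 - n * g**2
    if denom <= 0:
        p = 0.0
    else:
        t_g = math.sqrt(n * (n - 2) * g**2 / denom)
        p = min(1.0, 2 * n * stats.t.sf(t_g, n - 2))
    return GrubbsResult(idx if g > critical else None, float(g), float(critical), float(p))
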