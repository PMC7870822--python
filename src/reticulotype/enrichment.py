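"""Gene-set over-representation in patient networks.

Endophenotypes (fibrosis, hypertrophy signaling, ...) are represented as
gene sets.  For one patient network drawn from a universe of N genes, of
which K belong to a set, with n network genes in the universe and k of them
in the set, the one-tailed hypergeometric p-value P[X >= k] measures
over-representation.  Per-patient p-values across the sets of one catalog
are corrected with the Benjamini-Hochberg procedure; a cohort-level summary
reports, for each set, the fraction of patients whose q-value clears a
threshold.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "GeneSetCatalog",
    "EnrichmentResult",
    "read_gmt",
    "hypergeom_enrich",
    "benjamini_hochberg",
    "set_overlap_test",
    "enrich_cohort",
]


@dataclass
class GeneSetCatalog:
    """Named gene sets (e.g. one endophenotype per set)."""

    sets: dict[str, set[str]]
    source: str = ""

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise ValueError(f"gene set {name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> set[str]:
        return self.sets[name]

    def write_gmt(self, path) -> None:
        with open(path, "w") as fh:
            for name, members in self.sets.items():
                fh.write("\t".join([name, self.source or "na", *sorted(members)]) + "\n")


def read_gmt(path) -> GeneSetCatalog:
    """Read a GMT file: per line, set name, description, then member ids."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line needs >= 3 fields")
            name = fields[0]
            if name in sets:
                raise ValueError(f"{path}:{lineno}: duplicate set name {name!r}")
            sets[name] = set(fields[2:])
    return GeneSetCatalog(sets=sets, source=str(path))


@dataclass(frozen=True)
class EnrichmentResult:
    set_name: str
    k: int  # network genes in the set
    K: int  # universe genes in the set
    n: int  # network genes in the universe
    N: int  # universe size
    p: float
    q: float
    log_p: float  # -log10 p


def _upper_tail(k: int, N: int, K: int, n: int) -> float:
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def hypergeom_enrich(
    network_genes: Iterable[str],
    catalog: GeneSetCatalog,
    universe: Iterable[str],
) -> list[EnrichmentResult]:
    """Upper-tail hypergeometric enrichment of every catalog set.

    Network genes outside the universe are dropped (logged); catalog sets are
    intersected with the universe and sets that vanish are omitted (logged).
    BH correction runs across all retained sets; results sorted by p.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    net = set(network_genes)
    if not net:
        raise ValueError("empty network gene set")
    outside = net - universe
    if outside:
        logger.info("%d network gene(s) outside the universe dropped", len(outside))
        net &= universe
        if not net:
            raise ValueError("no network genes remain inside the universe")
    N, n = len(universe), len(net)
    rows: list[tuple[str, int, int]] = []
    for name, members in catalog.sets.items():
        members_u = members & universe
        if not members_u:
            logger.info("gene set %r absent from the universe; omitted", name)
            continue
        rows.append((name, len(net & members_u), len(members_u)))
    if not rows:
        return []
    p = [_upper_tail(k, N, K, n) for _, k, K in rows]
    q = benjamini_hochberg(p)
    results = [
        EnrichmentResult(
            set_name=name, k=k, K=K, n=n, N=N,
            p=p_i, q=q_i, log_p=-math.log10(p_i) if p_i > 0 else math.inf,
        )
        for (name, k, K), p_i, q_i in zip(rows, p, q)
    ]
    return sorted(results, key=lambda r: r.p)


def benjamini_hochberg(p_values: Sequence[float]) -> list[float]:
    """BH step-up q-values, order preserved relative to the input."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return []
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must be in [0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return [float(v) for v in q]


def set_overlap_test(
    setA: Iterable[str], setB: Iterable[str], universe: Iterable[str]
) -> tuple[int, float]:
    """Overlap size and upper-tail hypergeometric p for two gene sets.

    Symmetric in A and B.  Sets are intersected with the universe first.
    """
    universe = set(universe)
    A = set(setA) & universe
    B = set(setB) & universe
    if not universe or not A or not B:
        raise ValueError("sets and universe must be nonempty")
    k = len(A & B)
    return k, _upper_tail(k, len(universe), len(A), len(B))


def enrich_cohort(
    cohort: Sequence,
    catalog: GeneSetCatalog,
    universe: Iterable[str],
    q_threshold: float = 0.05,
) -> tuple[pd.DataFrame, pd.Series]:
    """Per-patient enrichment plus, per set, the fraction of patients enriched.

    BH correction is per patient across the catalog; the cohort frequency of
    a set counts patients with q below ``q_threshold``.
    """
    if not len(cohort):
        raise ValueError("empty cohort")
    universe = set(universe)
    frames = []
    for net in cohort:
        results = hypergeom_enrich(net.nodes, catalog, universe)
        frame = pd.DataFrame([r.__dict__ for r in results])
        frame.insert(0, "patient_id", net.patient_id)
        frames.append(frame)
    table = pd.concat(frames, ignore_index=True)
    freq = (
        table.assign(hit=table["q"] < q_threshold)
        .groupby("set_name")["hit"]
        .mean()
        .rename("cohort_frequency")
    )
    return table, freq
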