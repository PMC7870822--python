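"""Consolidated protein-protein interactome.

Interactions are treated as binary, undirected physical links: source files
may disagree on orientation or carry confidence scores, but the consolidated
map is a simple graph.  Edges are canonicalized as lexicographically sorted
pairs; self-loops are dropped (and counted); duplicates across sources are
merged with their source tags unioned.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx

logger = logging.getLogger(__name__)

__all__ = ["Interactome", "canonical_pair", "read_interactome", "induced_edges"]

Edge = tuple[str, str]


def canonical_pair(a: str, b: str) -> Edge:
    """Unordered pair in canonical (lexicographic) form."""
    return (a, b) if a <= b else (b, a)


@dataclass
class Interactome:
    """Simple undirected PPI graph with per-edge source provenance."""

    proteins: set[str]
    edges: set[Edge]
    source_tags: dict[Edge, set[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for a, b in self.edges:
            if a == b:
                raise ValueError(f"self-loop on {a!r}")
            if (a, b) != canonical_pair(a, b):
                raise ValueError(f"edge not canonical: {(a, b)!r}")
        endpoints = {p for e in self.edges for p in e}
        if not endpoints <= self.proteins:
            raise ValueError("edge endpoint missing from protein set")

    @property
    def n_proteins(self) -> int:
        return len(self.proteins)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def __contains__(self, pair: Edge) -> bool:
        return canonical_pair(*pair) in self.edges

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.proteins)
        g.add_edges_from(self.edges)
        return g

    def coverage(self, gene_ids: Iterable[str]) -> float:
        """Fraction of the given genes present in the interactome."""
        genes = list(gene_ids)
        if not genes:
            return 0.0
        return sum(g in self.proteins for g in genes) / len(genes)

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("protein_a\tprotein_b\tsources\n")
            for a, b in sorted(self.edges):
                tags = ",".join(sorted(self.source_tags.get((a, b), set())))
                fh.write(f"{a}\t{b}\t{tags}\n")


def _parse_edge_line(line: str, lineno: int, path) -> Edge | None:
    fields = line.rstrip("\n").split("\t")
    if len(fields) == 1:
        fields = line.split()
    # SIF: "A pp B" (interaction type in the middle)
    if len(fields) >= 3 and fields[1] in ("pp", "pd", "interacts"):
        a, b = fields[0], fields[2]
    elif len(fields) >= 2:
        a, b = fields[0], fields[1]
    else:
        raise ValueError(f"{path}:{lineno}: expected at least two columns")
    if not a or not b:
        raise ValueError(f"{path}:{lineno}: empty interactor id")
    if a == b:
        return None
    return canonical_pair(a, b)


def read_interactome(
    paths: Sequence, tags: Sequence[str] | None = None
) -> Interactome:
    """Union one or more edge-list files (TSV or SIF) into one interactome.

    The result is independent of file order; self-loops are dropped with a
    logged count and duplicate edges merged with unioned source tags.
    """
    paths = list(paths)
    if tags is None:
        tags = [str(p) for p in paths]
    if len(tags) != len(paths):
        raise ValueError("one tag per input file required")
    edges: set[Edge] = set()
    source_tags: dict[Edge, set[str]] = {}
    n_loops = 0
    for path, tag in zip(paths, tags):
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                if not line.strip() or line.startswith("#"):
                    continue
                if lineno == 1 and line.lower().startswith(("protein_a", "interactor")):
                    continue  # header row
                pair = _parse_edge_line(line, lineno, path)
                if pair is None:
                    n_loops += 1
                    continue
                edges.add(pair)
                source_tags.setdefault(pair, set()).add(tag)
    if n_loops:
        logger.info("dropped %d self-loop(s) during consolidation", n_loops)
    if not edges:
        raise ValueError("interactome is empty after consolidation")
    proteins = {p for e in edges for p in e}
    return Interactome(proteins=proteins, edges=edges, source_tags=source_tags)


def induced_edges(i: Interactome, pairs: Iterable[Edge]) -> set[Edge]:
    """Intersection of candidate gene pairs with the interactome's edges."""
    canon = {canonical_pair(*p) for p in pairs}
    return canon & i.edges
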