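"""Count-matrix handling for the network pipeline.

Raw RNA-Seq gene-by-sample count matrices are the substrate for everything
downstream: the reference co-expression model is fitted on the control
columns, and each patient column is tested against it one at a time.  This
module reads count TSVs, applies the control-based abundance filters, the
protein-coding restriction, computes per-gene coefficients of variation, and
normalizes counts for correlation analysis.

Filters deliberately look only at control samples: the gene universe of the
reference model must not depend on which patients happen to be present.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "GeneStats",
    "read_counts",
    "filter_genes",
    "restrict_protein_coding",
    "coefficient_of_variation",
    "normalize",
    "fold_change",
]

CONTROL = "control"
PATIENT = "patient"
PROTEIN_CODING = "protein_coding"


@dataclass
class ExpressionMatrix:
    """Gene x sample integer count matrix with gene biotypes and sample groups.

    Parameters
    ----------
    counts : pandas.DataFrame
        Non-negative integers, genes in rows, samples in columns.
    biotype : pandas.Series
        Per-gene label, indexed like ``counts``; at least the value
        ``"protein_coding"`` is meaningful downstream.
    group : pandas.Series
        Per-sample label, ``"control"`` or ``"patient"``, indexed by sample id.
    """

    counts: pd.DataFrame
    biotype: pd.Series = field(default=None)  # type: ignore[assignment]
    group: pd.Series = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.counts.index.duplicated().any():
            dup = self.counts.index[self.counts.index.duplicated()][0]
            raise ValueError(f"duplicate gene id: {dup!r}")
        if self.counts.columns.duplicated().any():
            dup = self.counts.columns[self.counts.columns.duplicated()][0]
            raise ValueError(f"duplicate sample id: {dup!r}")
        values = self.counts.to_numpy()
        if values.size and not np.issubdtype(values.dtype, np.integer):
            if np.isnan(values.astype(float)).any():
                raise ValueError("counts contain missing values")
            if not np.array_equal(values, np.floor(values)):
                raise ValueError("counts must be integers")
            self.counts = self.counts.astype(np.int64)
            values = self.counts.to_numpy()
        if values.size and (values < 0).any():
            raise ValueError("counts must be non-negative")
        if self.biotype is None:
            self.biotype = pd.Series(PROTEIN_CODING, index=self.counts.index)
        else:
            self.biotype = self.biotype.reindex(self.counts.index).fillna("unknown")
        if self.group is None:
            self.group = pd.Series(CONTROL, index=self.counts.columns)
        else:
            self.group = self.group.reindex(self.counts.columns)
            if self.group.isna().any():
                missing = list(self.group.index[self.group.isna()])
                raise ValueError(f"samples without group assignment: {missing}")
            bad = set(self.group.unique()) - {CONTROL, PATIENT}
            if bad:
                raise ValueError(f"unknown group labels: {sorted(bad)}")

    # -- conveniences -----------------------------------------------------
    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    @property
    def control_ids(self) -> list[str]:
        return list(self.group.index[self.group == CONTROL])

    @property
    def patient_ids(self) -> list[str]:
        return list(self.group.index[self.group == PATIENT])

    def select_genes(self, gene_ids: Sequence[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(
            counts=self.counts.loc[list(gene_ids)],
            biotype=self.biotype.loc[list(gene_ids)],
            group=self.group.copy(),
        )

    def with_groups(self, groups: Mapping[str, str]) -> "ExpressionMatrix":
        return replace(self, group=pd.Series(dict(groups)))


@dataclass(frozen=True)
class GeneStats:
    """Per-gene summary of read-count mean, spread and relative spread."""

    gene_id: str
    mean_count: float
    sd_count: float
    cv_percent: float
    undefined: bool = False


def read_counts(
    path,
    biotype_map: Mapping[str, str] | None = None,
    groups: Mapping[str, str] | None = None,
) -> ExpressionMatrix:
    """Read a TSV count matrix (header = sample ids, one row per gene).

    ``biotype_map`` optionally assigns a biotype per gene id; genes absent
    from the map get ``"unknown"``.  Without a map every gene is treated as
    protein coding (unannotated matrices stay fully usable).  ``groups``
    optionally assigns ``"control"``/``"patient"`` per sample.
    """
    try:
        table = pd.read_csv(path, sep="\t", index_col=0)
    except pd.errors.ParserError as exc:  # ragged rows: keep pandas' line number
        raise ValueError(f"malformed count matrix {path}: {exc}") from exc
    if table.index.duplicated().any():
        dup = table.index[table.index.duplicated()][0]
        raise ValueError(f"duplicate gene id in {path}: {dup!r}")
    biotype = None
    if biotype_map is not None:
        biotype = pd.Series({g: biotype_map.get(g, "unknown") for g in table.index})
    group = pd.Series(dict(groups)) if groups is not None else None
    return ExpressionMatrix(counts=table, biotype=biotype, group=group)


def read_biotype_map(path) -> dict[str, str]:
    """Read a two-column TSV (gene_id, biotype) into a mapping."""
    table = pd.read_csv(path, sep="\t", header=None, names=["gene_id", "biotype"])
    return dict(zip(table["gene_id"], table["biotype"]))


def filter_genes(
    m: ExpressionMatrix,
    mode: str = "any_sample",
    min_count: int = 10,
) -> ExpressionMatrix:
    """Two-stage abundance filter evaluated on control columns only.

    Stage 1 removes genes with zero counts in every control sample.  Stage 2
    keeps genes with at least ``min_count`` reads in at least one control
    (``mode="any_sample"``) or in every control (``mode="all_samples"``, the
    stricter robustness variant).  Patient columns are never consulted; gene
    order is preserved.  Idempotent.
    """
    if mode not in ("any_sample", "all_samples"):
        raise ValueError(f"unknown filter mode: {mode!r}")
    if min_count < 1:
        raise ValueError("min_count must be >= 1")
    controls = m.control_ids
    if not controls:
        raise ValueError("filter_genes requires at least one control sample")
    ctrl = m.counts[controls].to_numpy()
    stage1 = ctrl.sum(axis=1) > 0
    if mode == "any_sample":
        stage2 = (ctrl >= min_count).any(axis=1)
    else:
        stage2 = (ctrl >= min_count).all(axis=1)
    keep = stage1 & stage2
    return m.select_genes([g for g, k in zip(m.gene_ids, keep) if k])


def restrict_protein_coding(m: ExpressionMatrix) -> ExpressionMatrix:
    """Keep only protein-coding genes (networks are built over proteins)."""
    keep = m.biotype[m.biotype == PROTEIN_CODING].index
    if len(keep) == 0:
        raise ValueError("no protein-coding genes remain")
    return m.select_genes(list(keep))


def coefficient_of_variation(
    m: ExpressionMatrix, samples: Sequence[str] | None = None
) -> list[GeneStats]:
    """Per-gene CV in percent: sample (n-1) sd over mean, times 100.

    Genes with zero mean get ``cv_percent = nan`` and ``undefined=True``
    rather than raising.
    """
    cols = list(samples) if samples is not None else m.sample_ids
    if len(cols) < 2:
        raise ValueError("coefficient of variation needs >= 2 samples")
    x = m.counts[cols].to_numpy(dtype=float)
    mean = x.mean(axis=1)
    sd = x.std(axis=1, ddof=1)
    out: list[GeneStats] = []
    for g, mu, s in zip(m.gene_ids, mean, sd):
        if mu == 0:
            out.append(GeneStats(g, 0.0, float(s), math.nan, undefined=True))
        else:
            out.append(GeneStats(g, float(mu), float(s), float(s / mu * 100.0)))
    return out


def normalize(m: ExpressionMatrix, method: str = "log2_cpm") -> pd.DataFrame:
    """Normalize counts for correlation analysis.

    ``"log2_cpm"`` scales each sample to counts-per-million and applies
    log2(x+1); ``"raw"`` casts counts to float unchanged.  A sample with a
    zero library size cannot be scaled and is a hard error.
    """
    if method == "raw":
        return m.counts.astype(float)
    if method == "log2_cpm":
        totals = m.counts.sum(axis=0)
        zero = totals.index[totals == 0]
        if len(zero):
            raise ValueError(f"zero total count in sample(s): {list(zero)}")
        cpm = m.counts / totals * 1e6
        return np.log2(cpm + 1.0)
    raise ValueError(f"unknown normalization method: {method!r}")


def fold_change(a: float, b: float) -> float:
    """Read-count ratio a/b (e.g. 4227 vs 2081 reads -> 2.03-fold)."""
    if b == 0:
        raise ValueError("fold change undefined for zero denominator")
    return a / b
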