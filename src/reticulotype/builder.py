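"""Patient-specific perturbed-correlation network construction.

The core of the package.  A reference co-expression model is fitted once on
a small control cohort: the Pearson correlation r of every gene pair over
the n control samples.  One patient profile is then appended to the control
matrix and every pair's correlation is recomputed (r').  The perturbation
statistic for a pair is

    z = (r' - r) / ((1 - r^2) / (n - 1))

with a two-sided p-value from the standard normal and Bonferroni correction
over the family of tested pairs.  Pairs that remain significant and are
supported by a physical interaction in the consolidated interactome become
the edges of that patient's network (the "reticulotype").

The normal approximation for z is asymptotic in n.  At the small reference
sizes this design targets (n = 5), its null distribution is much heavier
than N(0, 1) — see docs/methods.md for the calibration analysis.  The
statistic is implemented exactly as defined; interpreting the resulting
networks as strictly error-controlled discoveries is not supported at
small n.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .expression import CONTROL, ExpressionMatrix, normalize
from .interactome import Interactome, canonical_pair

logger = logging.getLogger(__name__)

__all__ = [
    "count_pairs",
    "z_statistic",
    "PerturbationRecord",
    "Reticulotype",
    "ReticulotypeBuilder",
    "build_reticulotype",
    "run_cohort",
    "CohortResult",
]

_VAR_TOL = 1e-12


def count_pairs(m: int) -> int:
    """Number of distinct unordered gene pairs among m genes: m(m-1)/2."""
    if m < 2:
        raise ValueError("need at least 2 genes to form a pair")
    return m * (m - 1) // 2


def z_statistic(r, r_prime, n):
    """Perturbation z and two-sided normal p for a correlation change.

    z = (r' - r) / ((1 - r^2)/(n - 1)) with n the reference cohort size.
    Where |r| = 1 the scale collapses: a zero change gives z = 0, a nonzero
    change a signed infinity (p = 0).  Accepts scalars or arrays.
    """
    scalar = np.ndim(r) == 0 and np.ndim(r_prime) == 0
    r = np.atleast_1d(np.asarray(r, dtype=float))
    r_prime = np.atleast_1d(np.asarray(r_prime, dtype=float))
    delta = r_prime - r
    sigma = (1.0 - r**2) / (n - 1)
    z = np.empty_like(delta)
    degenerate = sigma <= 0
    with np.errstate(divide="ignore", invalid="ignore"):
        np.divide(delta, sigma, out=z, where=~degenerate)
    signs = np.sign(delta[degenerate])
    with np.errstate(invalid="ignore"):
        z[degenerate] = np.where(signs == 0.0, 0.0, signs * np.inf)
    p = 2.0 * stats.norm.sf(np.abs(z))
    if scalar:
        return float(z[0]), float(p[0])
    return z, p


@dataclass(frozen=True)
class PerturbationRecord:
    """One gene pair's correlation change when a patient sample is added."""

    gene_a: str
    gene_b: str
    r: float
    r_prime: float
    delta: float
    z: float
    p: float
    p_adjusted: float
    significant: bool


@dataclass
class Reticulotype:
    """One patient's PPI network of significantly perturbed gene pairs."""

    patient_id: str
    nodes: set[str]
    edges: set[tuple[str, str]]
    records: dict[tuple[str, str], PerturbationRecord]
    params: dict = field(default_factory=dict)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        for e in self.edges:
            g.add_edge(*e, **(self.records[e].__dict__ if e in self.records else {}))
        return g

    def to_frame(self) -> pd.DataFrame:
        rows = [self.records[e].__dict__ for e in sorted(self.edges)]
        cols = [
            "gene_a", "gene_b", "r", "r_prime", "delta", "z", "p",
            "p_adjusted", "significant",
        ]
        return pd.DataFrame(rows, columns=cols)


class ReticulotypeBuilder(BaseEstimator):
    """Estimator mapping patient expression profiles to perturbation networks.

    Parameters
    ----------
    alpha : float
        Significance level applied to Bonferroni-adjusted p-values.
    family : {"tested_pairs", "interactome_pairs"}
        Bonferroni family.  ``"tested_pairs"`` tests every valid gene pair
        and corrects over all of them (matching the method's canonical order of
        operations: test first, map to the interactome second).
        ``"interactome_pairs"`` restricts testing to pairs with a known
        physical interaction — a deliberately smaller family, tractable for
        large gene sets.
    interactome : Interactome
        The consolidated PPI map; required to build networks and for the
        ``"interactome_pairs"`` family.

    Attributes
    ----------
    gene_ids_ : list of str
        Gene order of the fitted reference.
    n_reference_ : int
        Number of control samples n.
    r_ : ndarray (m, m)
        Reference pairwise Pearson correlations (NaN where invalid).
    valid_pair_ : ndarray of bool (m, m)
        False where either gene has zero variance across controls.
    """

    def __init__(
        self,
        alpha: float = 0.05,
        family: str = "tested_pairs",
        interactome: Interactome | None = None,
    ):
        self.alpha = alpha
        self.family = family
        self.interactome = interactome

    # -- fitting ----------------------------------------------------------
    def fit(self, X, y=None, gene_ids: Sequence[str] | None = None):
        """Fit the reference correlation model on control samples.

        ``X`` is (n_samples, n_genes): rows are control samples, columns are
        genes (a DataFrame's columns supply ``gene_ids_``).
        """
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        if self.family not in ("tested_pairs", "interactome_pairs"):
            raise ValueError(f"unknown family mode: {self.family!r}")
        if isinstance(X, pd.DataFrame):
            if gene_ids is None:
                gene_ids = list(X.columns)
            X = X.to_numpy(dtype=float)
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-dimensional (samples x genes)")
        n, m = X.shape
        if n < 3:
            raise ValueError(
                f"need >= 3 control samples to fit the reference, got {n}"
            )
        if m < 2:
            raise ValueError("need >= 2 genes")
        if gene_ids is None:
            gene_ids = [f"g{i}" for i in range(m)]
        if len(gene_ids) != m:
            raise ValueError("gene_ids length does not match number of genes")

        self.gene_ids_ = list(gene_ids)
        self.n_reference_ = n
        mean = X.mean(axis=0)
        Xc = X - mean
        C = Xc.T @ Xc  # centered cross-products, the incremental sufficient stats
        var = np.diag(C)
        valid_gene = var > _VAR_TOL
        denom = np.sqrt(np.outer(var, var))
        with np.errstate(invalid="ignore", divide="ignore"):
            r = C / denom
        r[~valid_gene, :] = np.nan
        r[:, ~valid_gene] = np.nan
        np.fill_diagonal(r, 1.0)
        r = np.clip(r, -1.0, 1.0)

        self.mean_ = mean
        self._crossprod = C
        self.valid_gene_ = valid_gene
        self.valid_pair_ = np.outer(valid_gene, valid_gene)
        np.fill_diagonal(self.valid_pair_, False)
        self.r_ = r
        if self.family == "interactome_pairs" and self.interactome is None:
            raise ValueError("family='interactome_pairs' requires an interactome")
        self._tested_mask = self._make_tested_mask()
        return self

    def _make_tested_mask(self) -> np.ndarray:
        """Upper-triangular boolean mask of pairs this builder will test."""
        m = len(self.gene_ids_)
        mask = np.triu(self.valid_pair_, k=1)
        if self.family == "interactome_pairs":
            index = {g: i for i, g in enumerate(self.gene_ids_)}
            inter = np.zeros_like(mask)
            for a, b in self.interactome.edges:
                if a in index and b in index:
                    i, j = sorted((index[a], index[b]))
                    inter[i, j] = True
            mask &= inter
        return mask

    # -- perturbation -----------------------------------------------------
    def perturb(self, x, family_size: int | None = None) -> list[PerturbationRecord]:
        """Test every pair for correlation change when sample ``x`` is added.

        ``x`` is one patient's normalized profile aligned with ``gene_ids_``
        (a Series is aligned by index).  Returns records for tested pairs
        only; the Bonferroni family size defaults to the number of tested
        pairs under the configured family mode.
        """
        self._check_fitted()
        if isinstance(x, pd.Series):
            if list(x.index) != self.gene_ids_:
                if set(x.index) != set(self.gene_ids_):
                    raise ValueError("patient gene ids do not match the reference")
                x = x.loc[self.gene_ids_]
            x = x.to_numpy(dtype=float)
        x = np.asarray(x, dtype=float).ravel()
        if x.shape[0] != len(self.gene_ids_):
            raise ValueError(
                "patient profile length does not match the reference gene set"
            )
        r_prime, valid_prime = self._r_prime(x)
        mask = self._tested_mask & np.triu(valid_prime, k=1)
        n_dropped = int(self._tested_mask.sum() - mask.sum())
        if n_dropped:
            logger.info(
                "%d pair(s) excluded: zero variance after adding the patient",
                n_dropped,
            )
        ii, jj = np.nonzero(mask)
        if family_size is None:
            family_size = len(ii)
        r = self.r_[ii, jj]
        rp = r_prime[ii, jj]
        # |r| = 1 in the reference collapses the scale; z_statistic maps a
        # nonzero delta there to a signed infinity (logged below).
        z, p = z_statistic(r, rp, self.n_reference_)
        n_inf = int(np.isinf(z).sum())
        if n_inf:
            logger.info("%d pair(s) with |r|=1 and nonzero delta (z=inf)", n_inf)
        p_adj = np.minimum(1.0, p * family_size)
        sig = p_adj < self.alpha
        records = [
            PerturbationRecord(
                *canonical_pair(self.gene_ids_[i], self.gene_ids_[j]),
                r=float(r_k),
                r_prime=float(rp_k),
                delta=float(rp_k - r_k),
                z=float(z_k),
                p=float(p_k),
                p_adjusted=float(pa_k),
                significant=bool(s_k),
            )
            for i, j, r_k, rp_k, z_k, p_k, pa_k, s_k in zip(
                ii, jj, r, rp, z, p, p_adj, sig
            )
        ]
        return records

    def _r_prime(self, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Rank-1 update of the pairwise correlations for controls + x.

        With controls centered at their mean, the centered cross-product
        matrix of the n+1 samples is C + (n/(n+1)) * yc yc^T where
        yc = x - control_mean.  Correlations follow directly.
        """
        n = self.n_reference_
        yc = x - self.mean_
        M = self._crossprod + (n / (n + 1.0)) * np.outer(yc, yc)
        var = np.diag(M).copy()
        valid = var > _VAR_TOL
        denom = np.sqrt(np.outer(var, var))
        with np.errstate(invalid="ignore", divide="ignore"):
            rp = M / denom
        rp[~valid, :] = np.nan
        rp[:, ~valid] = np.nan
        np.fill_diagonal(rp, 1.0)
        rp = np.clip(rp, -1.0, 1.0)
        return rp, np.outer(valid, valid)

    # -- network construction --------------------------------------------
    def transform(self, X, patient_ids: Sequence[str] | None = None) -> list[Reticulotype]:
        """Build one network per patient row of ``X``."""
        self._check_fitted()
        if self.interactome is None:
            raise ValueError("an interactome is required to build networks")
        if isinstance(X, pd.DataFrame):
            if patient_ids is None:
                patient_ids = list(X.index)
            if list(X.columns) != self.gene_ids_:
                if set(X.columns) != set(self.gene_ids_):
                    raise ValueError("patient gene ids do not match the reference")
                X = X[self.gene_ids_]
            X = X.to_numpy(dtype=float)
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if patient_ids is None:
            patient_ids = [f"patient_{k}" for k in range(X.shape[0])]
        nets = []
        for pid, row in zip(patient_ids, X):
            records = self.perturb(row)
            nets.append(
                build_reticulotype(
                    records, self.interactome, pid, params=self._params_snapshot()
                )
            )
        return nets

    def fit_transform(self, X, y=None, **kw):  # controls != patients here
        raise NotImplementedError(
            "fit on control samples, then transform patient samples"
        )

    def _params_snapshot(self) -> dict:
        return {
            "alpha": self.alpha,
            "family": self.family,
            "n_reference": self.n_reference_,
            "n_genes": len(self.gene_ids_),
            "family_size": int(self._tested_mask.sum()),
        }

    def _check_fitted(self) -> None:
        if not hasattr(self, "r_"):
            raise ValueError("this ReticulotypeBuilder instance is not fitted yet")


def build_reticulotype(
    records: Iterable[PerturbationRecord],
    interactome: Interactome,
    patient_id: str,
    params: dict | None = None,
) -> Reticulotype:
    """Map significant perturbed pairs onto the interactome.

    Edges are the significant pairs with a known physical interaction; nodes
    are their endpoints (no isolated nodes).  An empty network is legal and
    logged.
    """
    sig = {
        canonical_pair(rec.gene_a, rec.gene_b): rec
        for rec in records
        if rec.significant
    }
    edges = set(sig) & interactome.edges
    nodes = {p for e in edges for p in e}
    if not edges:
        logger.info("patient %s: no significant pair maps to the interactome", patient_id)
    return Reticulotype(
        patient_id=patient_id,
        nodes=nodes,
        edges=edges,
        records={e: sig[e] for e in edges},
        params=params or {},
    )


@dataclass
class CohortResult:
    """Networks for every patient plus the shared fitted reference."""

    networks: list[Reticulotype]
    builder: ReticulotypeBuilder
    log: dict


def run_cohort(
    matrix: ExpressionMatrix,
    interactome: Interactome,
    normalization: str = "log2_cpm",
    alpha: float = 0.05,
    family: str = "tested_pairs",
) -> CohortResult:
    """Build one network per patient sample against a single fitted reference.

    The reference is fitted once on the control columns of ``matrix`` and
    reused for every patient (each patient is tested alone against the same
    control matrix).  Deterministic given its inputs.
    """
    controls = matrix.control_ids
    patients = matrix.patient_ids
    if not controls:
        raise ValueError("cohort has no control samples")
    values = normalize(matrix, method=normalization)
    builder = ReticulotypeBuilder(alpha=alpha, family=family, interactome=interactome)
    builder.fit(values[controls].T)
    nets = builder.transform(values[patients].T) if patients else []
    log = {
        "n_genes": matrix.n_genes,
        "n_controls": len(controls),
        "n_patients": len(patients),
        "normalization": normalization,
        "family": family,
        "family_size": int(builder._tested_mask.sum()),
        "n_valid_pairs": int(np.triu(builder.valid_pair_, k=1).sum()),
        "n_all_pairs": count_pairs(matrix.n_genes) if matrix.n_genes >= 2 else 0,
        "alpha": alpha,
        "per_patient": {
            net.patient_id: {"n_nodes": net.n_nodes, "n_edges": net.n_edges}
            for net in nets
        },
    }
    return CohortResult(networks=nets, builder=builder, log=log)
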