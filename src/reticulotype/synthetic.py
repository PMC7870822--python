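"""Synthetic myectomy-style cohorts with known ground truth.

The generator emulates the inputs of the study design this package
implements: a small healthy-control cohort (default n = 5) of RNA-Seq count
profiles with block-correlated gene modules, patient samples that perturb
the correlation structure of chosen modules, an interactome containing a
declared fraction of the within-module pairs plus sparse random background,
a gene-set catalog naming the modules, and a clinical table whose variable
is a noisy linear function of each patient's planted perturbation burden.

Count model
-----------
Per sample, each module has a latent activity factor f ~ N(0, 1).  A module
gene's log mean is

    log mu = baseline + loading * f + eps,   eps ~ N(0, sigma_e)

with loading = sqrt(rho) * tau and sigma_e = sqrt(1 - rho) * tau, so that
any two module genes have latent log-scale correlation rho and marginal
latent sd tau.  Background genes use independent N(0, tau) variation.
Counts are negative binomial around exp(log mu) with a common dispersion.

Perturbation effects (per patient, per module):

* ``"decouple"`` — the module loses coordination: each gene independently
  draws full-variance noise N(0, tau) in place of loading * f + eps
  (marginal variance preserved, correlation destroyed).  Ground-truth
  perturbed pairs: all within-module pairs.
* ``"flip"`` — part of the module inverts its coupling: the loading of a
  ``flip_fraction`` tail of the module's genes is negated, so pairs that
  cross the flipped boundary swing from +rho to -rho.  Ground-truth
  perturbed pairs: the crossing pairs.  (Negating every loading would leave
  all pairwise correlations unchanged, which is why the flip is partial.)

Perturbed modules are additionally *activated*: the patient's factor for a
perturbed module is drawn from N(activation, 1) rather than N(0, 1),
mirroring the strong differential expression of disease pathways in
diseased tissue.  Set ``activation=0`` for pure rewiring.

All randomness flows from a single integer seed.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from .enrichment import GeneSetCatalog
from .expression import CONTROL, PATIENT, ExpressionMatrix
from .interactome import Interactome, canonical_pair

__all__ = [
    "ModuleSpec",
    "SyntheticCohortSpec",
    "SyntheticTruth",
    "SyntheticCohort",
    "generate",
    "truth_recall",
    "RecallPrecision",
]

Edge = tuple[str, str]


@dataclass(frozen=True)
class ModuleSpec:
    """A correlated gene module: name, size, within-module latent rho."""

    name: str
    n_genes: int
    rho: float = 0.9

    def __post_init__(self) -> None:
        if self.n_genes < 2:
            raise ValueError(f"module {self.name!r} needs >= 2 genes")
        if not 0.0 <= self.rho < 1.0:
            raise ValueError(f"module {self.name!r}: rho must be in [0, 1)")


@dataclass
class SyntheticCohortSpec:
    """Full parameterization of one generated cohort.

    Defaults mirror the study conditions this package models: 5 controls,
    18 patients, 20-gene endophenotype modules with latent rho 0.9, bulk
    RNA-Seq-like negative binomial counts, an interactome with background
    density matching a genome-scale physical interactome (~1.6e-3), and a
    cardiac-output-style clinical variable declining with perturbation
    burden.
    """

    n_genes: int = 200
    n_controls: int = 5
    n_patients: int = 18
    modules: list[ModuleSpec] = field(default_factory=list)
    # per patient: list of (module_name, effect) with effect decouple|flip
    perturbations: list[list[tuple[str, str]]] = field(default_factory=list)
    latent_sd: float = 0.7
    activation: float = 2.5
    dispersion: float = 0.05
    log_mean_range: tuple[float, float] = (math.log(20.0), math.log(2000.0))
    flip_fraction: float = 0.5
    module_pair_coverage: float = 0.5
    background_edge_prob: float = 0.0016
    clinical_variable: str = "CO"
    clinical_intercept: float = 5.5
    clinical_slope: float = -0.01
    clinical_noise_sd: float = 0.3
    noncoding_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if sum(m.n_genes for m in self.modules) > self.n_genes:
            raise ValueError("module gene counts exceed n_genes")
        names = [m.name for m in self.modules]
        if len(set(names)) != len(names):
            raise ValueError("duplicate module names")
        if self.perturbations and len(self.perturbations) != self.n_patients:
            raise ValueError("need one perturbation list per patient")
        known = set(names)
        for plist in self.perturbations:
            for mod, effect in plist:
                if mod not in known:
                    raise ValueError(f"perturbation names unknown module {mod!r}")
                if effect not in ("decouple", "flip"):
                    raise ValueError(f"unknown effect {effect!r}")
        if not 0.0 < self.module_pair_coverage <= 1.0:
            raise ValueError("module_pair_coverage must be in (0, 1]")
        if not 0.0 <= self.background_edge_prob <= 1.0:
            raise ValueError("background_edge_prob must be in [0, 1]")
        if not 0.0 < self.flip_fraction < 1.0:
            raise ValueError("flip_fraction must be in (0, 1)")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")
        if self.n_controls < 3:
            raise ValueError("need >= 3 controls")

    @classmethod
    def default(cls, seed: int = 0) -> "SyntheticCohortSpec":
        """Study-emulating cohort: every patient perturbs the fibrosis
        module; 2 of 18 also perturb hypertrophy; extra modules cycle to
        spread the perturbation burden across patients."""
        modules = [
            ModuleSpec("fibrosis", 20, 0.9),
            ModuleSpec("hypertrophy", 20, 0.9),
            ModuleSpec("metabolism", 20, 0.9),
            ModuleSpec("inflammation", 20, 0.9),
        ]
        perturbations: list[list[tuple[str, str]]] = []
        for i in range(18):
            plist = [("fibrosis", "decouple")]
            if i < 2:
                plist.append(("hypertrophy", "decouple"))
            if i % 3 == 1:
                plist.append(("metabolism", "decouple"))
            if i % 3 == 2:
                plist.append(("metabolism", "decouple"))
                plist.append(("inflammation", "decouple"))
            perturbations.append(plist)
        return cls(modules=modules, perturbations=perturbations, seed=seed)


@dataclass
class SyntheticTruth:
    """Ground truth of one generated cohort."""

    perturbed_pairs: dict[str, set[Edge]]  # per patient, all planted pairs
    covered_pairs: dict[str, set[Edge]]  # planted pairs present in interactome
    module_members: dict[str, list[str]]
    clinical_params: dict

    def to_json(self, path) -> None:
        payload = {
            "perturbed_pairs": {
                k: sorted(map(list, v)) for k, v in self.perturbed_pairs.items()
            },
            "covered_pairs": {
                k: sorted(map(list, v)) for k, v in self.covered_pairs.items()
            },
            "module_members": self.module_members,
            "clinical_params": self.clinical_params,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)


@dataclass
class SyntheticCohort:
    expression: ExpressionMatrix
    interactome: Interactome
    catalog: GeneSetCatalog
    clinical: pd.DataFrame
    truth: SyntheticTruth
    spec: SyntheticCohortSpec


def _module_layout(spec: SyntheticCohortSpec) -> dict[str, list[str]]:
    gene_ids = [f"G{i:04d}" for i in range(spec.n_genes)]
    layout: dict[str, list[str]] = {}
    start = 0
    for mod in spec.modules:
        layout[mod.name] = gene_ids[start : start + mod.n_genes]
        start += mod.n_genes
    layout["__background__"] = gene_ids[start:]
    return layout


def _planted_pairs(spec: SyntheticCohortSpec, layout, mod_name, effect) -> set[Edge]:
    genes = layout[mod_name]
    if effect == "decouple":
        return {
            canonical_pair(a, b)
            for i, a in enumerate(genes)
            for b in genes[i + 1 :]
        }
    n_flip = int(round(spec.flip_fraction * len(genes)))
    keep, flip = genes[: len(genes) - n_flip], genes[len(genes) - n_flip :]
    return {canonical_pair(a, b) for a in keep for b in flip}


def generate(spec: SyntheticCohortSpec) -> SyntheticCohort:
    """Generate the full cohort (expression, interactome, catalog, clinical,
    truth), bit-reproducible from ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    layout = _module_layout(spec)
    gene_ids = [g for mod in spec.modules for g in layout[mod.name]]
    gene_ids += layout["__background__"]
    gene_index = {g: i for i, g in enumerate(gene_ids)}
    m = spec.n_genes
    lo, hi = spec.log_mean_range
    baseline = rng.uniform(lo, hi, m)
    tau = spec.latent_sd

    control_ids = [f"C{i + 1}" for i in range(spec.n_controls)]
    patient_ids = [f"P{i + 1:02d}" for i in range(spec.n_patients)]
    perturbations = spec.perturbations or [[] for _ in range(spec.n_patients)]

    def draw_sample(perturbed: dict[str, str]) -> np.ndarray:
        logmu = baseline.copy()
        for mod in spec.modules:
            genes = layout[mod.name]
            idx = np.array([gene_index[g] for g in genes])
            lam = math.sqrt(mod.rho) * tau
            sig_e = math.sqrt(1.0 - mod.rho) * tau
            effect = perturbed.get(mod.name)
            if effect == "decouple":
                logmu[idx] += tau * rng.standard_normal(len(idx))
                continue
            f = rng.standard_normal() + (spec.activation if effect else 0.0)
            loading = np.full(len(idx), lam)
            if effect == "flip":
                n_flip = int(round(spec.flip_fraction * len(idx)))
                loading[len(idx) - n_flip :] *= -1.0
            logmu[idx] += loading * f + sig_e * rng.standard_normal(len(idx))
        bg_idx = np.array(
            [gene_index[g] for g in layout["__background__"]], dtype=int
        )
        if bg_idx.size:
            logmu[bg_idx] += tau * rng.standard_normal(bg_idx.size)
        mu = np.exp(logmu)
        size = 1.0 / spec.dispersion
        return rng.negative_binomial(size, size / (size + mu))

    columns: dict[str, np.ndarray] = {}
    for cid in control_ids:
        columns[cid] = draw_sample({})
    truth_pairs: dict[str, set[Edge]] = {}
    for pid, plist in zip(patient_ids, perturbations):
        columns[pid] = draw_sample(dict(plist))
        pairs: set[Edge] = set()
        for mod_name, effect in plist:
            pairs |= _planted_pairs(spec, layout, mod_name, effect)
        truth_pairs[pid] = pairs

    counts = pd.DataFrame(columns, index=gene_ids)
    group = pd.Series(
        {**{c: CONTROL for c in control_ids}, **{p: PATIENT for p in patient_ids}}
    )
    biotype = pd.Series("protein_coding", index=gene_ids)
    if spec.noncoding_fraction > 0:
        n_nc = int(round(spec.noncoding_fraction * len(layout["__background__"])))
        for g in layout["__background__"][:n_nc]:
            biotype[g] = "lncRNA"
    expression = ExpressionMatrix(counts=counts, biotype=biotype, group=group)

    # interactome: an exact fraction of each module's pairs, plus background
    edges: set[Edge] = set()
    tags: dict[Edge, set[str]] = {}
    for mod in spec.modules:
        genes = layout[mod.name]
        pairs = [
            canonical_pair(a, b)
            for i, a in enumerate(genes)
            for b in genes[i + 1 :]
        ]
        n_keep = int(round(spec.module_pair_coverage * len(pairs)))
        chosen = rng.choice(len(pairs), size=n_keep, replace=False)
        for c in chosen:
            edges.add(pairs[c])
            tags.setdefault(pairs[c], set()).add("module")
    module_pairs_all = {
        canonical_pair(a, b)
        for mod in spec.modules
        for i, a in enumerate(layout[mod.name])
        for b in layout[mod.name][i + 1 :]
    }
    n_bg = rng.binomial(m * (m - 1) // 2, spec.background_edge_prob)
    while n_bg > 0:
        i, j = rng.integers(0, m, size=2)
        if i == j:
            continue
        pair = canonical_pair(gene_ids[i], gene_ids[j])
        if pair in module_pairs_all or pair in edges:
            continue
        edges.add(pair)
        tags.setdefault(pair, set()).add("background")
        n_bg -= 1
    interactome = Interactome(
        proteins={p for e in edges for p in e}, edges=edges, source_tags=tags
    )

    catalog = GeneSetCatalog(
        sets={mod.name: set(layout[mod.name]) for mod in spec.modules},
        source="synthetic",
    )

    covered = {pid: pairs & interactome.edges for pid, pairs in truth_pairs.items()}
    burden = {pid: len(covered[pid]) for pid in patient_ids}
    noise = rng.normal(0.0, spec.clinical_noise_sd, spec.n_patients)
    clinical = pd.DataFrame(
        {
            spec.clinical_variable: [
                spec.clinical_intercept + spec.clinical_slope * burden[pid] + e
                for pid, e in zip(patient_ids, noise)
            ]
        },
        index=pd.Index(patient_ids, name="patient_id"),
    )

    truth = SyntheticTruth(
        perturbed_pairs=truth_pairs,
        covered_pairs=covered,
        module_members={mod.name: layout[mod.name] for mod in spec.modules},
        clinical_params={
            "variable": spec.clinical_variable,
            "intercept": spec.clinical_intercept,
            "slope": spec.clinical_slope,
            "noise_sd": spec.clinical_noise_sd,
            "burden": burden,
        },
    )
    return SyntheticCohort(
        expression=expression,
        interactome=interactome,
        catalog=catalog,
        clinical=clinical,
        truth=truth,
        spec=spec,
    )


@dataclass(frozen=True)
class RecallPrecision:
    recall: float
    precision: float
    n_covered: int
    n_edges: int
    undefined: bool = False


def truth_recall(networks: Sequence, truth: SyntheticTruth) -> dict[str, RecallPrecision]:
    """Per patient: recall over interactome-covered planted pairs and
    precision of the network's edges against all planted pairs."""
    out: dict[str, RecallPrecision] = {}
    for net in networks:
        if net.patient_id not in truth.perturbed_pairs:
            raise KeyError(f"patient {net.patient_id!r} absent from truth")
        planted = truth.perturbed_pairs[net.patient_id]
        covered = truth.covered_pairs[net.patient_id]
        edges = {canonical_pair(*e) for e in net.edges}
        recall = len(edges & covered) / len(covered) if covered else math.nan
        if edges:
            precision = len(edges & planted) / len(edges)
            out[net.patient_id] = RecallPrecision(
                recall, precision, len(covered), len(edges)
            )
        else:
            out[net.patient_id] = RecallPrecision(
                0.0 if covered else math.nan, math.nan, len(covered), 0, True
            )
    return out
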