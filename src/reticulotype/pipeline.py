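"""End-to-end orchestration: simulate, build, analyze.

A single YAML config drives the whole run.  Every stage logs the counts it
saw (genes surviving each filter stage, pairs tested, edges retained) so
the run log alone reconstructs every threshold and family size used, and
every CSV output embeds a hash of the config that produced it.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import builder as builder_mod
from . import clinical as clinical_mod
from . import enrichment as enrichment_mod
from . import expression as expression_mod
from . import synthetic as synthetic_mod
from . import topology as topology_mod
from .interactome import read_interactome

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "cmd_simulate", "cmd_build", "cmd_analyze", "cmd_all"]

_DEFAULTS: dict[str, Any] = {
    "seed": 0,
    "output_dir": "out",
    "filter": {"mode": "any_sample", "min_count": 10},
    "normalization": "log2_cpm",
    "alpha": 0.05,
    "family": "tested_pairs",
    "enrichment": {"universe": "network_space", "q_threshold": 0.05},
    "association": {"variables": [], "method": "pearson", "feature_set": None},
    "groups": {"control_prefix": "C"},
}


@dataclasses.dataclass
class RunConfig:
    """Validated run configuration (YAML file, flat dict, or defaults)."""

    raw: dict

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        merged = json.loads(json.dumps(_DEFAULTS))
        for key, value in (data or {}).items():
            if isinstance(value, dict) and isinstance(merged.get(key), dict):
                merged[key].update(value)
            else:
                merged[key] = value
        cfg = cls(raw=merged)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if not 0.0 < float(self.raw["alpha"]) < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        if self.raw["family"] not in ("tested_pairs", "interactome_pairs"):
            raise ValueError(f"unknown family: {self.raw['family']!r}")
        if self.raw["filter"]["mode"] not in ("any_sample", "all_samples"):
            raise ValueError(f"unknown filter mode: {self.raw['filter']['mode']!r}")
        for key in ("counts", "clinical", "gene_sets", "biotypes"):
            path = self.inputs.get(key)
            if path and not Path(path).exists():
                raise ValueError(f"input path for {key!r} does not exist: {path}")
        for path in self.inputs.get("interactome", []) or []:
            if not Path(path).exists():
                raise ValueError(f"interactome path does not exist: {path}")

    @property
    def inputs(self) -> dict:
        return self.raw.get("inputs") or {}

    @property
    def output_dir(self) -> Path:
        return Path(self.raw["output_dir"])

    @property
    def seed(self) -> int:
        return int(self.raw["seed"])

    def config_hash(self) -> str:
        canon = json.dumps(self.raw, sort_keys=True, default=str)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]

    def groups_for(self, sample_ids) -> dict[str, str]:
        spec = self.raw.get("groups") or {}
        if "controls" in spec or "patients" in spec:
            out = {}
            for s in spec.get("controls", []):
                out[s] = "control"
            for s in spec.get("patients", []):
                out[s] = "patient"
            missing = [s for s in sample_ids if s not in out]
            if missing:
                raise ValueError(f"samples without group assignment: {missing}")
            return out
        prefix = spec.get("control_prefix", "C")
        return {
            s: ("control" if str(s).startswith(prefix) else "patient")
            for s in sample_ids
        }

    def synthetic_spec(self) -> synthetic_mod.SyntheticCohortSpec:
        sim = self.raw.get("simulate")
        if not sim:
            return synthetic_mod.SyntheticCohortSpec.default(seed=self.seed)
        sim = dict(sim)
        modules = [
            synthetic_mod.ModuleSpec(**m) for m in sim.pop("modules", [])
        ]
        perturbations = [
            [tuple(p) for p in plist] for plist in sim.pop("perturbations", [])
        ]
        sim.setdefault("seed", self.seed)
        if "log_mean_range" in sim:
            sim["log_mean_range"] = tuple(sim["log_mean_range"])
        return synthetic_mod.SyntheticCohortSpec(
            modules=modules, perturbations=perturbations, **sim
        )


def _setup_logging(outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(message)s"))
    root = logging.getLogger("reticulotype")
    root.setLevel(logging.INFO)
    root.addHandler(handler)


def _write_csv(frame: pd.DataFrame, path: Path, config_hash: str, index=False) -> None:
    with open(path, "w") as fh:
        fh.write(f"# config_hash={config_hash}\n")
        frame.to_csv(fh, index=index)


def cmd_simulate(config: RunConfig) -> dict[str, Path]:
    """Generate a synthetic cohort and write it in the pipeline's input
    formats (TSV counts, TSV interactome, GMT, CSV clinical, JSON truth)."""
    spec = config.synthetic_spec()
    cohort = synthetic_mod.generate(spec)
    outdir = config.output_dir
    _setup_logging(outdir)
    paths = {
        "counts": outdir / "counts.tsv",
        "biotypes": outdir / "biotypes.tsv",
        "interactome": outdir / "interactome.tsv",
        "gene_sets": outdir / "gene_sets.gmt",
        "clinical": outdir / "clinical.csv",
        "truth": outdir / "truth.json",
    }
    cohort.expression.counts.to_csv(paths["counts"], sep="\t", index_label="gene_id")
    cohort.expression.biotype.to_csv(
        paths["biotypes"], sep="\t", header=False
    )
    cohort.interactome.write_tsv(paths["interactome"])
    cohort.catalog.write_gmt(paths["gene_sets"])
    cohort.clinical.to_csv(paths["clinical"])
    cohort.truth.to_json(paths["truth"])
    logger.info(
        "simulated cohort: %d genes, %d controls, %d patients, %d PPI edges",
        spec.n_genes, spec.n_controls, spec.n_patients, cohort.interactome.n_edges,
    )
    return paths


def _load_inputs(config: RunConfig):
    inputs = config.inputs
    outdir = config.output_dir
    counts_path = inputs.get("counts") or outdir / "counts.tsv"
    biotype_path = inputs.get("biotypes") or (
        outdir / "biotypes.tsv" if (outdir / "biotypes.tsv").exists() else None
    )
    inter_paths = inputs.get("interactome") or [outdir / "interactome.tsv"]
    biotype_map = (
        expression_mod.read_biotype_map(biotype_path) if biotype_path else None
    )
    header = pd.read_csv(counts_path, sep="\t", index_col=0, nrows=0)
    groups = config.groups_for(list(header.columns))
    matrix = expression_mod.read_counts(counts_path, biotype_map, groups)
    interactome = read_interactome(list(inter_paths))
    return matrix, interactome


def cmd_build(config: RunConfig) -> dict:
    """expression -> interactome -> builder: one network per patient on disk."""
    outdir = config.output_dir
    _setup_logging(outdir)
    chash = config.config_hash()
    matrix, interactome = _load_inputs(config)
    n_raw = matrix.n_genes
    filt = config.raw["filter"]
    filtered = expression_mod.filter_genes(
        matrix, mode=filt["mode"], min_count=int(filt["min_count"])
    )
    coding = expression_mod.restrict_protein_coding(filtered)
    logger.info(
        "gene funnel: %d raw -> %d after abundance filter -> %d protein-coding",
        n_raw, filtered.n_genes, coding.n_genes,
    )
    logger.info(
        "interactome coverage of expression genes: %.3f",
        interactome.coverage(coding.gene_ids),
    )
    result = builder_mod.run_cohort(
        coding,
        interactome,
        normalization=config.raw["normalization"],
        alpha=float(config.raw["alpha"]),
        family=config.raw["family"],
    )
    logger.info("run log: %s", json.dumps(result.log, sort_keys=True))
    netdir = outdir / "networks"
    netdir.mkdir(parents=True, exist_ok=True)
    for net in result.networks:
        _write_csv(net.to_frame(), netdir / f"{net.patient_id}.tsv", chash)
    summary = {
        "config_hash": chash,
        "funnel": {
            "raw_genes": n_raw,
            "filtered_genes": filtered.n_genes,
            "protein_coding_genes": coding.n_genes,
        },
        **result.log,
    }
    with open(outdir / "build_summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)
    return {"result": result, "summary": summary, "coding": coding}


def _load_networks(config: RunConfig) -> list[builder_mod.Reticulotype]:
    netdir = config.output_dir / "networks"
    if not netdir.exists():
        raise ValueError(f"no networks found under {netdir}; run build first")
    nets = []
    for path in sorted(netdir.glob("*.tsv")):
        frame = pd.read_csv(path, sep=",", comment="#")
        records = {}
        for row in frame.itertuples(index=False):
            rec = builder_mod.PerturbationRecord(
                gene_a=row.gene_a, gene_b=row.gene_b, r=row.r,
                r_prime=row.r_prime, delta=row.delta, z=row.z, p=row.p,
                p_adjusted=row.p_adjusted, significant=bool(row.significant),
            )
            records[(row.gene_a, row.gene_b)] = rec
        edges = set(records)
        nets.append(
            builder_mod.Reticulotype(
                patient_id=path.stem,
                nodes={g for e in edges for g in e},
                edges=edges,
                records=records,
            )
        )
    return nets


def cmd_analyze(config: RunConfig) -> dict[str, Path]:
    """Topology, overlap, unique-edge, enrichment and association outputs."""
    outdir = config.output_dir
    _setup_logging(outdir)
    chash = config.config_hash()
    nets = _load_networks(config)
    if not nets:
        raise ValueError("no patient networks to analyze")
    matrix, interactome = _load_inputs(config)
    filt = config.raw["filter"]
    coding = expression_mod.restrict_protein_coding(
        expression_mod.filter_genes(
            matrix, mode=filt["mode"], min_count=int(filt["min_count"])
        )
    )
    written: dict[str, Path] = {}

    topo = topology_mod.summarize_cohort(nets)
    written["topology"] = outdir / "topology.csv"
    _write_csv(topo, written["topology"], chash)

    if len(nets) >= 2:
        for mode in ("node", "edge"):
            ov = topology_mod.pairwise_overlap(nets, mode=mode)
            path = outdir / f"overlap_{mode}s.csv"
            _write_csv(ov.values, path, chash, index=True)
            written[f"overlap_{mode}"] = path
        uniq = topology_mod.unique_edges(nets)
        uniq_frame = pd.DataFrame(
            {
                "patient_id": list(uniq),
                "n_unique_edges": [len(v) for v in uniq.values()],
            }
        )
        written["unique_edges"] = outdir / "unique_edges.csv"
        _write_csv(uniq_frame, written["unique_edges"], chash)
    else:
        logger.info("single network: overlap and unique-edge outputs skipped")

    gmt_path = config.inputs.get("gene_sets") or config.output_dir / "gene_sets.gmt"
    if Path(gmt_path).exists():
        catalog = enrichment_mod.read_gmt(gmt_path)
        universe = _universe(config, coding, interactome)
        q_thr = float(config.raw["enrichment"]["q_threshold"])
        table, freq = enrichment_mod.enrich_cohort(nets, catalog, universe, q_thr)
        written["enrichment"] = outdir / "enrichment.csv"
        _write_csv(table, written["enrichment"], chash)
        written["enrichment_frequency"] = outdir / "enrichment_frequency.csv"
        _write_csv(freq.reset_index(), written["enrichment_frequency"], chash)

        assoc_cfg = config.raw["association"]
        clin_path = config.inputs.get("clinical") or config.output_dir / "clinical.csv"
        if assoc_cfg.get("variables") and Path(clin_path).exists() and len(nets) >= 2:
            feature_set_name = assoc_cfg.get("feature_set") or next(iter(catalog.sets))
            reports = topology_mod.unique_feature_edges(
                nets, catalog[feature_set_name], feature_set_name
            )
            clinical = clinical_mod.read_clinical(clin_path)
            report = clinical_mod.association_report(
                clinical_mod.feature_from_reports(reports),
                clinical,
                assoc_cfg["variables"],
                methods=assoc_cfg.get("method", "pearson"),
            )
            written["association"] = outdir / "association.csv"
            _write_csv(report, written["association"], chash)
    return written


def _universe(config: RunConfig, coding, interactome) -> set[str]:
    mode = config.raw["enrichment"]["universe"]
    if mode == "network_space":
        return set(coding.gene_ids) & interactome.proteins
    if mode == "interactome":
        return set(interactome.proteins)
    if mode == "expression":
        return set(coding.gene_ids)
    raise ValueError(f"unknown enrichment universe mode: {mode!r}")


def cmd_all(config: RunConfig) -> dict:
    cmd_simulate(config)
    build = cmd_build(config)
    written = cmd_analyze(config)
    return {"build": build["summary"], "outputs": written}
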