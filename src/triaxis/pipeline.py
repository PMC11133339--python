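"""Config-driven driver wiring the analysis stages in dependency order.

filter -> differential expression -> co-expression modules -> cumulative
risk -> eQTM/DMC/mediation -> replication. Thresholds follow the study
design: DEG q < 0.05 feeds the methylation cascade, DEG q < 0.15 feeds
module detection, module DE q < 0.05 marks significant modules, eQTM
p < 0.05, family-wise 0.05 Bonferroni for DMCs, module-graph r > 0.5.

A single global seed fans out to per-stage child seeds by stable hashing of
the stage name, so disabling one stage never shifts another's randomness.
Reruns with identical config and inputs are bit-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as _io
from .de import DesignSpec, log_cpm_transform, run_differential_expression
from .methylation import (conditional_mediation, dmc_scan, eqtm_scan,
                          peak_eqtm, select_pairs)
from .modules import (NetworkParams, detect_modules, hub_genes,
                      module_differential_expression, module_expression,
                      module_graph, select_soft_power, signed_tom)
from .normalize import filter_genes
from .replication import replication_report
from .risk import run_risk_model

log = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "stage_seed"]

ALL_STAGES = ("filter", "deg", "modules", "risk", "methylation", "replication")
STAGE_DEPS = {
    "deg": ("filter",),
    "modules": ("deg",),
    "risk": ("modules",),
    "methylation": ("deg",),
    "replication": ("deg",),
}


@dataclass
class PipelineConfig:
    counts: str = "counts.tsv"
    beta: str = "beta.tsv"
    samples: str = "samples.tsv"
    gene_annotation: str = "genes.bed"
    cpg_manifest: str = "cpgs.tsv"
    interactions: str = "interactions.bedpe"
    external_table: str = "external_meta.tsv"
    out_dir: str = "results"
    seed: int = 0
    stages: tuple[str, ...] = ALL_STAGES
    deg_q: float = 0.05
    module_input_q: float = 0.15
    module_de_q: float = 0.05
    eqtm_p: float = 0.05
    dmc_alpha: float = 0.05
    module_graph_r: float = 0.5
    eqtm_latent_k: int = 60
    dmc_latent_k: int = 12
    deg_latent_k: int | str = 0
    filter_threshold: float = 20.0
    risk_modules: tuple | None = None

    def __post_init__(self):
        for name in ("deg_q", "module_input_q", "module_de_q", "eqtm_p",
                     "dmc_alpha", "module_graph_r"):
            v = getattr(self, name)
            if not (0 < v < 1):
                raise ValueError(f"{name} must be in (0, 1), got {v}")
        for st in self.stages:
            if st not in ALL_STAGES:
                raise ValueError(f"unknown stage {st!r}")
            for dep in STAGE_DEPS.get(st, ()):
                if dep not in self.stages:
                    raise ValueError(
                        f"stage {st!r} requires {dep!r} to be enabled")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        if "risk_modules" in raw and raw["risk_modules"] is not None:
            raw["risk_modules"] = tuple(raw["risk_modules"])
        return cls(**raw)

    def validate_paths(self, base: Path | None = None) -> None:
        base = base or Path(".")
        needed = {"filter": [self.counts, self.samples],
                  "methylation": [self.beta, self.gene_annotation,
                                  self.cpg_manifest],
                  "replication": [self.external_table]}
        for st, paths in needed.items():
            if st in self.stages:
                for p in paths:
                    if not (base / p).exists():
                        raise FileNotFoundError(f"stage {st!r}: missing {p}")


def stage_seed(seed: int, stage: str) -> int:
    """Deterministic child seed for a stage (stable across runs/platforms)."""
    return (seed * 1_000_003 + zlib.crc32(stage.encode())) % (2 ** 31)


def _config_hash(config: PipelineConfig) -> str:
    blob = json.dumps({k: (list(v) if isinstance(v, tuple) else v)
                       for k, v in asdict(config).items()}, sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig, base_dir=".") -> dict:
    """Execute the enabled stages and write results plus a run manifest.

    Returns a dict of in-memory results keyed by stage.
    """
    base = Path(base_dir)
    config.validate_paths(base)
    out = base / config.out_dir
    out.mkdir(parents=True, exist_ok=True)
    # manifest holds only deterministic fields so reruns are bit-identical
    manifest = {"config_hash": _config_hash(config), "seed": config.seed,
                "stages": [], "counts": {}}
    results: dict = {}
    t_all = time.time()

    counts = _io.read_count_matrix(base / config.counts)
    samples = _io.read_sample_table(base / config.samples)
    samples = samples.loc[counts.columns]

    def record(stage, t0, **counts_kw):
        manifest["stages"].append(stage)
        manifest["counts"].update(counts_kw)
        log.info("stage %s done in %.2fs %s", stage, time.time() - t0,
                 counts_kw)

    if "filter" in config.stages:
        t0 = time.time()
        retained = filter_genes(counts, samples,
                                threshold=config.filter_threshold)
        counts = counts.loc[retained]
        (out / "retained_genes.txt").write_text("\n".join(retained) + "\n")
        results["filter"] = retained
        record("filter", t0, genes_retained=len(retained))

    deg = None
    if "deg" in config.stages:
        t0 = time.time()
        deg = run_differential_expression(
            counts, samples,
            DesignSpec(latent_k=config.deg_latent_k),
            seed=stage_seed(config.seed, "deg"))
        _io.write_result_table(deg, out / "deg.tsv")
        results["deg"] = deg
        record("deg", t0, deg_total=len(deg),
               deg_sig=int((deg["q"] < config.deg_q).sum()))

    lib = counts.to_numpy(float).sum(axis=0)
    logcpm = pd.DataFrame(log_cpm_transform(counts.to_numpy(float), lib),
                          index=counts.index, columns=counts.columns)

    modset = None
    if "modules" in config.stages:
        t0 = time.time()
        module_genes = deg.loc[deg["q"] < config.module_input_q, "gene_id"]
        module_genes = [g for g in counts.index if g in set(module_genes)]
        if len(module_genes) < 2 * NetworkParams().min_module_size:
            raise ValueError(
                f"only {len(module_genes)} genes at q < "
                f"{config.module_input_q}; too few for module detection")
        expr = logcpm.loc[module_genes]
        power = select_soft_power(expr)
        tom = signed_tom(expr, power)
        assignments = detect_modules(tom, gene_ids=module_genes)
        mexpr = module_expression(expr, samples, assignments)
        mde = module_differential_expression(mexpr, samples)
        r = np.corrcoef(expr.to_numpy(float))
        adjacency = ((1 + r) / 2) ** power
        hubs = hub_genes(assignments, adjacency=adjacency,
                         gene_ids=module_genes)
        edges = module_graph(mexpr, r_threshold=config.module_graph_r) \
            if mexpr.shape[0] > 1 else pd.DataFrame()
        assignments.rename("module").to_frame().reset_index(names="gene_id") \
            .to_csv(out / "module_assignments.tsv", sep="\t", index=False)
        mexpr.to_csv(out / "module_expression.tsv", sep="\t",
                     float_format="%.6g")
        _io.write_result_table(mde, out / "module_de.tsv")
        _io.write_result_table(edges, out / "module_graph.tsv")
        results["modules"] = dict(power=power, assignments=assignments,
                                  expression=mexpr, de=mde, hubs=hubs,
                                  edges=edges)
        record("modules", t0, n_modules=len(set(assignments) - {0}),
               modules_sig=int((mde["q"] < config.module_de_q).sum()))
        modset = results["modules"]

    if "risk" in config.stages:
        t0 = time.time()
        mde_sig = modset["de"][modset["de"]["q"] < config.module_de_q]
        if len(mde_sig) < 1:
            raise ValueError("no significant modules for the risk stage")
        risk = run_risk_model(modset["expression"], samples, modset["de"],
                              modules=list(config.risk_modules)
                              if config.risk_modules else None)
        rows = [dict(k=k, odds_ratio=v[0], ci_lo=v[1], ci_hi=v[2])
                for k, v in risk.odds_ratios.items()]
        tab = pd.DataFrame(rows)
        tab["beta"] = risk.beta
        tab["p_additive"] = risk.p_additive
        tab["lrt_stat"] = risk.lrt_stat
        tab["lrt_df"] = risk.lrt_df
        tab["lrt_p"] = risk.lrt_p
        _io.write_result_table(tab, out / "risk.tsv")
        results["risk"] = risk
        record("risk", t0, risk_levels=len(set(risk.count)))

    if "methylation" in config.stages:
        t0 = time.time()
        beta = _io.read_beta_matrix(base / config.beta)
        annotation = _io.read_gene_annotation(base / config.gene_annotation)
        cpgs = _io.read_cpg_manifest(base / config.cpg_manifest)
        interactions = None
        if (base / config.interactions).exists():
            interactions = _io.read_interactions(base / config.interactions,
                                                 annotation)
        deg_genes = list(deg.loc[deg["q"] < config.deg_q, "gene_id"])
        pairs = select_pairs(deg_genes, annotation, cpgs, interactions)
        eqtm = eqtm_scan(logcpm, beta, pairs, samples,
                         latent_k=config.eqtm_latent_k,
                         seed=stage_seed(config.seed, "eqtm"),
                         sig_threshold=config.eqtm_p)
        _io.write_result_table(eqtm, out / "eqtm.tsv")
        sig = eqtm[eqtm["significant"]]
        med_rows = []
        dmc = pd.DataFrame()
        if len(sig):
            cpg_universe = sorted(sig["cpg_id"].unique())
            dmc = dmc_scan(beta.loc[cpg_universe], samples,
                           latent_k=config.dmc_latent_k,
                           seed=stage_seed(config.seed, "dmc"),
                           alpha=config.dmc_alpha)
            _io.write_result_table(dmc, out / "dmc.tsv")
            dmc_sig = set(dmc.loc[dmc["significant"], "cpg_id"])
            pos = {c.cpg_id: c.position for c in cpgs}
            for gene, grp in sig.groupby("gene_id", sort=True):
                gene_cpgs = [c for c in grp["cpg_id"] if c in dmc_sig]
                if not gene_cpgs:
                    continue
                peak = peak_eqtm(gene, gene_cpgs, logcpm, beta, samples,
                                 cpg_positions=pos)
                med_rows.append(conditional_mediation(gene, peak, logcpm,
                                                      beta, samples))
        mediation = pd.DataFrame([asdict(m) for m in med_rows])
        _io.write_result_table(mediation, out / "mediation.tsv")
        results["methylation"] = dict(pairs=pairs, eqtm=eqtm, dmc=dmc,
                                      mediation=mediation)
        record("methylation", t0, eqtm_tests=len(eqtm),
               eqtm_sig=int(eqtm["significant"].sum()) if len(eqtm) else 0,
               dmc_sig=int(dmc["significant"].sum()) if len(dmc) else 0,
               mediation_tested=len(mediation))

    if "replication" in config.stages:
        t0 = time.time()
        external = pd.read_csv(base / config.external_table, sep="\t")
        report = replication_report(deg, external, internal_q=config.deg_q)
        _io.write_result_table(pd.DataFrame([asdict(report)]),
                               out / "replication.tsv")
        results["replication"] = report
        record("replication", t0, replication_overlap=report.n_overlap)

    log.info("pipeline done in %.2fs", time.time() - t_all)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1,
                                                  sort_keys=True))
    results["manifest"] = manifest
    return results
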