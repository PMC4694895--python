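"""Orchestration of the full analysis cascade.

``run_pipeline`` drives simulate -> screen -> cluster -> qpcr -> proteomics
-> growth -> survival -> network over either simulated or file-based
inputs, writing per-stage TSV/JSON outputs plus a summary report. Every
stochastic stage draws from a stream derived from the single config seed,
so stages are independently reproducible and a rerun with the same seed is
byte-identical. A failing stage halts the run with a stage-named error;
outputs of completed stages are preserved.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import coexpression, growth as growth_mod, interactome, proteomics, \
    qpcr as qpcr_mod, screening, simulate as sim, survival as surv
from .io import ExpressionMatrix, read_expression, write_expression

__all__ = ["PipelineConfig", "PipelineStageError", "run_pipeline",
           "simulate_inputs"]

logger = logging.getLogger("glioscreen")

ALL_STAGES = ("screen", "cluster", "qpcr", "proteomics", "growth",
              "survival", "network")


class PipelineStageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass(frozen=True)
class PipelineConfig:
    out_dir: str = "glioscreen_out"
    seed: int = 0
    simulate: bool = True
    stages: tuple[str, ...] = ALL_STAGES
    # file inputs (used when simulate is False; any may be omitted, which
    # disables the stages that need it)
    expression_path: str | None = None
    metadata_path: str | None = None
    cq_path: str | None = None
    bands_path: str | None = None
    growth_path: str | None = None
    spheres_path: str | None = None
    survival_path: str | None = None
    edges_path: str | None = None
    # thresholds
    filter_threshold: float = 0.0
    alpha: float = 0.05
    fdr_q: float = 0.10
    k: int = 3
    survival_mode: str = "tertile"
    qpcr_iterations: int = 2000

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")

    @classmethod
    def from_file(cls, path, **overrides) -> "PipelineConfig":
        """Flat ``key = value`` config file; keyword overrides win."""
        kwargs: dict = {}
        text = Path(path).read_text()
        for line in text.splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, value = line.partition("=")
            key, value = key.strip(), value.strip()
            if key == "stages":
                kwargs[key] = tuple(s.strip() for s in value.split(",") if s)
            elif key in {"seed", "k", "qpcr_iterations"}:
                kwargs[key] = int(value)
            elif key in {"filter_threshold", "alpha", "fdr_q"}:
                kwargs[key] = float(value)
            elif key == "simulate":
                kwargs[key] = value.lower() in {"1", "true", "yes"}
            else:
                kwargs[key] = value
        valid = {f.name for f in fields(cls)}
        bad = set(kwargs) - valid
        if bad:
            raise ValueError(f"unknown config keys: {sorted(bad)}")
        kwargs.update(overrides)
        return cls(**kwargs)


def simulate_inputs(out_dir, seed: int,
                    config: sim.SimulationConfig | None = None) -> dict:
    """Emit a directory of simulated input files plus a planted-truth manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = replace(config or _default_sim_config(), seed=seed)
    expr = sim.simulate_expression(cfg)
    write_expression(expr, out / "expression.tsv", out / "metadata.tsv")
    cq = sim.simulate_cq(cfg)
    qpcr_mod.write_cq(cq, out / "cq.csv")
    qmeta = pd.DataFrame({"sample_id": sorted(cq.groups),
                          "group": [cq.groups[s] for s in sorted(cq.groups)]})
    qmeta.to_csv(out / "cq_metadata.tsv", sep="\t", index=False)
    bands = sim.simulate_bands(cfg)
    bands.data.to_csv(out / "bands.csv", index=False)
    growth, spheres = sim.simulate_growth(cfg)
    pd.DataFrame([(g.culture_id, g.t_days, g.n0, g.nt) for g in growth],
                 columns=["culture_id", "t_days", "n0", "nt"]
                 ).to_csv(out / "growth.csv", index=False)
    pd.DataFrame(
        [(a.culture_id, w + 1, c) for a in spheres
         for w, c in enumerate(a.counts)],
        columns=["culture_id", "well", "count"],
    ).to_csv(out / "spheres.csv", index=False)
    tab, arms = sim.simulate_survival(cfg)
    surv.write_survival(tab, out / "survival.tsv")
    edges = sim.simulate_edges(60, 150, seed=seed)
    pd.DataFrame(edges, columns=["node_a", "node_b"]
                 ).to_csv(out / "edges.tsv", sep="\t", index=False)
    man = sim.manifest(cfg)
    man["survival"]["planted_arms"] = arms.to_dict()
    (out / "manifest.json").write_text(json.dumps(man, indent=2))
    return man


def _default_sim_config() -> sim.SimulationConfig:
    """Study-shaped defaults, with one planted co-expression module."""
    planted = tuple(f"PG{i:02d}" for i in range(1, 21))
    return sim.SimulationConfig(
        module_spec=(sim.ModuleSpec("I", planted[:9], rho=0.9),),
        qpcr_spec=sim.QpcrSpec(
            fold_changes={g: f for g, f in zip(planted[:5],
                                               (8.0, 16.0, 4.0, 32.0, 12.0))}),
        western_spec=sim.WesternSpec(
            true_rpe={g: (2.0 + i, 1.0) for i, g in enumerate(planted[:5])}),
    )


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run all enabled stages; return (and write) the summary report."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": cfg.seed, "stages": list(cfg.stages)}
    inputs_dir = out / "inputs"

    if cfg.simulate:
        logger.info("simulating inputs into %s", inputs_dir)
        report["manifest"] = simulate_inputs(inputs_dir, cfg.seed)
        paths = {
            "expression": inputs_dir / "expression.tsv",
            "metadata": inputs_dir / "metadata.tsv",
            "cq": inputs_dir / "cq.csv",
            "cq_metadata": inputs_dir / "cq_metadata.tsv",
            "bands": inputs_dir / "bands.csv",
            "growth": inputs_dir / "growth.csv",
            "spheres": inputs_dir / "spheres.csv",
            "survival": inputs_dir / "survival.tsv",
            "edges": inputs_dir / "edges.tsv",
        }
    else:
        paths = {
            "expression": cfg.expression_path,
            "metadata": cfg.metadata_path,
            "cq": cfg.cq_path,
            "cq_metadata": cfg.metadata_path,
            "bands": cfg.bands_path,
            "growth": cfg.growth_path,
            "spheres": cfg.spheres_path,
            "survival": cfg.survival_path,
            "edges": cfg.edges_path,
        }

    candidates = None
    for stage in cfg.stages:
        logger.info("running stage %s", stage)
        try:
            if stage == "screen" and paths["expression"]:
                expr = read_expression(paths["expression"], paths["metadata"])
                candidates = screening.consistency_filter(
                    expr, cfg.filter_threshold)
                candidates.table.to_csv(out / "candidates.tsv", sep="\t",
                                        index_label="gene_id")
                report["screen"] = {"n_candidates": len(candidates),
                                    "genes": candidates.gene_ids}
            elif stage == "cluster" and paths["expression"]:
                expr = read_expression(paths["expression"], paths["metadata"])
                if candidates is not None and len(candidates) >= cfg.k:
                    expr = expr.subset_genes(candidates.gene_ids)
                d = coexpression.distance_matrix(expr, axis="genes")
                tree = coexpression.cluster(d)
                modules = coexpression.cut(tree, cfg.k)
                pd.Series(modules.assignment, name="module").to_csv(
                    out / "modules.tsv", sep="\t", index_label="gene_id")
                tree.merge_history().to_csv(out / "merge_history.tsv",
                                            sep="\t", index=False)
                report["cluster"] = {
                    lab: modules.members(lab) for lab in modules.labels()}
            elif stage == "qpcr" and paths["cq"]:
                cq = qpcr_mod.read_cq(paths["cq"], paths["cq_metadata"])
                res = qpcr_mod.relative_expression(
                    cq, alpha=cfg.alpha, iterations=cfg.qpcr_iterations,
                    seed=np.random.default_rng([cfg.seed % (2 ** 31), 101]))
                res.to_csv(out / "qpcr_results.tsv", sep="\t")
                report["qpcr"] = {g: {"ratio": round(r.ratio, 6),
                                      "p": round(r.p, 6), "call": r.call}
                                  for g, r in res.iterrows()}
            elif stage == "proteomics" and paths["bands"]:
                bands = proteomics.read_bands(paths["bands"])
                mat = proteomics.rpe(bands)
                mat.values.to_csv(out / "rpe.tsv", sep="\t",
                                  index_label="protein_id")
                report["proteomics"] = {
                    "n_proteins": int(mat.values.shape[0]),
                    "n_flagged": len(mat.qc_flags),
                }
            elif stage == "growth" and paths["growth"]:
                records = growth_mod.read_growth(paths["growth"])
                rows = []
                for rec in records:
                    value, shrinking = growth_mod.pdt(rec)
                    rows.append((rec.culture_id, value, shrinking))
                frame = pd.DataFrame(rows, columns=["culture_id", "pdt_days",
                                                    "shrinking"])
                frame.to_csv(out / "pdt.tsv", sep="\t", index=False)
                report["growth"] = {"pdt_days": dict(
                    zip(frame["culture_id"], frame["pdt_days"].round(6)))}
                if paths["spheres"]:
                    assays = growth_mod.read_spheres(paths["spheres"])
                    counts = {a.culture_id:
                              growth_mod.sphere_summary(a)["mean_count"]
                              for a in assays}
                    recip = {c: 1.0 / p for c, p in
                             report["growth"]["pdt_days"].items() if p > 0}
                    if len(set(counts) & set(recip)) >= 3:
                        r = growth_mod.assay_correlation(counts, recip)
                        report["growth"]["sphere_vs_reciprocal_pdt_r"] = \
                            round(r, 4)
            elif stage == "survival" and paths["survival"]:
                tab = surv.read_survival(paths["survival"])
                # level-based grouping: the survival question is about the
                # module's expression level, which Pearson-distance patient
                # clustering is blind to (it compares profile shapes)
                strat = surv.stratify(tab, tab.gene_columns, k=cfg.k,
                                      mode=cfg.survival_mode)
                pd.Series(strat.assignment, name="group").to_csv(
                    out / "stratification.tsv", sep="\t",
                    index_label="patient_id")
                labels = strat.labels()
                lo = tab.subset(strat.group("low"))
                hi = tab.subset(strat.group("high"))
                stat, p = surv.gbw_test(hi, lo)
                med = {lab: surv.km_median(surv.km(tab.subset(
                    strat.group(lab)))) for lab in ("low", "high")}
                report["survival"] = {
                    "groups": {lab: len(strat.group(lab)) for lab in labels},
                    "median_days": med,
                    "gbw_statistic": round(stat, 6),
                    "gbw_p": round(p, 6),
                }
            elif stage == "network" and paths["edges"]:
                g = interactome.read_edges(paths["edges"])
                hub_set = interactome.hubs(g)
                report["network"] = {
                    "n_nodes": g.number_of_nodes(),
                    "n_edges": g.number_of_edges(),
                    "hubs": sorted(hub_set),
                }
            else:
                logger.info("stage %s skipped (no input)", stage)
        except Exception as exc:  # halt with a stage-named error
            (out / "report.json").write_text(json.dumps(report, indent=2))
            raise PipelineStageError(stage, exc) from exc

    (out / "report.json").write_text(json.dumps(report, indent=2))
    return report
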