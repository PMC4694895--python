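"""Synthetic inputs with planted, recoverable structure.

Every pipeline stage can be exercised without external downloads: the
generators here emit expression matrices, qPCR Cq tables, western band
tables, growth/sphere records, survival tables and interaction edge lists
whose ground truth is known (and returned in a manifest), so estimators can
be tested by inversion — at zero noise every downstream estimator recovers
the planted parameter exactly.

Defaults mirror the study design the pipeline was built for: a 9-case
(tumor stem-cell) / 5-control (normal stem-cell) log2 expression matrix
with 20 planted consistently-separated genes at +2 / −2 log2 around a zero
background; a 7-case / 4-control qPCR design with two reference genes at
efficiency 2; 7-case / 2-control westerns; and a 200-patient survival table
with a baseline median of 383 days and hazard multiplier 2 for the planted
high-expression arm.

All randomness flows from ``config.seed``; each generator derives its own
independent stream, so identical configs give identical outputs and the
generators can be called in any order.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import CLUSTER_I_GENES, ExpressionMatrix, GROUP_CASE, GROUP_CONTROL
from .growth import GrowthRecord, SphereAssay
from .proteomics import BandTable
from .qpcr import CqTable
from .survival import SurvivalTable

__all__ = [
    "ModuleSpec",
    "QpcrSpec",
    "WesternSpec",
    "SurvivalSpec",
    "GrowthSpec",
    "SimulationConfig",
    "simulate_expression",
    "simulate_cq",
    "simulate_bands",
    "simulate_survival",
    "simulate_growth",
    "simulate_edges",
    "manifest",
]

# distinct sub-stream tags so generators are independently reproducible
_STREAMS = {"expression": 1, "cq": 2, "bands": 3, "survival": 4,
            "growth": 5, "edges": 6}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng([int(seed) % (2 ** 31), _STREAMS[stream]])


@dataclass(frozen=True)
class ModuleSpec:
    module_id: str
    genes: tuple[str, ...]
    rho: float

    def __post_init__(self) -> None:
        if not 0 <= self.rho < 1:
            raise ValueError("within-module correlation must lie in [0, 1)")


@dataclass(frozen=True)
class QpcrSpec:
    """Planted qPCR design: Cq = baseline - log2(fold)/log2(E) in cases."""

    fold_changes: Mapping[str, float] = field(
        default_factory=lambda: {"TARGET1": 8.0})
    reference_genes: tuple[str, ...] = ("ACTB", "GAPDH")
    efficiencies: Mapping[str, float] = field(default_factory=dict)
    n_case: int = 7
    n_control: int = 4
    n_replicates: int = 3
    baseline_cq: float = 25.0
    noise_sd: float = 0.25
    sample_effect_sd: float = 0.3

    def efficiency(self, gene: str) -> float:
        e = float(self.efficiencies.get(gene, 2.0))
        if not 1.0 < e <= 2.0:
            raise ValueError(f"efficiency for {gene!r} must lie in (1, 2]")
        return e


@dataclass(frozen=True)
class WesternSpec:
    """Planted relative protein expression per protein and group."""

    true_rpe: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {"PROT1": (2.0, 1.0)})  # (case, control)
    n_case: int = 7
    n_control: int = 2
    noise_sd: float = 0.2        # lognormal sigma on the band net intensity
    background: float = 100.0
    control_net: float = 1000.0


@dataclass(frozen=True)
class SurvivalSpec:
    """Two planted arms (low/high module expression) with exponential times."""

    n_patients: int = 200
    baseline_median_days: float = 383.0
    hazard_multiplier: float = 2.0
    censoring_rate: float = 0.2
    genes: tuple[str, ...] = CLUSTER_I_GENES
    expression_shift: float = 1.5
    expression_noise_sd: float = 1.0


@dataclass(frozen=True)
class GrowthSpec:
    """Cultures with planted doubling times and matched sphere counts."""

    n_cultures: int = 7
    pdt_days: tuple[float, ...] = ()
    t_days: float = 10.0
    n0: float = 1e5
    spheres_per_rate: float = 100.0   # planted counts = this / PDT
    n_wells: int = 6
    count_noise: bool = True


@dataclass(frozen=True)
class SimulationConfig:
    n_genes: int = 500
    n_case: int = 9
    n_control: int = 5
    planted_consistent_genes: tuple[str, ...] = tuple(
        f"PG{i:02d}" for i in range(1, 21))
    case_mean: float = 2.0
    control_mean: float = -2.0
    background_mean: float = 0.0
    noise_sd: float = 0.5
    seed: int = 0
    module_spec: tuple[ModuleSpec, ...] = ()
    qpcr_spec: QpcrSpec = field(default_factory=QpcrSpec)
    western_spec: WesternSpec = field(default_factory=WesternSpec)
    survival_spec: SurvivalSpec = field(default_factory=SurvivalSpec)
    growth_spec: GrowthSpec = field(default_factory=GrowthSpec)

    def __post_init__(self) -> None:
        for name in ("n_genes", "n_case", "n_control"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if len(self.planted_consistent_genes) > self.n_genes:
            raise ValueError("more planted genes than the gene universe holds")

    @property
    def gene_universe(self) -> list[str]:
        n_bg = self.n_genes - len(self.planted_consistent_genes)
        background = [f"BG{i:04d}" for i in range(1, n_bg + 1)]
        return list(self.planted_consistent_genes) + background

    @property
    def sample_ids(self) -> list[str]:
        return [f"GSC{i:02d}" for i in range(1, self.n_case + 1)] + \
               [f"NSC{i:02d}" for i in range(1, self.n_control + 1)]


def simulate_expression(config: SimulationConfig) -> ExpressionMatrix:
    """Log2 expression with planted consistent genes and co-expression modules.

    Planted genes sit at ``case_mean`` in cases and ``control_mean`` in
    controls (exactly so at zero noise); all other genes share the
    background mean. Module members load on a per-sample latent factor with
    weight sqrt(rho), giving pairwise within-module correlation ~ rho.
    """
    rng = _rng(config.seed, "expression")
    genes = config.gene_universe
    samples = config.sample_ids
    planted = set(config.planted_consistent_genes)
    universe = set(genes)
    for mod in config.module_spec:
        missing = set(mod.genes) - universe
        if missing:
            raise ValueError(
                f"module {mod.module_id!r} genes outside universe: "
                f"{sorted(missing)}")
    n_g, n_s = len(genes), len(samples)
    means = np.full((n_g, n_s), config.background_mean)
    planted_rows = [i for i, g in enumerate(genes) if g in planted]
    means[planted_rows, :config.n_case] = config.case_mean
    means[planted_rows, config.n_case:] = config.control_mean

    noise = rng.normal(0.0, 1.0, size=(n_g, n_s))
    values = means + config.noise_sd * noise
    for mod in config.module_spec:
        factor = rng.normal(0.0, 1.0, size=n_s)
        rows = [genes.index(g) for g in mod.genes]
        fresh = rng.normal(0.0, 1.0, size=(len(rows), n_s))
        values[rows] = (
            means[rows]
            + config.noise_sd * (np.sqrt(mod.rho) * factor[None, :]
                                 + np.sqrt(1 - mod.rho) * fresh)
        )
    meta = pd.DataFrame(
        {
            "group": [GROUP_CASE] * config.n_case
            + [GROUP_CONTROL] * config.n_control,
            "subtype": "",
            "culture_id": samples,
        },
        index=pd.Index(samples, name="sample_id"),
    )
    return ExpressionMatrix(pd.DataFrame(values, index=genes, columns=samples),
                            meta)


def simulate_cq(config: SimulationConfig) -> CqTable:
    """Cq tables whose Pfaffl ratio recovers the planted fold changes.

    For a target with planted linear fold change F and efficiency E, case
    samples sit ``log2(F)/log2(E)`` cycles below the control baseline;
    reference genes are unshifted. A per-sample loading shift (applied to
    every gene of that sample) and replicate noise are layered on top.
    """
    spec = config.qpcr_spec
    if not spec.reference_genes:
        raise ValueError("at least one reference gene is required")
    if spec.n_case <= 0 or spec.n_control <= 0:
        raise ValueError("group sizes must be positive")
    rng = _rng(config.seed, "cq")
    cases = [f"qGSC{i:02d}" for i in range(1, spec.n_case + 1)]
    ctrls = [f"qNSC{i:02d}" for i in range(1, spec.n_control + 1)]
    samples = cases + ctrls
    groups = {s: GROUP_CASE for s in cases} | {s: GROUP_CONTROL for s in ctrls}
    sample_shift = dict(zip(samples,
                            rng.normal(0.0, spec.sample_effect_sd,
                                       size=len(samples))))
    rows = []
    all_genes = list(spec.fold_changes) + list(spec.reference_genes)
    for gene in all_genes:
        is_ref = gene in spec.reference_genes
        e = spec.efficiency(gene)
        fold = 1.0 if is_ref else float(spec.fold_changes[gene])
        if fold <= 0:
            raise ValueError(f"planted fold change for {gene!r} must be > 0")
        shift_cycles = np.log2(fold) / np.log2(e)
        for s in samples:
            center = spec.baseline_cq + sample_shift[s]
            if groups[s] == GROUP_CASE:
                center -= shift_cycles
            for rep in range(1, spec.n_replicates + 1):
                cq = center + rng.normal(0.0, spec.noise_sd)
                rows.append((gene, s, rep, cq, e, is_ref))
    data = pd.DataFrame(rows, columns=["gene_id", "sample_id", "replicate",
                                       "cq", "efficiency", "is_reference"])
    return CqTable(data, groups)


def simulate_bands(config: SimulationConfig) -> BandTable:
    """Western band intensities: true RPE x loading control x lognormal noise."""
    spec = config.western_spec
    if not spec.true_rpe:
        raise ValueError("no proteins specified")
    rng = _rng(config.seed, "bands")
    cases = [f"wGSC{i:02d}" for i in range(1, spec.n_case + 1)]
    ctrls = [f"wNSC{i:02d}" for i in range(1, spec.n_control + 1)]
    rows = []
    for s in cases + ctrls:
        is_case = s in cases
        control_net = spec.control_net * \
            float(np.exp(rng.normal(0.0, spec.noise_sd)))
        for protein, (rpe_case, rpe_ctrl) in spec.true_rpe.items():
            true = rpe_case if is_case else rpe_ctrl
            band_net = true * control_net * \
                float(np.exp(rng.normal(0.0, spec.noise_sd)))
            rows.append((protein, s, band_net + spec.background,
                         spec.background, control_net + spec.background,
                         spec.background))
    data = pd.DataFrame(rows, columns=["protein_id", "sample_id", "band",
                                       "band_bg", "control", "control_bg"])
    return BandTable(data)


def simulate_survival(config: SimulationConfig) -> tuple[SurvivalTable, pd.Series]:
    """Exponential survival with a planted high-expression arm.

    Half the patients form the planted ``low`` arm (hazard log 2 / baseline
    median), half the ``high`` arm (hazard multiplied). Module-gene
    expression separates the arms with gene-specific shift weights (spread
    0.5x-1.5x around ``expression_shift``), so both level- and
    pattern-based stratification can recover the arms. Censoring times are
    independent exponentials calibrated to the requested rate in the low
    arm. Returns the table and the planted arm labels.
    """
    spec = config.survival_spec
    if spec.n_patients < 2:
        raise ValueError("need at least 2 patients")
    rng = _rng(config.seed, "survival")
    n = spec.n_patients
    n_high = n // 2
    patients = [f"P{i:04d}" for i in range(1, n + 1)]
    arm = np.array(["high"] * n_high + ["low"] * (n - n_high))
    h_low = np.log(2.0) / spec.baseline_median_days
    hazard = np.where(arm == "high", h_low * spec.hazard_multiplier, h_low)
    t_event = rng.exponential(1.0 / hazard)
    if spec.censoring_rate > 0:
        h_cens = h_low * spec.censoring_rate / (1.0 - spec.censoring_rate)
        t_cens = rng.exponential(1.0 / h_cens, size=n)
    else:
        t_cens = np.full(n, np.inf)
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)

    genes = list(spec.genes)
    weights = spec.expression_shift * np.linspace(0.5, 1.5, len(genes))
    sign = np.where(arm == "high", 1.0, -1.0)
    expr = sign[:, None] * weights[None, :] + \
        rng.normal(0.0, spec.expression_noise_sd, size=(n, len(genes)))
    data = pd.DataFrame(expr, index=pd.Index(patients, name="patient_id"),
                        columns=genes)
    data.insert(0, "time_days", time)
    data.insert(1, "event", event)
    data.insert(2, "subtype", "")
    return SurvivalTable(data), pd.Series(arm, index=patients, name="arm")


def simulate_growth(config: SimulationConfig
                    ) -> tuple[list[GrowthRecord], list[SphereAssay]]:
    """Cultures with planted doubling times and sphere counts ~ growth rate."""
    spec = config.growth_spec
    if spec.n_cultures <= 0:
        raise ValueError("need at least one culture")
    rng = _rng(config.seed, "growth")
    pdts = np.asarray(spec.pdt_days if spec.pdt_days
                      else np.linspace(2.0, 8.0, spec.n_cultures))
    growth, spheres = [], []
    for i, pdt_days in enumerate(pdts, start=1):
        cid = f"T{i:02d}"
        nt = spec.n0 * 2.0 ** (spec.t_days / pdt_days)
        growth.append(GrowthRecord(cid, spec.t_days, spec.n0, nt))
        lam = spec.spheres_per_rate / pdt_days
        if spec.count_noise:
            counts = rng.poisson(lam, size=spec.n_wells).astype(float)
        else:
            counts = np.full(spec.n_wells, lam)
        spheres.append(SphereAssay(cid, tuple(counts)))
    return growth, spheres


def simulate_edges(n_nodes: int, n_edges: int,
                   seed: int = 0) -> list[tuple[str, str]]:
    """Preferential-attachment edge list (scale-free-ish degree tail)."""
    if n_nodes < 2 or n_edges < 1:
        raise ValueError("need at least 2 nodes and 1 edge")
    rng = _rng(seed, "edges")
    nodes = [f"N{i:03d}" for i in range(n_nodes)]
    degree = np.ones(n_nodes)
    edges: set[tuple[int, int]] = set()
    attempts = 0
    while len(edges) < n_edges and attempts < 50 * n_edges:
        attempts += 1
        p = degree / degree.sum()
        a = int(rng.choice(n_nodes, p=p))
        b = int(rng.choice(n_nodes, p=p))
        if a == b or (min(a, b), max(a, b)) in edges:
            continue
        edges.add((min(a, b), max(a, b)))
        degree[a] += 1
        degree[b] += 1
    return [(nodes[a], nodes[b]) for a, b in sorted(edges)]


def manifest(config: SimulationConfig) -> dict:
    """Planted ground truths, for test harnesses and pipeline reports."""
    return {
        "seed": config.seed,
        "planted_consistent_genes": list(config.planted_consistent_genes),
        "case_mean": config.case_mean,
        "control_mean": config.control_mean,
        "expected_fold_change": 2.0 ** (config.case_mean - config.control_mean),
        "modules": {m.module_id: {"genes": list(m.genes), "rho": m.rho}
                    for m in config.module_spec},
        "qpcr_fold_changes": dict(config.qpcr_spec.fold_changes),
        "western_true_rpe": {p: list(v) for p, v in
                             config.western_spec.true_rpe.items()},
        "survival": {
            "hazard_multiplier": config.survival_spec.hazard_multiplier,
            "baseline_median_days": config.survival_spec.baseline_median_days,
        },
    }
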