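"""Efficiency-corrected relative expression and the fixed-reallocation test.

The relative expression ratio of a target gene between case and control
groups is

    ratio = E_t ** dCq_t / G,     G = geomean over references of E_r ** dCq_r

where ``dCq = mean Cq(control) - mean Cq(case)`` and ``E`` is the per-gene
amplification efficiency per cycle (2 for perfect doubling, in which case
the ratio reduces to the classic ``2**-ddCt``). Significance comes from a
fixed-reallocation randomization test: group labels are reassigned between
samples (group sizes fixed), the ratio recomputed for each reallocation, and
the two-sided p-value is the proportion of reallocations whose |log ratio|
is at least the observed one, counting the observed allocation — so p is
never 0. Reallocation is exhaustive whenever the number of distinct
allocations does not exceed the iteration budget, Monte-Carlo otherwise.

Technical replicates are averaged to one Cq per (gene, sample) before any
group statistics, and reallocation moves samples, not replicates.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io import GROUP_CASE, GROUP_CONTROL

__all__ = [
    "CqTable",
    "RelativeExpressionResult",
    "pfaffl_ratio",
    "reallocation_test",
    "call_regulation",
    "relative_expression",
    "DEFAULT_EFFICIENCY",
]

DEFAULT_EFFICIENCY = 2.0

_REQUIRED = ("gene_id", "sample_id", "replicate", "cq", "efficiency",
             "is_reference")


@dataclass(frozen=True)
class CqTable:
    """qPCR crossing-point measurements plus the sample -> group mapping.

    ``data`` columns: gene_id, sample_id, replicate, cq, efficiency,
    is_reference. Missing efficiencies default to 2 (perfect doubling).
    """

    data: pd.DataFrame
    groups: Mapping[str, str]

    def __post_init__(self) -> None:
        missing = [c for c in _REQUIRED if c not in self.data.columns]
        if missing:
            raise ValueError(f"CqTable is missing columns: {missing}")
        d = self.data.copy()
        d["efficiency"] = d["efficiency"].fillna(DEFAULT_EFFICIENCY).astype(float)
        if (d["cq"] <= 0).any():
            raise ValueError("Cq values must be positive")
        if ((d["efficiency"] <= 1) | (d["efficiency"] > 2)).any():
            raise ValueError("efficiencies must lie in (1, 2]")
        unknown = set(d["sample_id"]) - set(self.groups)
        if unknown:
            raise ValueError(f"samples without a group: {sorted(unknown)}")
        if not d["is_reference"].any():
            raise ValueError("at least one reference gene is required")
        object.__setattr__(self, "data", d)

    @property
    def reference_genes(self) -> list[str]:
        return sorted(self.data.loc[self.data["is_reference"], "gene_id"].unique())

    @property
    def target_genes(self) -> list[str]:
        return sorted(self.data.loc[~self.data["is_reference"], "gene_id"].unique())

    def sample_cq(self, gene: str) -> pd.Series:
        """Replicates averaged to one Cq per sample for ``gene``."""
        sub = self.data[self.data["gene_id"] == gene]
        if sub.empty:
            raise KeyError(f"gene not measured: {gene!r}")
        return sub.groupby("sample_id")["cq"].mean()

    def efficiency(self, gene: str) -> float:
        sub = self.data.loc[self.data["gene_id"] == gene, "efficiency"]
        if sub.empty:
            raise KeyError(f"gene not measured: {gene!r}")
        vals = sub.unique()
        if len(vals) > 1:
            raise ValueError(f"inconsistent efficiencies for {gene!r}: {vals}")
        return float(vals[0])

    def _group_samples(self, cq: pd.Series) -> tuple[list[str], list[str]]:
        case = [s for s in cq.index if self.groups[s] == GROUP_CASE]
        ctrl = [s for s in cq.index if self.groups[s] == GROUP_CONTROL]
        return case, ctrl


@dataclass(frozen=True)
class RelativeExpressionResult:
    gene_id: str
    ratio: float
    p: float
    call: str

    def __post_init__(self) -> None:
        if self.ratio <= 0:
            raise ValueError("ratio must be positive")
        if not 0 < self.p <= 1:
            raise ValueError("p must lie in (0, 1]")


def _delta_cq(t: CqTable, gene: str) -> float:
    cq = t.sample_cq(gene)
    case, ctrl = t._group_samples(cq)
    if not case or not ctrl:
        raise ValueError(f"gene {gene!r} lacks measurements in one group")
    return float(cq[ctrl].mean() - cq[case].mean())


def pfaffl_ratio(t: CqTable, gene: str) -> float:
    """Efficiency-corrected case/control expression ratio for ``gene``.

    Reference genes are aggregated by the geometric mean of their individual
    efficiency-corrected factors.
    """
    refs = t.reference_genes
    if gene in refs:
        raise ValueError(f"{gene!r} is a reference gene")
    log2_target = _delta_cq(t, gene) * np.log2(t.efficiency(gene))
    log2_refs = [_delta_cq(t, r) * np.log2(t.efficiency(r)) for r in refs]
    return float(2.0 ** (log2_target - float(np.mean(log2_refs))))


def _per_sample_scores(t: CqTable, gene: str) -> tuple[np.ndarray, np.ndarray]:
    """Per-sample combined log2 quantity v_s and the case indicator.

    v_s = Cq(target, s) * log2(E_t) - mean over refs of Cq(ref, s) * log2(E_r);
    the log2 ratio for any group allocation is mean_ctrl(v) - mean_case(v).
    Requires a complete design: every sample measured for the target and all
    references.
    """
    refs = t.reference_genes
    target_cq = t.sample_cq(gene)
    ref_cq = {r: t.sample_cq(r) for r in refs}
    samples = sorted(target_cq.index)
    for r, cq in ref_cq.items():
        if not set(samples) <= set(cq.index):
            raise ValueError(
                f"reference {r!r} not measured in every sample of {gene!r}")
    v = target_cq[samples].to_numpy() * np.log2(t.efficiency(gene))
    v -= np.mean(
        [ref_cq[r][samples].to_numpy() * np.log2(t.efficiency(r)) for r in refs],
        axis=0,
    )
    is_case = np.array([t.groups[s] == GROUP_CASE for s in samples])
    if not is_case.any() or is_case.all():
        raise ValueError(f"gene {gene!r} lacks measurements in one group")
    return v, is_case


def reallocation_test(
    t: CqTable,
    gene: str,
    iterations: int = 2000,
    seed: int | np.random.Generator | None = None,
) -> float:
    """Two-sided fixed-reallocation p-value for ``gene``'s expression ratio."""
    v, is_case = _per_sample_scores(t, gene)
    n, n_case = v.size, int(is_case.sum())
    if n_case < 2 or n - n_case < 2:
        raise ValueError("need at least 2 observations per group")
    total = v.sum()

    def abs_log_ratio(case_mask: np.ndarray) -> np.ndarray:
        case_sum = case_mask @ v
        n_ctrl = n - n_case
        return np.abs((total - case_sum) / n_ctrl - case_sum / n_case)

    observed = float(abs_log_ratio(is_case[None, :].astype(float))[0])
    n_alloc = comb(n, n_case)
    tol = 1e-9 * max(1.0, observed)
    if n_alloc <= iterations:
        masks = np.zeros((n_alloc, n), dtype=float)
        for i, idx in enumerate(combinations(range(n), n_case)):
            masks[i, list(idx)] = 1.0
        stats = abs_log_ratio(masks)
        return float(np.count_nonzero(stats >= observed - tol) / n_alloc)
    rng = np.random.default_rng(seed)
    masks = np.zeros((iterations, n), dtype=float)
    for i in range(iterations):
        masks[i, rng.choice(n, size=n_case, replace=False)] = 1.0
    stats = abs_log_ratio(masks)
    hits = int(np.count_nonzero(stats >= observed - tol))
    return float((1 + hits) / (1 + iterations))


def read_cq(path, metadata_path) -> CqTable:
    """Read a Cq CSV plus a sample-metadata TSV carrying the group column."""
    data = pd.read_csv(path)
    meta = pd.read_csv(metadata_path, sep="\t", dtype=str).set_index("sample_id")
    groups = meta["group"].to_dict()
    return CqTable(data, groups)


def write_cq(t: CqTable, path) -> None:
    t.data.to_csv(path, index=False)


def call_regulation(res: RelativeExpressionResult, alpha: float = 0.05) -> str:
    """UP/DR when the ratio departs from 1 at level ``alpha``, else NS."""
    if res.ratio > 1 and res.p < alpha:
        return "UP"
    if res.ratio < 1 and res.p < alpha:
        return "DR"
    return "NS"


def relative_expression(
    t: CqTable,
    genes: Iterable[str] | None = None,
    alpha: float = 0.05,
    iterations: int = 2000,
    seed: int | np.random.Generator | None = None,
) -> pd.DataFrame:
    """Ratio, reallocation p and regulation call for each target gene."""
    rng = np.random.default_rng(seed)
    rows = []
    for gene in (t.target_genes if genes is None else genes):
        ratio = pfaffl_ratio(t, gene)
        p = reallocation_test(t, gene, iterations=iterations, seed=rng)
        res = RelativeExpressionResult(gene, ratio, p, "NS")
        rows.append((gene, ratio, p, call_regulation(res, alpha)))
    return pd.DataFrame(rows, columns=["gene_id", "ratio", "p", "call"]).set_index(
        "gene_id")
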