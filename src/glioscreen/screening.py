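"""The gene-selection computation: consistency filter and linear fold changes.

A gene passes the consistency filter when its log2 expression is strictly
below the threshold in *every* control sample and strictly above it in
*every* case sample — an all-or-nothing rule that trades statistical power
for candidates that are uniformly off in controls and uniformly on in cases.
Values exactly at the threshold exclude the gene.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import ExpressionMatrix

__all__ = ["CandidateSet", "consistency_filter", "linear_fold_change",
           "collapse_probes"]


@dataclass(frozen=True)
class CandidateSet:
    """Genes passing the consistency filter, with their fold changes.

    ``table`` is indexed by gene id with columns ``fc`` (linear fold change,
    case over control), ``case_mean`` and ``control_mean`` (log2).
    """

    table: pd.DataFrame
    threshold: float

    @property
    def gene_ids(self) -> list[str]:
        return list(self.table.index)

    def __len__(self) -> int:
        return len(self.table)

    def __contains__(self, gene: str) -> bool:
        return gene in self.table.index


def consistency_filter(expr: ExpressionMatrix, threshold: float = 0.0) -> CandidateSet:
    """Select genes below ``threshold`` in all controls and above it in all cases.

    Strict inequalities on both sides; the selected set is invariant to
    sample and gene order and can only shrink as the threshold rises.
    """
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    case, ctrl = expr.case_samples, expr.control_samples
    if not case or not ctrl:
        raise ValueError("need at least one case and one control sample")
    case_vals = expr.values[case].to_numpy()
    ctrl_vals = expr.values[ctrl].to_numpy()
    keep = (ctrl_vals.max(axis=1) < threshold) & (case_vals.min(axis=1) > threshold)
    case_mean = case_vals.mean(axis=1)
    ctrl_mean = ctrl_vals.mean(axis=1)
    table = pd.DataFrame(
        {
            "fc": 2.0 ** (case_mean - ctrl_mean),
            "case_mean": case_mean,
            "control_mean": ctrl_mean,
        },
        index=expr.values.index,
    )[keep]
    return CandidateSet(table, threshold)


def linear_fold_change(expr: ExpressionMatrix, gene: str) -> float:
    """Antilog of the difference of group means on the log2 scale."""
    if gene not in expr.values.index:
        raise KeyError(f"unknown gene: {gene!r}")
    case, ctrl = expr.case_samples, expr.control_samples
    if not case or not ctrl:
        raise ValueError("need at least one case and one control sample")
    diff = expr.values.loc[gene, case].mean() - expr.values.loc[gene, ctrl].mean()
    return float(2.0 ** diff)


def collapse_probes(expr: ExpressionMatrix,
                    probe_to_gene: dict[str, str]) -> ExpressionMatrix:
    """Collapse probe-level rows to genes, keeping the maximum-mean probe.

    Probes absent from the map are dropped. Deterministic: among probes of a
    gene the one with the largest overall mean is retained (first in row
    order on exact ties).
    """
    mapped = expr.values.loc[[p for p in expr.values.index if p in probe_to_gene]]
    if mapped.empty:
        raise ValueError("no probes map to genes")
    genes = pd.Series({p: probe_to_gene[p] for p in mapped.index})
    means = mapped.mean(axis=1)
    best = (
        pd.DataFrame({"gene": genes, "mean": means})
        .groupby("gene", sort=False)["mean"]
        .idxmax()
    )
    collapsed = mapped.loc[best]
    collapsed.index = best.index
    return ExpressionMatrix(collapsed, expr.metadata)
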