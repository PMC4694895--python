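import numpy as np
import pandas as pd
import pytest

from glioscreen.io import ExpressionMatrix
from glioscreen.qpcr import CqTable
from glioscreen.survival import SurvivalTable


def make_expression(values: dict[str, list[float]], n_case: int,
                    sample_ids: list[str] | None = None) -> ExpressionMatrix:
    """Build a small matrix from {gene: row}; first n_case samples are cases."""
    frame = pd.DataFrame.from_dict(values, orient="index", dtype=float)
    n = frame.shape[1]
    samples = sample_ids or [f"S{i}" for i in range(n)]
    frame.columns = samples
    meta = pd.DataFrame(
        {"group": ["case"] * n_case + ["control"] * (n - n_case)},
        index=pd.Index(samples, name="sample_id"),
    )
    return ExpressionMatrix(frame, meta)


def make_cq(targets: dict[str, tuple[list[float], list[float]]],
            references: dict[str, tuple[list[float], list[float]]],
            efficiency: float = 2.0) -> CqTable:
    """Build a CqTable from per-gene (case Cqs, control Cqs) lists."""
    rows = []
    groups = {}
    for gene, (case, ctrl) in {**targets, **references}.items():
        is_ref = gene in references
        for i, cq in enumerate(case):
            s = f"C{i}"
            groups[s] = "case"
            rows.append((gene, s, 1, cq, efficiency, is_ref))
        for i, cq in enumerate(ctrl):
            s = f"N{i}"
            groups[s] = "control"
            rows.append((gene, s, 1, cq, efficiency, is_ref))
    data = pd.DataFrame(rows, columns=["gene_id", "sample_id", "replicate",
                                       "cq", "efficiency", "is_reference"])
    return CqTable(data, groups)


def make_survival(times, events, patient_ids=None, **gene_columns) -> SurvivalTable:
    ids = patient_ids or [f"P{i}" for i in range(len(times))]
    frame = pd.DataFrame({"time_days": times, "event": events},
                         index=pd.Index(ids, name="patient_id"))
    for gene, vals in gene_columns.items():
        frame[gene] = vals
    return SurvivalTable(frame)


@pytest.fixture
def rng():
    return np.random.default_rng(20150720)
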