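"""Shared domain types, file readers/writers and packaged reference tables.

The pipeline's tabular interchange formats are deliberately plain:

* expression matrices — TSV, genes as rows (first column header ``gene_id``),
  samples as columns, values on the log2 scale;
* sample metadata — TSV with columns ``sample_id``, ``group`` and optional
  ``subtype`` / ``culture_id``; ``group`` must be ``case`` or ``control``;
* two reference tables shipped with the package: the 20-gene overview of the
  expression screen (fold changes per assay plus RNA–protein Pearson
  coefficients) and the curated list of protein–protein interactions with
  their documented intermediaries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "Table1Fixture",
    "Table2Fixture",
    "Table2Row",
    "read_expression",
    "write_expression",
    "load_table1",
    "load_table2",
    "load_table2_graph",
    "GROUP_CASE",
    "GROUP_CONTROL",
]

GROUP_CASE = "case"
GROUP_CONTROL = "control"
_VALID_GROUPS = frozenset({GROUP_CASE, GROUP_CONTROL})


@dataclass(frozen=True)
class ExpressionMatrix:
    """A validated gene x sample grid of log2 expression values.

    ``values`` is a DataFrame indexed by gene id with sample ids as columns;
    ``metadata`` is indexed by sample id and carries at least ``group``
    (``case``/``control``) plus optional ``subtype`` and ``culture_id``.
    """

    values: pd.DataFrame
    metadata: pd.DataFrame

    def __post_init__(self) -> None:
        v, m = self.values, self.metadata
        if v.index.duplicated().any():
            dup = v.index[v.index.duplicated()][0]
            raise ValueError(f"duplicate gene id: {dup!r}")
        if v.columns.duplicated().any():
            dup = v.columns[v.columns.duplicated()][0]
            raise ValueError(f"duplicate sample id: {dup!r}")
        if "group" not in m.columns:
            raise ValueError("metadata is missing the 'group' column")
        missing = [s for s in v.columns if s not in m.index]
        if missing:
            raise ValueError(f"samples lacking metadata: {missing}")
        bad = set(m.loc[list(v.columns), "group"]) - _VALID_GROUPS
        if bad:
            raise ValueError(f"unknown group labels: {sorted(bad)}")
        arr = v.to_numpy(dtype=float)
        if not np.isfinite(arr).all():
            raise ValueError("expression values must be finite (no NA)")
        # keep metadata aligned to the value columns, drop extras
        object.__setattr__(self, "metadata", m.loc[list(v.columns)].copy())
        object.__setattr__(self, "values", v.astype(float))

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def groups(self) -> pd.Series:
        return self.metadata["group"]

    def samples_in_group(self, group: str) -> list[str]:
        return list(self.metadata.index[self.metadata["group"] == group])

    @property
    def case_samples(self) -> list[str]:
        return self.samples_in_group(GROUP_CASE)

    @property
    def control_samples(self) -> list[str]:
        return self.samples_in_group(GROUP_CONTROL)

    def subset_samples(self, sample_ids: Sequence[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values[list(sample_ids)],
                                self.metadata.loc[list(sample_ids)])

    def subset_genes(self, gene_ids: Sequence[str]) -> "ExpressionMatrix":
        unknown = [g for g in gene_ids if g not in self.values.index]
        if unknown:
            raise KeyError(f"unknown gene ids: {unknown}")
        return ExpressionMatrix(self.values.loc[list(gene_ids)], self.metadata)


def read_expression(path: str | Path, metadata_path: str | Path) -> ExpressionMatrix:
    """Read an expression TSV plus its sample-metadata TSV.

    Metadata rows for samples absent from the matrix are ignored with a
    warning; matrix samples without metadata raise ``ValueError``.
    """
    values = pd.read_csv(path, sep="\t", index_col="gene_id")
    if values.index.duplicated().any():
        dup = values.index[values.index.duplicated()][0]
        raise ValueError(f"duplicate gene row in {path}: {dup!r}")
    try:
        values = values.astype(float)
    except ValueError as exc:
        raise ValueError(f"non-numeric expression cell in {path}: {exc}") from exc
    meta = pd.read_csv(metadata_path, sep="\t", dtype=str).set_index("sample_id")
    extra = [s for s in meta.index if s not in values.columns]
    if extra:
        warnings.warn(f"metadata contains unknown samples (ignored): {extra}",
                      stacklevel=2)
        meta = meta.drop(index=extra)
    return ExpressionMatrix(values, meta)


def write_expression(m: ExpressionMatrix, path: str | Path,
                     metadata_path: str | Path) -> None:
    m.values.to_csv(path, sep="\t", index_label="gene_id")
    m.metadata.to_csv(metadata_path, sep="\t", index_label="sample_id")


# ---------------------------------------------------------------------------
# packaged reference tables


@dataclass(frozen=True)
class Table1Fixture:
    """The 20-gene overview of the expression screen.

    One row per candidate gene: linear fold changes measured on microarray,
    qPCR and western blot, the per-assay regulation calls (UP/DR/NS), the
    RNA–protein Pearson coefficient magnitude as printed and its sign
    (negative for RAPGEF4, RHBDD1 and MCC, whose protein levels moved against
    their transcripts).
    """

    frame: pd.DataFrame
    aliases: Mapping[str, tuple[str, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        f = self.frame
        if len(f) != 20:
            raise ValueError(f"expected 20 genes, got {len(f)}")
        if f.index.duplicated().any():
            raise ValueError("duplicate gene ids in overview table")
        r = f["rna_protein_r"]
        if ((r < 0) | (r > 1)).any():
            raise ValueError("printed correlation magnitudes must lie in [0, 1]")
        if not set(f["correlation_sign"]) <= {1, -1}:
            raise ValueError("correlation_sign must be +1 or -1")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.frame.index)

    def signed_r(self, gene: str) -> float:
        row = self.frame.loc[gene]
        return float(row["correlation_sign"] * row["rna_protein_r"])

    def fold_changes(self, assay: str) -> pd.Series:
        """Linear fold changes for ``assay`` in {microarray, qpcr, western}."""
        col = f"{assay}_fc"
        if col not in self.frame.columns:
            raise KeyError(f"unknown assay: {assay!r}")
        return self.frame[col].astype(float)


@dataclass(frozen=True)
class Table2Row:
    protein_a: str
    protein_b: str
    direct: bool
    via: tuple[str, ...]
    section: str = ""


@dataclass(frozen=True)
class Table2Fixture:
    """Curated protein-pair interactions with documented intermediaries.

    ``direct`` pairs are documented physical interactions; indirect pairs are
    linked through every protein in ``via``. A pair may be both direct and
    mediated (e.g. BMI1–CDC6, bound directly and linked via ATM).
    """

    rows: tuple[Table2Row, ...]

    def __post_init__(self) -> None:
        for row in self.rows:
            if not row.protein_a or not row.protein_b:
                raise ValueError("empty protein id in interaction row")
            if any(not x for x in row.via):
                raise ValueError(
                    f"empty intermediary id in row {row.protein_a}-{row.protein_b}")

    def pairs(self) -> list[tuple[str, str]]:
        return [(r.protein_a, r.protein_b) for r in self.rows]

    def via_list(self, a: str, b: str) -> tuple[str, ...]:
        """Union of documented intermediaries for the unordered pair (a, b)."""
        out: list[str] = []
        for r in self.rows:
            if {r.protein_a, r.protein_b} == {a, b}:
                out.extend(x for x in r.via if x not in out)
        return tuple(out)

    def edges(self) -> list[tuple[str, str, bool]]:
        """Expand rows to (node, node, mediated) edges.

        Direct rows yield the edge (a, b); every intermediary x yields the
        two mediated edges (a, x) and (x, b).
        """
        out: list[tuple[str, str, bool]] = []
        for r in self.rows:
            if r.direct:
                out.append((r.protein_a, r.protein_b, False))
            for x in r.via:
                out.append((r.protein_a, x, True))
                out.append((x, r.protein_b, True))
        return out


def _data_path(name: str):
    return resources.files("glioscreen").joinpath("data", name)


def load_table1() -> Table1Fixture:
    with resources.as_file(_data_path("table1.csv")) as p:
        f = pd.read_csv(p, index_col="gene_id",
                        dtype={"aliases": str}, keep_default_na=False)
    aliases = {g: tuple(a.split("|")) for g, a in f["aliases"].items() if a}
    f = f.drop(columns=["aliases"])
    for col in ("microarray_fc", "qpcr_fc", "western_fc", "rna_protein_r"):
        f[col] = f[col].astype(float)
    f["correlation_sign"] = f["correlation_sign"].astype(int)
    return Table1Fixture(f, aliases)


def load_table2() -> Table2Fixture:
    with resources.as_file(_data_path("table2.csv")) as p:
        f = pd.read_csv(p, keep_default_na=False)
    rows = tuple(
        Table2Row(
            protein_a=rec.protein_a.strip(),
            protein_b=rec.protein_b.strip(),
            direct=rec.direct.strip().lower() == "yes",
            via=tuple(x for x in rec.via.split("|") if x),
            section=rec.section,
        )
        for rec in f.itertuples()
    )
    return Table2Fixture(rows)


def load_table2_graph():
    """The interaction graph implied by the packaged interaction table.

    Convenience wrapper around :func:`glioscreen.interactome.build_graph`;
    mediated (via-derived) edges carry ``mediated=True``.
    """
    from .interactome import build_graph

    return build_graph(load_table2().edges())


# canonical nine-gene co-expression module (gene cluster I) and the three
# genes whose RNA-protein correlation is negative
CLUSTER_I_GENES: tuple[str, ...] = (
    "CENPA", "DLG7", "PBK", "CDC6", "KIF15", "KIF18A", "EZH2", "DEPDC1", "HMMR",
)
NEGATIVE_CORRELATION_GENES: tuple[str, ...] = ("RAPGEF4", "RHBDD1", "MCC")
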