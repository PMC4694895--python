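"""Western-blot quantification and RNA-protein correlation summaries.

Relative protein expression (RPE) is densitometry arithmetic: the band
intensity minus its local background, divided by the background-subtracted
intensity of the loading-control (beta-actin) band from the same lane. A
band falling below its own background is recorded as RPE 0 with a QC flag —
the protein is simply absent — rather than as an error; a non-positive
loading-control net intensity is an error because the lane cannot be
normalized.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .coexpression import ClusterTree, DistanceMatrix, cluster, \
    distance_matrix_from_rows, pearson_r
from .io import Table1Fixture

__all__ = [
    "BandTable",
    "RPEMatrix",
    "rpe",
    "rna_protein_r",
    "summarize_correlations",
    "normalize_sphere_counts",
    "targeted_proteomics_cluster",
]

_REQUIRED = ("protein_id", "sample_id", "band", "band_bg", "control",
             "control_bg")


@dataclass(frozen=True)
class BandTable:
    """Densitometry records: band and loading-control intensities per lane."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in _REQUIRED if c not in self.data.columns]
        if missing:
            raise ValueError(f"BandTable is missing columns: {missing}")
        num = self.data[list(_REQUIRED[2:])]
        if (num.to_numpy(dtype=float) < 0).any():
            raise ValueError("intensities must be non-negative")


@dataclass(frozen=True)
class RPEMatrix:
    """Protein x sample grid of relative protein expression.

    ``qc_flags`` marks (protein, sample) cells whose band net intensity was
    negative and was clamped to 0.
    """

    values: pd.DataFrame
    qc_flags: frozenset[tuple[str, str]] = field(default_factory=frozenset)

    def profile(self, protein: str) -> pd.Series:
        return self.values.loc[protein]


def read_bands(path) -> BandTable:
    """Read a densitometry CSV (protein_id, sample_id, band, band_bg, control, control_bg)."""
    return BandTable(pd.read_csv(path))


def rpe(b: BandTable) -> RPEMatrix:
    """Background-subtract and normalize band intensities to the loading control."""
    flags = set()
    records = {}
    for rec in b.data.itertuples():
        control_net = rec.control - rec.control_bg
        if control_net <= 0:
            raise ValueError(
                f"non-positive loading-control net intensity in sample "
                f"{rec.sample_id!r}")
        band_net = rec.band - rec.band_bg
        if band_net < 0:
            band_net = 0.0
            flags.add((rec.protein_id, rec.sample_id))
        records[(rec.protein_id, rec.sample_id)] = band_net / control_net
    frame = pd.Series(records).unstack()
    # preserve first-appearance order of proteins and samples
    proteins = list(dict.fromkeys(b.data["protein_id"]))
    samples = list(dict.fromkeys(b.data["sample_id"]))
    frame = frame.reindex(index=proteins, columns=samples)
    return RPEMatrix(frame, frozenset(flags))


def rna_protein_r(
    gene: str,
    qpcr_profile: Mapping[str, float] | pd.Series,
    rpe_profile: Mapping[str, float] | pd.Series,
) -> float:
    """Pearson correlation of mRNA vs protein levels over shared samples."""
    q = pd.Series(qpcr_profile, dtype=float)
    p = pd.Series(rpe_profile, dtype=float)
    shared = [s for s in q.index if s in p.index]
    if len(shared) < 3:
        raise ValueError(f"gene {gene!r}: need at least 3 shared samples")
    return pearson_r(q[shared].to_numpy(), p[shared].to_numpy())


def summarize_correlations(
    fixture: Table1Fixture,
    gene_set: Iterable[str] | None = None,
    signed: bool = True,
) -> tuple[float, float]:
    """Mean and population SD of per-gene RNA-protein coefficients.

    With ``signed`` the sign recorded for each gene is restored onto the
    printed magnitude; otherwise magnitudes are summarized as printed. SD
    uses divisor n (population convention).
    """
    genes = list(fixture.gene_ids if gene_set is None else gene_set)
    if not genes:
        raise ValueError("empty gene set")
    unknown = [g for g in genes if g not in fixture.frame.index]
    if unknown:
        raise KeyError(f"genes not in fixture: {unknown}")
    if signed:
        vals = np.array([fixture.signed_r(g) for g in genes])
    else:
        vals = fixture.frame.loc[genes, "rna_protein_r"].to_numpy(dtype=float)
    return float(vals.mean()), float(vals.std(ddof=0))


def normalize_sphere_counts(
    counts: Mapping[str, float] | pd.Series,
    control_baseline: float = 0.0,
) -> pd.Series:
    """Scale sphere counts to [0, 1]: control baseline -> 0, maximum -> 1."""
    s = pd.Series(counts, dtype=float)
    span = s.max() - control_baseline
    if span <= 0:
        raise ValueError("maximum count must exceed the control baseline")
    return ((s - control_baseline) / span).clip(0.0, 1.0)


def targeted_proteomics_cluster(
    rpe_matrix: RPEMatrix,
    extra_features: Mapping[str, Mapping[str, float] | pd.Series] | None = None,
) -> tuple[ClusterTree, DistanceMatrix]:
    """Cluster protein RPE profiles together with appended assay features.

    ``extra_features`` maps a feature name (e.g. ``sphere_ability`` already
    normalized to [0, 1], or ``1/PDT``) to its per-sample values; features
    must cover the RPE sample set exactly. Rows are clustered with Pearson
    distance and average linkage.
    """
    frame = rpe_matrix.values.copy()
    samples = list(frame.columns)
    if extra_features:
        for name, feat in extra_features.items():
            s = pd.Series(feat, dtype=float)
            if set(s.index) != set(samples):
                raise ValueError(
                    f"feature {name!r} does not share the RPE sample set")
            frame.loc[name] = s[samples].to_numpy()
    d = distance_matrix_from_rows(frame.to_numpy(dtype=float),
                                  list(frame.index), metric="pearson")
    return cluster(d), d
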