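"""Growth-assay arithmetic: doubling times, sphere summaries, correlations.

Population doubling time for a culture counted N0 cells at the start and Nt
after t days is ``PDT = t * log 2 / (log Nt - log N0)`` — the logarithm base
cancels. A shrinking culture (Nt < N0) yields a negative PDT, reported
as-is with a flag; Nt = N0 is singular.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import log
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .coexpression import pearson_r

__all__ = ["GrowthRecord", "SphereAssay", "pdt", "mean_pdt", "sphere_summary",
           "assay_correlation"]


@dataclass(frozen=True)
class GrowthRecord:
    culture_id: str
    t_days: float
    n0: float
    nt: float

    def __post_init__(self) -> None:
        if self.t_days <= 0:
            raise ValueError("elapsed time must be positive")
        if self.n0 <= 0 or self.nt <= 0:
            raise ValueError("cell counts must be positive")


@dataclass(frozen=True)
class SphereAssay:
    """Per-well sphere counts (and optionally per-sphere diameters, in um)."""

    culture_id: str
    counts: tuple[float, ...]
    diameters: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if not self.counts:
            raise ValueError("empty sphere assay")
        if any(c < 0 for c in self.counts):
            raise ValueError("sphere counts must be non-negative")
        if any(d <= 0 for d in self.diameters):
            raise ValueError("sphere diameters must be positive")


def read_growth(path) -> list[GrowthRecord]:
    """Read a growth CSV with columns culture_id, t_days, n0, nt."""
    f = pd.read_csv(path)
    return [GrowthRecord(str(r.culture_id), float(r.t_days), float(r.n0),
                         float(r.nt)) for r in f.itertuples()]


def read_spheres(path) -> list[SphereAssay]:
    """Read a sphere CSV with columns culture_id, well, count."""
    f = pd.read_csv(path)
    return [
        SphereAssay(str(cid), tuple(sub["count"].astype(float)))
        for cid, sub in f.groupby("culture_id", sort=False)
    ]


def pdt(rec: GrowthRecord) -> tuple[float, bool]:
    """Population doubling time in days and a shrinking-culture flag."""
    if rec.nt == rec.n0:
        raise ValueError(
            f"PDT undefined for culture {rec.culture_id!r}: Nt equals N0")
    value = rec.t_days * log(2.0) / (log(rec.nt) - log(rec.n0))
    return value, value < 0


def mean_pdt(records: Sequence[GrowthRecord]) -> tuple[float, float]:
    """Mean and population SD of per-passage PDTs for one culture."""
    if not records:
        raise ValueError("no growth records")
    vals = np.array([pdt(r)[0] for r in records])
    return float(vals.mean()), float(vals.std(ddof=0))


def sphere_summary(a: SphereAssay) -> dict[str, float]:
    """Arithmetic means and population SDs of counts and diameters."""
    counts = np.asarray(a.counts, dtype=float)
    out = {
        "mean_count": float(counts.mean()),
        "sd_count": float(counts.std(ddof=0)),
    }
    if a.diameters:
        diam = np.asarray(a.diameters, dtype=float)
        out["mean_diameter"] = float(diam.mean())
        out["sd_diameter"] = float(diam.std(ddof=0))
    return out


def assay_correlation(
    x: Mapping[str, float] | pd.Series,
    y: Mapping[str, float] | pd.Series,
) -> float:
    """Pearson correlation of two per-culture measurements on matched cultures.

    Any transform (e.g. reciprocal PDT) is applied by the caller.
    """
    xs = pd.Series(x, dtype=float)
    ys = pd.Series(y, dtype=float)
    shared = [c for c in xs.index if c in ys.index]
    if len(shared) < 3:
        raise ValueError("need at least 3 cultures in common")
    return pearson_r(xs[shared].to_numpy(), ys[shared].to_numpy())
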