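"""Module-score patient stratification and survival comparison.

Patients carrying expression of a gene module are stratified into low /
intermediate / high expression groups (z-score per gene, hierarchical
clustering of patients, clusters ranked by mean module z-score; a simpler
rank-tertile mode is also provided). Groups are compared with the
Kaplan-Meier product-limit estimator and the Gehan-Breslow-Wilcoxon test —
a weighted log-rank whose weight at each event time is the total number at
risk, so early deaths dominate. Deaths are processed before censorings at
tied times. A univariate logistic screen with Benjamini-Hochberg FDR
control covers probe-level group discrimination.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from math import comb
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .coexpression import cluster, cut, distance_matrix_from_rows

__all__ = [
    "SurvivalTable",
    "Stratification",
    "KMCurve",
    "stratify",
    "km",
    "km_median",
    "gbw_test",
    "logistic_screen",
    "bh_adjust",
]

_META_COLS = ("time_days", "event", "subtype")


@dataclass(frozen=True)
class SurvivalTable:
    """Per-patient time/event records joined to module-gene expression.

    ``data`` is indexed by patient id with columns ``time_days`` (> 0),
    ``event`` (1 = death observed, 0 = censored), optional ``subtype`` and
    one log2-expression column per module gene.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        d = self.data
        if "time_days" not in d.columns or "event" not in d.columns:
            raise ValueError("SurvivalTable needs time_days and event columns")
        if (d["time_days"] <= 0).any():
            raise ValueError("survival times must be positive")
        if not set(d["event"].unique()) <= {0, 1}:
            raise ValueError("event must be 0 or 1")
        if d.index.duplicated().any():
            raise ValueError("duplicate patient ids")

    @property
    def patient_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def gene_columns(self) -> list[str]:
        return [c for c in self.data.columns if c not in _META_COLS]

    def expression(self, genes: Sequence[str]) -> pd.DataFrame:
        missing = [g for g in genes if g not in self.data.columns]
        if missing:
            raise KeyError(f"genes not in table: {missing}")
        return self.data[list(genes)].astype(float)

    def subset(self, patient_ids: Iterable[str]) -> "SurvivalTable":
        return SurvivalTable(self.data.loc[list(patient_ids)])

    def times_events(self) -> tuple[np.ndarray, np.ndarray]:
        return (self.data["time_days"].to_numpy(dtype=float),
                self.data["event"].to_numpy(dtype=int))


@dataclass(frozen=True)
class Stratification:
    assignment: dict[str, str]
    genes: tuple[str, ...]
    k: int

    def group(self, label: str) -> list[str]:
        return [p for p, g in self.assignment.items() if g == label]

    def labels(self) -> list[str]:
        return list(dict.fromkeys(self.assignment.values()))


def read_survival(path) -> SurvivalTable:
    """Read a survival TSV: patient_id, time_days, event, subtype, gene columns."""
    f = pd.read_csv(path, sep="\t").set_index("patient_id")
    return SurvivalTable(f)


def write_survival(tab: SurvivalTable, path) -> None:
    tab.data.to_csv(path, sep="\t", index_label="patient_id")


def _group_labels(k: int) -> list[str]:
    if k == 1:
        return ["all"]
    if k == 2:
        return ["low", "high"]
    if k == 3:
        return ["low", "intermediate", "high"]
    return ["low"] + [f"mid{i}" for i in range(1, k - 1)] + ["high"]


def stratify(
    tab: SurvivalTable,
    genes: Sequence[str],
    k: int = 3,
    mode: Literal["cluster", "tertile"] = "cluster",
) -> Stratification:
    """Partition patients into k module-expression groups.

    Expression is z-scored per gene across patients. In ``cluster`` mode
    patients are hierarchically clustered (Pearson distance on their
    z-score vectors, average linkage) and the k clusters are ranked by mean
    module z-score; in ``tertile`` mode patients are ranked by mean z-score
    and split into k near-equal groups. The group with the largest mean
    z-score is always labelled ``high``.
    """
    expr = tab.expression(genes)
    n = len(expr)
    if k > n:
        raise ValueError(f"k={k} exceeds the number of patients ({n})")
    sd = expr.std(ddof=0)
    if (sd == 0).any():
        bad = sd.index[sd == 0][0]
        raise ValueError(f"constant gene across patients: {bad!r}")
    z = (expr - expr.mean()) / sd
    mean_z = z.mean(axis=1)

    if mode == "cluster":
        d = distance_matrix_from_rows(z.to_numpy(dtype=float),
                                      [str(p) for p in expr.index],
                                      metric="pearson")
        modules = cut(cluster(d), k)
        raw = pd.Series({p: modules.assignment[str(p)] for p in expr.index})
    elif mode == "tertile":
        order = mean_z.rank(method="first")
        raw = pd.Series(
            pd.qcut(order, q=k, labels=False, duplicates="drop"),
            index=expr.index,
        ).astype(str)
    else:
        raise ValueError("mode must be 'cluster' or 'tertile'")

    rank = raw.groupby(raw).apply(lambda idx: mean_z[idx.index].mean())
    ordered = rank.sort_values().index
    labels = _group_labels(len(ordered))
    relabel = {raw_label: labels[i] for i, raw_label in enumerate(ordered)}
    assignment = {p: relabel[raw[p]] for p in expr.index}
    return Stratification(assignment, tuple(genes), k)


@dataclass(frozen=True)
class KMCurve:
    """Product-limit survival curve: distinct event times, S(t), at-risk counts."""

    event_times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    n: int

    def step(self, t: float) -> float:
        """S(t) of the right-continuous step function."""
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def km(tab: SurvivalTable) -> KMCurve:
    """Kaplan-Meier product-limit estimator.

    At tied times deaths are processed before censorings, i.e. a patient
    censored at t is still at risk for deaths occurring at t.
    """
    times, events = tab.times_events()
    if times.size == 0:
        raise ValueError("empty survival table")
    order = np.argsort(times, kind="stable")
    times, events = times[order], events[order]
    event_times = np.unique(times[events == 1])
    surv, risks = [], []
    s = 1.0
    for t in event_times:
        n_risk = int(np.count_nonzero(times >= t))
        d = int(np.count_nonzero((times == t) & (events == 1)))
        s *= 1.0 - d / n_risk
        surv.append(s)
        risks.append(n_risk)
    return KMCurve(event_times, np.asarray(surv), np.asarray(risks, dtype=int),
                   n=times.size)


def km_median(curve: KMCurve) -> float | None:
    """Smallest event time with S(t) <= 0.5, or None if S never reaches 0.5."""
    below = np.nonzero(curve.survival <= 0.5)[0]
    if below.size == 0:
        return None
    return float(curve.event_times[below[0]])


def _gbw_statistic(times: np.ndarray, events: np.ndarray,
                   in_a: np.ndarray) -> float:
    """Gehan-Breslow-Wilcoxon chi-square statistic (weight = number at risk)."""
    event_times = np.unique(times[events == 1])
    u = 0.0
    var = 0.0
    for t in event_times:
        at_risk = times >= t
        n_i = int(at_risk.sum())
        n1 = int((at_risk & in_a).sum())
        dead = (times == t) & (events == 1)
        d_i = int(dead.sum())
        d1 = int((dead & in_a).sum())
        frac = n1 / n_i
        u += n_i * (d1 - d_i * frac)
        if n_i > 1:
            var += (n_i ** 2) * d_i * frac * (1 - frac) * (n_i - d_i) / (n_i - 1)
    if var == 0.0:
        return 0.0
    return u * u / var


def gbw_test(
    a: SurvivalTable,
    b: SurvivalTable,
    exact: bool = False,
) -> tuple[float, float]:
    """Compare two survival groups with the Gehan-Breslow-Wilcoxon test.

    Returns ``(statistic, p)``. By default p is two-sided from the
    chi-square reference with 1 df. With ``exact=True`` the p-value is
    instead the proportion of all fixed-size reallocations of patients
    between the groups whose statistic is at least the observed one
    (observed allocation counted; only feasible for small totals).
    The test is symmetric in its arguments.
    """
    ta, ea = a.times_events()
    tb, eb = b.times_events()
    if ta.size == 0 or tb.size == 0:
        raise ValueError("both groups must be non-empty")
    times = np.concatenate([ta, tb])
    events = np.concatenate([ea, eb])
    if not events.any():
        raise ValueError("no events in either group")
    n, n_a = times.size, ta.size
    in_a = np.zeros(n, dtype=bool)
    in_a[:n_a] = True
    observed = _gbw_statistic(times, events, in_a)
    if not exact:
        return observed, float(sps.chi2.sf(observed, df=1))
    n_alloc = comb(n, n_a)
    if n_alloc > 200_000:
        raise ValueError("exact reallocation infeasible for this group size")
    hits = 0
    mask = np.zeros(n, dtype=bool)
    tol = 1e-9 * max(1.0, observed)
    for idx in combinations(range(n), n_a):
        mask[:] = False
        mask[list(idx)] = True
        if _gbw_statistic(times, events, mask) >= observed - tol:
            hits += 1
    return observed, hits / n_alloc


def logistic_screen(
    y: Sequence[int],
    x: pd.DataFrame,
) -> pd.DataFrame:
    """Univariate logistic regression of a binary label on each probe.

    ``x`` is samples x probes. Returns per-probe maximum-likelihood slope,
    two-sided Wald p, and a ``separated`` flag; completely separated probes
    get no p-value (NaN). A constant probe carries no information: slope 0,
    p 1.
    """
    import statsmodels.api as sm
    from statsmodels.tools.sm_exceptions import PerfectSeparationError

    y = np.asarray(y, dtype=float)
    if set(np.unique(y)) != {0.0, 1.0}:
        raise ValueError("response must contain both classes (0 and 1)")
    if y.size != len(x):
        raise ValueError("response and probe matrix disagree on sample count")
    rows = []
    for probe in x.columns:
        v = x[probe].to_numpy(dtype=float)
        if not np.isfinite(v).all():
            raise ValueError(f"non-finite values for probe {probe!r}")
        if v.std() == 0:
            rows.append((probe, 0.0, 1.0, False))
            continue
        design = sm.add_constant(v)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = sm.Logit(y, design).fit(disp=0, maxiter=200)
            if not fit.mle_retvals.get("converged", False) or \
                    abs(fit.params[1]) > 1e3:
                rows.append((probe, np.nan, np.nan, True))
            else:
                rows.append((probe, float(fit.params[1]),
                             float(fit.pvalues[1]), False))
        except (PerfectSeparationError, np.linalg.LinAlgError):
            rows.append((probe, np.nan, np.nan, True))
    return pd.DataFrame(rows, columns=["probe", "slope", "p", "separated"]
                        ).set_index("probe")


def bh_adjust(pvalues: Sequence[float], q: float = 0.10
              ) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: adjusted p-values and pass flags at ``q``."""
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    reject, adjusted, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return adjusted, reject
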