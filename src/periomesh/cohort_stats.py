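"""Cohort-level statistics: descriptive tables, cluster-robust means, bleeding.

Teeth are clustered within patients, so naive SEs (sd/sqrt(n)) understate the
uncertainty of cohort means.  For estimating a mean, a GEE linear model with
identity link reduces exactly to the grand mean with the cluster-sum sandwich
variance, which is what :func:`clustered_mean` implements directly:

    se^2 = sum_i ( sum_{j in i} (x_ij - xbar) )^2 / n^2

with a Wald chi-squared statistic (estimate/se)^2 against chi2(1) and a
95% CI of estimate +/- 1.96 se.  The paired dichotomous bleeding outcome is
tested with the exact binomial McNemar test (valid at any discordant count).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

#: normal 95% multiplier (Wald); no small-cluster correction, see docs/methods.md
Z95 = 1.96


@dataclass
class SummaryRow:
    """One descriptive row in the Table-1/Table-2 layout."""

    label: str
    n: int
    mean: float
    sd: float
    min: float
    max: float
    p25: float
    median: float
    p75: float

    def to_dict(self) -> dict:
        return self.__dict__.copy()


def describe(values, label: str = "", decimals: int = 2) -> SummaryRow:
    """Mean, SD (n-1), min/max and linearly interpolated quartiles.

    Quartiles use the inclusive method (linear interpolation between order
    statistics).  Values are rounded to ``decimals`` for table replication;
    raise on empty or non-finite input.
    """
    x = np.asarray(values, dtype=np.float64).ravel()
    if x.size == 0:
        raise ValueError("describe() requires at least one value")
    if not np.all(np.isfinite(x)):
        raise ValueError("describe() requires finite values")
    r = lambda q: float(np.round(q, decimals))
    sd = float(np.std(x, ddof=1)) if x.size > 1 else 0.0
    return SummaryRow(
        label=label,
        n=int(x.size),
        mean=r(np.mean(x)),
        sd=r(sd),
        min=r(np.min(x)),
        max=r(np.max(x)),
        p25=r(np.percentile(x, 25, method="linear")),
        median=r(np.percentile(x, 50, method="linear")),
        p75=r(np.percentile(x, 75, method="linear")),
    )


@dataclass
class ClusteredEstimate:
    """Cluster-robust mean estimate with Wald chi-squared inference."""

    estimate: float
    robust_se: float
    ci95: tuple
    wald_chi2: float
    p_value: float
    n_clusters: int
    degenerate: bool = False


def clustered_mean(values, cluster_ids) -> ClusteredEstimate:
    """Grand mean with the cluster-sum sandwich SE (intercept-only GEE).

    Requires at least two clusters.  If all residual cluster sums vanish
    (e.g. constant data) the estimate is flagged degenerate: the CI collapses
    to a point and the Wald statistic/p-value are undefined (NaN).
    """
    x = np.asarray(values, dtype=np.float64).ravel()
    ids = np.asarray(cluster_ids).ravel()
    if len(x) != len(ids):
        raise ValueError("values and cluster_ids must have equal length")
    uniq, inv = np.unique(ids, return_inverse=True)
    if len(uniq) < 2:
        raise ValueError("clustered_mean needs >= 2 clusters")
    n = len(x)
    est = float(np.mean(x))
    sums = np.bincount(inv, weights=x - est)
    se = float(np.sqrt(np.sum(sums**2)) / n)
    if se == 0.0:
        return ClusteredEstimate(
            estimate=est, robust_se=0.0, ci95=(est, est),
            wald_chi2=float("nan"), p_value=float("nan"),
            n_clusters=len(uniq), degenerate=True,
        )
    chi2 = (est / se) ** 2
    p = float(stats.chi2.sf(chi2, df=1))
    return ClusteredEstimate(
        estimate=est,
        robust_se=se,
        ci95=(est - Z95 * se, est + Z95 * se),
        wald_chi2=float(chi2),
        p_value=p,
        n_clusters=len(uniq),
    )


def naive_mean_ci(values) -> tuple:
    """Classical sd/sqrt(n) 95% CI, ignoring clustering (for comparison)."""
    x = np.asarray(values, dtype=np.float64).ravel()
    se = float(np.std(x, ddof=1) / np.sqrt(len(x)))
    m = float(np.mean(x))
    return (m - Z95 * se, m + Z95 * se)


# ---------------------------------------------------------------------------
# bleeding transitions
# ---------------------------------------------------------------------------

def mcnemar_exact_p(resolved: int, appeared: int) -> float:
    """Exact binomial McNemar p: 2 * min-tail of Binomial(b+c, 1/2), capped at 1."""
    b, c = int(resolved), int(appeared)
    if b < 0 or c < 0:
        raise ValueError("counts must be nonnegative")
    n = b + c
    if n == 0:
        return 1.0
    return float(min(1.0, 2.0 * stats.binom.cdf(min(b, c), n, 0.5)))


@dataclass
class BleedingTransitions:
    """Paired bleeding-on-probing transition table with prevalences (%)."""

    stayed: int
    resolved: int
    appeared: int
    never: int
    n: int
    prevalence0_pct: float
    prevalence1_pct: float
    resolved_pct: float
    appeared_pct: float
    mcnemar_p: float

    def to_dict(self) -> dict:
        return self.__dict__.copy()


def bleeding_transitions(records) -> BleedingTransitions:
    """Count paired bleeding transitions and test marginal homogeneity.

    ``records`` is an iterable with ``bleeding0``/``bleeding1`` attributes (or
    a pair of boolean arrays).  Prevalences are percentages of all teeth,
    rounded to 1 decimal.
    """
    if isinstance(records, tuple) and len(records) == 2:
        b0 = np.asarray(records[0], dtype=bool)
        b1 = np.asarray(records[1], dtype=bool)
    else:
        records = list(records)
        b0 = np.asarray([r.bleeding0 for r in records], dtype=bool)
        b1 = np.asarray([r.bleeding1 for r in records], dtype=bool)
    if len(b0) != len(b1):
        raise ValueError("bleeding flag arrays differ in length")
    n = len(b0)
    stayed = int(np.sum(b0 & b1))
    resolved = int(np.sum(b0 & ~b1))
    appeared = int(np.sum(~b0 & b1))
    never = int(np.sum(~b0 & ~b1))
    pct = lambda k: float(np.round(100.0 * k / n, 1)) if n else float("nan")
    return BleedingTransitions(
        stayed=stayed,
        resolved=resolved,
        appeared=appeared,
        never=never,
        n=n,
        prevalence0_pct=pct(stayed + resolved),
        prevalence1_pct=pct(stayed + appeared),
        resolved_pct=pct(resolved),
        appeared_pct=pct(appeared),
        mcnemar_p=mcnemar_exact_p(resolved, appeared),
    )


# ---------------------------------------------------------------------------
# cohort summary
# ---------------------------------------------------------------------------

@dataclass
class CohortSummary:
    """Descriptive rows, clustered CIs and the bleeding table for one cohort."""

    rows: dict = field(default_factory=dict)
    estimates: dict = field(default_factory=dict)
    bleeding: BleedingTransitions | None = None
    n: int = 0

    def to_frame(self) -> pd.DataFrame:
        recs = []
        for label, row in self.rows.items():
            rec = row.to_dict()
            est = self.estimates.get(label)
            if est is not None:
                rec["ci95_low"] = est.ci95[0]
                rec["ci95_high"] = est.ci95[1]
                rec["robust_se"] = est.robust_se
                rec["p_value"] = est.p_value
            recs.append(rec)
        return pd.DataFrame(recs)


#: variable -> rounding used in the printed tables (2 dp for probing depths,
#: 3 dp for digital losses)
_DECIMALS = {"pst0": 2, "pst1": 2, "diff": 2, "height_loss": 3, "width_loss": 3}


def summarize_cohort(chart: pd.DataFrame | None = None,
                     measurements: pd.DataFrame | None = None) -> CohortSummary:
    """Build the cohort summary from a clinical chart and/or measurement table.

    ``chart`` needs columns patient_id, tooth_id, pst0, pst1 (and optionally
    bleeding0/bleeding1); ``measurements`` needs patient_id, tooth_id,
    height_loss, width_loss, status.  Unmeasurable teeth (status != "ok") are
    excluded from the digital summaries.
    """
    summary = CohortSummary()

    def add(label: str, values, clusters) -> None:
        summary.rows[label] = describe(values, label, decimals=_DECIMALS[label])
        if len(np.unique(clusters)) >= 2:
            summary.estimates[label] = clustered_mean(values, clusters)

    if chart is not None and len(chart):
        add("pst0", chart["pst0"].to_numpy(), chart["patient_id"].to_numpy())
        add("pst1", chart["pst1"].to_numpy(), chart["patient_id"].to_numpy())
        add("diff", (chart["pst1"] - chart["pst0"]).to_numpy(),
            chart["patient_id"].to_numpy())
        summary.n = len(chart)
        if {"bleeding0", "bleeding1"}.issubset(chart.columns):
            summary.bleeding = bleeding_transitions(
                (chart["bleeding0"].to_numpy(), chart["bleeding1"].to_numpy())
            )
    if measurements is not None and len(measurements):
        ok = measurements[measurements["status"] == "ok"]
        if len(ok):
            add("height_loss", ok["height_loss"].to_numpy(),
                ok["patient_id"].to_numpy())
            add("width_loss", ok["width_loss"].to_numpy(),
                ok["patient_id"].to_numpy())
            summary.n = summary.n or len(ok)
    return summary
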