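"""Case-level cohort statistics: percentages, 2x2 association tests,
biomarker-status correlations, Kaplan-Meier estimation, log-rank tests,
and biomarker-high/low stratification.

The product-limit estimator and the log-rank statistic are implemented
directly (they are the core quantities of the outcome analysis and their
internals — per-group observed/expected events, hypergeometric variance —
are exposed in the results); scipy supplies the reference distributions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .sc import bh_adjust


def percent_positive(n_pos: int, n_total: int) -> int:
    """Percentage of positive cases, rounded half-up to the nearest integer.

    Uses exact rational arithmetic so printed-style values such as
    19% for 5/26 are reproduced without floating-point rounding artifacts.
    """
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    if not 0 <= n_pos <= n_total:
        raise ValueError("need 0 <= n_pos <= n_total")
    return int(math.floor(Fraction(100 * n_pos, n_total) + Fraction(1, 2)))


@dataclass
class CrosstabResult:
    """2x2 cross-tabulation with Fisher's exact test and a sample odds
    ratio (0.5 continuity correction when any cell is zero)."""

    table: np.ndarray  # rows: row call True/False, cols: column call True/False
    odds_ratio: float
    fisher_p: float
    n_excluded_missing: int
    degenerate_margin: bool


def crosstab(
    cohort: pd.DataFrame, row_call: str, column_call: str
) -> CrosstabResult:
    """Cross-tabulate two boolean case-level calls.

    Rows with a missing value in either call are excluded (and counted).
    The odds ratio is the sample ``ad/bc`` with a 0.5 continuity
    correction applied to all cells when any cell is zero; the p-value is
    the two-sided Fisher exact test.  A table with an empty margin is
    flagged degenerate (odds ratio undefined).
    """
    sub = cohort[[row_call, column_call]]
    missing = sub.isna().any(axis=1)
    sub = sub[~missing]
    r = sub[row_call].astype(bool).to_numpy()
    c = sub[column_call].astype(bool).to_numpy()
    table = np.array(
        [
            [int((r & c).sum()), int((r & ~c).sum())],
            [int((~r & c).sum()), int((~r & ~c).sum())],
        ]
    )
    degenerate = (table.sum(axis=0) == 0).any() or (
        table.sum(axis=1) == 0
    ).any()
    t = table.astype(float)
    if (t == 0).any():
        t = t + 0.5
    odds_ratio = (
        float("nan")
        if degenerate
        else float(t[0, 0] * t[1, 1] / (t[0, 1] * t[1, 0]))
    )
    fisher_p = float(stats.fisher_exact(table, alternative="two-sided")[1])
    return CrosstabResult(
        table=table,
        odds_ratio=odds_ratio,
        fisher_p=fisher_p,
        n_excluded_missing=int(missing.sum()),
        degenerate_margin=bool(degenerate),
    )


def status_marker_correlation(
    status: pd.DataFrame, markers: pd.DataFrame
) -> pd.DataFrame:
    """Point-biserial correlation of each binary status with each
    continuous per-case marker level.

    Pearson's r on the 0/1-coded status against the marker values, with
    Benjamini-Hochberg correction across every computed pair.  Pairs with
    a zero-variance column (or fewer than 3 complete cases) are undefined
    and flagged, not reported as zero.
    """
    rows = []
    for s in status.columns:
        for m in markers.columns:
            sv = status[s].astype(float)
            mv = markers[m].astype(float)
            ok = ~(sv.isna() | mv.isna())
            sv, mv = sv[ok].to_numpy(), mv[ok].to_numpy()
            if len(sv) < 3 or np.ptp(sv) == 0 or np.ptp(mv) == 0:
                rows.append(
                    dict(status=s, marker=m, r=np.nan, p_value=np.nan,
                         n=len(sv), defined=False)
                )
                continue
            r, p = stats.pearsonr(sv, mv)
            rows.append(
                dict(status=s, marker=m, r=float(r), p_value=float(p),
                     n=len(sv), defined=True)
            )
    out = pd.DataFrame(rows)
    defined = out["defined"].to_numpy()
    q = np.full(len(out), np.nan)
    if defined.any():
        q[defined] = bh_adjust(out.loc[defined, "p_value"].to_numpy())
    out["q_value"] = q
    out["significant"] = out["q_value"] < 0.05
    return out


# ---------------------------------------------------------------------------
# Survival
# ---------------------------------------------------------------------------


@dataclass
class KMEstimate:
    """Product-limit (Kaplan-Meier) survival curve.

    ``survival[i]`` is the estimate just after ``event_times[i]``; the
    curve starts at 1 and is right-continuous, so landmark lookups use the
    last event time at or before the landmark.
    """

    event_times: np.ndarray  # distinct times with >= 1 event, sorted
    survival: np.ndarray
    n_at_risk: np.ndarray
    n_events: np.ndarray

    def survival_at(self, t: float) -> float:
        """Step-function (right-continuous) lookup of S(t)."""
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.event_times,
                "n_at_risk": self.n_at_risk,
                "n_events": self.n_events,
                "survival": self.survival,
            }
        )


def km_estimate(times: Sequence[float], events: Sequence[bool]) -> KMEstimate:
    """Kaplan-Meier product-limit estimator.

    Censored observations leave the risk set without contributing an event
    factor; with no censoring the curve equals the empirical survival
    function.
    """
    times = np.asarray(times, float)
    events = np.asarray(events, bool)
    if times.size == 0:
        raise ValueError("need at least one observation")
    if (times < 0).any():
        raise ValueError("negative survival times")
    order = np.argsort(times, kind="stable")
    times, events = times[order], events[order]
    distinct = np.unique(times[events])
    surv = []
    at_risk = []
    n_ev = []
    s = 1.0
    for t in distinct:
        n = int((times >= t).sum())
        d = int(((times == t) & events).sum())
        s *= 1.0 - d / n
        surv.append(s)
        at_risk.append(n)
        n_ev.append(d)
    return KMEstimate(
        event_times=distinct,
        survival=np.asarray(surv),
        n_at_risk=np.asarray(at_risk, int),
        n_events=np.asarray(n_ev, int),
    )


@dataclass
class LogRankResult:
    chi_square: float
    degrees_freedom: int
    p_value: float
    observed: np.ndarray  # events per group
    expected: np.ndarray


def logrank(
    times: Sequence[float],
    events: Sequence[bool],
    groups: Sequence,
) -> LogRankResult:
    """Two-group log-rank test.

    At each distinct event time the observed events in group 0 are
    compared with their hypergeometric expectation and variance given the
    risk sets; the chi-square statistic is ``(O - E)^2 / V`` on 1 degree
    of freedom.  The per-group observed minus expected events sum to zero
    by construction.
    """
    times = np.asarray(times, float)
    events = np.asarray(events, bool)
    groups = np.asarray(groups)
    labels = np.unique(groups)
    if labels.size != 2:
        raise ValueError(f"need exactly 2 groups, got {labels.size}")
    if not events.any():
        raise ValueError("no events in the cohort")
    g0 = groups == labels[0]
    o0 = 0.0
    e0 = 0.0
    var = 0.0
    for t in np.unique(times[events]):
        at_risk = times >= t
        n = int(at_risk.sum())
        n0 = int((at_risk & g0).sum())
        d = int(((times == t) & events).sum())
        d0 = int(((times == t) & events & g0).sum())
        o0 += d0
        e0 += d * n0 / n
        if n > 1:
            var += d * (n0 / n) * (1 - n0 / n) * (n - d) / (n - 1)
    observed = np.array([o0, float(events.sum()) - o0])
    expected = np.array([e0, float(events.sum()) - e0])
    if var == 0:
        chi2 = 0.0
        p = 1.0
    else:
        chi2 = (o0 - e0) ** 2 / var
        p = float(stats.chi2.sf(chi2, df=1))
    return LogRankResult(
        chi_square=float(chi2),
        degrees_freedom=1,
        p_value=p,
        observed=observed,
        expected=expected,
    )


@dataclass
class Stratification:
    """Binary phenotype-high calls with the cutoff that produced them."""

    calls: pd.DataFrame  # case_id, value, phenotype_high
    cutoff: float
    rule: str
    n_excluded: int


def stratify_by_phenotype(
    values: pd.Series, cutoff: float | None = None
) -> Stratification:
    """Dichotomize a per-case statistic into phenotype-high / -low.

    The default cutoff is the cohort median with ties going to "low"
    (strictly-greater rule); an absolute cutoff can be supplied.  Cases
    with an undefined statistic are excluded and counted.
    """
    values = values.astype(float)
    defined = values.dropna()
    if defined.empty:
        raise ValueError("no case has a defined statistic")
    rule = "median" if cutoff is None else "absolute"
    if cutoff is None:
        cutoff = float(defined.median())
    calls = pd.DataFrame(
        {
            "case_id": defined.index,
            "value": defined.to_numpy(),
            "phenotype_high": defined.to_numpy() > cutoff,
        }
    ).reset_index(drop=True)
    return Stratification(
        calls=calls,
        cutoff=float(cutoff),
        rule=rule,
        n_excluded=int(values.isna().sum()),
    )
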