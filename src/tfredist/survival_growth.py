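"""Kaplan-Meier estimation, logrank comparison across activity strata, and
the log-linear exponential growth model with a treatment x time interaction
test."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats

from .io_formats import SurvivalRecord

__all__ = [
    "KMEstimate",
    "km_estimate",
    "logrank_test",
    "GrowthFit",
    "growth_interaction_test",
]


@dataclass
class KMEstimate:
    """Product-limit survival curve: S(t) over the distinct event times."""

    group: str
    event_times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray

    def survival_at(self, t: float) -> float:
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def km_estimate(records: Sequence[SurvivalRecord], group: str = "all") -> KMEstimate:
    """Kaplan-Meier product-limit estimate; ties put events before
    censorings at equal times (the standard convention)."""
    if not records:
        raise ValueError("no records")
    times = np.array([r.time for r in records], dtype=float)
    events = np.array([r.event for r in records], dtype=int)
    if (times < 0).any():
        raise ValueError("negative follow-up time")
    kmf = KaplanMeierFitter()
    kmf.fit(times, events)
    event_times = np.array(sorted({t for t, e in zip(times, events) if e == 1}))
    surv = np.array([float(kmf.survival_function_at_times(t).iloc[0]) for t in event_times])
    at_risk = np.array([(times >= t).sum() for t in event_times])
    return KMEstimate(group=group, event_times=event_times, survival=surv, at_risk=at_risk)


def logrank_test(
    groups: Mapping[str, Sequence[SurvivalRecord]],
) -> tuple[float, int, float]:
    """Unstratified, unweighted logrank test across >= 2 groups.

    Returns (chi-square, df, p).
    """
    labels, times, events = [], [], []
    for label, recs in groups.items():
        for r in recs:
            labels.append(label)
            times.append(r.time)
            events.append(r.event)
    nonempty = {label for label in labels}
    if len(nonempty) < 2:
        raise ValueError("logrank needs >= 2 non-empty groups")
    if sum(events) == 0:
        raise ValueError("logrank needs >= 1 event")
    res = multivariate_logrank_test(
        pd.Series(times), pd.Series(labels), pd.Series(events)
    )
    df = len(nonempty) - 1
    return float(res.test_statistic), df, float(res.p_value)


@dataclass
class GrowthFit:
    """Log-linear growth fit with treatment-modified rate.

    Full model: ln(N) ~ b0 + b1*day + b2*treated + b3*day*treated; the
    reduced model drops the treatment terms.  The F test targets the
    interaction (difference in growth rate); doubling time per condition is
    ln(2)/rate in days.
    """

    coefficients: dict
    rss_full: float
    rss_reduced: float
    f_stat: float
    pvalue: float
    doubling_times: dict
    reference_condition: str
    treated_condition: str


def growth_interaction_test(
    table: pd.DataFrame, reference: str | None = None
) -> GrowthFit:
    """ANOVA for a treatment effect on exponential growth rate.

    ``table`` columns: day, condition, replicate, count (counts > 0).  The
    reduced model is ln(count) ~ day; the full model adds the treatment
    indicator and its interaction with day; F compares the two with
    Delta df = 2, and the interaction coefficient is the rate difference.
    """
    required = {"day", "condition", "count"}
    if not required <= set(table.columns):
        raise ValueError(f"growth table needs columns {sorted(required)}")
    if (table["count"] <= 0).any():
        raise ValueError("non-positive cell count: log-linear model undefined")
    conditions = sorted(table["condition"].unique())
    if len(conditions) != 2:
        raise ValueError(f"need exactly 2 conditions, got {conditions}")
    if reference is None:
        reference = "DMSO" if "DMSO" in conditions else conditions[0]
    treated = [c for c in conditions if c != reference][0]
    y = np.log(table["count"].to_numpy(dtype=float))
    day = table["day"].to_numpy(dtype=float)
    tr = (table["condition"] == treated).to_numpy(dtype=float)

    X_red = sm.add_constant(day)
    X_full = np.column_stack([np.ones(len(y)), day, tr, day * tr])
    fit_red = sm.OLS(y, X_red).fit()
    fit_full = sm.OLS(y, X_full).fit()
    rss_red = float(fit_red.ssr)
    rss_full = float(fit_full.ssr)
    df_full = len(y) - X_full.shape[1]
    ddf = X_full.shape[1] - X_red.shape[1]
    if df_full <= 0:
        raise ValueError("not enough observations for the full model")
    # noiseless fixtures drive both RSS to rounding-level values; treat
    # differences below machine-scale of the response as exactly zero
    eps = max(1e-12, 1e-12 * float((y**2).sum()))
    if rss_red - rss_full <= eps:
        f, p = 0.0, 1.0
    elif rss_full <= eps:
        f, p = np.inf, 0.0
    else:
        f = ((rss_red - rss_full) / ddf) / (rss_full / df_full)
        p = float(stats.f.sf(f, ddf, df_full))
    b0, b1, b2, b3 = fit_full.params
    rates = {reference: float(b1), treated: float(b1 + b3)}
    doubling = {
        c: (np.log(2) / r if r > 0 else np.inf) for c, r in rates.items()
    }
    return GrowthFit(
        coefficients={
            "intercept": float(b0),
            "rate": float(b1),
            "treated": float(b2),
            "rate_x_treated": float(b3),
        },
        rss_full=rss_full,
        rss_reduced=rss_red,
        f_stat=float(f),
        pvalue=p,
        doubling_times=doubling,
        reference_condition=reference,
        treated_condition=treated,
    )
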