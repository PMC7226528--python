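"""Deregulation-group survival analysis.

Kaplan–Meier product-limit estimation with Greenwood variance and log-log
(complementary log) 95% confidence intervals, five-year survival extraction,
the unweighted log-rank test, and univariate Cox proportional-hazards
regression with Efron tie handling and a designated reference group — the
reference being the patients without deregulation, so hazard ratios read as
"up vs not" / "down vs not".

Estimation is delegated to lifelines (Efron ties and exponential-Greenwood
log-log intervals are its defaults); this module fixes the contracts:
five years = 60 months, groups below a minimum size or with zero events are
reported descriptively with NA hazard ratios, and monotone-likelihood
divergence is flagged rather than silently reported.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import multivariate_logrank_test
from scipy import stats

from .core_io import ClinicalTable, CohortError, SampleTable

FIVE_YEARS_MONTHS = 60.0
#: |log-hazard| beyond which a fit is flagged as monotone-likelihood divergence
DIVERGENCE_BOUND = 15.0


@dataclass
class KMCurve:
    """Kaplan–Meier curve: estimates, Greenwood variance and log-log CI."""

    timeline: np.ndarray
    survival: pd.Series              # S(t) on the event/censor timeline
    ci_lower: pd.Series
    ci_upper: pd.Series
    variance: pd.Series              # Greenwood variance of S(t)
    event_table: pd.DataFrame        # at-risk counts, observed events, censored
    n: int
    n_events: int

    @property
    def censor_times(self) -> np.ndarray:
        tab = self.event_table
        return tab.index[tab["censored"] > 0].to_numpy()

    @property
    def last_time(self) -> float:
        return float(self.timeline.max())


@dataclass
class LogRankResult:
    statistic: float
    df: int
    p_value: float


@dataclass
class CoxResult:
    """Per-level hazard ratios vs the reference group.

    ``table`` is indexed by group level with columns coef, hr, ci_lower,
    ci_upper, p, n, n_events and diverged; the reference level carries no row.
    """

    reference: str
    table: pd.DataFrame
    converged: bool


def _check_records(time: pd.Series, event: pd.Series) -> tuple[np.ndarray, np.ndarray]:
    t = np.asarray(time, dtype=float)
    e = np.asarray(event, dtype=int)
    if len(t) == 0:
        raise CohortError("no survival records")
    if (t < 0).any():
        raise CohortError("negative survival time")
    if not set(np.unique(e)).issubset({0, 1}):
        raise CohortError("event indicator must be 0/1")
    return t, e


def km_fit(time: pd.Series, event: pd.Series) -> KMCurve:
    """Product-limit estimate with Greenwood variance and 95% log-log CI."""
    t, e = _check_records(time, event)
    kmf = KaplanMeierFitter(alpha=0.05)
    kmf.fit(t, e)
    surv = kmf.survival_function_["KM_estimate"]
    ci = kmf.confidence_interval_
    tab = kmf.event_table
    # Greenwood: var(S) = S^2 * cumsum(d / (n (n - d))) over event times
    d = tab["observed"].to_numpy(dtype=float)
    n_at_risk = tab["at_risk"].to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(
            (d > 0) & (n_at_risk > d), d / (n_at_risk * (n_at_risk - d)), 0.0
        )
    var = pd.Series(
        surv.to_numpy() ** 2 * np.cumsum(terms), index=surv.index, name="greenwood"
    )
    return KMCurve(
        timeline=surv.index.to_numpy(dtype=float),
        survival=surv,
        ci_lower=ci.iloc[:, 0],
        ci_upper=ci.iloc[:, 1],
        variance=var,
        event_table=tab,
        n=int(len(t)),
        n_events=int(e.sum()),
    )


def survival_at(curve: KMCurve, t: float = FIVE_YEARS_MONTHS) -> dict:
    """Step-function S(t) with its CI; flags extrapolation past follow-up.

    The value is carried forward from the last step at or before ``t``; when
    ``t`` exceeds the last observed time the last step is returned with
    ``beyond_follow_up`` set.
    """
    est = float(curve.survival.asof(t))
    lo = float(curve.ci_lower.asof(t))
    hi = float(curve.ci_upper.asof(t))
    return {
        "t": float(t),
        "estimate": est,
        "ci_lower": lo,
        "ci_upper": hi,
        "beyond_follow_up": bool(t > curve.last_time),
    }


def logrank(records: pd.DataFrame, group_col: str = "group") -> LogRankResult:
    """Unweighted log-rank chi-square across >=2 non-empty groups."""
    t, e = _check_records(records["time"], records["event"])
    groups = records[group_col].astype(str).to_numpy()
    levels = pd.unique(groups)
    if len(levels) < 2:
        raise CohortError("log-rank needs >=2 non-empty groups")
    res = multivariate_logrank_test(t, groups, e)
    df = len(levels) - 1
    stat = float(res.test_statistic)
    return LogRankResult(
        statistic=stat,
        df=df,
        p_value=float(stats.chi2.sf(stat, df)),
    )


def cox_univariate(
    records: pd.DataFrame, reference: str, group_col: str = "group"
) -> CoxResult:
    """Univariate Cox PH fit of a categorical group, Efron tie handling.

    One model, dummy-coded against ``reference``; Wald 95% CIs. Levels whose
    coefficient exceeds the divergence bound (monotone likelihood, e.g. a
    zero-event group fitted anyway) are flagged ``diverged`` and their CI/p
    set to NA.
    """
    t, e = _check_records(records["time"], records["event"])
    groups = records[group_col].astype(str)
    levels = list(pd.unique(groups))
    if reference not in levels:
        raise CohortError(f"reference group {reference!r} not present")
    if len(levels) < 2:
        raise CohortError("Cox fit needs >=2 groups")
    if e.sum() == 0:
        raise CohortError("Cox fit needs >=1 event")
    others = [g for g in levels if g != reference]
    design = pd.DataFrame({"time": t, "event": e})
    for g in others:
        design[f"g_{g}"] = (groups == g).astype(float).to_numpy()
    converged = True
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph = CoxPHFitter()
            cph.fit(design, duration_col="time", event_col="event")
    except ConvergenceError:
        converged = False
        cph = None
    rows = []
    for g in others:
        mask = (groups == g).to_numpy()
        row = {
            "group": g,
            "n": int(mask.sum()),
            "n_events": int(e[mask].sum()),
        }
        if cph is None:
            row.update(
                coef=np.nan, hr=np.nan, ci_lower=np.nan, ci_upper=np.nan,
                p=np.nan, diverged=True,
            )
        else:
            coef = float(cph.params_[f"g_{g}"])
            se = float(cph.standard_errors_[f"g_{g}"])
            diverged = abs(coef) > DIVERGENCE_BOUND
            row["coef"] = coef
            row["hr"] = float(np.exp(coef))
            if diverged:
                row.update(ci_lower=np.nan, ci_upper=np.nan, p=np.nan, diverged=True)
            else:
                row["ci_lower"] = float(np.exp(coef - 1.959963984540054 * se))
                row["ci_upper"] = float(np.exp(coef + 1.959963984540054 * se))
                row["p"] = float(cph.summary.loc[f"g_{g}", "p"])
                row["diverged"] = False
        rows.append(row)
    table = pd.DataFrame(rows).set_index("group")
    return CoxResult(reference=reference, table=table, converged=converged)


@dataclass
class SurvivalReport:
    """Per-gene, per-stratum survival report for the deregulation groups."""

    gene: str
    stratum: str
    endpoint: str
    group_table: pd.DataFrame          # n, events, five-year % and CI per group
    curves: dict[str, KMCurve] = field(repr=False, default_factory=dict)
    logrank: Optional[LogRankResult] = None
    cox: Optional[CoxResult] = None
    small_groups: list[str] = field(default_factory=list)


def _endpoint_columns(clinical: ClinicalTable, endpoint: str) -> tuple[str, str]:
    endpoint = endpoint.lower()
    if endpoint == "os":
        return "os_months", "os_event"
    if endpoint == "dfs":
        if not clinical.has_dfs:
            raise CohortError("clinical table has no DFS columns")
        return "dfs_months", "dfs_event"
    raise CohortError(f"unknown endpoint {endpoint!r} (want OS or DFS)")


def survival_by_deregulation(
    calls: pd.DataFrame,
    clinical: ClinicalTable,
    samples: SampleTable,
    gene: str,
    stratum: str = "all",
    endpoint: str = "os",
    reference: str = "not",
    min_group_size: int = 3,
) -> SurvivalReport:
    """KM per deregulation group, five-year survival, log-rank, Cox vs ``not``.

    ``stratum`` is one of ``all``/``hpv_pos``/``hpv_neg``; patients with
    unknown HPV status only enter ``all``. Groups smaller than
    ``min_group_size`` (or with zero events) are excluded from the Cox fit
    and reported descriptively.
    """
    time_col, event_col = _endpoint_columns(clinical, endpoint)
    sub = calls[calls["gene_symbol"] == gene]
    if sub.empty:
        raise CohortError(f"no calls for gene {gene!r}")
    merged = sub.merge(clinical.table, on="patient_id", how="inner")
    hpv = samples.hpv_of_patients()
    merged = merged.merge(
        hpv.rename("hpv_status"), left_on="patient_id", right_index=True, how="left"
    )
    if stratum == "hpv_pos":
        merged = merged[merged["hpv_status"] == "positive"]
    elif stratum == "hpv_neg":
        merged = merged[merged["hpv_status"] == "negative"]
    elif stratum != "all":
        raise CohortError(f"unknown stratum {stratum!r}")
    merged = merged.dropna(subset=[time_col, event_col])
    if merged.empty:
        raise CohortError(f"no patients with follow-up in stratum {stratum!r}")
    records = pd.DataFrame(
        {
            "time": merged[time_col].astype(float).to_numpy(),
            "event": merged[event_col].astype(int).to_numpy(),
            "group": merged["call"].astype(str).to_numpy(),
        }
    )
    curves: dict[str, KMCurve] = {}
    rows = []
    for group, g in records.groupby("group"):
        curve = km_fit(g["time"], g["event"])
        curves[group] = curve
        at5 = survival_at(curve, FIVE_YEARS_MONTHS)
        rows.append(
            {
                "group": group,
                "n": curve.n,
                "n_events": curve.n_events,
                "five_year_pct": 100.0 * at5["estimate"],
                "five_year_ci_lower_pct": 100.0 * at5["ci_lower"],
                "five_year_ci_upper_pct": 100.0 * at5["ci_upper"],
                "beyond_follow_up": at5["beyond_follow_up"],
            }
        )
    group_table = pd.DataFrame(rows).set_index("group")
    report = SurvivalReport(
        gene=gene, stratum=stratum, endpoint=endpoint.lower(),
        group_table=group_table, curves=curves,
    )
    sizes = records["group"].value_counts()
    small = sorted(sizes[sizes < min_group_size].index)
    report.small_groups = small
    present = [g for g in sizes.index if g not in small]
    if len(present) >= 2:
        usable = records[records["group"].isin(present)]
        report.logrank = logrank(usable)
        # zero-event groups make the likelihood monotone; report NA instead
        eventful = [
            g for g in present
            if g == reference or usable.loc[usable["group"] == g, "event"].sum() > 0
        ]
        if reference in eventful and len(eventful) >= 2:
            fit_records = usable[usable["group"].isin(eventful)]
            if fit_records["event"].sum() > 0:
                report.cox = cox_univariate(fit_records, reference=reference)
    return report
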