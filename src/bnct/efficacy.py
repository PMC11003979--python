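"""Survival and locomotor efficacy statistics for preclinical cohorts.

Survival is analysed with the Kaplan–Meier product-limit estimator and the
two-group log-rank test; treatment benefit is summarised as the percent
increase in life span, %ILS = (MST_treated − MST_untreated) × 100 /
MST_untreated, on group median survival times (MST). Median confidence
intervals use the Brookmeyer–Crowley construction (inverting the pointwise
confidence band of S(t) at 0.5, on the log-transformed survival scale) —
the standard choice for small preclinical cohorts.

Hind-limb locomotion is scored on the Basso–Beattie–Bresnahan (BBB)
open-field scale, an integer 0 (no hind-limb movement) to 21 (normal gait).
The study endpoint is death or a BBB score of 5 or less; a euthanised or
dead animal scores 0 on every later assessment day. Group trajectories are
compared with a one-way MANOVA on the per-day score vectors (Wilks' Λ with
Rao's F approximation).

Kaplan–Meier, log-rank and median-CI computations are delegated to
``lifelines``; the MANOVA to ``statsmodels``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _lifelines_logrank
from lifelines.utils import median_survival_times

from ._rounding import round_half_up

__all__ = [
    "BBB_MAX",
    "BBB_ENDPOINT",
    "AnimalRecord",
    "KMCurve",
    "MedianSurvival",
    "LogrankResult",
    "SurvivalSummary",
    "BBBMatrix",
    "ManovaResult",
    "km_estimate",
    "median_survival",
    "logrank_test",
    "percent_ils",
    "survival_summary",
    "prepare_bbb_matrix",
    "bbb_group_compare",
    "format_p",
]

#: Top of the BBB locomotor scale (normal gait).
BBB_MAX = 21
#: Euthanasia threshold: a score at or below this ends the observation.
BBB_ENDPOINT = 5


@dataclass(frozen=True)
class AnimalRecord:
    """One animal: group, survival outcome and daily BBB scores.

    ``bbb_series`` maps assessment day (integer, day 0 = first assessment
    of the experiment) to the BBB score on that day; no scores may exist
    after ``survival_days``. ``event`` is 1 for death or endpoint
    euthanasia, 0 for censoring (e.g. survival to the end of observation).
    """

    subject_id: str
    group: str
    survival_days: float
    event: int
    bbb_series: dict[int, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.survival_days <= 0:
            raise ValueError(f"survival_days must be > 0, got {self.survival_days!r}")
        if self.event not in (0, 1):
            raise ValueError(f"event must be 0 or 1, got {self.event!r}")
        for day, score in self.bbb_series.items():
            if not (0 <= int(score) <= BBB_MAX):
                raise ValueError(
                    f"BBB score {score!r} on day {day} outside [0, {BBB_MAX}]"
                )
            if day > self.survival_days:
                raise ValueError(
                    f"BBB score on day {day} after survival_days={self.survival_days}"
                )


@dataclass(frozen=True)
class KMCurve:
    """Product-limit survival curve.

    ``event_times`` are the distinct times at which deaths occurred,
    ``at_risk`` the risk-set size just before each, ``survival`` the value
    of S(t) immediately after. S(0) = 1 by construction. The raw
    (durations, events) data ride along for downstream refits.
    """

    event_times: np.ndarray
    at_risk: np.ndarray
    survival: np.ndarray
    durations: np.ndarray
    events: np.ndarray

    def survival_at(self, t: float) -> float:
        """Step-function evaluation of S(t)."""
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


@dataclass(frozen=True)
class MedianSurvival:
    median: float
    ci95: tuple[float, float]
    defined: bool  # False when S(t) never reaches 0.5


@dataclass(frozen=True)
class LogrankResult:
    chi2: float
    p: float
    defined: bool = True

    @property
    def p_formatted(self) -> str:
        return format_p(self.p)


@dataclass(frozen=True)
class SurvivalSummary:
    """One row of a survival table: group size, mean ± SD, MST, CI, %ILS."""

    group: str
    n: int
    mean: float
    sd: float
    median: float
    ci95: tuple[float, float]
    pct_ils: float | None  # None for the reference group itself
    p_vs_reference: float | None


@dataclass(frozen=True)
class BBBMatrix:
    """Rectangular subjects × assessment-days score matrix."""

    groups: np.ndarray  # group label per row
    subjects: np.ndarray  # subject id per row
    days: np.ndarray  # common day grid (columns)
    scores: np.ndarray  # int matrix, 0..21


@dataclass(frozen=True)
class ManovaResult:
    wilks_lambda: float
    f_value: float
    df_num: float
    df_den: float
    p: float
    days_used: tuple[int, ...]
    thinned: bool  # True when days were dropped to keep the MANOVA full rank


def format_p(p: float, floor: float = 1e-4) -> str:
    """Render a p-value the way preclinical tables do: '< 0.0001' below floor."""
    if p != p:
        return "NA"
    if p < floor:
        return f"< {floor:g}"
    return f"{p:.4g}"


def _as_arrays(times, events) -> tuple[np.ndarray, np.ndarray]:
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    if t.size == 0:
        raise ValueError("no subjects")
    if t.shape != e.shape:
        raise ValueError(f"times and events differ in length: {t.shape} vs {e.shape}")
    if (t <= 0).any():
        raise ValueError("all survival times must be > 0")
    if not np.isin(e, (0, 1)).all():
        raise ValueError("events must be 0/1 indicators")
    return t, e


def km_estimate(times, events) -> KMCurve:
    """Kaplan–Meier product-limit estimate.

    Tied events at the same time drop S jointly; a subject censored at t
    leaves the risk set after t.
    """
    t, e = _as_arrays(times, events)
    kmf = KaplanMeierFitter()
    kmf.fit(t, e)
    table = kmf.event_table
    observed = table[table["observed"] > 0]
    sf = kmf.survival_function_["KM_estimate"]
    event_times = observed.index.to_numpy(dtype=float)
    return KMCurve(
        event_times=event_times,
        at_risk=observed["at_risk"].to_numpy(dtype=int),
        survival=sf.loc[observed.index].to_numpy(dtype=float),
        durations=t,
        events=e,
    )


def median_survival(curve: KMCurve, alpha: float = 0.05) -> MedianSurvival:
    """MST (smallest t with S(t) ≤ 0.5) with Brookmeyer–Crowley 95% CI.

    When the curve never reaches 0.5 (heavy censoring) the median is
    undefined: ``defined`` is False and ``median`` is +inf.
    """
    kmf = KaplanMeierFitter(alpha=alpha)
    kmf.fit(curve.durations, curve.events)
    median = float(kmf.median_survival_time_)
    ci = median_survival_times(kmf.confidence_interval_)
    lo = float(ci.iloc[0, 0])
    hi = float(ci.iloc[0, 1])
    defined = math.isfinite(median)
    if not defined:
        warnings.warn("survival curve never reaches 0.5; median undefined")
    return MedianSurvival(median=median, ci95=(lo, hi), defined=defined)


def _records_to_arrays(records) -> tuple[np.ndarray, np.ndarray]:
    return (
        np.array([r.survival_days for r in records], dtype=float),
        np.array([r.event for r in records], dtype=int),
    )


def logrank_test(group_a, group_b) -> LogrankResult:
    """Two-group log-rank test (1 df chi-square on observed − expected).

    Accepts sequences of :class:`AnimalRecord` or ``(times, events)``
    pairs of arrays. With no events in either group the statistic is
    undefined and flagged.
    """
    if isinstance(group_a, tuple):
        ta, ea = _as_arrays(*group_a)
        tb, eb = _as_arrays(*group_b)
    else:
        if len(group_a) == 0 or len(group_b) == 0:
            raise ValueError("both groups must be nonempty")
        ta, ea = _records_to_arrays(group_a)
        tb, eb = _records_to_arrays(group_b)
    if ea.sum() + eb.sum() == 0:
        warnings.warn("no events in either group; log-rank undefined")
        return LogrankResult(chi2=float("nan"), p=float("nan"), defined=False)
    res = _lifelines_logrank(ta, tb, event_observed_A=ea, event_observed_B=eb)
    return LogrankResult(chi2=float(res.test_statistic), p=float(res.p_value))


def percent_ils(
    mst_treated: float, mst_untreated: float, ndigits: int | None = 1
) -> float:
    """Percent increase in life span of a treated group over the reference.

    ``(MST_treated − MST_untreated) × 100 / MST_untreated``, rounded
    half-up to ``ndigits`` decimals for reporting (``ndigits=None`` keeps
    full precision).
    """
    if mst_untreated <= 0:
        raise ValueError(f"reference MST must be > 0, got {mst_untreated!r}")
    value = (mst_treated - mst_untreated) * 100.0 / mst_untreated
    return value if ndigits is None else round_half_up(value, ndigits)


def survival_summary(
    records: list[AnimalRecord], reference_group: str
) -> list[SurvivalSummary]:
    """Per-group survival table with %ILS and log-rank p versus a reference.

    Groups are ordered with the reference first, then alphabetically.
    """
    by_group: dict[str, list[AnimalRecord]] = {}
    for r in records:
        by_group.setdefault(r.group, []).append(r)
    if reference_group not in by_group:
        raise ValueError(
            f"reference group {reference_group!r} absent; have {sorted(by_group)}"
        )
    ref = by_group[reference_group]
    ref_median = median_survival(km_estimate(*_records_to_arrays(ref)))
    order = [reference_group] + sorted(g for g in by_group if g != reference_group)
    out = []
    for group in order:
        recs = by_group[group]
        times, events = _records_to_arrays(recs)
        med = median_survival(km_estimate(times, events))
        if group == reference_group:
            ils, p = None, None
        else:
            ils = percent_ils(med.median, ref_median.median) if med.defined else None
            lr = logrank_test(recs, ref)
            p = lr.p if lr.defined else None
        out.append(
            SurvivalSummary(
                group=group,
                n=len(recs),
                mean=float(times.mean()),
                sd=float(times.std(ddof=1)) if len(recs) > 1 else 0.0,
                median=med.median,
                ci95=med.ci95,
                pct_ils=ils,
                p_vs_reference=p,
            )
        )
    return out


def prepare_bbb_matrix(
    records: list[AnimalRecord],
    start_day: int,
    end_day: int | None = None,
    missing: str = "error",
) -> BBBMatrix:
    """Align BBB series on a common day grid, scoring dead animals 0.

    The grid runs from ``start_day`` to ``end_day`` (default: the last
    assessment or survival day over all records). Days after an animal's
    death (event = 1) score 0 per the study rule; days before death must
    be present in the series or, with ``missing="carry_forward"``, are
    filled with the last earlier score.
    """
    if missing not in ("error", "carry_forward"):
        raise ValueError(f"missing must be 'error' or 'carry_forward', got {missing!r}")
    if end_day is None:
        last = 0
        for r in records:
            candidates = [int(r.survival_days)]
            if r.bbb_series:
                candidates.append(max(r.bbb_series))
            last = max(last, *candidates)
        end_day = last
    days = np.arange(start_day, end_day + 1)
    if days.size == 0 or not records:
        return BBBMatrix(
            groups=np.array([r.group for r in records]),
            subjects=np.array([r.subject_id for r in records]),
            days=days,
            scores=np.zeros((len(records), 0), dtype=int),
        )
    scores = np.zeros((len(records), days.size), dtype=int)
    for i, rec in enumerate(records):
        for j, day in enumerate(days):
            if rec.event == 1 and day > rec.survival_days:
                scores[i, j] = 0
            elif int(day) in rec.bbb_series:
                scores[i, j] = int(rec.bbb_series[int(day)])
            elif missing == "carry_forward":
                earlier = [d for d in rec.bbb_series if d < day]
                if not earlier:
                    raise ValueError(
                        f"{rec.subject_id}: no score on or before day {day}"
                    )
                scores[i, j] = int(rec.bbb_series[max(earlier)])
            else:
                raise ValueError(
                    f"{rec.subject_id}: missing BBB assessment on day {day}"
                )
    return BBBMatrix(
        groups=np.array([r.group for r in records]),
        subjects=np.array([r.subject_id for r in records]),
        days=days,
        scores=scores,
    )


def bbb_group_compare(matrix: BBBMatrix, max_days: int | None = None) -> ManovaResult:
    """One-way MANOVA across groups on the per-day BBB score vectors.

    Days with zero within-group variance carry no error information and
    are dropped; if more response days remain than the within-group error
    degrees of freedom support, the grid is thinned evenly (flagged) so
    the error covariance stays full rank. Reports Wilks' Λ with Rao's F
    approximation.
    """
    from statsmodels.multivariate.manova import MANOVA

    labels = np.asarray(matrix.groups)
    unique_groups = np.unique(labels)
    if unique_groups.size < 2:
        raise ValueError("need at least 2 groups")
    for g in unique_groups:
        if (labels == g).sum() < 2:
            raise ValueError(f"group {g!r} has fewer than 2 subjects")
    scores = np.asarray(matrix.scores, dtype=float)
    n, p = scores.shape
    if p == 0:
        raise ValueError("empty day grid")

    # within-group variance per day
    within = np.zeros(p)
    for g in unique_groups:
        sub = scores[labels == g]
        within += ((sub - sub.mean(axis=0)) ** 2).sum(axis=0)
    keep = within > 0
    thinned = bool((~keep).any())
    if not keep.any():
        raise ValueError("no assessment day has within-group variance")
    idx = np.flatnonzero(keep)

    err_df = n - unique_groups.size
    budget = err_df if max_days is None else min(err_df, max_days)

    def _cross_products(cols: np.ndarray):
        sub = scores[:, cols]
        grand = sub.mean(axis=0)
        h = np.zeros((cols.size, cols.size))
        e = np.zeros((cols.size, cols.size))
        for g in unique_groups:
            block = sub[labels == g]
            diff = block.mean(axis=0) - grand
            h += block.shape[0] * np.outer(diff, diff)
            centred = block - block.mean(axis=0)
            e += centred.T @ centred
        return sub, h, e

    # shrink the day grid until the error matrix is invertible: highly
    # collinear trajectories can make E rank-deficient well below err_df
    chosen = None
    for b in range(min(budget, idx.size), 0, -1):
        sel = np.unique(np.linspace(0, idx.size - 1, b).round().astype(int))
        candidate = idx[sel]
        sub, h_mat, e_mat = _cross_products(candidate)
        if candidate.size == 1 or np.linalg.cond(e_mat) < 1e10:
            chosen = candidate
            break
    idx = chosen
    if idx.size < np.flatnonzero(keep).size:
        thinned = True
        warnings.warn(
            f"BBB day grid thinned to {idx.size} days to keep the error "
            "covariance full rank"
        )

    days_used = tuple(int(matrix.days[i]) for i in idx)
    n_resp = sub.shape[1]
    q = unique_groups.size - 1  # hypothesis df

    def _rao(lmbda: float) -> ManovaResult:
        # Rao's F approximation to Wilks' lambda
        p_, q_ = n_resp, q
        if p_**2 + q_**2 - 5 > 0:
            t = math.sqrt((p_**2 * q_**2 - 4) / (p_**2 + q_**2 - 5))
        else:
            t = 1.0
        df1 = p_ * q_
        df2 = (err_df - (p_ - q_ + 1) / 2) * t - (p_ * q_ - 2) / 2
        root = lmbda ** (1 / t)
        f_val = (1 - root) / root * df2 / df1 if root > 0 else float("inf")
        from scipy import stats as _st

        p_val = float(_st.f.sf(f_val, df1, df2)) if math.isfinite(f_val) else 0.0
        return ManovaResult(
            wilks_lambda=lmbda,
            f_value=f_val,
            df_num=float(df1),
            df_den=float(df2),
            p=p_val,
            days_used=days_used,
            thinned=thinned,
        )

    if np.trace(h_mat) <= 1e-12 * max(np.trace(e_mat), 1.0):
        # identical group means: Wilks' lambda is exactly 1 (statsmodels
        # cannot form the test from an empty eigenvalue set)
        return _rao(1.0)
    if n_resp == 1:
        # single assessment day: Wilks reduces to the one-way ANOVA F
        return _rao(float(e_mat[0, 0] / (e_mat[0, 0] + h_mat[0, 0])))

    cols = [f"d{d}" for d in days_used]
    df = pd.DataFrame(sub, columns=cols)
    df["group"] = labels
    formula = " + ".join(cols) + " ~ C(group)"
    mv = MANOVA.from_formula(formula, data=df)
    stat = mv.mv_test().results["C(group)"]["stat"]
    row = stat.loc["Wilks' lambda"]
    return ManovaResult(
        wilks_lambda=float(row["Value"]),
        f_value=float(row["F Value"]),
        df_num=float(row["Num DF"]),
        df_den=float(row["Den DF"]),
        p=float(row["Pr > F"]),
        days_used=days_used,
        thinned=thinned,
    )
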