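"""Trial outcome measures and cross-trial summaries.

The primary outcomes mirror a UK two-week-wait (TWW) service audit:
the percentage of referred patients first seen within 14 days, the mean
time from GP presentation to first clinic attendance in weekdays, the
number of overspill appointments generated, and completion counts by
cancer status — each summarised over replications as a mean with a 95%
t-interval.

Two clock conventions matter and are deliberate: both the TWW target and
"time to clinic" are measured from the patient's initial GP
presentation, so a patient whose referral is delayed by a six-week
return always misses the 14-day target even if seen promptly after
returning.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .config import MIN_PER_DAY, MIN_PER_WEEK, ConfigError
from .engine import TrialLog

TWW_TARGET_DAYS = 14


def _day(t: float) -> int:
    return int(t // MIN_PER_DAY)


def time_to_clinic_weekdays(start_time: float, first_clinic_time: float) -> int:
    """Weekdays (Mon–Fri) elapsed between the two calendar dates.

    Counts the weekdays strictly after the start date up to and including
    the clinic date: same day → 0; Friday → Monday → 1; any 14-calendar-day
    interval → 10.  Simulation time zero is a Monday.
    """
    if first_clinic_time < start_time:
        raise ConfigError("first clinic attendance precedes the start time")
    d0, d1 = _day(start_time), _day(first_clinic_time)
    full_weeks, rem = divmod(d1 - d0, 7)
    count = 5 * full_weeks
    for d in range(d0 + 7 * full_weeks + 1, d1 + 1):
        if d % 7 < 5:
            count += 1
    return count


def tww_met(start_time: float, first_clinic_time: float) -> bool:
    """True iff the first clinic attendance falls within 14 calendar days
    of the start date (the initial GP presentation)."""
    if first_clinic_time < start_time:
        raise ConfigError("first clinic attendance precedes the start time")
    return _day(first_clinic_time) - _day(start_time) <= TWW_TARGET_DAYS


@dataclass
class TrialResult:
    """Per-replication outcome metrics over the collection window."""

    completing_total: int = 0
    completing_cancer: int = 0
    completing_noncancer: int = 0
    time_to_clinic_cancer: float = np.nan
    time_to_clinic_noncancer: float = np.nan
    tww_pct_cancer: float = np.nan
    tww_pct_noncancer: float = np.nan
    tww_pct_overall: float = np.nan
    overspill_appointments: int = 0
    referred_pct_overall: float = np.nan
    referred_pct_cancer: float = np.nan
    referred_pct_noncancer: float = np.nan
    delayed_pct_cancer: float = np.nan          # among cancer completions
    delayed_pct_noncancer_referred: float = np.nan  # among referred non-cancer

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


METRICS = [f.name for f in dataclasses.fields(TrialResult)]


def compute_trial_metrics(log: TrialLog,
                          collection_window: tuple[float, float] | None = None,
                          ) -> TrialResult:
    """Reduce one trial's log to its outcome metrics.

    Only exits (and overspill routings) inside the collection window
    count; "completing the model" means exiting by any route — full
    diagnostics, discharge after assessment, or never being referred.
    """
    cfg = log.config
    if collection_window is None:
        w0 = cfg.warmup_weeks * MIN_PER_WEEK
        w1 = cfg.horizon_weeks * MIN_PER_WEEK
    else:
        w0, w1 = collection_window
        if w0 < 0 or w1 > log.horizon_minutes or w0 >= w1:
            raise ConfigError("collection window outside the simulated span")

    completed = [p for p in log.patients
                 if p.completion_time is not None
                 and p.exit_type != "in_system"
                 and w0 <= p.completion_time < w1]
    res = TrialResult()
    res.completing_total = len(completed)
    res.completing_cancer = sum(p.has_cancer for p in completed)
    res.completing_noncancer = res.completing_total - res.completing_cancer
    res.overspill_appointments = sum(w0 <= t < w1 for t in log.overspill_times)

    referred = [p for p in completed if p.referral_kind != "none"]
    if res.completing_total:
        res.referred_pct_overall = 100.0 * len(referred) / res.completing_total
    if res.completing_cancer:
        res.referred_pct_cancer = 100.0 * sum(
            p.referral_kind != "none" for p in completed if p.has_cancer
        ) / res.completing_cancer
        res.delayed_pct_cancer = 100.0 * sum(
            p.referral_kind == "delayed" for p in completed if p.has_cancer
        ) / res.completing_cancer
    nc_ref = [p for p in referred if not p.has_cancer]
    if res.completing_noncancer:
        res.referred_pct_noncancer = 100.0 * len(nc_ref) / res.completing_noncancer
    if nc_ref:
        res.delayed_pct_noncancer_referred = 100.0 * sum(
            p.referral_kind == "delayed" for p in nc_ref) / len(nc_ref)

    # waiting-time outcomes: referred patients who attended the clinic,
    # both clocks anchored at the initial GP presentation
    for stratum, cancer in (("cancer", True), ("noncancer", False)):
        seen = [p for p in referred
                if p.has_cancer == cancer and p.first_clinic_time is not None]
        if not seen:
            continue
        ttc = [time_to_clinic_weekdays(p.gp_arrival_time, p.first_clinic_time)
               for p in seen]
        met = [tww_met(p.gp_arrival_time, p.first_clinic_time) for p in seen]
        setattr(res, f"time_to_clinic_{stratum}", float(np.mean(ttc)))
        setattr(res, f"tww_pct_{stratum}", 100.0 * float(np.mean(met)))
    seen_all = [p for p in referred if p.first_clinic_time is not None]
    if seen_all:
        res.tww_pct_overall = 100.0 * float(np.mean(
            [tww_met(p.gp_arrival_time, p.first_clinic_time) for p in seen_all]))
    return res


def summarize_trials(results: list[TrialResult], ci_method: str = "t",
                     ) -> pd.DataFrame:
    """Mean and two-sided 95% interval per metric across replications.

    ``ci_method`` is ``"t"`` (default) or ``"normal"``.  Metrics that are
    NaN in some trials (e.g. a stratum with no completions) use the
    trials in which they are defined.
    """
    if len(results) < 2:
        raise ConfigError("need at least 2 trials to summarise")
    if ci_method not in ("t", "normal"):
        raise ConfigError(f"unknown ci_method {ci_method!r}")
    rows = []
    for metric in METRICS:
        x = np.array([getattr(r, metric) for r in results], dtype=float)
        x = x[~np.isnan(x)]
        if len(x) == 0:
            rows.append((metric, np.nan, np.nan, np.nan, 0))
            continue
        mean = float(np.mean(x))
        if len(x) == 1:
            rows.append((metric, mean, np.nan, np.nan, 1))
            continue
        se = float(np.std(x, ddof=1)) / np.sqrt(len(x))
        crit = (stats.t.ppf(0.975, len(x) - 1) if ci_method == "t"
                else stats.norm.ppf(0.975))
        rows.append((metric, mean, mean - crit * se, mean + crit * se, len(x)))
    return pd.DataFrame(rows, columns=["metric", "mean", "ci_low", "ci_high",
                                       "n_trials"]).set_index("metric")


def trials_frame(results: list[TrialResult], strategy: str = "") -> pd.DataFrame:
    """Tidy per-trial frame: one row per (trial, metric)."""
    records = []
    for i, r in enumerate(results):
        for metric, value in r.as_dict().items():
            records.append({"trial": i, "strategy": strategy,
                            "metric": metric, "value": value})
    return pd.DataFrame.from_records(records)
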