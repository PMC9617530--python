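"""Synthetic patient population: the simulator's sole data source.

Generates the stream of symptomatic GP presentations with cancer status,
the post-assessment diagnostic pathway each patient would follow in
clinic, and per-activity service times.  Sampling is vectorised with
numpy so a full 64-week trial's population (~13,000 patients) is drawn
up front in milliseconds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import (
    ACTIVITIES,
    BIOPSY,
    INITIAL_ASSESSMENT,
    MAMMOGRAM,
    MIN_PER_WEEK,
    SEQUENCE_LABELS,
    ULTRASOUND,
    WEEKS_PER_YEAR,
    ArrivalConfig,
    ConfigError,
    DurationModel,
    PathwayTable,
)


@dataclass
class Patient:
    """One simulated individual and their full pathway record.

    Times are simulation minutes; ``None`` marks events that never
    happened (e.g. ``referral_time`` for a never-referred patient).
    """

    id: int
    gp_arrival_time: float
    has_cancer: bool = False
    risk_result: str = "not_tested"        # low | high | not_tested
    referral_kind: str = "none"            # immediate | delayed | none
    referral_time: float | None = None
    first_clinic_time: float | None = None
    activity_sequence: tuple[str, ...] = ()
    discharged_after_assessment: bool = False
    completion_time: float | None = None
    overspill_events: int = 0
    # engine state: index of the next activity still to be done
    next_activity: int = field(default=0, repr=False)
    durations: dict = field(default_factory=dict, repr=False)
    exit_type: str | None = field(default=None, repr=False)


def generate_arrivals(horizon_weeks: int,
                      arrivals: ArrivalConfig,
                      rng: np.random.Generator) -> np.ndarray:
    """Sample GP presentation times (minutes) over ``horizon_weeks``.

    Default mode is a homogeneous Poisson process on continuous calendar
    time whose expected count over 52 weeks is ``annual_volume ×
    demand_multiplier``.  Windowed mode confines exponential
    inter-arrivals (the literal audit convention) to the first
    ``window_minutes_per_week`` minutes of each week; weekly totals agree
    in expectation when the window matches ``annual_volume ×
    interarrival_mean / 52``.
    """
    if horizon_weeks <= 0:
        raise ConfigError(f"horizon_weeks must be positive, got {horizon_weeks}")
    arrivals.validate()
    if arrivals.demand_multiplier == 0:
        return np.empty(0)

    if arrivals.mode == "calendar":
        rate = arrivals.annual_volume * arrivals.demand_multiplier / (
            WEEKS_PER_YEAR * MIN_PER_WEEK)  # per minute
        horizon = horizon_weeks * MIN_PER_WEEK
        n = rng.poisson(rate * horizon)
        times = np.sort(rng.uniform(0.0, horizon, size=n))
    else:  # windowed
        mean = arrivals.interarrival_mean_minutes / arrivals.demand_multiplier
        window = arrivals.window_minutes_per_week
        per_week = []
        for week in range(horizon_weeks):
            # draw enough exponential gaps to overrun the window, then trim
            n_hint = max(8, int(window / mean * 1.5) + 8)
            gaps = rng.exponential(mean, size=n_hint)
            t = np.cumsum(gaps)
            while t[-1] < window:
                more = rng.exponential(mean, size=n_hint)
                t = np.concatenate([t, t[-1] + np.cumsum(more)])
            t = t[t < window]
            per_week.append(week * MIN_PER_WEEK + t)
        times = np.concatenate(per_week) if per_week else np.empty(0)
    # Poisson-process times are almost surely distinct; enforce it anyway so
    # downstream FIFO ordering has no ties.
    return np.unique(times)


def assign_cancer(n: int, prevalence: float,
                  rng: np.random.Generator) -> np.ndarray:
    """Bernoulli(prevalence) cancer status, independent across patients."""
    if not 0.0 <= prevalence <= 1.0:
        raise ConfigError(f"prevalence must lie in [0, 1], got {prevalence}")
    return rng.random(n) < prevalence


_LABELS = tuple(SEQUENCE_LABELS)


def sample_clinic_pathway(has_cancer: np.ndarray,
                          table: PathwayTable,
                          rng: np.random.Generator,
                          ) -> tuple[list[tuple[str, ...]], np.ndarray]:
    """Draw each patient's ordered clinic activity sequence.

    Every sequence starts with initial assessment.  25% of non-cancer
    patients (by default) are discharged after it; the rest draw one of
    the nine audit sequences for their stratum.  Sequences containing
    both imaging modalities are order-resolved mammogram-first with
    probability 0.60.  Cancer patients are never discharged and always
    end with exactly one biopsy (appended when the drawn label lacks it).

    Returns (sequences, discharged) aligned with ``has_cancer``.
    """
    table.validate()
    n = len(has_cancer)
    p_nc = np.array([table.noncancer[lbl] for lbl in _LABELS])
    p_c = np.array([table.cancer[lbl] for lbl in _LABELS])
    label_idx = np.where(
        has_cancer,
        rng.choice(len(_LABELS), size=n, p=p_c / p_c.sum()),
        rng.choice(len(_LABELS), size=n, p=p_nc / p_nc.sum()),
    )
    discharged = (~has_cancer) & (
        rng.random(n) < table.discharge_after_assessment_probability_noncancer)
    mammo_first = rng.random(n) < table.mammogram_first_probability

    sequences: list[tuple[str, ...]] = []
    for i in range(n):
        if discharged[i]:
            sequences.append((INITIAL_ASSESSMENT,))
            continue
        acts = list(SEQUENCE_LABELS[_LABELS[label_idx[i]]])
        if MAMMOGRAM in acts and ULTRASOUND in acts:
            order = [MAMMOGRAM, ULTRASOUND] if mammo_first[i] else [ULTRASOUND, MAMMOGRAM]
            acts = order + [a for a in acts if a == BIOPSY]
        if has_cancer[i] and BIOPSY not in acts:
            acts.append(BIOPSY)
        sequences.append((INITIAL_ASSESSMENT, *acts))
    return sequences, discharged


def sample_duration(activity: str, model: DurationModel,
                    rng: np.random.Generator, size: int | None = None):
    """Sample service time(s) for one activity, in minutes.

    Triangular (symmetric, median-preserving) around the central value for
    assessment and imaging; the stated two-point mixture for biopsy.
    """
    if activity == BIOPSY:
        lo, hi = model.biopsy_options
        u = rng.random(size)
        return np.where(u < model.biopsy_mix, lo, hi) if size is not None else (
            lo if u < model.biopsy_mix else hi)
    if activity not in model.central:
        raise ConfigError(f"unknown activity {activity!r}")
    mode = model.central[activity]
    w = model.relative_half_width * mode
    if w == 0.0:
        return np.full(size, mode) if size is not None else mode
    return rng.triangular(mode - w, mode, mode + w, size=size)


def sample_population(horizon_weeks: int,
                      arrivals: ArrivalConfig,
                      prevalence: float,
                      table: PathwayTable,
                      durations: DurationModel,
                      rng: np.random.Generator) -> list[Patient]:
    """Draw a complete patient population for one trial.

    Per-activity durations (and imaging prep times) are pre-sampled per
    patient: each activity is performed at most once, even across
    overspill return visits, so one draw per patient-activity suffices.
    """
    times = generate_arrivals(horizon_weeks, arrivals, rng)
    n = len(times)
    cancer = assign_cancer(n, prevalence, rng)
    sequences, discharged = sample_clinic_pathway(cancer, table, rng)
    dur = {a: np.asarray(sample_duration(a, durations, rng, size=n), dtype=float)
           for a in ACTIVITIES}
    prep = np.full(n, durations.prep_minutes, dtype=float)

    patients = []
    for i in range(n):
        d = {a: dur[a][i] for a in sequences[i]}
        d["prep"] = prep[i]
        patients.append(Patient(
            id=i,
            gp_arrival_time=float(times[i]),
            has_cancer=bool(cancer[i]),
            activity_sequence=sequences[i],
            discharged_after_assessment=bool(discharged[i]),
            durations=d,
        ))
    return patients
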