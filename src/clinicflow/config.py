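"""Configuration objects for the two-week-wait breast clinic simulator.

Everything the simulator consumes is configuration: there is no external
data set.  The defaults encode a medium-to-large UK symptomatic breast
clinic — 10,542 two-week-wait (TWW) referrals a year, 4.76% cancer
prevalence, a weekly schedule of seven full half-day clinics plus one
low-capacity add-on clinic, queue-responsive booking, and a staff roster
with role-specific eligibility for each diagnostic activity.

All times inside the simulator are minutes on a continuous 52-week
calendar; time zero is a Monday at 00:00.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import yaml

MIN_PER_DAY = 1440
MIN_PER_WEEK = 7 * MIN_PER_DAY
WEEKS_PER_YEAR = 52

INITIAL_ASSESSMENT = "initial_assessment"
MAMMOGRAM = "mammogram"
ULTRASOUND = "ultrasound"
BIOPSY = "biopsy"
ACTIVITIES = (INITIAL_ASSESSMENT, MAMMOGRAM, ULTRASOUND, BIOPSY)

#: Nine diagnostic sequences a patient may follow after initial assessment.
#: Labels that contain both imaging modalities are order-resolved at sampling
#: time (mammogram first with probability ``mammogram_first_probability``),
#: so e.g. "mammogram_ultrasound" and "ultrasound_mammogram" differ only in
#: their audit-derived frequency, not in the order they imply.
SEQUENCE_LABELS: dict[str, tuple[str, ...]] = {
    "mammogram": (MAMMOGRAM,),
    "mammogram_ultrasound": (MAMMOGRAM, ULTRASOUND),
    "mammogram_ultrasound_biopsy": (MAMMOGRAM, ULTRASOUND, BIOPSY),
    "ultrasound": (ULTRASOUND,),
    "ultrasound_mammogram": (ULTRASOUND, MAMMOGRAM),
    "ultrasound_mammogram_biopsy": (ULTRASOUND, MAMMOGRAM, BIOPSY),
    "ultrasound_biopsy": (ULTRASOUND, BIOPSY),
    "biopsy": (BIOPSY,),
    "mammogram_biopsy": (MAMMOGRAM, BIOPSY),
}

ROLES = (
    "consultant",
    "nurse_practitioner",
    "physician_associate",
    "band7_sonographer",
    "band6_sonographer",
    "band6_non_sonographer",
    "grade2_assistant",
)

#: Staff eligible for each activity, in seize order.  The ordering conserves
#: the scarcest staff: generalists are tried before sonographers, and
#: assistants before band-6 staff for patient preparation.
ELIGIBLE_STAFF: dict[str, tuple[str, ...]] = {
    INITIAL_ASSESSMENT: ("physician_associate", "nurse_practitioner", "consultant"),
    MAMMOGRAM: ("band6_non_sonographer", "band6_sonographer", "band7_sonographer"),
    ULTRASOUND: ("band6_sonographer", "band7_sonographer"),
    "prep": ("grade2_assistant", "band6_non_sonographer", "band6_sonographer"),
    # biopsy seizes a consultant AND one assistant drawn from this order
    "biopsy_assistant": ("grade2_assistant", "band6_non_sonographer", "band6_sonographer"),
}

DEFAULT_ROOMS = {INITIAL_ASSESSMENT: 4, MAMMOGRAM: 3, ULTRASOUND: 4, BIOPSY: 4}


class ConfigError(ValueError):
    """Raised when a configuration fails validation."""


def _check(cond: bool, msg: str) -> None:
    if not cond:
        raise ConfigError(msg)


# ---------------------------------------------------------------------------
# synthetic-population configuration
# ---------------------------------------------------------------------------

@dataclass
class PathwayTable:
    """Audit-derived frequencies of the nine post-assessment diagnostic
    sequences, one column per cancer stratum, plus the two global rules:
    60% of mixed-imaging pathways run mammogram first, and 25% of
    non-cancer patients are discharged straight after initial assessment.
    """

    noncancer: dict[str, float] = field(default_factory=lambda: {
        "mammogram": 0.012766,
        "mammogram_ultrasound": 0.272533,
        "mammogram_ultrasound_biopsy": 0.035168,
        "ultrasound": 0.394921,
        "ultrasound_mammogram": 0.181688,
        "ultrasound_mammogram_biopsy": 0.023445,
        "ultrasound_biopsy": 0.060947,
        "biopsy": 0.017845,
        "mammogram_biopsy": 0.000686,
    })
    cancer: dict[str, float] = field(default_factory=lambda: {
        "mammogram": 0.005525,
        "mammogram_ultrasound": 0.038122,
        "mammogram_ultrasound_biopsy": 0.510497,
        "ultrasound": 0.013812,
        "ultrasound_mammogram": 0.025414,
        "ultrasound_mammogram_biopsy": 0.340331,
        "ultrasound_biopsy": 0.035912,
        "biopsy": 0.027624,
        "mammogram_biopsy": 0.002762,
    })
    mammogram_first_probability: float = 0.60
    discharge_after_assessment_probability_noncancer: float = 0.25

    def validate(self) -> "PathwayTable":
        for name, stratum in (("noncancer", self.noncancer), ("cancer", self.cancer)):
            _check(set(stratum) == set(SEQUENCE_LABELS),
                   f"{name} stratum must give all nine sequence labels")
            _check(all(0.0 <= p <= 1.0 for p in stratum.values()),
                   f"{name} probabilities must lie in [0, 1]")
            total = sum(stratum.values())
            # printed 6-d.p. tables can be off by exactly 1e-6; admit that
            _check(abs(total - 1.0) <= 2e-6,
                   f"{name} probabilities sum to {total:.8f}, not 1")
        _check(0.0 <= self.mammogram_first_probability <= 1.0,
               "mammogram_first_probability must lie in [0, 1]")
        _check(0.0 <= self.discharge_after_assessment_probability_noncancer <= 1.0,
               "discharge probability must lie in [0, 1]")
        return self


@dataclass
class DurationModel:
    """Activity service times, in minutes.

    Initial assessment, mammogram and ultrasound follow a symmetric
    triangular distribution around the stated central value (mode = median
    = the clinic's typical time) with a relative half-width expressing
    "some variation"; the biopsy is a two-point 30/45-minute mixture with
    equal weights, its preparation already folded in.  Imaging activities
    carry a separate patient-preparation step.
    """

    central: dict[str, float] = field(default_factory=lambda: {
        INITIAL_ASSESSMENT: 10.0, MAMMOGRAM: 20.0, ULTRASOUND: 20.0,
    })
    biopsy_options: tuple[float, float] = (30.0, 45.0)
    biopsy_mix: float = 0.5          # probability of the first option
    relative_half_width: float = 0.25  # 0 -> degenerate (exact) durations
    prep_minutes: float = 5.0         # imaging prep; fixed length

    def validate(self) -> "DurationModel":
        _check(set(self.central) == {INITIAL_ASSESSMENT, MAMMOGRAM, ULTRASOUND},
               "central durations must cover initial_assessment, mammogram, ultrasound")
        _check(all(v > 0 for v in self.central.values()), "durations must be positive")
        _check(all(v > 0 for v in self.biopsy_options), "biopsy options must be positive")
        _check(0.0 <= self.biopsy_mix <= 1.0, "biopsy_mix must lie in [0, 1]")
        _check(0.0 <= self.relative_half_width < 1.0,
               "relative_half_width must lie in [0, 1)")
        _check(self.prep_minutes >= 0, "prep_minutes must be non-negative")
        return self


@dataclass
class ArrivalConfig:
    """GP presentation process.

    The governing parameter is the annual volume over a 52-week calendar:
    by default presentations form a homogeneous Poisson process on
    continuous calendar time with expected total ``annual_volume ×
    demand_multiplier``.  ``mode="windowed"`` instead reproduces the
    literal audit convention — exponential inter-arrival times (mean
    ``interarrival_mean_minutes``) confined to a weekly arrival window —
    for fidelity experiments; both conventions share the same weekly
    expectation when the window is sized consistently.
    """

    annual_volume: float = 10_542.0
    demand_multiplier: float = 1.0
    mode: str = "calendar"  # "calendar" | "windowed"
    interarrival_mean_minutes: float = 16.2778
    window_minutes_per_week: float = 10_542.0 * 16.2778 / 52.0  # ≈ 55 h/week

    def validate(self) -> "ArrivalConfig":
        _check(self.annual_volume > 0, "annual_volume must be positive")
        _check(self.demand_multiplier >= 0, "demand_multiplier must be non-negative")
        _check(self.mode in ("calendar", "windowed"), f"unknown arrival mode {self.mode!r}")
        _check(self.interarrival_mean_minutes > 0, "interarrival mean must be positive")
        _check(0 < self.window_minutes_per_week <= MIN_PER_WEEK,
               "arrival window must fit in a week")
        return self


# ---------------------------------------------------------------------------
# triage configuration
# ---------------------------------------------------------------------------

STANDARD_CARE = "standard_care"
PINPOINT = "pinpoint"


@dataclass
class TriageConfig:
    """Primary-care stage.

    Standard care refers every presenting patient immediately.  Under the
    risk-test arm a high-risk result triggers immediate referral; GPs
    overrule a fraction of low-risk results (immediate referral anyway);
    remaining low-risk patients either return with persisting symptoms
    after ``delay_weeks`` (a delayed referral) or never enter secondary
    care.
    """

    arm: str = STANDARD_CARE
    sensitivity: float = 0.98
    specificity: float = 0.20
    gp_override_probability: float = 0.0
    delayed_return_probability_cancer: float = 1.0
    delayed_return_probability_noncancer: float = 0.0
    delay_weeks: float = 6.0
    turnaround_minutes: float = 0.0  # test result assumed back at referral time

    def validate(self) -> "TriageConfig":
        _check(self.arm in (STANDARD_CARE, PINPOINT), f"unknown arm {self.arm!r}")
        for name in ("sensitivity", "specificity", "gp_override_probability",
                     "delayed_return_probability_cancer",
                     "delayed_return_probability_noncancer"):
            v = getattr(self, name)
            _check(0.0 <= v <= 1.0, f"{name} must lie in [0, 1], got {v}")
        _check(self.delay_weeks > 0, "delay_weeks must be positive")
        _check(self.turnaround_minutes >= 0, "turnaround must be non-negative")
        return self


# ---------------------------------------------------------------------------
# clinic configuration
# ---------------------------------------------------------------------------

AM_START = 9 * 60    # 09:00
PM_START = 14 * 60   # 14:00
SESSION_MINUTES = 240
OVERTIME_MINUTES = 15.0

#: (name, weekday 0=Mon, start minute-of-day, kind)
WEEKLY_SESSIONS: tuple[tuple[str, int, int, str], ...] = (
    ("mon_am", 0, AM_START, "full"),
    ("tue_am", 1, AM_START, "add_on"),
    ("tue_pm", 1, PM_START, "full"),
    ("wed_am", 2, AM_START, "full"),
    ("wed_pm", 2, PM_START, "full"),
    ("thu_am", 3, AM_START, "full"),
    ("thu_pm", 3, PM_START, "full"),
    ("fri_am", 4, AM_START, "full"),
)
SESSION_NAMES = tuple(s[0] for s in WEEKLY_SESSIONS)


@dataclass
class BookingRule:
    """Queue-responsive booking of new patients into full clinics.

    A full clinic books ``base_new_slots_full`` new patients; above a
    referral backlog of ``queue_threshold`` the booking grows by one for
    every ``queue_step`` additional patients, capped at ``max_new_slots``.
    ``first_boost_at`` fixes the phase of the stepping rule: the first
    extra slot appears at that backlog (just above the threshold) and
    further slots every ``queue_step`` beyond it.
    The add-on clinic always books exactly ``base_new_slots_addon``.
    ``notice_days`` is the minimum interval between the referral decision
    and the earliest clinic a patient can attend (appointment logistics);
    overspill returners are exempt.
    """

    base_new_slots_full: int = 25
    base_new_slots_addon: int = 10
    queue_threshold: int = 380
    queue_step: int = 15
    first_boost_at: int = 385
    max_new_slots: int = 34
    overspill_slots_full: int = 5
    overspill_slots_addon: int = 6
    notice_days: float = 7.0

    def validate(self) -> "BookingRule":
        _check(self.base_new_slots_full > 0 and self.base_new_slots_addon > 0,
               "base slot counts must be positive")
        _check(self.max_new_slots >= self.base_new_slots_full,
               "max_new_slots must be at least the base full-clinic booking")
        _check(self.queue_step > 0, "queue_step must be positive")
        _check(self.queue_threshold >= 0, "queue_threshold must be non-negative")
        _check(self.queue_threshold < self.first_boost_at
               <= self.queue_threshold + self.queue_step,
               "first_boost_at must lie within one step above the threshold")
        _check(self.overspill_slots_full >= 0 and self.overspill_slots_addon >= 0,
               "overspill slot counts must be non-negative")
        _check(self.notice_days >= 0, "notice_days must be non-negative")
        return self


@dataclass
class ResourceRoster:
    """Per-session staff counts by role, availability fractions, and rooms.

    Availability is the fraction of the shift not lost to other duties
    (admin, follow-ups); it thins each role's parallel capacity.  With
    ``availability_mode="stochastic_round"`` the fractional part of
    ``count × availability`` is resolved by a per-session Bernoulli draw
    (so the long-run mean capacity equals the thinned value);
    ``"floor"`` always rounds down.
    """

    full_session: dict[str, int] = field(default_factory=lambda: {
        "consultant": 2, "nurse_practitioner": 1, "physician_associate": 1,
        "band7_sonographer": 2, "band6_sonographer": 1,
        "band6_non_sonographer": 1, "grade2_assistant": 2,
    })
    addon_session: dict[str, int] = field(default_factory=lambda: {
        "consultant": 1, "nurse_practitioner": 1, "physician_associate": 1,
        "band7_sonographer": 1, "band6_sonographer": 1,
        "band6_non_sonographer": 1, "grade2_assistant": 1,
    })
    #: default availability is calibrated (coordinate bisection, 20-trial
    #: evaluations) so the simulated standard-care annual overspill count
    #: matches the clinic's 2019 audit figure of 1,664
    availability: dict[str, float] = field(default_factory=lambda: {
        role: 0.805 for role in ROLES})
    availability_mode: str = "stochastic_round"  # or "floor"
    rooms: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_ROOMS))

    def validate(self) -> "ResourceRoster":
        for name, counts in (("full_session", self.full_session),
                             ("addon_session", self.addon_session)):
            _check(set(counts) <= set(ROLES), f"{name} has unknown roles")
            _check(all(isinstance(c, int) and c >= 0 for c in counts.values()),
                   f"{name} counts must be non-negative integers")
        _check(set(self.availability) <= set(ROLES), "availability has unknown roles")
        _check(all(0.0 < a <= 1.0 for a in self.availability.values()),
               "availability fractions must lie in (0, 1]")
        _check(self.availability_mode in ("stochastic_round", "floor"),
               f"unknown availability_mode {self.availability_mode!r}")
        _check(set(self.rooms) == set(ACTIVITIES), "rooms must cover the four activities")
        _check(all(isinstance(c, int) and c >= 0 for c in self.rooms.values()),
               "room counts must be non-negative integers")
        return self

    def counts_for(self, kind: str) -> dict[str, int]:
        return self.full_session if kind == "full" else self.addon_session

    def check_no_deadlock(self, enabled_kinds: Iterable[str]) -> None:
        """Reject configurations in which some required activity could never
        run in any enabled session (no eligible staff anywhere, or no room)."""
        kinds = set(enabled_kinds)
        _check(bool(kinds), "schedule has no enabled sessions")
        for activity in ACTIVITIES:
            _check(self.rooms[activity] > 0, f"no room for {activity}")
            if activity == BIOPSY:
                needs = [("consultant",), ELIGIBLE_STAFF["biopsy_assistant"]]
            else:
                needs = [ELIGIBLE_STAFF[activity]]
            if activity in (MAMMOGRAM, ULTRASOUND):
                needs.append(ELIGIBLE_STAFF["prep"])
            for roles in needs:
                ok = any(
                    any(self.counts_for(kind).get(r, 0) > 0 for r in roles)
                    for kind in kinds
                )
                _check(ok, f"no eligible staff for {activity} "
                           f"(roles {'/'.join(roles)}) in any enabled session")


# ---------------------------------------------------------------------------
# scenario = one simulated strategy
# ---------------------------------------------------------------------------

@dataclass
class ScenarioConfig:
    """Everything needed to run one strategy: triage behaviour, demand,
    schedule reconfiguration, resources and the simulation horizon."""

    name: str = "standard_care"
    arrivals: ArrivalConfig = field(default_factory=ArrivalConfig)
    prevalence: float = 0.0476
    pathway: PathwayTable = field(default_factory=PathwayTable)
    durations: DurationModel = field(default_factory=DurationModel)
    triage: TriageConfig = field(default_factory=TriageConfig)
    booking: BookingRule = field(default_factory=BookingRule)
    roster: ResourceRoster = field(default_factory=ResourceRoster)
    disabled_sessions: tuple[str, ...] = ()
    warmup_weeks: int = 12
    collection_weeks: int = 52
    overtime_minutes: float = OVERTIME_MINUTES

    def validate(self) -> "ScenarioConfig":
        _check(bool(self.name), "scenario needs a name")
        self.arrivals.validate()
        _check(0.0 <= self.prevalence <= 1.0, "prevalence must lie in [0, 1]")
        self.pathway.validate()
        self.durations.validate()
        self.triage.validate()
        self.booking.validate()
        self.roster.validate()
        unknown = set(self.disabled_sessions) - set(SESSION_NAMES)
        _check(not unknown, f"unknown session name(s): {sorted(unknown)}")
        _check(self.warmup_weeks >= 0, "warmup_weeks must be non-negative")
        _check(self.collection_weeks > 0, "collection_weeks must be positive")
        _check(self.overtime_minutes >= 0, "overtime must be non-negative")
        enabled_kinds = [kind for (nm, _d, _s, kind) in WEEKLY_SESSIONS
                         if nm not in self.disabled_sessions]
        if enabled_kinds:  # a fully disabled schedule is allowed (degenerate run)
            self.roster.check_no_deadlock(enabled_kinds)
        return self

    @property
    def horizon_weeks(self) -> int:
        return self.warmup_weeks + self.collection_weeks

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: Mapping) -> "ScenarioConfig":
        data = dict(data)

        def sub(key, klass):
            if key in data and isinstance(data[key], Mapping):
                d = dict(data[key])
                if key == "durations" and "biopsy_options" in d:
                    d["biopsy_options"] = tuple(d["biopsy_options"])
                data[key] = klass(**d)

        sub("arrivals", ArrivalConfig)
        sub("pathway", PathwayTable)
        sub("durations", DurationModel)
        sub("triage", TriageConfig)
        sub("booking", BookingRule)
        sub("roster", ResourceRoster)
        if "disabled_sessions" in data:
            data["disabled_sessions"] = tuple(data["disabled_sessions"])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        _check(not unknown, f"unknown scenario field(s): {sorted(unknown)}")
        return cls(**data).validate()

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ScenarioConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def replace(self, **kw) -> "ScenarioConfig":
        return dataclasses.replace(self, **kw)
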