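"""Discrete-event engine: weekly clinic schedule, queue-responsive
booking, and the intra-session resource simulation.

A trial simulates warm-up plus collection (12 + 52 weeks by default).
GP presentations stream in continuously; referred patients join a FIFO
referral queue and are booked, up to the session's planned capacity, into
the first clinic starting at least ``notice_days`` after their referral.
Inside a session every patient works through their remaining diagnostic
activities, each seizing a room and eligible staff (imaging runs as an
atomic prep → image subprocess that holds the room throughout).  New
activities may start up to the closing instant and started work always
completes; patients still queueing at close are routed to the clinic
returns queue ("overspill") and re-admitted, FIFO, into reserved return
slots on a later day.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass

import numpy as np

from .config import (
    BIOPSY,
    ELIGIBLE_STAFF,
    INITIAL_ASSESSMENT,
    MAMMOGRAM,
    MIN_PER_DAY,
    MIN_PER_WEEK,
    SESSION_MINUTES,
    SESSION_NAMES,
    ULTRASOUND,
    WEEKLY_SESSIONS,
    BookingRule,
    ConfigError,
    ResourceRoster,
    ScenarioConfig,
)
from .population import Patient, sample_population
from .triage import triage_population

IMAGING = (MAMMOGRAM, ULTRASOUND)


@dataclass(frozen=True)
class SessionPlan:
    """One scheduled half-day clinic on the simulation calendar."""

    name: str
    kind: str            # full | add_on
    week: int
    start: float         # absolute minutes
    close: float

    @property
    def overspill_slots(self):  # resolved against the booking rule by the caller
        raise AttributeError("use BookingRule for slot counts")


def build_weekly_schedule(disabled: tuple[str, ...] = ()) -> list[tuple[str, int, int, str]]:
    """The weekly session templates minus any disabled sessions.

    Service-reconfiguration scenarios disable sessions by name
    (e.g. ``("wed_am",)``); unknown names are rejected.
    """
    unknown = set(disabled) - set(SESSION_NAMES)
    if unknown:
        raise ConfigError(f"unknown session name(s): {sorted(unknown)}")
    return [s for s in WEEKLY_SESSIONS if s[0] not in disabled]


def expand_schedule(disabled: tuple[str, ...], horizon_weeks: int) -> list[SessionPlan]:
    templates = build_weekly_schedule(disabled)
    plans = []
    for week in range(horizon_weeks):
        for name, day, start_min, kind in templates:
            start = week * MIN_PER_WEEK + day * MIN_PER_DAY + start_min
            plans.append(SessionPlan(name=name, kind=kind, week=week,
                                     start=start, close=start + SESSION_MINUTES))
    return plans


def plan_session_capacity(kind: str, queue_length: int, rule: BookingRule) -> int:
    """New-patient slots for the next session given the referral backlog.

    Add-on clinics always book their fixed number.  Full clinics book
    the base 25 at or below the 380 threshold; the first extra patient is
    booked once the backlog reaches ``first_boost_at`` (385, just above
    the threshold), one more per further 15-patient increment, capped at
    34.
    """
    if queue_length < 0:
        raise ConfigError("queue_length must be non-negative")
    if kind == "add_on":
        return rule.base_new_slots_addon
    if queue_length < rule.first_boost_at:
        return rule.base_new_slots_full
    extra = 1 + (queue_length - rule.first_boost_at) // rule.queue_step
    return min(rule.max_new_slots, rule.base_new_slots_full + extra)


def book_session(plan: SessionPlan,
                 referral_queue: list,
                 returns_queue: list,
                 rule: BookingRule,
                 queue_length: int | None = None,
                 ) -> tuple[int, list, list]:
    """Book one session from the two FIFO queues (mutating both).

    Pulls up to the planned new-patient count from the referral queue and
    up to the session's reserved return slots from the clinic-returns
    queue (entries ``(overspill_time, patient)``; only patients who
    overspilled on an earlier calendar day are eligible).  Reserved
    return slots left unused are never converted to new-patient slots.
    ``queue_length`` is the backlog driving the responsive rule and
    defaults to the bookable queue's length.

    Returns ``(planned_new, booked_new, admitted_returns)``.
    """
    if queue_length is None:
        queue_length = len(referral_queue)
    planned = plan_session_capacity(plan.kind, queue_length, rule)
    booked = referral_queue[:planned]
    del referral_queue[:planned]
    slots = (rule.overspill_slots_full if plan.kind == "full"
             else rule.overspill_slots_addon)
    day = plan.start // MIN_PER_DAY
    admitted = []
    while (returns_queue and len(admitted) < slots
           and returns_queue[0][0] // MIN_PER_DAY < day):
        admitted.append(returns_queue.pop(0)[1])
    return planned, booked, admitted


# ---------------------------------------------------------------------------
# intra-session simulation
# ---------------------------------------------------------------------------

class _SessionSim:
    """Event-driven simulation of one clinic session.

    Patients are present from the session start.  Each activity seizes a
    room plus eligible staff; mammogram/ultrasound run as a prep → image
    subprocess in which the room is held from prep start (a patient is
    picked up for prep only once an imaging room is free) and the patient
    may wait, room in hand, for imaging staff.  Dispatch scans waiting
    patients in queue-entry order, so FIFO discipline holds within every
    activity queue.
    """

    def __init__(self, plan: SessionPlan, patients: list[Patient],
                 rooms: dict[str, int], staff: dict[str, int],
                 events: list | None):
        self.plan = plan
        self.start = plan.start
        self.close = plan.close
        self.rooms = dict(rooms)
        self.staff = dict(staff)
        self.events = events
        self.heap: list = []
        self.seq = 0
        # waiting: (entry_seq, patient) ready to start their next activity
        self.waiting: list[tuple[int, Patient]] = []
        # patients holding an imaging room after prep, waiting for staff
        self.img_wait: dict[str, list[Patient]] = {m: [] for m in IMAGING}
        self.held: dict[int, list] = {}   # patient id -> [(res_kind, key), ...]
        self.completed: list[Patient] = []
        self.overspilled: list[Patient] = []
        # a modality whose imaging staff is absent all session must not
        # start preps (the room would be held forever)
        self.modality_possible = {
            m: any(self.staff.get(r, 0) > 0 for r in ELIGIBLE_STAFF[m])
            for m in IMAGING}
        for p in patients:
            self._enqueue(p)

    # -- bookkeeping --------------------------------------------------------

    def _log(self, t, p, event, activity=""):
        if self.events is not None:
            self.events.append((t, p.id, event, activity, self.plan.name))

    def _enqueue(self, p: Patient):
        self.seq += 1
        self.waiting.append((self.seq, p))

    def _push(self, t, kind, p, activity):
        self.seq += 1
        heapq.heappush(self.heap, (t, self.seq, kind, p, activity))

    def _take_staff(self, roles) -> str | None:
        for r in roles:
            if self.staff.get(r, 0) > 0:
                self.staff[r] -= 1
                return r
        return None

    def _seize(self, p: Patient, items):
        self.held.setdefault(p.id, []).extend(items)

    def _release_all(self, p: Patient):
        for kind, key in self.held.pop(p.id, []):
            if kind == "room":
                self.rooms[key] += 1
            else:
                self.staff[key] += 1

    def _release_one(self, p: Patient, kind, key):
        self.held[p.id].remove((kind, key))
        if kind == "room":
            self.rooms[key] += 1
        else:
            self.staff[key] += 1

    # -- starts -------------------------------------------------------------

    def _try_start(self, t: float, p: Patient) -> bool:
        a = p.activity_sequence[p.next_activity]
        if a == INITIAL_ASSESSMENT or a == BIOPSY:
            if self.rooms[a] <= 0:
                return False
            if a == BIOPSY:
                if self.staff.get("consultant", 0) <= 0:
                    return False
                # peek the assistant before committing the consultant
                if not any(self.staff.get(r, 0) > 0
                           for r in ELIGIBLE_STAFF["biopsy_assistant"]):
                    return False
                self.rooms[a] -= 1
                self.staff["consultant"] -= 1
                assistant = self._take_staff(ELIGIBLE_STAFF["biopsy_assistant"])
                self._seize(p, [("room", a), ("staff", "consultant"),
                                ("staff", assistant)])
            else:
                staff = self._take_staff(ELIGIBLE_STAFF[a])
                if staff is None:
                    return False
                self.rooms[a] -= 1
                self._seize(p, [("room", a), ("staff", staff)])
            self._log(t, p, "activity_start", a)
            self._push(t + p.durations[a], "activity_done", p, a)
            return True
        # imaging subprocess: room + prep staff now, imaging staff later
        if not self.modality_possible[a] or self.rooms[a] <= 0:
            return False
        prep_staff = self._take_staff(ELIGIBLE_STAFF["prep"])
        if prep_staff is None:
            return False
        self.rooms[a] -= 1
        self._seize(p, [("room", a), ("staff", prep_staff)])
        self._log(t, p, "prep_start", a)
        self._push(t + p.durations["prep"], "prep_done", p, a)
        return True

    def _try_start_imaging(self, t: float, p: Patient, a: str) -> bool:
        staff = self._take_staff(ELIGIBLE_STAFF[a])
        if staff is None:
            return False
        self._seize(p, [("staff", staff)])
        self._log(t, p, "activity_start", a)
        self._push(t + p.durations[a], "activity_done", p, a)
        return True

    def _dispatch(self, t: float):
        # room-holding post-prep patients first: they entered service earliest
        for a in IMAGING:
            q = self.img_wait[a]
            while q and self._try_start_imaging(t, q[0], a):
                q.pop(0)
        if t > self.close:
            return  # no new activities after the closing instant
        still = []
        for entry in self.waiting:
            if not self._try_start(t, entry[1]):
                still.append(entry)
        self.waiting = still

    # -- event handlers -----------------------------------------------------

    def _on_activity_done(self, t, p: Patient, a: str):
        self._release_all(p)
        self._log(t, p, "activity_end", a)
        p.next_activity += 1
        if p.next_activity >= len(p.activity_sequence):
            p.completion_time = t
            p.exit_type = "discharged" if p.discharged_after_assessment else "completed"
            self._log(t, p, p.exit_type, "")
            self.completed.append(p)
        elif t <= self.close:
            self._enqueue(p)
        else:
            self._overspill(t, p)

    def _on_prep_done(self, t, p: Patient, a: str):
        # release the prep staff member; the room stays held
        staff_item = next(item for item in self.held[p.id] if item[0] == "staff")
        self._release_one(p, *staff_item)
        self._log(t, p, "prep_end", a)
        if not self._try_start_imaging(t, p, a):
            self.img_wait[a].append(p)

    def _overspill(self, t, p: Patient):
        p.overspill_events += 1
        self._log(t, p, "overspill", "")
        self.overspilled.append(p)

    # -- main loop ----------------------------------------------------------

    def run(self) -> None:
        self._dispatch(self.start)
        while self.heap:
            t, _seq, kind, p, a = heapq.heappop(self.heap)
            if kind == "activity_done":
                self._on_activity_done(t, p, a)
            else:
                self._on_prep_done(t, p, a)
            self._dispatch(t)
        for _seq, p in self.waiting:  # never started their next activity
            self._overspill(self.close, p)
        self.waiting = []


def effective_staff(roster: ResourceRoster, kind: str,
                    rng: np.random.Generator) -> dict[str, int]:
    """Thin each role's parallel capacity by its availability fraction.

    The fractional part of ``count × availability`` is resolved by a
    Bernoulli draw per role per session (default), keeping the long-run
    mean capacity at the thinned value; ``"floor"`` mode always rounds
    down.
    """
    out = {}
    for role, count in roster.counts_for(kind).items():
        eff = count * roster.availability.get(role, 1.0)
        base = int(np.floor(eff))
        frac = eff - base
        if roster.availability_mode == "stochastic_round" and frac > 0:
            base += int(rng.random() < frac)
        out[role] = base
    return out


def run_session(plan: SessionPlan, patients: list[Patient],
                roster: ResourceRoster, rng: np.random.Generator,
                events: list | None = None,
                staff: dict[str, int] | None = None,
                ) -> tuple[list[Patient], list[Patient]]:
    """Simulate one session; returns (completed, overspilled).

    ``staff`` overrides the roster-derived effective staffing (used by
    tests that pin exact server counts).
    """
    if staff is None:
        staff = effective_staff(roster, plan.kind, rng)
    sim = _SessionSim(plan, patients, roster.rooms, staff, events)
    sim.run()
    return sim.completed, sim.overspilled


# ---------------------------------------------------------------------------
# whole-trial simulation
# ---------------------------------------------------------------------------

@dataclass
class SessionRecord:
    name: str
    kind: str
    week: int
    start: float
    queue_length: int
    planned_new: int
    booked_new: int
    admitted_returns: int
    overspill_count: int


@dataclass
class TrialLog:
    """Complete record of one replication."""

    config: ScenarioConfig
    patients: list[Patient]
    sessions: list[SessionRecord]
    overspill_times: list[float]
    events: list | None = None

    @property
    def horizon_minutes(self) -> float:
        return self.config.horizon_weeks * MIN_PER_WEEK


def run_trial(config: ScenarioConfig, seed, collect_events: bool = False) -> TrialLog:
    """One replication: arrivals → triage → booking → sessions → exits.

    Deterministic given the seed (any value acceptable to
    ``numpy.random.default_rng``, including a ``SeedSequence``).
    """
    config.validate()
    rng = np.random.default_rng(seed)
    pop_rng, triage_rng, clinic_rng = rng.spawn(3)

    patients = sample_population(
        config.horizon_weeks, config.arrivals, config.prevalence,
        config.pathway, config.durations, pop_rng)
    triage_population(patients, config.triage, triage_rng)

    events = [] if collect_events else None
    if events is not None:
        for p in patients:
            events.append((p.gp_arrival_time, p.id, "gp_arrival", "", ""))
            if p.referral_time is not None:
                events.append((p.referral_time, p.id, "referral",
                               p.referral_kind, ""))

    # referral stream, FIFO by referral time (maturity preserves this order)
    referred = sorted(
        (p for p in patients if p.referral_time is not None),
        key=lambda p: (p.referral_time, p.id))
    # notice counts calendar days: a patient referred on day d can attend
    # sessions from day d + notice_days (same weekday one week later)
    notice_days = config.booking.notice_days
    n_ref = len(referred)
    i_matured = 0      # next referred patient not yet bookable
    i_referred = 0     # next referred patient whose referral is in the future
    matured: list[Patient] = []
    returns: list[tuple[float, Patient]] = []
    booked_total = 0

    plans = expand_schedule(config.disabled_sessions, config.horizon_weeks)
    records: list[SessionRecord] = []
    overspill_times: list[float] = []

    for plan in plans:
        plan_day = plan.start // MIN_PER_DAY
        while i_matured < n_ref and \
                referred[i_matured].referral_time // MIN_PER_DAY \
                + notice_days <= plan_day:
            matured.append(referred[i_matured])
            i_matured += 1
        while i_referred < n_ref and \
                referred[i_referred].referral_time <= plan.start:
            i_referred += 1

        # backlog driving the responsive rule: referred but not yet seen
        queue_length = i_referred - booked_total
        planned, booked_new, admitted = book_session(
            plan, matured, returns, config.booking, queue_length)
        booked_total += len(booked_new)
        for p in booked_new:
            p.first_clinic_time = plan.start
        if events is not None:
            for p in booked_new:
                events.append((plan.start, p.id, "booked", "new", plan.name))
            for p in admitted:
                events.append((plan.start, p.id, "booked", "return", plan.name))

        attending = admitted + booked_new  # returners have waited longest
        staff = effective_staff(config.roster, plan.kind, clinic_rng)
        sim = _SessionSim(plan, attending, config.roster.rooms, staff, events)
        sim.run()
        for p in sim.overspilled:
            returns.append((plan.close, p))
            overspill_times.append(plan.close)

        records.append(SessionRecord(
            name=plan.name, kind=plan.kind, week=plan.week, start=plan.start,
            queue_length=queue_length, planned_new=planned,
            booked_new=len(booked_new), admitted_returns=len(admitted),
            overspill_count=len(sim.overspilled)))

    # anyone not exited is still in the system at the horizon
    for p in patients:
        if p.exit_type is None:
            p.exit_type = "in_system"

    return TrialLog(config=config, patients=patients, sessions=records,
                    overspill_times=overspill_times, events=events)
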