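"""Discrete-event engine: schedule, queue-responsive booking, the
intra-session resource simulation (checked against hand-computed
schedules) and whole-trial invariants."""

import dataclasses
from collections import Counter

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from clinicflow import (
    BookingRule,
    ConfigError,
    ResourceRoster,
    book_session,
    build_weekly_schedule,
    plan_session_capacity,
    preset,
    run_session,
    run_trial,
)
from clinicflow.config import (
    BIOPSY,
    INITIAL_ASSESSMENT,
    MAMMOGRAM,
    MIN_PER_DAY,
    SESSION_NAMES,
    ULTRASOUND,
)
from clinicflow.engine import effective_staff, expand_schedule

from conftest import make_patient, make_plan, scale_roster

IA, M, US, B = INITIAL_ASSESSMENT, MAMMOGRAM, ULTRASOUND, BIOPSY
RULE = BookingRule()


class TestSchedule:
    def test_full_week_has_eight_sessions_and_185_base_slots(self):
        sessions = build_weekly_schedule()
        assert len(sessions) == 8
        base = sum(RULE.base_new_slots_full if kind == "full"
                   else RULE.base_new_slots_addon
                   for _n, _d, _s, kind in sessions)
        assert base == 7 * 25 + 10 == 185

    def test_sessions_in_chronological_order(self):
        plans = expand_schedule((), 2)
        starts = [p.start for p in plans]
        assert starts == sorted(starts) and len(plans) == 16

    def test_disabling_add_on_leaves_seven(self):
        assert len(build_weekly_schedule(("tue_am",))) == 7

    def test_unknown_session_rejected(self):
        with pytest.raises(ConfigError):
            build_weekly_schedule(("sat_am",))

    def test_fully_disabled_schedule_still_simulates(self):
        cfg = preset("standard_care").replace(
            disabled_sessions=SESSION_NAMES, warmup_weeks=0,
            collection_weeks=2).validate()
        log = run_trial(cfg, 0)
        assert log.sessions == []
        assert all(p.exit_type == "in_system" for p in log.patients)


class TestCapacityRule:
    @pytest.mark.parametrize("q,expected", [
        (0, 25), (380, 25), (384, 25), (385, 26), (395, 26),
        (515, 34), (10_000, 34)])
    def test_full_clinic_slots(self, q, expected):
        assert plan_session_capacity("full", q, RULE) == expected

    def test_add_on_fixed_regardless_of_queue(self):
        assert plan_session_capacity("add_on", 10_000, RULE) == 10

    def test_negative_queue_rejected(self):
        with pytest.raises(ConfigError):
            plan_session_capacity("full", -1, RULE)

    @given(q=st.integers(0, 5000), dq=st.integers(0, 500))
    def test_monotone_and_bounded(self, q, dq):
        a = plan_session_capacity("full", q, RULE)
        b = plan_session_capacity("full", q + dq, RULE)
        assert 25 <= a <= b <= 34


class TestBooking:
    def test_fifo_booking_respects_planned_capacity(self):
        queue = list(range(100))
        planned, booked, admitted = book_session(
            make_plan(), queue, [], RULE)
        assert planned == 25 and booked == list(range(25))
        assert queue == list(range(25, 100)) and admitted == []

    def test_unused_return_reserve_not_converted_to_new_slots(self):
        queue = list(range(500))
        returns = [(0.0, "r1"), (0.0, "r2")]
        planned, booked, admitted = book_session(
            make_plan(start=2 * MIN_PER_DAY), queue, returns, RULE)
        assert admitted == ["r1", "r2"]
        # 3 reserve slots unused; new bookings still capped at the plan
        assert len(booked) == plan_session_capacity("full", 500, RULE)

    def test_same_day_overspill_not_readmitted(self):
        returns = [(100.0, "early"), (100.0 + MIN_PER_DAY, "late")]
        _, _, admitted = book_session(
            make_plan(start=MIN_PER_DAY + 540), [], returns, RULE)
        assert admitted == ["early"]

    def test_empty_queues_run_empty_session(self):
        planned, booked, admitted = book_session(make_plan(), [], [], RULE)
        assert planned == 25 and booked == [] and admitted == []


MICRO_ROSTER = ResourceRoster(
    full_session={"consultant": 1, "band7_sonographer": 1, "grade2_assistant": 1},
    availability={r: 1.0 for r in ("consultant", "band7_sonographer",
                                   "grade2_assistant")})


class TestSessionOracle:
    """run_session against hand-simulated schedules at zero dispersion."""

    def _micro_patients(self):
        return [make_patient(i, (IA, US), {IA: 10.0, US: 20.0}, False)
                for i in range(2)]

    def test_hand_simulated_micro_instance(self, rng):
        # P1: assess 0-10, prep 10-15, US 15-35.
        # P2: assess 10-20 (single consultant), prep 20-25,
        #     US 35-55 (single sonographer busy until 35).
        patients = self._micro_patients()
        events = []
        completed, overspilled = run_session(
            make_plan(), patients, MICRO_ROSTER, rng, events=events)
        assert [p.id for p in completed] == [0, 1] and not overspilled
        assert [p.completion_time for p in completed] == [35.0, 55.0]
        timeline = [(t, pid, ev, act) for t, pid, ev, act, _ in events]
        assert (15.0, 0, "activity_start", US) in timeline
        assert (20.0, 1, "prep_start", US) in timeline
        assert (35.0, 1, "activity_start", US) in timeline

    def test_second_sonographer_shrinks_makespan(self, rng):
        roster = dataclasses.replace(
            MICRO_ROSTER,
            full_session={**MICRO_ROSTER.full_session, "band7_sonographer": 2},
            availability={**MICRO_ROSTER.availability})
        completed, _ = run_session(make_plan(), self._micro_patients(),
                                   roster, rng)
        assert [p.completion_time for p in completed] == [35.0, 45.0]

    def test_started_activity_finishes_in_overtime(self, rng):
        # one patient starts US at 235 (before close), runs to 255;
        # remaining time at close (15) is within the overtime allowance
        p1 = make_patient(0, (IA, US), {IA: 230.0, US: 20.0})
        completed, overspilled = run_session(
            make_plan(), [p1],
            dataclasses.replace(MICRO_ROSTER, availability={
                r: 1.0 for r in MICRO_ROSTER.availability}), rng)
        assert completed and completed[0].completion_time == 255.0

    def test_queued_at_close_overspills_with_remaining_sequence(self, rng):
        # P1 monopolises the consultant past close; P2 never starts
        p1 = make_patient(0, (IA,), {IA: 250.0})
        p2 = make_patient(1, (IA, US), {IA: 10.0, US: 20.0})
        completed, overspilled = run_session(
            make_plan(), [p1, p2], MICRO_ROSTER, rng)
        assert [p.id for p in completed] == [0]
        assert [p.id for p in overspilled] == [1]
        assert overspilled[0].next_activity == 0  # full sequence preserved
        assert overspilled[0].overspill_events == 1

    def test_discharged_patient_exits_after_assessment(self, rng):
        p = make_patient(0, (IA,), {IA: 10.0}, discharged=True)
        completed, _ = run_session(make_plan(), [p], MICRO_ROSTER, rng)
        assert completed[0].exit_type == "discharged"

    def test_biopsy_seizes_consultant_and_assistant(self, rng):
        # two biopsies, one consultant: strictly sequential despite
        # two free assistants and four rooms
        roster = dataclasses.replace(
            MICRO_ROSTER,
            full_session={"consultant": 1, "grade2_assistant": 2},
            availability={"consultant": 1.0, "grade2_assistant": 1.0})
        ps = [make_patient(i, (B,), {B: 30.0}) for i in range(2)]
        completed, _ = run_session(make_plan(), ps, roster, rng)
        assert [p.completion_time for p in completed] == [30.0, 60.0]


class TestEffectiveStaff:
    def test_floor_mode(self):
        roster = dataclasses.replace(
            preset("standard_care").roster, availability_mode="floor")
        staff = effective_staff(roster, "full", np.random.default_rng(0))
        assert staff["consultant"] == 1  # floor(2 * 0.805)

    def test_stochastic_rounding_preserves_mean(self, rng):
        roster = preset("standard_care").roster
        draws = [effective_staff(roster, "full", rng)["consultant"]
                 for _ in range(4000)]
        assert np.mean(draws) == pytest.approx(2 * 0.805, abs=0.03)

    def test_deadlock_config_rejected_before_simulation(self):
        cfg = preset("standard_care")
        no_consultants = {**cfg.roster.full_session, "consultant": 0}
        bad = cfg.replace(roster=dataclasses.replace(
            cfg.roster, full_session=no_consultants,
            addon_session={**cfg.roster.addon_session, "consultant": 0}))
        with pytest.raises(ConfigError, match="biopsy"):
            bad.validate()


@pytest.fixture(scope="module")
def logged_trial():
    cfg = preset("standard_care").replace(
        warmup_weeks=2, collection_weeks=8).validate()
    return run_trial(cfg, 7, collect_events=True)


class TestTrialInvariants:
    def test_conservation_of_patients(self, logged_trial):
        by_exit = Counter(p.exit_type for p in logged_trial.patients)
        assert sum(by_exit.values()) == len(logged_trial.patients)
        assert (by_exit["completed"] + by_exit["discharged"]
                + by_exit["no_referral"] + by_exit["in_system"]
                == len(logged_trial.patients))

    def test_fifo_attendance_order(self, logged_trial):
        seen = [p for p in logged_trial.patients
                if p.first_clinic_time is not None]
        seen.sort(key=lambda p: (p.referral_time, p.id))
        first = [p.first_clinic_time for p in seen]
        assert all(a <= b for a, b in zip(first, first[1:]))

    def test_capacity_caps_every_session(self, logged_trial):
        for rec in logged_trial.sessions:
            if rec.kind == "full":
                assert rec.booked_new <= 34 and rec.admitted_returns <= 5
            else:
                assert rec.booked_new <= 10 and rec.admitted_returns <= 6
            assert rec.planned_new == plan_session_capacity(
                rec.kind, rec.queue_length, logged_trial.config.booking)

    def test_weekly_bookings_never_exceed_cap(self, logged_trial):
        weekly = Counter()
        for rec in logged_trial.sessions:
            weekly[rec.week] += rec.booked_new
        assert max(weekly.values()) <= 7 * 34 + 10

    def test_no_activity_repeated_across_overspills(self, logged_trial):
        starts = Counter((pid, act) for _t, pid, ev, act, _s
                         in logged_trial.events if ev == "activity_start")
        assert max(starts.values()) == 1

    def test_patient_timestamps_ordered(self, logged_trial):
        for p in logged_trial.patients:
            if p.referral_time is not None:
                assert p.referral_time >= p.gp_arrival_time
            if p.first_clinic_time is not None:
                assert p.first_clinic_time >= p.referral_time
            if p.exit_type in ("completed", "discharged"):
                assert p.completion_time >= p.first_clinic_time

    def test_same_seed_reproduces_identical_logs(self, small_config):
        a = run_trial(small_config, 42, collect_events=True)
        b = run_trial(small_config, 42, collect_events=True)
        assert a.events == b.events
        assert a.sessions == b.sessions
        assert a.overspill_times == b.overspill_times

    def test_unconstrained_resources_mean_no_overspill(self):
        """With effectively unlimited staff, rooms and slots every referred
        patient is seen at their first attendable session and no overspill
        occurs."""
        cfg = preset("standard_care")
        cfg = cfg.replace(
            warmup_weeks=0, collection_weeks=6,
            booking=dataclasses.replace(cfg.booking, base_new_slots_full=400,
                                        base_new_slots_addon=400,
                                        max_new_slots=400),
            roster=dataclasses.replace(
                scale_roster(cfg, staff_scale=20, availability=1.0).roster,
                rooms={a: 50 for a in cfg.roster.rooms}),
        ).validate()
        log = run_trial(cfg, 3)
        assert sum(r.overspill_count for r in log.sessions) == 0
        plans = expand_schedule((), 6)
        for p in log.patients:
            if p.first_clinic_time is None:
                continue
            ref_day = p.referral_time // MIN_PER_DAY
            earliest = min(
                (pl.start for pl in plans
                 if pl.start // MIN_PER_DAY >= ref_day + 7), default=None)
            assert p.first_clinic_time == earliest

    def test_more_demand_means_longer_waits(self):
        """Mean time to clinic is non-decreasing in the demand multiplier
        (paired seeds)."""
        waits = []
        for mult in (1.0, 1.3):
            cfg = preset("standard_care")
            cfg = cfg.replace(warmup_weeks=4, collection_weeks=8,
                              arrivals=dataclasses.replace(
                                  cfg.arrivals, demand_multiplier=mult))
            log = run_trial(cfg.validate(), 11)
            seen = [p for p in log.patients if p.first_clinic_time is not None]
            waits.append(np.mean([p.first_clinic_time - p.referral_time
                                  for p in seen]))
        assert waits[1] > waits[0]
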