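import dataclasses

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from clinicflow import Patient, SessionPlan, preset

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_config():
    """Standard care at a short horizon for fast whole-trial tests."""
    return preset("standard_care").replace(
        warmup_weeks=2, collection_weeks=8).validate()


def make_patient(pid, sequence, durations, discharged=False):
    """Hand-built patient for session-level oracle tests."""
    d = dict(durations)
    d.setdefault("prep", 5.0)
    return Patient(id=pid, gp_arrival_time=0.0, activity_sequence=tuple(sequence),
                   discharged_after_assessment=discharged, durations=d)


def make_plan(start=0.0, kind="full", minutes=240.0):
    return SessionPlan(name="test", kind=kind, week=0,
                       start=start, close=start + minutes)


def scale_roster(cfg, staff_scale=None, availability=None):
    """Config copy with uniform roster tweaks."""
    roster = cfg.roster
    kw = {}
    if staff_scale is not None:
        kw["full_session"] = {r: c * staff_scale for r, c in roster.full_session.items()}
        kw["addon_session"] = {r: c * staff_scale for r, c in roster.addon_session.items()}
    if availability is not None:
        kw["availability"] = {r: availability for r in roster.availability}
    return cfg.replace(roster=dataclasses.replace(roster, **kw))
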