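"""Named strategy presets.

``standard_care`` refers every presenting patient immediately.  The two
risk-test scenarios bracket the uncertainty about how GPs and low-risk
patients behave:

* ``scenario1`` — full adherence: only high-risk results are referred,
  and every low-risk cancer patient returns for a delayed referral at
  six weeks.
* ``scenario2`` — imperfect adherence: GPs overrule 20% of low-risk
  results, and 10% of the remaining non-referred non-cancer patients
  also return at six weeks.

Service-reconfiguration presets apply the scenario-2 triage parameters
with one or two weekly clinics removed from the schedule.
"""

from __future__ import annotations

from .config import PINPOINT, STANDARD_CARE, ConfigError, ScenarioConfig, TriageConfig


def standard_care() -> ScenarioConfig:
    return ScenarioConfig(name="standard_care",
                          triage=TriageConfig(arm=STANDARD_CARE)).validate()


def scenario1() -> ScenarioConfig:
    return ScenarioConfig(
        name="scenario1",
        triage=TriageConfig(
            arm=PINPOINT, gp_override_probability=0.0,
            delayed_return_probability_cancer=1.0,
            delayed_return_probability_noncancer=0.0),
    ).validate()


def scenario2() -> ScenarioConfig:
    return ScenarioConfig(
        name="scenario2",
        triage=TriageConfig(
            arm=PINPOINT, gp_override_probability=0.20,
            delayed_return_probability_cancer=1.0,
            delayed_return_probability_noncancer=0.10),
    ).validate()


def _reconfigured(base: ScenarioConfig, name: str,
                  disabled: tuple[str, ...]) -> ScenarioConfig:
    return base.replace(name=name, disabled_sessions=disabled).validate()


_BUILDERS = {
    "standard_care": standard_care,
    "scenario1": scenario1,
    "scenario2": scenario2,
    "scenario2_no_tue_am": lambda: _reconfigured(
        scenario2(), "scenario2_no_tue_am", ("tue_am",)),
    "scenario2_no_wed_am": lambda: _reconfigured(
        scenario2(), "scenario2_no_wed_am", ("wed_am",)),
    "scenario2_no_tue_wed": lambda: _reconfigured(
        scenario2(), "scenario2_no_tue_wed", ("tue_am", "wed_am")),
}

PRESET_NAMES = tuple(_BUILDERS)


def preset(name: str) -> ScenarioConfig:
    """Build a fresh, validated preset configuration by name."""
    try:
        builder = _BUILDERS[name]
    except KeyError:
        raise ConfigError(
            f"unknown preset {name!r}; choose from {', '.join(PRESET_NAMES)}"
        ) from None
    return builder()


def fixture_path():
    """Path of the shipped YAML fixture holding the three primary arms
    (including the full audit pathway table)."""
    from pathlib import Path
    return Path(__file__).parent / "presets" / "scenarios.yaml"


def scenario_fixtures() -> dict[str, ScenarioConfig]:
    """Load the shipped YAML fixture into validated configurations."""
    import yaml
    with open(fixture_path()) as fh:
        data = yaml.safe_load(fh)
    return {name: ScenarioConfig.from_dict(d) for name, d in data.items()}
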