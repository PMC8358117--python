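import pytest

from neuroloop.devicesim import (
    Bound,
    Device,
    GroupLimits,
    SimConfig,
    StimProgram,
    US,
)

START = 1_600_000_000 * US


@pytest.fixture
def limits() -> dict[str, GroupLimits]:
    lim = GroupLimits(Bound(0.0, 5.0), Bound(2.0, 200.0), Bound(60.0, 450.0))
    return {g: lim for g in "ABCD"}


@pytest.fixture
def global_limits() -> GroupLimits:
    return GroupLimits(Bound(0.0, 10.0), Bound(1.0, 500.0), Bound(40.0, 1000.0))


@pytest.fixture
def device(limits) -> Device:
    return Device(limits, drain_pct_per_hour=2.0, seed=7)


@pytest.fixture
def short_config() -> SimConfig:
    """One minute, four channels, lossless link."""
    return SimConfig(duration_s=60.0, start_uutc=START, seed=11)


@pytest.fixture
def seizure_config() -> SimConfig:
    """Ten minutes with one 30-s seizure halfway through."""
    return SimConfig(
        duration_s=600.0,
        start_uutc=START,
        seizure_times=((START + 300 * US, 30.0),),
        preictal_lead_min=2.0,
        seed=5,
    )


@pytest.fixture
def baseline_program() -> StimProgram:
    return StimProgram(2.0, 145.0, 90.0)
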