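"""Emulation of the on-device (embedded) classifier.

The implant's adaptive mode runs a linear discriminant over two
power-in-band features, with a single threshold producing a High/Low
detection state. State transitions feed the adaptive stimulation lookup:
each classified brain state (baseline wake, baseline sleep, pre-seizure,
seizure) maps to a physician-configured stimulation program, validated
against the adaptive group's clinician limits at configuration load time,
never at runtime.

Band power is the one-sided magnitude-squared spectrum summed over the band
(rectangular window over the update window, default 1 s), scaled so that a
sine of amplitude A inside the band reports ≈ A²/2 and the full 0–Nyquist
band of a noise signal reports ≈ its variance (Parseval).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .devicesim import StimProgram, GroupLimits

__all__ = [
    "PowerBandConfig",
    "band_power",
    "LdConfig",
    "LdState",
    "ld_update",
    "run_ld",
    "AdaptiveConfig",
    "adaptive_target",
    "calibrate_ld_threshold",
]

BRAIN_STATES = ("baseline_wake", "baseline_sleep", "pre_seizure", "seizure")


@dataclass(frozen=True)
class PowerBandConfig:
    """One power-in-band feature: channel index, band edges, update interval."""

    channel: int
    f_lo: float
    f_hi: float
    update_interval_s: float = 1.0

    def validate(self, fs: float) -> None:
        if not 0 < self.f_lo < self.f_hi:
            raise ValueError("band must satisfy 0 < f_lo < f_hi")
        if self.f_hi > fs / 2:
            raise ValueError(f"band upper edge {self.f_hi} Hz above Nyquist {fs / 2} Hz")


def band_power(window: np.ndarray, fs: float, band: PowerBandConfig) -> float:
    """Mean-square signal power within [f_lo, f_hi) for one channel window."""
    band.validate(fs)
    x = np.asarray(window, dtype=np.float64)
    if x.ndim == 2:
        x = x[band.channel]
    n = len(x)
    spec = np.abs(np.fft.rfft(x)) ** 2
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    sel = (freqs >= band.f_lo) & (freqs < band.f_hi)
    # one-sided power: double interior bins, never DC/Nyquist (band excludes DC)
    scale = np.full(spec.shape, 2.0)
    scale[0] = 1.0
    if n % 2 == 0:
        scale[-1] = 1.0
    return float((scale[sel] * spec[sel]).sum() / n ** 2)


# ---------------------------------------------------------------------------
# LD state machine
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LdConfig:
    """One linear discriminant with one threshold.

    The discriminant d = w·f + b is compared against the threshold each
    update; ``onset_count`` consecutive updates at or above it enter High and
    ``offset_count`` consecutive updates below it return to Low (debounce;
    both default to 1, matching a bare single-threshold detector).
    """

    weights: tuple[float, ...]
    bias: float
    threshold: float
    onset_count: int = 1
    offset_count: int = 1

    def __post_init__(self) -> None:
        if self.onset_count < 1 or self.offset_count < 1:
            raise ValueError("onset_count and offset_count must be >= 1")

    def discriminant(self, features) -> float:
        return float(np.dot(self.weights, features) + self.bias)


@dataclass
class LdState:
    state: str = "Low"  # {"High", "Low"}
    above: int = 0
    below: int = 0


def ld_update(ld: LdState, config: LdConfig, features) -> tuple[LdState, bool]:
    """One deterministic FSM step; returns (new state, transition flag)."""
    d = config.discriminant(features)
    new = LdState(ld.state, ld.above, ld.below)
    transition = False
    if d >= config.threshold:
        new.above += 1
        new.below = 0
        if new.state == "Low" and new.above >= config.onset_count:
            new.state = "High"
            transition = True
    else:
        new.below += 1
        new.above = 0
        if new.state == "High" and new.below >= config.offset_count:
            new.state = "Low"
            transition = True
    return new, transition


def run_ld(config: LdConfig, feature_trace: np.ndarray) -> list[str]:
    """Replay a feature trace through the FSM; returns the state after each
    update. Pure function of (config, trace)."""
    st = LdState()
    out = []
    for f in np.atleast_2d(np.asarray(feature_trace)):
        st, _ = ld_update(st, config, f)
        out.append(st.state)
    return out


def calibrate_ld_threshold(
    config_weights: tuple[float, ...],
    bias: float,
    features_seizure: np.ndarray,
    features_baseline: np.ndarray,
) -> float:
    """Midpoint-of-means threshold between the two classes' discriminant
    values — the offline calibration step that precedes deployment."""
    w = np.asarray(config_weights)
    d_sz = np.asarray(features_seizure) @ w + bias
    d_bl = np.asarray(features_baseline) @ w + bias
    return float((d_sz.mean() + d_bl.mean()) / 2.0)


# ---------------------------------------------------------------------------
# adaptive stimulation lookup
# ---------------------------------------------------------------------------

class AdaptiveConfig:
    """Per-brain-state stimulation programs for the adaptive group.

    Every state must be configured and every program must satisfy the
    adaptive group's limits; both are checked at load time so lookup can
    never fail or emit an out-of-bounds program at runtime.
    """

    def __init__(self, programs: dict[str, StimProgram], limits: GroupLimits) -> None:
        missing = [s for s in BRAIN_STATES if s not in programs]
        if missing:
            raise ValueError(f"missing adaptive programs for states: {missing}")
        for state, prog in programs.items():
            bad = limits.violations(prog)
            if bad:
                raise ValueError(f"program for {state} violates adaptive limits: {bad}")
        self.programs = dict(programs)
        self.limits = limits


def adaptive_target(
    config: AdaptiveConfig,
    *,
    ld_state: str = "Low",
    risk_state: str = "Low",
    sleep_state: str = "wake",
) -> tuple[str, StimProgram]:
    """Resolve the current brain state and return its program.

    Priority: seizure (embedded LD High) over pre-seizure (predictor High)
    over baseline sleep/wake. Pure lookup.
    """
    if ld_state == "High":
        state = "seizure"
    elif risk_state == "High":
        state = "pre_seizure"
    elif sleep_state == "sleep":
        state = "baseline_sleep"
    else:
        state = "baseline_wake"
    return state, config.programs[state]
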