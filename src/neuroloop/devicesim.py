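"""Synthetic implanted-device stand-in.

Generates ground-truth-annotated multi-channel intracranial EEG (local field
potentials), packetizes it through a lossy/jittery telemetry link model,
models battery drain, and enforces the device-side command contract
(clinician limit validation, therapy preconditions, status queries).

Signal morphology
-----------------
The real device streams whatever the brain produces; here each brain state is
given a synthetic signature chosen so that the downstream analytics' target
feature is discriminative by construction:

* background — per-channel independent pink (1/f) noise;
* sleep      — a shared high-amplitude delta (0.5–4 Hz) oscillation is added,
               so delta-band relative power dominates;
* pre-ictal  — a shared pink-noise component is mixed in, raising
               inter-channel correlation without changing total power much;
* seizure    — a shared high-amplitude rhythmic 3–8 Hz burst (slow chirp),
               giving both high per-second RMS and high correlation.

Samples are signed 16-bit ADC counts with a configurable microvolt-per-count
conversion stored in channel metadata.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

__all__ = [
    "SimConfig",
    "TelemetryPacket",
    "StimProgram",
    "GroupLimits",
    "DeviceState",
    "Device",
    "Command",
    "QueryStatus",
    "SetGroup",
    "SetProgram",
    "EnableStreams",
    "TherapyOn",
    "TherapyOff",
    "ImpedanceRequest",
    "Ack",
    "Reject",
    "GroundTruthEvent",
    "simulate_recording",
    "emit_packets",
    "write_ground_truth_csv",
]

US = 1_000_000  # microseconds per second (uUTC arithmetic)


# ---------------------------------------------------------------------------
# configuration & domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SimConfig:
    """Parameters of one simulated recording session.

    Times are uUTC (microseconds since the Unix epoch, UTC). ``seizure_times``
    holds ``(onset_uutc, duration_s)`` pairs; each seizure is preceded by a
    pre-ictal window of ``preictal_lead_min`` minutes that abuts the onset.
    """

    n_channels: int = 4
    fs: float = 250.0
    packet_ms: int = 100
    duration_s: float = 60.0
    start_uutc: int = 1_600_000_000 * US
    seizure_times: tuple[tuple[int, float], ...] = ()
    preictal_lead_min: float = 60.0
    sleep_intervals: tuple[tuple[int, int], ...] = ()
    battery_ins_pct: float = 100.0
    battery_ctm_pct: float = 100.0
    drain_pct_per_hour: float = 1.0
    p_drop: float = 0.0
    p_delay: float = 0.0
    max_delay_s: float = 0.0
    seed: int = 0
    # signal-shape knobs (defaults are the study conditions; see docs/methods.md)
    uv_per_count: float = 0.5
    background_rms_uv: float = 25.0
    seizure_gain: float = 5.0       # burst amplitude, multiples of background RMS
    sleep_delta_gain: float = 3.0   # delta amplitude, multiples of background RMS
    preictal_corr: float = 0.6      # shared-component variance fraction pre-ictally
    seizure_f_lo: float = 3.0
    seizure_f_hi: float = 8.0

    def __post_init__(self) -> None:
        if not 1 <= self.n_channels <= 4:
            raise ValueError("n_channels must be in 1..4 (device streams up to four LFP channels)")
        if self.packet_ms not in (50, 100):
            raise ValueError("packet_ms must be 50 or 100")
        if self.fs <= 0 or self.duration_s <= 0:
            raise ValueError("fs and duration_s must be positive")
        n_per_packet = self.fs * self.packet_ms / 1000.0
        if abs(n_per_packet - round(n_per_packet)) > 1e-9:
            raise ValueError("fs * packet_ms must give an integer sample count")
        ivs = sorted((int(t), int(t + d * US)) for t, d in self.seizure_times)
        for (a0, a1), (b0, b1) in zip(ivs, ivs[1:]):
            if b0 < a1:
                raise ValueError("overlapping seizure intervals")

    @property
    def samples_per_packet(self) -> int:
        return int(round(self.fs * self.packet_ms / 1000.0))

    @property
    def n_samples(self) -> int:
        return int(round(self.duration_s * self.fs))


@dataclass(frozen=True)
class TelemetryPacket:
    """One 50/100-ms multi-channel sample burst.

    ``gen_uutc`` is the generation timestamp of the first sample; ``seq`` is a
    monotone counter assigned at generation. The link model may drop, delay or
    reorder delivery but never alters contents.
    """

    gen_uutc: int
    seq: int
    n_samples: int
    samples: tuple[tuple[int, ...], ...]  # per-channel ADC counts
    stream: str = "time_domain"


@dataclass(frozen=True)
class GroundTruthEvent:
    uutc_start: int
    uutc_end: int
    label: str  # {"seizure", "preictal", "sleep"}


# --- stimulation programs & limits (shared with stimctl) -------------------

@dataclass(frozen=True)
class StimProgram:
    """One stimulation parameter tuple: amplitude (mA), rate (Hz), pulse width (µs)."""

    amplitude_ma: float
    rate_hz: float
    pulse_width_us: float
    electrodes: tuple[int, ...] = (0, 1)

    def __post_init__(self) -> None:
        for v in (self.amplitude_ma, self.rate_hz, self.pulse_width_us):
            if not np.isfinite(v) or v < 0:
                raise ValueError("stimulation parameters must be finite and non-negative")


@dataclass(frozen=True)
class Bound:
    lower: float
    upper: float

    def __post_init__(self) -> None:
        if self.lower > self.upper:
            raise ValueError("lower bound exceeds upper bound")

    def contains(self, v: float) -> bool:
        return self.lower <= v <= self.upper


@dataclass(frozen=True)
class GroupLimits:
    """Clinician per-group bounds, each nested inside the global system bounds."""

    amplitude_ma: Bound
    rate_hz: Bound
    pulse_width_us: Bound

    def violations(self, p: StimProgram) -> list[str]:
        out = []
        if not self.amplitude_ma.contains(p.amplitude_ma):
            out.append("amplitude_ma")
        if not self.rate_hz.contains(p.rate_hz):
            out.append("rate_hz")
        if not self.pulse_width_us.contains(p.pulse_width_us):
            out.append("pulse_width_us")
        return out


# ---------------------------------------------------------------------------
# recording generator
# ---------------------------------------------------------------------------

def _pink_noise(rng: np.random.Generator, n: int) -> np.ndarray:
    """Unit-RMS pink (1/f) noise via spectral shaping of white Gaussian noise."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n)
    f[0] = f[1] if n > 1 else 1.0  # avoid div-by-zero at DC
    spec /= np.sqrt(f)
    x = np.fft.irfft(spec, n)
    sd = x.std()
    return x / sd if sd > 0 else x


def simulate_recording(config: SimConfig) -> tuple[list[GroundTruthEvent], np.ndarray]:
    """Generate a ground-truth-annotated multi-channel recording.

    Returns ``(ground_truth, signal)`` where ``signal`` is an int16 array of
    shape ``(n_channels, n_samples)`` in ADC counts. Deterministic for a fixed
    config (the seed is part of the config).
    """
    rng = np.random.default_rng(config.seed)
    C, N, fs = config.n_channels, config.n_samples, config.fs
    sigma = config.background_rms_uv / config.uv_per_count  # counts

    # independent pink background + one shared pink component for correlation shifts
    own = np.stack([_pink_noise(rng, N) for _ in range(C)])
    shared = _pink_noise(rng, N)

    t_rel = np.arange(N) / fs  # seconds from start
    truth: list[GroundTruthEvent] = []
    mix = np.zeros(N)  # shared-variance fraction rho(t), 0 = independent channels

    def idx(uutc: float) -> int:
        return int(np.clip(round((uutc - config.start_uutc) / US * fs), 0, N))

    # pre-ictal windows: raise inter-channel correlation before each onset
    for onset, dur in sorted(config.seizure_times):
        lead = int(config.preictal_lead_min * 60 * US)
        p0, p1 = max(onset - lead, config.start_uutc), onset
        if p1 > p0:
            mix[idx(p0):idx(p1)] = config.preictal_corr
            truth.append(GroundTruthEvent(int(p0), int(p1), "preictal"))

    signal = np.sqrt(1.0 - mix) * own + np.sqrt(mix) * shared[None, :]
    signal *= sigma

    # sleep: shared delta oscillation with a slowly wandering frequency
    for s0, s1 in config.sleep_intervals:
        i0, i1 = idx(s0), idx(s1)
        if i1 <= i0:
            continue
        n = i1 - i0
        f_delta = 1.0 + 0.8 * np.sin(2 * np.pi * 0.01 * t_rel[i0:i1] + rng.uniform(0, 2 * np.pi))
        phase = 2 * np.pi * np.cumsum(f_delta) / fs
        delta = config.sleep_delta_gain * sigma * np.sin(phase)
        signal[:, i0:i1] += delta[None, :]
        truth.append(GroundTruthEvent(int(s0), int(s1), "sleep"))

    # seizures: shared rhythmic burst chirping down through the 3–8 Hz band
    for onset, dur in sorted(config.seizure_times):
        i0, i1 = idx(onset), idx(onset + dur * US)
        if i1 <= i0:
            continue
        n = i1 - i0
        frac = np.linspace(0.0, 1.0, n)
        f_inst = config.seizure_f_hi - (config.seizure_f_hi - config.seizure_f_lo) * frac
        phase = 2 * np.pi * np.cumsum(f_inst) / fs
        env = np.minimum(1.0, np.minimum(frac, 1.0 - frac) * 10.0 + 0.05)  # soft on/offset
        burst = config.seizure_gain * sigma * env * np.sin(phase + rng.uniform(0, 2 * np.pi))
        jitter = 0.1 * sigma * rng.standard_normal((C, n))
        signal[:, i0:i1] += burst[None, :] + jitter
        truth.append(GroundTruthEvent(int(onset), int(onset + dur * US), "seizure"))

    truth.sort(key=lambda e: (e.uutc_start, e.label))
    counts = np.clip(np.rint(signal), -32768, 32767).astype(np.int16)
    return truth, counts


def write_ground_truth_csv(path, truth: Iterable[GroundTruthEvent]) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["uutc_start", "uutc_end", "label"])
        for ev in truth:
            w.writerow([ev.uutc_start, ev.uutc_end, ev.label])


# ---------------------------------------------------------------------------
# packetization & link model
# ---------------------------------------------------------------------------

def packetize(signal: np.ndarray, config: SimConfig) -> list[TelemetryPacket]:
    """Split a recording into telemetry packets in generation order (no loss)."""
    n_pp = config.samples_per_packet
    n_full = signal.shape[1] // n_pp
    packet_us = int(round(config.packet_ms * 1000))
    out = []
    for k in range(n_full):
        chunk = signal[:, k * n_pp:(k + 1) * n_pp]
        out.append(TelemetryPacket(
            gen_uutc=config.start_uutc + k * packet_us,
            seq=k,
            n_samples=n_pp,
            samples=tuple(tuple(int(v) for v in ch) for ch in chunk),
        ))
    return out


def emit_packets(
    signal: np.ndarray, config: SimConfig
) -> list[tuple[int, TelemetryPacket]]:
    """Run packets through the lossy/jittery link model.

    Returns ``(delivery_uutc, packet)`` pairs sorted by delivery time: with
    probability ``p_drop`` a packet is never delivered; with probability
    ``p_delay`` its delivery is postponed by up to ``max_delay_s``. Contents
    and ``gen_uutc`` are never altered; order of delivery may differ from
    generation order. Uses a seed derived from the config seed so signal
    generation and the link draw independent randomness.
    """
    rng = np.random.default_rng((config.seed, 0x11A8))
    packets = packetize(signal, config)
    packet_us = int(round(config.packet_ms * 1000))
    delivered: list[tuple[int, int, TelemetryPacket]] = []
    for p in packets:
        if rng.random() < config.p_drop:
            continue
        delay_us = 0
        if config.p_delay > 0 and rng.random() < config.p_delay:
            delay_us = int(rng.uniform(0, config.max_delay_s) * US)
        delivery = p.gen_uutc + packet_us + delay_us
        delivered.append((delivery, p.seq, p))
    delivered.sort(key=lambda t: (t[0], t[1]))
    return [(d, p) for d, _, p in delivered]


# ---------------------------------------------------------------------------
# device command contract
# ---------------------------------------------------------------------------

class Command:
    """Marker base class for device commands."""


@dataclass(frozen=True)
class QueryStatus(Command):
    pass


@dataclass(frozen=True)
class SetGroup(Command):
    group: str  # "A".."D"


@dataclass(frozen=True)
class SetProgram(Command):
    group: str
    program: StimProgram


@dataclass(frozen=True)
class EnableStreams(Command):
    streams: frozenset[str]


@dataclass(frozen=True)
class TherapyOn(Command):
    pass


@dataclass(frozen=True)
class TherapyOff(Command):
    pass


@dataclass(frozen=True)
class ImpedanceRequest(Command):
    pairs: tuple[tuple[int, int], ...]


@dataclass(frozen=True)
class Ack:
    payload: dict | None = None


@dataclass(frozen=True)
class Reject:
    reason: str  # machine-readable: limit_violation, no_valid_therapy, ...
    detail: str = ""


@dataclass
class DeviceState:
    """Mutable device-side state; the device rejects commands that would
    violate its group limits, so an active program always satisfies them."""

    battery_ins_pct: float = 100.0
    battery_ctm_pct: float = 100.0
    active_group: str = "A"
    programs: dict[str, StimProgram] = field(default_factory=dict)
    limits: dict[str, GroupLimits] = field(default_factory=dict)
    streaming: set[str] = field(default_factory=set)
    therapy_on: bool = False
    connected: bool = True


class Device:
    """Command-level simulator of the implanted neurostimulator.

    ``handle`` applies one command and returns ``Ack`` or ``Reject`` (with a
    machine-readable reason code); ``advance`` moves the simulated clock and
    drains the batteries.
    """

    GROUPS = ("A", "B", "C", "D")

    def __init__(
        self,
        limits: dict[str, GroupLimits],
        drain_pct_per_hour: float = 1.0,
        battery_ins_pct: float = 100.0,
        battery_ctm_pct: float = 100.0,
        impedances_ohm: dict[tuple[int, int], float] | None = None,
        seed: int = 0,
    ) -> None:
        self.state = DeviceState(
            battery_ins_pct=battery_ins_pct,
            battery_ctm_pct=battery_ctm_pct,
            limits=dict(limits),
        )
        self.drain_pct_per_hour = drain_pct_per_hour
        self.impedances_ohm = impedances_ohm or {}
        self._rng = np.random.default_rng((seed, 0x1F))

    def advance(self, seconds: float) -> None:
        drain = self.drain_pct_per_hour * seconds / 3600.0
        self.state.battery_ins_pct = max(0.0, self.state.battery_ins_pct - drain)
        self.state.battery_ctm_pct = max(0.0, self.state.battery_ctm_pct - drain)

    # -- command dispatch ---------------------------------------------------

    def handle(self, cmd: Command) -> Ack | Reject:
        if isinstance(cmd, QueryStatus):
            s = self.state
            return Ack({
                "battery_ins_pct": s.battery_ins_pct,
                "battery_ctm_pct": s.battery_ctm_pct,
                "active_group": s.active_group,
                "program": s.programs.get(s.active_group),
                "streaming": frozenset(s.streaming),
                "therapy_on": s.therapy_on,
            })
        if isinstance(cmd, SetGroup):
            if cmd.group not in self.GROUPS:
                return Reject("unknown_group", cmd.group)
            self.state.active_group = cmd.group
            return Ack()
        if isinstance(cmd, SetProgram):
            if cmd.group not in self.GROUPS:
                return Reject("unknown_group", cmd.group)
            lim = self.state.limits.get(cmd.group)
            if lim is None:
                return Reject("no_limits_configured", cmd.group)
            bad = lim.violations(cmd.program)
            if bad:
                return Reject("limit_violation", ",".join(bad))
            self.state.programs[cmd.group] = cmd.program
            return Ack()
        if isinstance(cmd, EnableStreams):
            self.state.streaming = set(cmd.streams)
            return Ack()
        if isinstance(cmd, TherapyOn):
            if self.state.programs.get(self.state.active_group) is None:
                return Reject("no_valid_therapy")
            self.state.therapy_on = True
            return Ack()
        if isinstance(cmd, TherapyOff):
            self.state.therapy_on = False
            return Ack()
        if isinstance(cmd, ImpedanceRequest):
            if len(cmd.pairs) > 16:
                return Reject("too_many_pairs", str(len(cmd.pairs)))
            vals = {}
            for pair in cmd.pairs:
                base = self.impedances_ohm.get(tuple(pair), 1000.0)
                vals[tuple(pair)] = float(base + self._rng.normal(0, base * 0.01))
            return Ack({"impedances_ohm": vals})
        return Reject("unknown_command", type(cmd).__name__)
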