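"""Stimulation governance.

Programs live in four device groups: A–C open-loop (A doubles as the safe
mode / baseline), D adaptive. Every program is validated in layers — desired
settings against clinician per-group bounds against global system bounds —
every time parameters are applied and again on every supervisor keepalive
tick. The parameter-sweep ("stimulation trial") sequencer walks up to 24
pre-configured combinations (amplitudes × rates across two sets, each set
with its own pulse width and electrode contacts), alternating stimulation
cycles with rest intervals at baseline, and persists a cursor to disk so an
interrupted trial resumes from the combination being tested.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass
from pathlib import Path

from .devicesim import Ack, Bound, Device, GroupLimits, Reject, SetProgram, StimProgram

__all__ = [
    "Violation",
    "validate_program",
    "apply_program",
    "TrialSet",
    "TrialPlan",
    "build_trial_schedule",
    "TrialRunner",
    "resume_trial",
    "ModeConfig",
    "select_mode",
]


# ---------------------------------------------------------------------------
# layered validation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Violation:
    layer: str       # {"clinician", "global"}
    parameter: str   # {"amplitude_ma", "rate_hz", "pulse_width_us"}
    value: float
    lower: float
    upper: float


def _check_layer(program: StimProgram, limits: GroupLimits, layer: str) -> list[Violation]:
    out = []
    for name in ("amplitude_ma", "rate_hz", "pulse_width_us"):
        bound: Bound = getattr(limits, name)
        value = getattr(program, name)
        if not bound.contains(value):
            out.append(Violation(layer, name, value, bound.lower, bound.upper))
    return out


def validate_program(
    program: StimProgram,
    clinician_limits: GroupLimits,
    global_limits: GroupLimits | None = None,
) -> list[Violation]:
    """Check every layer and return every violated bound (empty list = ok)."""
    violations = _check_layer(program, clinician_limits, "clinician")
    if global_limits is not None:
        violations += _check_layer(program, global_limits, "global")
    return violations


def apply_program(
    device: Device,
    group: str,
    program: StimProgram,
    clinician_limits: GroupLimits,
    global_limits: GroupLimits | None = None,
) -> dict:
    """Validate locally, then send to the device, whose independent
    validation must agree (defense in depth).

    Returns an action record. A device rejection despite a local pass is a
    ``discrepancy_alarm`` — it indicates the device's limit configuration has
    drifted from the supervisor's copy.
    """
    violations = validate_program(program, clinician_limits, global_limits)
    if violations:
        return {"applied": False, "violations": violations, "discrepancy": False}
    resp = device.handle(SetProgram(group, program))
    if isinstance(resp, Reject):
        return {
            "applied": False, "violations": [], "discrepancy": True,
            "reason": resp.reason, "detail": resp.detail,
        }
    return {"applied": True, "violations": [], "discrepancy": False}


# ---------------------------------------------------------------------------
# trial plan & schedule
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TrialSet:
    """One of the two trial sets: shared pulse width and contacts, up to
    3 amplitudes × 4 rates."""

    pulse_width_us: float
    electrodes: tuple[int, ...]
    amplitudes_ma: tuple[float, ...]
    rates_hz: tuple[float, ...]
    group: str  # "B" or "C"

    def __post_init__(self) -> None:
        if not 1 <= len(self.amplitudes_ma) <= 3:
            raise ValueError("a trial set holds 1..3 amplitudes")
        if not 1 <= len(self.rates_hz) <= 4:
            raise ValueError("a trial set holds 1..4 rates")
        if self.group not in ("B", "C"):
            raise ValueError("trial sets run in groups B and C")


@dataclass(frozen=True)
class TrialPlan:
    sets: tuple[TrialSet, ...]
    cycle_duration_s: float
    rest_interval_s: float
    n_cycles: int = 1

    def __post_init__(self) -> None:
        if not 1 <= len(self.sets) <= 2:
            raise ValueError("a plan holds one or two sets")
        n = sum(len(s.amplitudes_ma) * len(s.rates_hz) for s in self.sets)
        if n > 24:
            raise ValueError(f"{n} combinations exceed the 24-combination ceiling")
        if self.cycle_duration_s <= 0 or self.rest_interval_s < 0 or self.n_cycles < 1:
            raise ValueError("invalid trial timing")

    @property
    def n_combinations(self) -> int:
        return sum(len(s.amplitudes_ma) * len(s.rates_hz) for s in self.sets)


def build_trial_schedule(
    plan: TrialPlan, limits: dict[str, GroupLimits],
    global_limits: GroupLimits | None = None,
) -> list[tuple[str, StimProgram]]:
    """Enumerate one cycle's (group, program) list.

    Per set: rates outer loop, amplitudes inner loop (so every rate is tested
    with every amplitude, in a documented stable order); sets sequential.
    Every combination must pass validation for its trial group or the plan is
    rejected at build time.
    """
    schedule: list[tuple[str, StimProgram]] = []
    for s in plan.sets:
        for rate in s.rates_hz:
            for amp in s.amplitudes_ma:
                prog = StimProgram(amp, rate, s.pulse_width_us, s.electrodes)
                bad = validate_program(prog, limits[s.group], global_limits)
                if bad:
                    raise ValueError(f"trial combination violates limits: {bad}")
                schedule.append((s.group, prog))
    return schedule


# ---------------------------------------------------------------------------
# trial runner (crash-resumable)
# ---------------------------------------------------------------------------

def _atomic_write_json(path: Path, obj: dict) -> None:
    tmp = path.with_suffix(".tmp")
    tmp.write_text(json.dumps(obj))
    os.replace(tmp, path)


class TrialRunner:
    """Clock-driven trial sequencer.

    ``tick(now_uutc)`` returns the phase at ``now``:
    ``("stim", group, program)`` during a stimulation cycle,
    ``("rest", "A", None)`` during a rest interval, or ``("done", ..)`` when
    every cycle has completed. The cursor (combination index and cycle) is
    persisted atomically on every phase transition; after a crash,
    :func:`resume_trial` re-runs the interrupted combination from its start
    (the conservative reading of resume-from-last-tested).
    """

    def __init__(
        self,
        plan: TrialPlan,
        limits: dict[str, GroupLimits],
        cursor_path: str | os.PathLike,
        global_limits: GroupLimits | None = None,
        start_uutc: int = 0,
        start_combo: int = 0,
        start_cycle: int = 0,
    ) -> None:
        self.plan = plan
        self.schedule = build_trial_schedule(plan, limits, global_limits)
        self.cursor_path = Path(cursor_path)
        self.start_uutc = start_uutc
        self.start_combo = start_combo
        self.start_cycle = start_cycle
        self._last_now: int | None = None
        self._last_persisted: tuple[int, int] | None = None
        self.stopped = False
        self.warnings: list[str] = []

    def stop(self) -> tuple[str, str, None]:
        """Immediate return to safe mode (group A baseline)."""
        self.stopped = True
        return ("rest", "A", None)

    def tick(self, now_uutc: int):
        if self.stopped:
            return ("rest", "A", None)
        if self._last_now is not None and now_uutc < self._last_now:
            self.warnings.append(f"clock regression at {now_uutc}; tick ignored")
            now_uutc = self._last_now
        self._last_now = now_uutc

        us = 1_000_000
        slot = (self.plan.cycle_duration_s + self.plan.rest_interval_s) * us
        n = len(self.schedule)
        elapsed = now_uutc - self.start_uutc
        if elapsed < 0:
            return ("rest", "A", None)
        # position in the resumed run: offset by the resume cursor
        k_global = int(elapsed // slot) + self.start_cycle * n + self.start_combo
        cycle, combo = divmod(k_global, n)
        if cycle >= self.plan.n_cycles:
            self._persist(self.plan.n_cycles, 0, terminal=True)
            return ("done", None, None)
        in_slot = elapsed % slot
        if in_slot < self.plan.cycle_duration_s * us:
            self._persist(cycle, combo)
            group, program = self.schedule[combo]
            return ("stim", group, program)
        # during rest the tested combination is complete: the cursor points at
        # its successor, so a crash here resumes with the next combination
        nxt_cycle, nxt_combo = divmod(k_global + 1, n)
        if nxt_cycle >= self.plan.n_cycles:
            self._persist(self.plan.n_cycles, 0, terminal=True)
        else:
            self._persist(nxt_cycle, nxt_combo)
        return ("rest", "A", None)

    def _persist(self, cycle: int, combo: int, terminal: bool = False) -> None:
        if self._last_persisted == (cycle, combo) and not terminal:
            return
        self._last_persisted = (cycle, combo)
        _atomic_write_json(self.cursor_path, {
            "cycle": cycle, "combo": combo, "terminal": terminal,
            "n_combinations": len(self.schedule),
        })


def resume_trial(
    plan: TrialPlan,
    limits: dict[str, GroupLimits],
    cursor_path: str | os.PathLike,
    start_uutc: int,
    global_limits: GroupLimits | None = None,
) -> tuple[TrialRunner, list[str]]:
    """Rebuild a runner from a persisted cursor.

    The interrupted combination is re-tested from its start. A missing or
    corrupt cursor restarts the trial from the first combination, with a
    warning the caller should annotate.
    """
    warnings: list[str] = []
    combo = cycle = 0
    path = Path(cursor_path)
    try:
        cur = json.loads(path.read_text())
        if cur.get("terminal"):
            combo, cycle = 0, plan.n_cycles  # already finished
        else:
            combo, cycle = int(cur["combo"]), int(cur["cycle"])
    except (OSError, ValueError, KeyError):
        warnings.append("trial cursor missing or corrupt; restarting from combination 1")
    runner = TrialRunner(
        plan, limits, cursor_path, global_limits,
        start_uutc=start_uutc, start_combo=combo, start_cycle=cycle,
    )
    runner.warnings.extend(warnings)
    return runner, warnings


# ---------------------------------------------------------------------------
# day / night parameter modes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModeConfig:
    """Day/night overlay windows in local minutes-of-day, half-open
    [start, end); the two windows must tile the 24 h exactly."""

    day_start_min: int
    day_end_min: int

    def __post_init__(self) -> None:
        if not (0 <= self.day_start_min < self.day_end_min <= 24 * 60):
            raise ValueError("day window must satisfy 0 <= start < end <= 1440")


def select_mode(now_local_min: float, config: ModeConfig) -> str:
    """'day' if the local time falls in [day_start, day_end), else 'night'."""
    m = now_local_min % (24 * 60)
    return "day" if config.day_start_min <= m < config.day_end_min else "night"
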