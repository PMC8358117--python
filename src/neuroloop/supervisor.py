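"""Supervisory loop and the annotation subsystem.

The supervisor runs a 30-s keepalive tick on the simulated clock: it queries
both batteries, disconnects streaming once (on the crossing edge) when the
implant battery reaches 25%, warns when streaming is expected but no data
has arrived for 30 minutes, re-sends stimulation parameters when the device
copy has drifted from the desired copy, applies the day/night parameter
overlay, and emits an hourly status annotation aligned to wall-clock hours.

Annotations are written to a dual store — an append-only CSV file and a
SQLite database — which must agree row-for-row at every flush. Reminders
(medication, battery charging, surveys) are computed purely from the
schedule and the clock, and each occurrence fires exactly once.
"""

from __future__ import annotations

import csv
import json
import sqlite3
from dataclasses import dataclass, field
from pathlib import Path

from .devicesim import (
    Ack,
    Device,
    ImpedanceRequest,
    QueryStatus,
    SetProgram,
    StimProgram,
    US,
)
from .stimctl import ModeConfig, select_mode, validate_program

__all__ = [
    "Annotation",
    "AnnotationStore",
    "Reminder",
    "ReminderSchedule",
    "due_reminders",
    "Supervisor",
    "SimLink",
    "reconnect",
    "impedance_test",
    "BATTERY_DISCONNECT_PCT",
    "NO_DATA_WARNING_MIN",
    "KEEPALIVE_S",
]

KEEPALIVE_S = 30
BATTERY_DISCONNECT_PCT = 25.0
NO_DATA_WARNING_MIN = 30.0

ANNOTATION_TYPES = (
    "seizure_patient", "aura", "medication", "detection", "prediction_state",
    "sleep_state", "stim_change", "status", "impedance", "warning",
)
SOURCES = ("patient", "analytics", "embedded", "system")


# ---------------------------------------------------------------------------
# annotations: dual CSV + SQL store
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Annotation:
    uutc: int
    type: str
    source: str
    payload: dict

    def __post_init__(self) -> None:
        if self.type not in ANNOTATION_TYPES:
            raise ValueError(f"unknown annotation type {self.type!r}")
        if self.source not in SOURCES:
            raise ValueError(f"unknown annotation source {self.source!r}")


_SCHEMA = """
CREATE TABLE IF NOT EXISTS annotations (
    id INTEGER PRIMARY KEY AUTOINCREMENT,
    uutc INTEGER NOT NULL,
    type TEXT NOT NULL,
    source TEXT NOT NULL,
    payload TEXT NOT NULL
);
CREATE TABLE IF NOT EXISTS meta (key TEXT PRIMARY KEY, value TEXT);
INSERT OR REPLACE INTO meta VALUES ('schema_version', '1');
"""


class AnnotationStore:
    """Append-only event store with CSV/SQL parity.

    Each event is appended atomically to both stores in one call; if either
    backend is unwritable the event is buffered in memory and flushed on
    recovery, preserving parity. Patient seizure/aura events additionally
    invoke a video-capture hook (a no-op stub here).
    """

    CSV_COLUMNS = ("uutc", "type", "source", "payload")

    def __init__(self, root: str | Path, video_hook=None) -> None:
        self.root = Path(root)
        self.root.mkdir(parents=True, exist_ok=True)
        self.csv_path = self.root / "annotations.csv"
        self.db_path = self.root / "annotations.sqlite"
        self.video_hook = video_hook or (lambda ann: None)
        self._buffer: list[Annotation] = []
        self.fail_writes = False  # fault-injection switch for tests
        if not self.csv_path.exists():
            with open(self.csv_path, "w", newline="") as fh:
                csv.writer(fh).writerow(self.CSV_COLUMNS)
        self._db = sqlite3.connect(self.db_path)
        self._db.executescript(_SCHEMA)
        self._db.commit()

    def record(self, ann: Annotation) -> None:
        if ann.type in ("seizure_patient", "aura") and ann.source == "patient":
            self.video_hook(ann)
        self._buffer.append(ann)
        self.flush()

    def flush(self) -> None:
        if self.fail_writes or not self._buffer:
            return
        rows = [(a.uutc, a.type, a.source, json.dumps(a.payload, sort_keys=True))
                for a in self._buffer]
        with open(self.csv_path, "a", newline="") as fh:
            csv.writer(fh).writerows(rows)
        self._db.executemany("INSERT INTO annotations(uutc,type,source,payload) VALUES (?,?,?,?)", rows)
        self._db.commit()
        self._buffer.clear()

    # -- reading / parity ---------------------------------------------------

    def csv_rows(self) -> list[dict]:
        with open(self.csv_path, newline="") as fh:
            return list(csv.DictReader(fh))

    def sql_rows(self, type_filter: str | None = None) -> list[tuple]:
        q = "SELECT uutc,type,source,payload FROM annotations"
        args: tuple = ()
        if type_filter:
            q += " WHERE type=?"
            args = (type_filter,)
        return self._db.execute(q + " ORDER BY id", args).fetchall()

    def counts(self) -> tuple[int, int]:
        """(CSV row count, SQL row count) — equal whenever flushed."""
        n_csv = len(self.csv_rows())
        n_sql = self._db.execute("SELECT COUNT(*) FROM annotations").fetchone()[0]
        return n_csv, n_sql

    def close(self) -> None:
        self.flush()
        self._db.close()


# ---------------------------------------------------------------------------
# reminders
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Reminder:
    kind: str                  # {"medication", "battery", "survey"}
    first_local_min: float     # minutes from schedule epoch
    payload: str = ""
    recurrence_min: float | None = None  # None = one-shot


@dataclass
class ReminderSchedule:
    entries: list[Reminder] = field(default_factory=list)
    _fired: set = field(default_factory=set)

    def occurrences_until(self, now_local_min: float):
        for i, r in enumerate(self.entries):
            if r.recurrence_min:
                k = 0
                t = r.first_local_min
                while t <= now_local_min:
                    yield (i, k, r, t)
                    k += 1
                    t = r.first_local_min + k * r.recurrence_min
            elif r.first_local_min <= now_local_min:
                yield (i, 0, r, r.first_local_min)


def due_reminders(schedule: ReminderSchedule, now_local_min: float) -> list[tuple[Reminder, float]]:
    """Every occurrence due at or before ``now`` that has not fired yet.

    Pure given (schedule state, now); calling twice at the same instant
    returns the second time an empty list (idempotent per occurrence).
    """
    out = []
    for i, k, r, t in schedule.occurrences_until(now_local_min):
        if (i, k) not in schedule._fired:
            schedule._fired.add((i, k))
            out.append((r, t))
    return out


# ---------------------------------------------------------------------------
# connection management
# ---------------------------------------------------------------------------

class SimLink:
    """Simulated radio link: a set of advertising device ids, of which only
    previously paired ones may be connected; queries fail while out of
    range."""

    def __init__(self, paired_ids: set[str], advertising: set[str] | None = None,
                 in_range: bool = True) -> None:
        self.paired_ids = set(paired_ids)
        self.advertising = set(advertising or paired_ids)
        self.in_range = in_range
        self.connected_id: str | None = None
        self.failures = 0

    def query_ok(self) -> bool:
        ok = self.in_range and self.connected_id is not None
        self.failures = 0 if ok else self.failures + 1
        return ok


def reconnect(link: SimLink, max_scans: int = 3) -> tuple[bool, list[dict]]:
    """Re-establish the link after more than three consecutive failures.

    Scans only known (paired) devices — an unpaired advertiser is ignored.
    Returns (connected, annotation payloads for every step taken).
    """
    events = [{"type": "status", "event": "reconnect_started", "failures": link.failures}]
    if link.failures <= 3:
        return False, [{"type": "warning", "event": "reconnect_not_due",
                        "failures": link.failures}]
    for _ in range(max_scans):
        candidates = sorted(link.advertising & link.paired_ids)
        if link.in_range and candidates:
            link.connected_id = candidates[0]
            link.failures = 0
            events.append({"type": "status", "event": "reconnected",
                           "device": link.connected_id})
            return True, events
        events.append({"type": "warning", "event": "scan_empty"})
    events.append({"type": "warning", "event": "reconnect_exhausted_degraded_mode"})
    return False, events


# ---------------------------------------------------------------------------
# impedance testing
# ---------------------------------------------------------------------------

def impedance_test(
    device: Device, pairs: list[tuple[int, int]], store: AnnotationStore, now_uutc: int
) -> dict[tuple[int, int], float]:
    """Measure up to 16 contact pairs.

    Warns, waits for sensing to complete (simulated as immediate), disables
    sensing and stimulation, measures, restores the prior state exactly, and
    writes per-pair values to the annotation store. More than 16 pairs is
    rejected before any state change.
    """
    if len(pairs) > 16:
        raise ValueError(f"{len(pairs)} contact pairs exceed the 16-pair limit")
    store.record(Annotation(now_uutc, "warning", "system",
                            {"event": "impedance_pending_stim_sense_pause"}))
    prior_streams = set(device.state.streaming)
    prior_therapy = device.state.therapy_on
    device.state.streaming = set()
    device.state.therapy_on = False
    try:
        resp = device.handle(ImpedanceRequest(tuple(tuple(p) for p in pairs)))
        assert isinstance(resp, Ack)
        values = resp.payload["impedances_ohm"]
    finally:
        device.state.streaming = prior_streams
        device.state.therapy_on = prior_therapy
    store.record(Annotation(now_uutc, "impedance", "system", {
        "pairs": {f"{a}-{b}": round(v, 1) for (a, b), v in values.items()},
    }))
    return values


# ---------------------------------------------------------------------------
# the keepalive supervisor
# ---------------------------------------------------------------------------

class Supervisor:
    """Holds supervisor state across keepalive ticks.

    ``desired_programs`` is the tablet-side source of truth per group; the
    device copy is compared against it every tick and re-sent on discrepancy.
    """

    def __init__(
        self,
        device: Device,
        store: AnnotationStore,
        desired_programs: dict[str, StimProgram],
        limits: dict[str, "GroupLimits"],
        mode_config: ModeConfig | None = None,
        night_overrides: dict[str, StimProgram] | None = None,
        epoch_uutc: int = 0,
    ) -> None:
        self.device = device
        self.store = store
        self.desired_programs = dict(desired_programs)
        self.day_programs = dict(desired_programs)
        self.night_overrides = dict(night_overrides or {})
        self.limits = limits
        self.mode_config = mode_config
        self.epoch_uutc = epoch_uutc
        self.streaming_expected = True
        self.streaming_connected = True
        self.last_data_uutc: int | None = None
        self.battery_disconnect_fired = False
        self.last_hourly_status_hour: int | None = None
        self.current_mode: str | None = None

    def note_data(self, uutc: int) -> None:
        """Telemetry layer callback: data arrived at ``uutc``."""
        self.last_data_uutc = uutc

    def keepalive_tick(self, now_uutc: int) -> list[dict]:
        """One 30-s supervisory tick; returns the action list (each action is
        also annotated). A tick performs at most one disconnect, one re-send
        and one hourly status."""
        actions: list[dict] = []
        dev = self.device

        # (a) battery queries
        status = dev.handle(QueryStatus())
        assert isinstance(status, Ack)
        ins = status.payload["battery_ins_pct"]
        ctm = status.payload["battery_ctm_pct"]
        actions.append({"action": "battery_query", "ins_pct": ins, "ctm_pct": ctm})

        # (b) battery policy: disconnect streaming once on the crossing edge
        if (ins <= BATTERY_DISCONNECT_PCT and self.streaming_connected
                and not self.battery_disconnect_fired):
            self.streaming_connected = False
            self.battery_disconnect_fired = True
            actions.append({"action": "streaming_disconnect", "ins_pct": ins})
            self._annotate(now_uutc, "warning", "system",
                           {"event": "battery_streaming_disconnect", "ins_pct": ins})

        # (c) no-data warning at 30 simulated minutes
        if self.streaming_expected and self.streaming_connected:
            ref = self.last_data_uutc if self.last_data_uutc is not None else self.epoch_uutc
            silent_min = (now_uutc - ref) / US / 60.0
            if silent_min >= NO_DATA_WARNING_MIN:
                actions.append({"action": "no_data_warning", "silent_min": silent_min})
                self._annotate(now_uutc, "warning", "system",
                               {"event": "no_data_in_30_min", "silent_min": round(silent_min, 2)})
                self.last_data_uutc = now_uutc  # re-arm rather than warn every tick

        # (e) day/night overlay (before the discrepancy check so a mode flip
        # updates the desired copy this same tick)
        if self.mode_config is not None:
            now_min = (now_uutc - self.epoch_uutc) / US / 60.0
            mode = select_mode(now_min, self.mode_config)
            if mode != self.current_mode:
                self.current_mode = mode
                self.desired_programs = dict(self.day_programs)
                if mode == "night":
                    self.desired_programs.update(self.night_overrides)
                actions.append({"action": "mode_overlay", "mode": mode})
                self._annotate(now_uutc, "status", "system",
                               {"event": "mode_overlay", "mode": mode})

        # (d) program discrepancy: validate then re-send (at most one per tick)
        for group, desired in self.desired_programs.items():
            current = dev.state.programs.get(group)
            if current != desired:
                if validate_program(desired, self.limits[group]):
                    continue  # never send an invalid program
                resp = dev.handle(SetProgram(group, desired))
                actions.append({
                    "action": "program_resend", "group": group,
                    "old": repr(current), "new": repr(desired),
                    "ok": isinstance(resp, Ack),
                })
                self._annotate(now_uutc, "stim_change", "system", {
                    "event": "program_resend", "group": group,
                    "old": repr(current), "new": repr(desired),
                })
                break

        # (f) hourly status aligned to wall-clock hour boundaries
        hour = int(now_uutc // (3600 * US))
        if hour != self.last_hourly_status_hour:
            self.last_hourly_status_hour = hour
            actions.append({"action": "hourly_status"})
            self._annotate(now_uutc, "status", "system", {
                "event": "hourly_status", "ins_pct": round(ins, 3),
                "ctm_pct": round(ctm, 3),
                "active_group": status.payload["active_group"],
                "therapy_on": status.payload["therapy_on"],
                "streaming_connected": self.streaming_connected,
            })
        return actions

    def _annotate(self, uutc: int, type_: str, source: str, payload: dict) -> None:
        self.store.record(Annotation(uutc, type_, source, payload))
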