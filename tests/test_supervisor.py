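"""Keepalive policies, reconnect, impedance, annotations, reminders."""

import numpy as np
import pytest

from neuroloop.devicesim import (
    Device,
    EnableStreams,
    SetProgram,
    StimProgram,
    US,
)
from neuroloop.stimctl import ModeConfig
from neuroloop.supervisor import (
    Annotation,
    AnnotationStore,
    KEEPALIVE_S,
    Reminder,
    ReminderSchedule,
    SimLink,
    Supervisor,
    due_reminders,
    impedance_test,
    reconnect,
)

from conftest import START


@pytest.fixture
def store(tmp_path):
    return AnnotationStore(tmp_path / "ann")


def _supervisor(device, store, limits, program, **kw):
    device.handle(SetProgram("A", program))
    return Supervisor(device, store, {"A": program}, limits, epoch_uutc=START, **kw)


class TestKeepalive:
    def test_quiet_tick_queries_batteries_only(self, device, store, limits, baseline_program):
        sup = _supervisor(device, store, limits, baseline_program)
        sup.note_data(START)
        sup.last_hourly_status_hour = int(START // (3600 * US))  # hourly already done
        actions = sup.keepalive_tick(START + 30 * US)
        assert [a["action"] for a in actions] == ["battery_query"]

    def test_battery_disconnect_fires_exactly_once_at_crossing(self, store, limits, baseline_program):
        # 1% per 10 simulated minutes = 6%/h, starting at 30%
        device = Device(limits, drain_pct_per_hour=6.0, battery_ins_pct=30.0)
        sup = _supervisor(device, store, limits, baseline_program)
        disconnect_levels = []
        now = START
        for _ in range(2 * 120):  # one simulated hour
            device.advance(KEEPALIVE_S)
            now += KEEPALIVE_S * US
            sup.note_data(now)
            for a in sup.keepalive_tick(now):
                if a["action"] == "streaming_disconnect":
                    disconnect_levels.append(a["ins_pct"])
        assert len(disconnect_levels) == 1
        assert disconnect_levels[0] == pytest.approx(25.0, abs=1e-9)

    def test_no_data_warning_at_thirty_minutes(self, device, store, limits, baseline_program):
        sup = _supervisor(device, store, limits, baseline_program)
        warned_at = None
        now = START
        for _ in range(70):
            now += 60 * US  # 1-min ticks for brevity; policy is time-based
            for a in sup.keepalive_tick(now):
                if a["action"] == "no_data_warning" and warned_at is None:
                    warned_at = now
        assert warned_at == START + 30 * 60 * US
        rows = store.sql_rows("warning")
        assert any("no_data_in_30_min" in r[3] for r in rows)

    def test_program_discrepancy_resent(self, device, store, limits, baseline_program):
        sup = _supervisor(device, store, limits, baseline_program)
        sup.note_data(START)
        # fault injection: device program mutated behind the supervisor's back
        device.state.programs["A"] = StimProgram(1.0, 50.0, 90.0)
        actions = sup.keepalive_tick(START + 30 * US)
        resend = [a for a in actions if a["action"] == "program_resend"]
        assert len(resend) == 1 and resend[0]["ok"]
        assert device.state.programs["A"] == baseline_program
        assert any(r[1] == "stim_change" for r in store.sql_rows())

    def test_day_night_overlay_switches_desired_programs(self, device, store, limits, baseline_program):
        night = StimProgram(1.0, 100.0, 90.0)
        sup = _supervisor(
            device, store, limits, baseline_program,
            mode_config=ModeConfig(7 * 60, 22 * 60),
            night_overrides={"A": night},
        )
        sup.note_data(START)
        sup.keepalive_tick(START + 1 * US)            # minute 0: night
        assert sup.desired_programs["A"] == night
        sup.keepalive_tick(START + 8 * 3600 * US)     # 08:00: day
        assert sup.desired_programs["A"] == baseline_program

    def test_hourly_status_once_per_hour(self, device, store, limits, baseline_program):
        sup = _supervisor(device, store, limits, baseline_program)
        sup.last_hourly_status_hour = int(START // (3600 * US))
        now = START
        n_status = 0
        for _ in range(240):  # two simulated hours of 30-s ticks
            sup.note_data(now)
            now += KEEPALIVE_S * US
            n_status += sum(a["action"] == "hourly_status" for a in sup.keepalive_tick(now))
        assert n_status == 2


class TestReconnect:
    def test_not_due_until_more_than_three_failures(self):
        link = SimLink({"ctm-1"})
        link.failures = 3
        ok, events = reconnect(link)
        assert not ok and events[0]["event"] == "reconnect_not_due"
        link.failures = 4
        ok, _ = reconnect(link)
        assert ok and link.connected_id == "ctm-1"

    def test_unpaired_advertiser_ignored(self):
        link = SimLink(paired_ids={"ctm-1"}, advertising={"rogue-9"})
        link.failures = 5
        ok, events = reconnect(link)
        assert not ok
        assert link.connected_id is None

    def test_reconnects_within_sixty_seconds_of_coming_in_range(self):
        link = SimLink({"ctm-1"}, in_range=False)
        link.connected_id = None
        t = 0
        reconnected_at = None
        while t <= 300:
            if t == 90:
                link.in_range = True
            if not link.query_ok() and link.failures > 3:
                ok, _ = reconnect(link)
                if ok and reconnected_at is None:
                    reconnected_at = t
            t += KEEPALIVE_S
        assert reconnected_at is not None
        assert reconnected_at - 90 <= 60


class TestImpedance:
    def test_sixteen_pairs_measured_and_annotated(self, device, store):
        device.handle(EnableStreams(frozenset({"time_domain"})))
        pairs = [(a, b) for a in range(4) for b in range(4, 8)]  # 16
        values = impedance_test(device, pairs, store, START)
        assert len(values) == 16
        rows = store.sql_rows("impedance")
        assert len(rows) == 1

    def test_seventeen_pairs_rejected_before_state_change(self, device, store):
        device.handle(EnableStreams(frozenset({"time_domain"})))
        before = set(device.state.streaming)
        with pytest.raises(ValueError, match="16"):
            impedance_test(device, [(0, i) for i in range(17)], store, START)
        assert device.state.streaming == before
        assert store.sql_rows("impedance") == []

    def test_state_restored_after_measurement(self, device, store, baseline_program):
        device.handle(SetProgram("A", baseline_program))
        device.handle(EnableStreams(frozenset({"time_domain", "accel"})))
        from neuroloop.devicesim import TherapyOn
        device.handle(TherapyOn())
        before = (set(device.state.streaming), device.state.active_group,
                  device.state.therapy_on)
        impedance_test(device, [(0, 1)], store, START)
        after = (set(device.state.streaming), device.state.active_group,
                 device.state.therapy_on)
        assert before == after


class TestAnnotationStore:
    def test_single_event_parity(self, store):
        store.record(Annotation(START, "medication", "patient", {"drug": "LEV", "mg": 500}))
        csv_rows = store.csv_rows()
        sql = store.sql_rows()
        assert len(csv_rows) == len(sql) == 1
        assert csv_rows[0]["payload"] == sql[0][3]

    def test_thousand_mixed_events_recount(self, store):
        rng = np.random.default_rng(0)
        types = ["seizure_patient", "medication", "status", "detection", "warning"]
        for k in range(1000):
            store.record(Annotation(START + k * US, str(rng.choice(types)),
                                    "system", {"k": k}))
        assert store.counts() == (1000, 1000)

    def test_type_query_matches_csv_filter(self, store):
        rng = np.random.default_rng(1)
        types = ["seizure_patient", "aura", "status"]
        for k in range(300):
            store.record(Annotation(START + k, str(rng.choice(types)), "analytics", {}))
        n_sql = len(store.sql_rows("seizure_patient"))
        n_csv = sum(1 for r in store.csv_rows() if r["type"] == "seizure_patient")
        assert n_sql == n_csv > 0

    def test_parity_preserved_across_write_failures(self, store):
        store.record(Annotation(START, "status", "system", {"i": 0}))
        store.fail_writes = True  # fault injection: both backends unwritable
        for i in range(1, 6):
            store.record(Annotation(START + i, "status", "system", {"i": i}))
        assert store.counts() == (1, 1)  # nothing half-written
        store.fail_writes = False
        store.flush()
        assert store.counts() == (6, 6)
        payloads = [r[3] for r in store.sql_rows()]
        assert payloads == [f'{{"i": {i}}}' for i in range(6)]

    def test_patient_seizure_triggers_video_hook(self, tmp_path):
        captured = []
        s = AnnotationStore(tmp_path / "ann", video_hook=captured.append)
        s.record(Annotation(START, "seizure_patient", "patient", {}))
        s.record(Annotation(START, "detection", "analytics", {}))
        assert len(captured) == 1

    def test_unknown_type_rejected(self):
        with pytest.raises(ValueError):
            Annotation(START, "party", "patient", {})


class TestReminders:
    def test_empty_schedule(self):
        assert due_reminders(ReminderSchedule(), 100.0) == []

    def test_five_minute_recurrence_yields_twelve_per_hour(self):
        sched = ReminderSchedule([Reminder("medication", 5.0, recurrence_min=5.0)])
        out = due_reminders(sched, 60.0)
        assert len(out) == 12  # minutes 5,10,...,60

    def test_idempotent_within_same_instant(self):
        sched = ReminderSchedule([Reminder("battery", 10.0, recurrence_min=10.0)])
        first = due_reminders(sched, 30.0)
        assert len(first) == 3
        assert due_reminders(sched, 30.0) == []

    def test_one_shot_fires_once(self):
        sched = ReminderSchedule([Reminder("survey", 15.0)])
        assert len(due_reminders(sched, 20.0)) == 1
        assert due_reminders(sched, 25.0) == []
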