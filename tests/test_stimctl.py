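"""Limit validation, trial scheduling/resume, day-night modes."""

import itertools
import json

import pytest
from hypothesis import given, settings, strategies as st

from neuroloop.devicesim import Bound, Device, GroupLimits, StimProgram
from neuroloop.stimctl import (
    ModeConfig,
    TrialPlan,
    TrialRunner,
    TrialSet,
    apply_program,
    build_trial_schedule,
    resume_trial,
    select_mode,
    validate_program,
)

US = 1_000_000


class TestValidation:
    def test_inside_all_bounds_ok(self, limits, global_limits, baseline_program):
        assert validate_program(baseline_program, limits["A"], global_limits) == []

    def test_violation_names_the_clinician_layer(self, limits, global_limits):
        prog = StimProgram(7.0, 100.0, 90.0)  # > clinician 5.0, < global 10.0
        v = validate_program(prog, limits["B"], global_limits)
        assert [x.layer for x in v] == ["clinician"]
        assert v[0].parameter == "amplitude_ma"

    @given(
        st.tuples(st.floats(0, 12), st.floats(0, 400), st.floats(0, 800)),
        st.tuples(st.floats(0, 6), st.floats(0, 6),
                  st.floats(0, 250), st.floats(0, 250),
                  st.floats(0, 500), st.floats(0, 500)),
    )
    @settings(max_examples=100, deadline=None)
    def test_verdict_matches_brute_force(self, pvals, bvals):
        prog = StimProgram(*pvals)
        a0, a1, r0, r1, w0, w1 = bvals
        lim = GroupLimits(Bound(min(a0, a1), max(a0, a1)),
                          Bound(min(r0, r1), max(r0, r1)),
                          Bound(min(w0, w1), max(w0, w1)))
        got = {v.parameter for v in validate_program(prog, lim)}
        expect = set()
        for name in ("amplitude_ma", "rate_hz", "pulse_width_us"):
            b = getattr(lim, name)
            x = getattr(prog, name)
            if not (b.lower <= x <= b.upper):
                expect.add(name)
        assert got == expect


class TestApplyProgram:
    def test_valid_program_acked(self, device, limits, baseline_program):
        out = apply_program(device, "B", baseline_program, limits["B"])
        assert out["applied"] and not out["discrepancy"]
        assert device.state.programs["B"] == baseline_program

    def test_stale_device_limits_raise_discrepancy_alarm(self, limits, baseline_program):
        # device was configured with tighter limits than the supervisor knows
        tight = GroupLimits(Bound(0.0, 1.0), Bound(2.0, 200.0), Bound(60.0, 450.0))
        device = Device({g: tight for g in "ABCD"})
        out = apply_program(device, "B", baseline_program, limits["B"])
        assert not out["applied"] and out["discrepancy"]
        assert out["reason"] == "limit_violation"

    def test_local_violation_never_reaches_device(self, device, limits):
        bad = StimProgram(50.0, 100.0, 90.0)
        out = apply_program(device, "B", bad, limits["B"])
        assert not out["applied"] and out["violations"]
        assert "B" not in device.state.programs


def _two_set_plan(n_cycles=1, cycle_s=4.0, rest_s=2.0):
    s1 = TrialSet(90.0, (0, 1), (1.0, 2.0, 3.0), (30.0, 60.0, 120.0, 180.0), "B")
    s2 = TrialSet(120.0, (2, 3), (1.5, 2.5, 3.5), (40.0, 80.0, 140.0, 190.0), "C")
    return TrialPlan((s1, s2), cycle_s, rest_s, n_cycles)


class TestSchedule:
    def test_twenty_four_combinations(self, limits, global_limits):
        plan = _two_set_plan()
        sched = build_trial_schedule(plan, limits, global_limits)
        assert len(sched) == 24
        assert plan.n_combinations == 24
        assert len(set(sched)) == 24  # all distinct

    def test_order_matches_product_oracle(self, limits):
        plan = _two_set_plan()
        sched = build_trial_schedule(plan, limits)
        oracle = []
        for s in plan.sets:
            for rate, amp in itertools.product(s.rates_hz, s.amplitudes_ma):
                oracle.append((s.group, StimProgram(amp, rate, s.pulse_width_us, s.electrodes)))
        assert sched == oracle

    def test_single_combination_plan(self, limits):
        plan = TrialPlan((TrialSet(90.0, (0, 1), (1.0,), (30.0,), "B"),), 4.0, 2.0)
        assert len(build_trial_schedule(plan, limits)) == 1

    def test_limit_violating_combination_rejected_at_build(self, limits):
        s = TrialSet(90.0, (0, 1), (1.0, 9.0), (30.0,), "B")  # 9 mA > 5 mA bound
        plan = TrialPlan((s,), 4.0, 2.0)
        with pytest.raises(ValueError, match="violates"):
            build_trial_schedule(plan, limits)

    def test_set_cardinality_caps(self):
        with pytest.raises(ValueError):
            TrialSet(90.0, (0, 1), (1.0, 2.0, 3.0, 4.0), (1, 2, 3, 4), "B")
        with pytest.raises(ValueError):
            TrialSet(90.0, (0, 1), (1.0,), (1, 2, 3, 4, 5), "B")


class TestRunner:
    def test_phases_and_accounting(self, limits, tmp_path):
        """Schedule-replay oracle: ticking through a full run at 0.5-s
        resolution accounts each combination exactly n_cycles×cycle_duration
        of simulated time."""
        plan = _two_set_plan(n_cycles=2, cycle_s=4.0, rest_s=2.0)
        runner = TrialRunner(plan, limits, tmp_path / "cursor.json", start_uutc=0)
        step = US // 2
        active: dict = {}
        t = 0
        while True:
            phase, group, prog = runner.tick(t)
            if phase == "done":
                break
            if phase == "stim":
                active[(group, prog)] = active.get((group, prog), 0) + step
            t += step
        assert len(active) == 24
        assert all(v == 2 * 4 * US for v in active.values())

    def test_first_cycle_and_rest_phase(self, limits, tmp_path):
        plan = _two_set_plan()
        runner = TrialRunner(plan, limits, tmp_path / "c.json", start_uutc=0)
        phase, group, prog = runner.tick(1 * US)
        sched = build_trial_schedule(plan, limits)
        assert phase == "stim" and (group, prog) == sched[0]
        phase, group, prog = runner.tick(5 * US)  # inside rest of slot 0
        assert phase == "rest" and group == "A"

    def test_stop_returns_to_safe_mode_immediately(self, limits, tmp_path):
        plan = _two_set_plan()
        runner = TrialRunner(plan, limits, tmp_path / "c.json", start_uutc=0)
        runner.tick(1 * US)
        assert runner.stop() == ("rest", "A", None)
        assert runner.tick(2 * US) == ("rest", "A", None)

    def test_clock_regression_ignored_with_warning(self, limits, tmp_path):
        plan = _two_set_plan()
        runner = TrialRunner(plan, limits, tmp_path / "c.json", start_uutc=0)
        p1 = runner.tick(13 * US)
        p2 = runner.tick(7 * US)  # clock went backwards
        assert p1 == p2
        assert runner.warnings


class TestResume:
    def test_crash_mid_combination_resumes_same_combination(self, limits, tmp_path):
        plan = _two_set_plan()
        cursor = tmp_path / "cursor.json"
        runner = TrialRunner(plan, limits, cursor, start_uutc=0)
        # combination index 6 runs in slot 6: t in [36, 40) s
        runner.tick(int(37.5 * US))
        sched = build_trial_schedule(plan, limits)
        resumed, warnings = resume_trial(plan, limits, cursor, start_uutc=1000 * US)
        assert warnings == []
        phase, group, prog = resumed.tick(1001 * US)
        assert phase == "stim" and (group, prog) == sched[6]

    def test_crash_during_rest_resumes_successor(self, limits, tmp_path):
        plan = _two_set_plan()
        cursor = tmp_path / "cursor.json"
        runner = TrialRunner(plan, limits, cursor, start_uutc=0)
        runner.tick(int(40.5 * US))  # rest following combination 6
        sched = build_trial_schedule(plan, limits)
        resumed, _ = resume_trial(plan, limits, cursor, start_uutc=0)
        phase, group, prog = resumed.tick(1 * US)
        assert (group, prog) == sched[7]

    def test_missing_cursor_restarts_with_warning(self, limits, tmp_path):
        plan = _two_set_plan()
        resumed, warnings = resume_trial(plan, limits, tmp_path / "gone.json", start_uutc=0)
        assert warnings and "restarting" in warnings[0]
        sched = build_trial_schedule(plan, limits)
        assert resumed.tick(1 * US)[2] == sched[0][1]

    def test_corrupt_cursor_restarts_with_warning(self, limits, tmp_path):
        cursor = tmp_path / "cursor.json"
        cursor.write_text("{not json")
        resumed, warnings = resume_trial(_two_set_plan(), limits, cursor, start_uutc=0)
        assert warnings

    def test_cursor_is_valid_json_at_every_transition(self, limits, tmp_path):
        plan = _two_set_plan(n_cycles=1, cycle_s=1.0, rest_s=1.0)
        cursor = tmp_path / "cursor.json"
        runner = TrialRunner(plan, limits, cursor, start_uutc=0)
        t = 0
        while runner.tick(t)[0] != "done":
            cur = json.loads(cursor.read_text())
            assert 0 <= cur["combo"] < 24
            t += US // 4


class TestDayNight:
    CFG = ModeConfig(day_start_min=7 * 60, day_end_min=22 * 60)

    @pytest.mark.parametrize("minute,expect", [
        (9 * 60, "day"),
        (23 * 60 + 30, "night"),
        (22 * 60, "night"),   # boundary instant: half-open [start, end)
        (7 * 60, "day"),
        (3 * 60, "night"),
    ])
    def test_mode_windows(self, minute, expect):
        assert select_mode(minute, self.CFG) == expect

    def test_bad_window_rejected(self):
        with pytest.raises(ValueError):
            ModeConfig(day_start_min=1200, day_end_min=600)
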