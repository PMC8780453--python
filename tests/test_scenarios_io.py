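"""Scenario loading and execution, telemetry analysis, heatmap export."""

import numpy as np
import pandas as pd
import pytest

from sacm.plant import pv_volume
from sacm.scenarios_io import (
    ARC_TEST_MATRIX,
    TelemetryLog,
    bin_intervals,
    bundled_scenario,
    bundled_scenario_names,
    export_heatmap,
    fluid_balance,
    load_scenario,
    run_arc_condition,
    run_scenario,
)
from sacm.supervisor import EventKind


@pytest.fixture(scope="module")
def scenario1_log():
    return run_scenario(bundled_scenario("scenario_1"), seed=1)


@pytest.fixture(scope="module")
def scenario2_log():
    return run_scenario(bundled_scenario("scenario_2"), seed=1)


class TestLoading:
    def test_bundled_inventory(self):
        assert bundled_scenario_names() == [
            f"scenario_{i}" for i in range(1, 6)
        ]

    def test_interval_counts(self):
        """Scenario 1 has three normalized intervals, the rest five."""
        assert bundled_scenario("scenario_1").n_intervals == 3
        for i in range(2, 6):
            assert bundled_scenario(f"scenario_{i}").n_intervals == 5

    def test_scenario5_has_simultaneous_complications(self):
        spec = bundled_scenario("scenario_5")
        # internal hemorrhage enters in interval 4 and persists while the
        # tourniquet is loosened in interval 5
        acts4 = [e.action for e in spec.intervals[3].events]
        acts5 = [e.action for e in spec.intervals[4].events]
        assert "set_internal_hemorrhage" in acts4
        assert "loosen_tourniquet" in acts5
        stop = [
            e for e in spec.intervals[4].on_end
            if e.action == "set_internal_hemorrhage" and e.rate_ml_min == 0
        ]
        assert stop, "hemorrhage must persist until the final interval ends"

    def test_malformed_file_names_offending_key(self, tmp_path):
        bad = tmp_path / "bad.yaml"
        bad.write_text(
            "name: x\nintervals:\n- until: {map_below: 75}\n  bogus_key: 1\n"
        )
        with pytest.raises(ValueError, match="bogus_key"):
            load_scenario(bad)

    def test_loosen_fraction_validated(self, tmp_path):
        bad = tmp_path / "bad2.yaml"
        bad.write_text(
            "name: x\nintervals:\n"
            "- events: [{action: loosen_tourniquet, fraction: 1.5}]\n"
            "  until: {duration_s: 1}\n"
        )
        with pytest.raises(ValueError):
            load_scenario(bad)

    def test_roundtrip_from_file(self, tmp_path):
        from importlib import resources

        src = resources.files("sacm").joinpath("scenarios/scenario_3.yaml")
        dst = tmp_path / "s3.yaml"
        dst.write_text(src.read_text())
        assert load_scenario(dst) == bundled_scenario("scenario_3")


class TestRunScenario:
    def test_initial_hemorrhage_stops_near_75(self, scenario1_log):
        b1 = scenario1_log.interval_boundaries[1]
        frame = scenario1_log.frame
        at_b1 = frame[frame.t <= b1].central_map.tail(50).mean()
        assert at_b1 == pytest.approx(75.0, abs=1.5)

    def test_scenario1_ends_at_target(self, scenario1_log):
        final = scenario1_log.frame.central_map.tail(50).mean()
        assert final >= 0.995 * 95.0

    def test_determinism(self):
        a = run_scenario(bundled_scenario("scenario_1"), seed=7)
        b = run_scenario(bundled_scenario("scenario_1"), seed=7)
        pd.testing.assert_frame_equal(a.frame, b.frame)
        assert [(e.t, e.kind) for e in a.events] == [
            (e.t, e.kind) for e in b.events
        ]

    def test_scenario2_two_reengagement_pairs(self, scenario2_log):
        pairs = scenario2_log.event_times(EventKind.LOOSE_DETECTED)
        reeng = scenario2_log.event_times(EventKind.ATKT_REENGAGED)
        assert len(pairs) == 2 and len(reeng) == 2
        # loosening never dropped MAP below the 85 mmHg intervention
        # threshold, so no additional resuscitation ran
        assert len(scenario2_log.event_times(EventKind.ARC_STARTED)) == 1
        final = scenario2_log.frame.central_map.tail(50).mean()
        assert final > 85.0

    def test_scenario3_two_low_map_resuscitations(self):
        log = run_scenario(bundled_scenario("scenario_3"), seed=1)
        assert len(log.event_times(EventKind.LOW_MAP_DETECTED)) == 2
        assert len(log.event_times(EventKind.ARC_STARTED)) == 3
        assert log.frame.central_map.tail(50).mean() >= 0.995 * 95.0

    def test_scenario4_event_sequence(self):
        log = run_scenario(bundled_scenario("scenario_4"), seed=1)
        t3 = log.interval_boundaries[3]
        late = [e.kind for e in log.events if e.t > t3 - 1e-9]
        order = [
            k for k in late
            if k in (EventKind.LOOSE_DETECTED, EventKind.ATKT_REENGAGED,
                     EventKind.LOW_MAP_DETECTED, EventKind.ARC_STARTED)
        ]
        assert order == [
            EventKind.LOOSE_DETECTED, EventKind.ATKT_REENGAGED,
            EventKind.LOW_MAP_DETECTED, EventKind.ARC_STARTED,
        ]

    def test_scenario5_handles_simultaneous_complications(self):
        log = run_scenario(bundled_scenario("scenario_5"), seed=1)
        t4 = log.interval_boundaries[4]
        late = [e for e in log.events if e.t >= t4 - 1e-9]
        kinds = [e.kind for e in late]
        assert EventKind.ATKT_REENGAGED in kinds
        assert EventKind.ARC_STARTED in kinds
        assert log.frame.central_map.tail(50).mean() >= 0.995 * 95.0

    @pytest.mark.parametrize("name", ["scenario_3", "scenario_5"])
    def test_no_concurrent_duplicate_subcontrollers(self, name):
        """ARC/aTKT activations never overlap an already-running instance."""
        log = run_scenario(bundled_scenario(name), seed=1)
        arc_starts = log.event_times(EventKind.ARC_STARTED)
        arc_done = log.event_times(EventKind.ARC_COMPLETED)
        assert len(arc_starts) == len(arc_done)
        for nxt, done in zip(arc_starts[1:], arc_done):
            assert nxt >= done
        tkt_start = sorted(
            log.event_times(EventKind.ATKT_REENGAGED)
        )
        tkt_done = log.event_times(EventKind.ATKT_ENGAGED)
        for s in tkt_start:
            finished_before = [d for d in tkt_done if d <= s]
            assert len(finished_before) >= 1

    def test_extremity_occluded_at_scenario_end(self, scenario2_log):
        tail = scenario2_log.frame.tail(100)
        assert (tail.cuff_pressure > 150).all()
        # no further extremity loss at the end of the run
        fb = scenario2_log.frame.fluid_balance
        assert fb.iloc[-1] == pytest.approx(fb.iloc[-100], abs=0.1)


class TestFluidBalance:
    def test_matches_vessel_volume_change(self, scenario1_log):
        """fluid_balance(t) equals v(t) - v(0) at every tick (conservation)."""
        from sacm.plant import whole_blood_curve

        frame = scenario1_log.frame
        v0 = pv_volume(95.0, whole_blood_curve())  # scenario starts at baseline
        diff = frame.fluid_balance - (frame.v_vessel - v0)
        assert np.abs(diff.to_numpy()).max() < 1e-6

    def test_quiet_scenario_is_identically_zero(self, tmp_path):
        quiet = tmp_path / "quiet.yaml"
        quiet.write_text(
            "name: quiet\nintervals:\n- until: {duration_s: 10}\n"
        )
        log = run_scenario(load_scenario(quiet), seed=0)
        assert (log.frame.fluid_balance == 0).all()

    def test_scenario1_shape(self, scenario1_log):
        """Fluid is lost during the hemorrhage/bleed intervals and recovered
        during resuscitation."""
        fb = fluid_balance(scenario1_log)
        b = scenario1_log.interval_boundaries
        t = fb.index.to_numpy()
        v = fb.to_numpy()
        end_b1 = v[t <= b[1]][-1]
        end_b2 = v[t <= b[2]][-1]
        final = v[-1]
        assert end_b1 < -100.0  # initial hemorrhage
        assert end_b2 < end_b1  # extremity bleed continues the loss
        assert final > end_b2 + 100.0  # resuscitation recovers volume
        assert final == pytest.approx(0.0, abs=35.0)


class TestBinning:
    def test_bin_structure(self, scenario1_log):
        binned = bin_intervals(scenario1_log)
        coords = binned.index.to_numpy()
        assert coords[0] == pytest.approx(0.0)
        assert coords[-1] < 3.0
        assert np.all(np.diff(coords) > 0)
        assert {
            "distal_map", "cuff_pressure", "central_map",
            "infusion_rate", "fluid_balance",
        } <= set(binned.columns)

    def test_wrong_bin_count_rejected(self, scenario1_log):
        with pytest.raises(ValueError):
            bin_intervals(scenario1_log, n_bins=5)

    def test_constant_channel_stays_constant(self, tmp_path):
        quiet = tmp_path / "quiet.yaml"
        quiet.write_text(
            "name: quiet\nintervals:\n"
            "- until: {duration_s: 5}\n- until: {duration_s: 5}\n"
        )
        log = run_scenario(load_scenario(quiet), seed=0)
        binned = bin_intervals(log, n_bins=2)
        assert (binned.fluid_balance == 0).all()


class TestHeatmap:
    def test_constant_max_trace_is_all_ones(self):
        trace = [(float(t), 1200.0) for t in range(10)]
        m, meta = export_heatmap([trace])
        assert m.shape == (1, 10)
        assert np.allclose(m, 1.0)

    def test_mixed_lengths_padded_to_longest(self):
        short = [(0.0, 600.0), (4.0, 600.0)]
        long = [(0.0, 300.0), (9.0, 300.0)]
        m, meta = export_heatmap([short, long])
        assert m.shape == (2, 10)
        assert meta["longest_duration_s"] == 9.0
        assert np.allclose(m[0, :5], 0.5)
        assert np.allclose(m[0, 5:], 0.0)  # padded after completion
        assert np.allclose(m[1], 0.25)

    def test_normalization_round_trips(self):
        trace = [(0.0, 480.0), (5.0, 480.0)]
        m, meta = export_heatmap([trace])
        assert np.allclose(m * meta["q_max_ml_min"], 480.0)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            export_heatmap([])


class TestArcMatrix:
    def test_eight_conditions(self):
        assert len(ARC_TEST_MATRIX) == 8
        wb = [k for k, v in ARC_TEST_MATRIX.items() if v["infusate"] == "whole_blood"]
        cr = [k for k, v in ARC_TEST_MATRIX.items() if v["infusate"] == "crystalloid"]
        assert len(wb) == 6 and len(cr) == 2
        sfs = {v["scaling_factor"] for v in ARC_TEST_MATRIX.values()}
        assert sfs == {0.5, 1.0, 2.0}
        hems = {v["hem_rate"] for v in ARC_TEST_MATRIX.values()}
        assert hems == {0.0, 120.0, 240.0, 360.0}

    def test_condition_runs_and_crystalloid_is_slower(self):
        wb = run_arc_condition("wb_baseline", seed=0)
        cr = run_arc_condition("cryst_baseline", seed=0)
        assert wb.reached_target and cr.reached_target
        # >2x fluid capacity means more volume and a longer infusion
        assert cr.total_infused > 2 * wb.total_infused
        assert cr.duration > wb.duration

    def test_unknown_condition_rejected(self):
        with pytest.raises(ValueError):
            run_arc_condition("nope")
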