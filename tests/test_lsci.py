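"""Spatial speckle-contrast flowmetry and the guidance state machine."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from strokelab import lsci
from strokelab.synthetic import gen_speckle_stack
from strokelab.synthetic.phantoms import FlowPhantom


def _uniform_stack(tau_c=1e-4, shape=(48, 48), n_frames=8, seed=0):
    ph = FlowPhantom(tau_c_map=np.full(shape, tau_c),
                     vessel_mask=np.zeros(shape, bool),
                     region_labels=np.zeros(shape, np.int8))
    return gen_speckle_stack(ph, n_frames=n_frames, seed=seed)


class TestSpatialContrast:
    def test_constant_frame_has_zero_contrast(self):
        cmap = lsci.spatial_contrast(np.full((20, 20), 7.0))
        assert np.all(cmap.K == 0.0)

    def test_checkerboard_hand_value(self):
        # 7x7 window over a {0, 2} checkerboard: 25 zeros and 24 twos,
        # mean 48/49, population sigma sqrt(2400)/49, K = sqrt(2400)/48
        yy, xx = np.mgrid[0:9, 0:9]
        frame = 2.0 * ((yy + xx) % 2)
        cmap = lsci.spatial_contrast(frame, window=7)
        assert cmap.K[4, 4] == pytest.approx(np.sqrt(2400.0) / 48.0,
                                             rel=1e-12)

    def test_fully_developed_speckle_contrast_near_one(self):
        stack = _uniform_stack(tau_c=100.0, shape=(256, 256), n_frames=1)
        k = lsci.spatial_contrast(stack.frames[0]).K
        assert np.nanmean(k ** 2) == pytest.approx(1.0, abs=0.06)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(c=st.floats(min_value=1e-3, max_value=1e3))
    def test_scale_invariance(self, c):
        rng = np.random.default_rng(0)
        frame = rng.exponential(size=(24, 24))
        k1 = lsci.spatial_contrast(frame).K
        k2 = lsci.spatial_contrast(c * frame).K
        assert np.allclose(k1, k2, rtol=1e-8)

    def test_masked_border_policy(self):
        rng = np.random.default_rng(0)
        k = lsci.spatial_contrast(rng.exponential(size=(16, 16)),
                                  border="mask").K
        assert np.all(np.isnan(k[:3, :])) and np.all(np.isnan(k[:, -3:]))
        assert np.all(np.isfinite(k[3:-3, 3:-3]))

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            lsci.spatial_contrast(np.ones((5, 5)), window=7)
        with pytest.raises(ValueError):
            lsci.spatial_contrast(np.ones((16, 16)), window=6)
        with pytest.raises(ValueError):
            lsci.spatial_contrast(np.ones(16))


class TestBloodFlowIndex:
    def test_inverse_square_arithmetic(self):
        cmap = lsci.ContrastMap(K=np.array([[1.0, 0.5]]))
        bfi = lsci.blood_flow_index(cmap).bfi
        assert bfi[0, 0] == 1.0 and bfi[0, 1] == 4.0

    def test_low_contrast_masked_not_infinite(self):
        cmap = lsci.ContrastMap(K=np.array([[0.0, 1e-6]]))
        bfi = lsci.blood_flow_index(cmap, k_floor=1e-3).bfi
        assert np.all(np.isnan(bfi))

    def test_k_floor_must_be_positive(self):
        with pytest.raises(ValueError):
            lsci.blood_flow_index(lsci.ContrastMap(K=np.ones((2, 2))),
                                  k_floor=0.0)


class TestRelativeCBF:
    def test_baseline_against_itself_is_100_percent(self):
        stack = _uniform_stack(n_frames=8)
        roi = {"all": np.ones((48, 48), bool)}
        _, traces = lsci.relative_cbf(stack, (0.0, stack.n_frames / 40.0),
                                      roi, smooth_s=0.0)
        assert traces.percent_baseline.mean() == pytest.approx(100.0,
                                                               rel=1e-9)

    def test_gap_intervals_are_missing_not_interpolated(self):
        stack = _uniform_stack(n_frames=16)
        roi = {"all": np.ones((48, 48), bool)}
        maps, traces = lsci.relative_cbf(stack, (0.0, 0.1), roi,
                                         gaps=[(0.2, 0.3)])
        t = traces.t_s.to_numpy()
        in_gap = (t >= 0.2) & (t < 0.3)
        assert in_gap.sum() > 0
        assert traces.percent_baseline[in_gap].isna().all()
        assert traces.percent_baseline[~in_gap].notna().all()
        assert np.all(np.isnan(maps[in_gap]))

    def test_empty_baseline_rejected(self):
        stack = _uniform_stack(n_frames=4)
        with pytest.raises(ValueError):
            lsci.relative_cbf(stack, (5.0, 6.0), {})

    def test_roi_shape_mismatch_rejected(self):
        stack = _uniform_stack(n_frames=4)
        with pytest.raises(ValueError):
            lsci.relative_cbf(stack, (0.0, 0.1),
                              {"bad": np.ones((3, 3), bool)})


def _step_traces(length=700, occl_at=60, occl_level=15.0,
                 recan=None, region_level=35.0):
    t = np.arange(float(length))
    vessel = np.full(length, 100.0)
    vessel[occl_at:] = occl_level
    if recan is not None:
        r0, r1, level = recan
        vessel[r0:r1] = level
    region = np.where(vessel < 50, region_level, 100.0)
    return vessel, region, t


class TestOcclusionGuidance:
    def test_no_occlusion_stays_full_and_unconfirmed(self):
        t = np.arange(600.0)
        trace = lsci.occlusion_guidance(np.full(600, 100.0),
                                        np.full(600, 100.0), t)
        assert list(trace.events.state) == ["FULL"]
        assert not trace.occlusion_confirmed

    def test_step_occlusion_hand_walk(self):
        # drop to 15% at t=60 held: 5 consecutive 1-s samples of >=80% drop
        # complete at t=64, half-power holds 120 s, off at t=184
        vessel, region, t = _step_traces()
        trace = lsci.occlusion_guidance(vessel, region, t)
        events = list(zip(trace.events.t_s, trace.events.state))
        assert events == [(0.0, "FULL"), (64.0, "HALF"), (184.0, "OFF")]
        assert trace.occlusion_confirmed
        assert list(trace.events.power_mw) == [0.6, 0.3, 0.0]

    def test_recanalization_rearms_and_reoccludes(self):
        # flow returns to 90% at t=400..449, then occludes again
        vessel, region, t = _step_traces(recan=(400, 450, 90.0))
        trace = lsci.occlusion_guidance(vessel, region, t)
        events = list(zip(trace.events.t_s, trace.events.state))
        assert events == [(0.0, "FULL"), (64.0, "HALF"), (184.0, "OFF"),
                          (404.0, "FULL"), (454.0, "HALF"), (574.0, "OFF")]

    def test_region_criterion_required_for_confirmation(self):
        vessel, _, t = _step_traces()
        region = np.full(len(t), 100.0)  # supplied region never drops
        trace = lsci.occlusion_guidance(vessel, region, t)
        assert not trace.occlusion_confirmed
        assert "HALF" in set(trace.events.state)  # still drives the laser

    def test_half_intervals_never_shorter_than_hold(self):
        vessel, region, t = _step_traces(recan=(400, 450, 90.0))
        trace = lsci.occlusion_guidance(vessel, region, t)
        ev = trace.events
        for i in range(len(ev) - 1):
            if ev.iloc[i].state == "HALF":
                assert ev.iloc[i + 1].t_s - ev.iloc[i].t_s >= 120.0

    def test_optimized_full_time_bounded_by_fixed_protocol(self):
        vessel, region, t = _step_traces()
        trace = lsci.occlusion_guidance(vessel, region, t)
        full_s = trace.total_time_in(lsci.LaserState.FULL, t[-1])
        assert full_s <= 900.0

    def test_gap_samples_satisfy_no_criterion(self):
        # a gap right at the occlusion delays the debounce: the five
        # consecutive valid samples only complete at t=74
        vessel, region, t = _step_traces()
        vessel[60:70] = np.nan
        trace = lsci.occlusion_guidance(vessel, region, t)
        events = list(zip(trace.events.t_s, trace.events.state))
        assert events[:2] == [(0.0, "FULL"), (74.0, "HALF")]

    def test_mismatched_clocks_rejected(self):
        with pytest.raises(ValueError):
            lsci.occlusion_guidance(np.ones(10), np.ones(9), np.arange(10.0))
        t_bad = np.array([0.0, 1.0, 2.0, 4.0, 5.0])
        with pytest.raises(ValueError):
            lsci.occlusion_guidance(np.ones(5), np.ones(5), t_bad)


class TestNonoptimizedProtocol:
    def test_default_is_15_minutes_full(self):
        trace = lsci.nonoptimized_protocol()
        assert list(zip(trace.events.t_s, trace.events.state)) == [
            (0.0, "FULL"), (900.0, "OFF")]

    def test_zero_duration_flagged(self):
        trace = lsci.nonoptimized_protocol(0.0)
        assert trace.flags and list(trace.events.state) == ["OFF"]

    def test_deterministic(self):
        a, b = lsci.nonoptimized_protocol(300), lsci.nonoptimized_protocol(300)
        pd.testing.assert_frame_equal(a.events, b.events)


def test_field_of_view_closed_form():
    assert lsci.field_of_view_mm(2048, 5.5, 2.0) == pytest.approx(5.632)
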