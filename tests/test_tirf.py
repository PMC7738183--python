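"""TIRF photometry: filtering, detection, segmentation, model fit, modes."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial import cKDTree

from granulekit import synthetic, tirf

from conftest import noisy_event_trace


class TestPreprocess:
    def test_window_one_is_identity(self):
        stack = np.random.default_rng(0).poisson(50, (20, 8, 8))
        assert np.array_equal(tirf.preprocess(stack, 1), stack.astype(float))

    def test_constant_stack_unchanged(self):
        stack = np.full((11, 4, 4), 7.0)
        assert np.allclose(tirf.preprocess(stack, 5), stack)

    def test_alternating_series_interior_average(self):
        series = np.tile([0.0, 2.0], 10)
        stack = series[:, None, None] * np.ones((1, 1))
        out = tirf.preprocess(stack, 3)[:, 0, 0]
        # windows centred on the 2-valued frames average (0+2+0)/3, and on
        # interior 0-valued frames (2+0+2)/3
        assert np.allclose(out[1:-1:2], 2 / 3)
        assert np.allclose(out[2:-1:2], 4 / 3)

    def test_edges_use_shrunk_window(self):
        stack = np.arange(6, dtype=float)[:, None, None] * np.ones((1, 1))
        out = tirf.preprocess(stack, 3)[:, 0, 0]
        assert out[0] == pytest.approx(0.5)  # mean of frames 0..1
        assert out[-1] == pytest.approx(4.5)

    @pytest.mark.parametrize("window", [0, 2, 99])
    def test_invalid_window_raises(self, window):
        with pytest.raises(ValueError):
            tirf.preprocess(np.zeros((10, 4, 4)), window)


class TestDetect:
    def test_background_only_yields_no_detections(self):
        stack = np.random.default_rng(1).poisson(100, (100, 64, 64)).astype(float)
        assert len(tirf.detect(stack).centers) == 0

    def test_spots_detected_within_one_pixel(self, small_stack):
        stack, truth = small_stack
        det = tirf.detect(tirf.preprocess(stack, 3))
        tree = cKDTree(truth[["x_px", "y_px"]].to_numpy())
        dd, ii = tree.query(det.centers)
        assert len(det.centers) == len(truth)
        assert np.all(dd < 1.0)
        assert len(set(ii)) == len(truth)

    def test_nearby_spots_merge_to_one(self):
        img = np.zeros((1, 40, 40))
        for cx, amp in [(20, 100.0), (22, 60.0)]:
            yy, xx = np.mgrid[0:40, 0:40]
            img[0] += amp * np.exp(-(((xx - cx) ** 2) + (yy - 20) ** 2) / (2 * 1.2**2))
        det = tirf.detect(img, min_separation=4.0)
        assert len(det.centers) == 1

    def test_empty_stack_raises(self):
        with pytest.raises(ValueError):
            tirf.detect(np.empty((0, 4, 4)))


class TestExtractTraces:
    def test_uniform_image_gives_zero_after_background_subtraction(self):
        stack = np.full((30, 32, 32), 55.0)
        tr = tirf.extract_traces(stack, np.array([[16.0, 16.0]]))[0]
        assert np.allclose(tr.values, 0.0)

    def test_center_at_edge_raises(self):
        stack = np.zeros((10, 32, 32))
        with pytest.raises(ValueError):
            tirf.extract_traces(stack, np.array([[1.0, 16.0]]))


class TestSegmentEvent:
    def test_flat_noisy_trace_has_no_event(self):
        rng = np.random.default_rng(0)
        tr = tirf.IntensityTrace(1000 + rng.normal(0, 20, 300), 0.05, (0, 0))
        assert tirf.segment_event(tr) is None

    def test_noiseless_trace_onset_exact(self, syt7_pop):
        ev = synthetic.event_params(syt7_pop, onset_s=5.0)
        vals, _ = synthetic.simulate_trace(ev, 0.05, 400, 0.0)
        onset, end = tirf.segment_event(tirf.IntensityTrace(vals, 0.05, (0, 0)))
        assert onset == 100

    def test_noisy_onset_within_two_frames_95pct(self, syt7_pop, syt9_pop):
        hits = n = 0
        for pop in (syt7_pop, syt9_pop):
            for seed in range(100):
                tr, truth = noisy_event_trace(pop, seed)
                seg = tirf.segment_event(tr)
                if seg is None:
                    continue
                n += 1
                hits += abs(seg[0] - truth["onset_s"] / 0.05) <= 2
        assert n >= 190
        assert hits / n >= 0.95

    def test_short_trace_raises(self):
        with pytest.raises(ValueError):
            tirf.segment_event(tirf.IntensityTrace(np.ones(10), 0.05, (0, 0)))


class TestFitRelease:
    def test_noiseless_fit_is_exact(self, syt7_pop):
        ev = synthetic.event_params(syt7_pop, onset_s=5.0)
        vals, truth = synthetic.simulate_trace(ev, 0.05, 400, 0.0)
        tr = tirf.IntensityTrace(vals, 0.05, (0, 0))
        fe = tirf.fit_release(tr, tirf.segment_event(tr))
        assert fe.delta_ic == pytest.approx(truth["delta_ic"], rel=1e-6)
        assert fe.i_dock == pytest.approx(1000.0, rel=1e-6)
        assert fe.pore_rate == pytest.approx(syt7_pop.pore_rate, rel=1e-6)
        assert fe.post_rate == pytest.approx(syt7_pop.post_rate, rel=1e-6)

    def test_zero_gain_trace_fits_near_zero_step(self, syt7_pop):
        from dataclasses import replace

        ev = synthetic.event_params(replace(syt7_pop, collapse_gain=0.0), onset_s=3.0)
        vals, _ = synthetic.simulate_trace(ev, 0.05, 400, noise_sd=15.0, seed=4)
        tr = tirf.IntensityTrace(vals, 0.05, (0, 0))
        fe = tirf.fit_release(tr, tirf.segment_event(tr))
        assert fe.delta_ic < 3 * 15.0

    @pytest.mark.parametrize("pop_fixture", ["syt7_pop", "syt9_pop"])
    def test_mean_delta_ic_recovered_within_10pct(self, pop_fixture, request):
        pop = request.getfixturevalue(pop_fixture)
        fits, trues = [], []
        for seed in range(100):
            tr, truth = noisy_event_trace(pop, seed)
            seg = tirf.segment_event(tr)
            if seg is None:
                continue
            fits.append(tirf.fit_release(tr, seg).delta_ic)
            trues.append(truth["delta_ic"])
        assert np.mean(fits) == pytest.approx(np.mean(trues), rel=0.10)


class TestClassifyModes:
    def _events(self, deltas):
        return [tirf.FusionEvent(0, 1, max(d, 0.0), 1, 1, 1000, 1.0) for d in deltas]

    def test_bimodal_events_classified_correctly(self, syt7_pop, syt9_pop):
        rng = np.random.default_rng(0)
        d_slow = synthetic.event_params(syt7_pop, 1.0).delta_ic
        d_fast = synthetic.event_params(syt9_pop, 1.0).delta_ic
        deltas = np.r_[rng.normal(d_slow, 18, 250), rng.normal(d_fast, 20, 250)]
        labels = ["slow"] * 250 + ["fast"] * 250
        events, report = tirf.classify_modes(self._events(deltas))
        acc = np.mean([e.mode == lab for e, lab in zip(events, labels)])
        assert not report["degenerate"]
        assert acc >= 0.95

    def test_single_population_collapses_to_one_label(self):
        rng = np.random.default_rng(1)
        events, report = tirf.classify_modes(self._events(rng.normal(110, 18, 100)))
        assert report["degenerate"]
        assert {e.mode for e in events} == {"slow"}
        events, report = tirf.classify_modes(self._events(rng.normal(294, 20, 100)))
        assert {e.mode for e in events} == {"fast"}

    def test_too_few_events_raises(self):
        with pytest.raises(ValueError):
            tirf.classify_modes(self._events(np.ones(5)))


class TestCentroidDrift:
    def _spot_stack(self, shift):
        yy, xx = np.mgrid[0:32, 0:32]
        early = np.exp(-(((xx - 16) ** 2) + (yy - 16) ** 2) / (2 * 1.2**2))
        late = np.exp(-(((xx - 16 - shift) ** 2) + (yy - 16) ** 2) / (2 * 1.2**2))
        return np.concatenate([np.tile(100 * early, (10, 1, 1)),
                               np.tile(100 * late, (10, 1, 1))])

    def test_static_spot_has_negligible_drift(self):
        d = tirf.centroid_drift(self._spot_stack(0), (16, 16), slice(0, 10), slice(10, 20))
        assert d < 0.1

    def test_shifted_spot_exceeds_exclusion_cut(self):
        d = tirf.centroid_drift(self._spot_stack(2), (16, 16), slice(0, 10), slice(10, 20))
        assert d > 1.0  # moved well beyond measurement noise

    def test_window_at_edge_raises(self):
        with pytest.raises(ValueError):
            tirf.centroid_drift(self._spot_stack(0), (1, 16), slice(0, 10), slice(10, 20))


class TestDurationsAndDocking:
    def test_per_cell_means(self):
        df = tirf.release_durations_by_cell({"c1": [1.0, 2.0, 3.0], "c2": [4.0]})
        assert df.set_index("cell").loc["c1", "mean_s"] == pytest.approx(2.0)
        assert df.attrs["group_mean_s"] == pytest.approx(3.0)

    def test_fast_scenario_shorter_than_slow(self, syt7_pop, syt9_pop):
        # strong depolarisation recruits the fast syt9 mode; mild only slow
        fast = synthetic.event_params(syt9_pop, 1.0).duration
        slow = synthetic.event_params(syt7_pop, 1.0).duration
        assert fast < slow

    def test_empty_group_raises(self):
        with pytest.raises(ValueError):
            tirf.release_durations_by_cell({})

    @pytest.mark.parametrize("count,ref,expect", [(50, 50, 1.0), (25, 50, 0.5), (0, 50, 0.0)])
    def test_docking_normalization(self, count, ref, expect):
        assert tirf.normalize_docking(count, ref) == pytest.approx(expect)

    def test_zero_reference_raises(self):
        with pytest.raises(ValueError):
            tirf.normalize_docking(5, 0)


class TestManders:
    def test_identical_masks_give_unity(self):
        img = np.zeros((10, 10))
        img[2:5, 2:5] = 7.0
        m1, m2 = tirf.manders(img, img, thr_a=1.0, thr_b=1.0)
        assert (m1, m2) == (1.0, 1.0)

    def test_disjoint_masks_give_zero(self):
        a = np.zeros((10, 10))
        b = np.zeros((10, 10))
        a[0:3, 0:3] = 5.0
        b[6:9, 6:9] = 5.0
        m1, m2 = tirf.manders(a, b, thr_a=1.0, thr_b=1.0)
        assert (m1, m2) == (0.0, 0.0)

    def test_partial_overlap_worked_example(self):
        a = np.zeros((2, 2))
        a[0, 0], a[0, 1] = 10.0, 30.0
        b = np.zeros((2, 2))
        b[0, 1] = 5.0
        m1, _ = tirf.manders(a, b, thr_a=1.0, thr_b=1.0)
        assert m1 == pytest.approx(0.75)

    def test_all_zero_channel_raises(self):
        with pytest.raises(ValueError):
            tirf.manders(np.zeros((4, 4)), np.ones((4, 4)))

    @given(scale=st.floats(min_value=0.01, max_value=100.0))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_invariant_to_positive_channel_scaling(self, scale):
        rng = np.random.default_rng(3)
        a = rng.uniform(0, 10, (16, 16))
        b = rng.uniform(0, 10, (16, 16))
        m = tirf.manders(a, b, thr_a=5.0, thr_b=5.0)
        ms = tirf.manders(a * scale, b, thr_a=5.0 * scale, thr_b=5.0)
        assert ms == pytest.approx(m, rel=1e-9)


class TestPipelineDeterminism:
    def test_same_stack_and_config_give_identical_event_table(self, small_stack):
        stack, _ = small_stack

        def table():
            filt = tirf.preprocess(stack, 3)
            det = tirf.detect(filt)
            traces = tirf.extract_traces(filt, det.centers, frame_interval=0.05)
            rows = []
            for tr in traces:
                seg = tirf.segment_event(tr)
                if seg:
                    fe = tirf.fit_release(tr, seg)
                    rows.append((fe.onset_frame, fe.collapse_frame, fe.delta_ic))
            return rows

        assert table() == table()
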