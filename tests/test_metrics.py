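"""I-VT classification, heatmaps and accuracy reports."""

import numpy as np
import pytest

from camgaze.errors import MetricsError
from camgaze.geometry import ScreenGeometry, visual_angle_error
from camgaze.metrics import (IVTConfig, accuracy_report, build_heatmap,
                             fixation_count, fixation_stats, ivt_classify)
from camgaze.tracker import GazeSample

SCREEN = ScreenGeometry(1920, 1080, 480.0, 270.0, 500.0)


def make_samples(points, rate=30.0, t0=0.0, valid=None):
    samples = []
    for i, p in enumerate(points):
        s = GazeSample(timestamp=t0 + i / rate, gaze=np.asarray(p, dtype=float),
                       gaze_left=np.asarray(p, dtype=float),
                       gaze_right=np.asarray(p, dtype=float),
                       head_state="fixed", reference_point=np.zeros(2))
        if valid is not None and not valid[i]:
            s.valid = False
        samples.append(s)
    return samples


def brute_force_ivt(samples, screen, config):
    """Independent velocity-threshold oracle: pairwise velocities, then
    segment-and-filter, written without reference to the implementation."""
    n = len(samples)
    labels = ["invalid"] * n
    valid = [i for i, s in enumerate(samples) if s.valid]
    if not valid:
        return labels, []
    dts = [samples[valid[k + 1]].timestamp - samples[valid[k]].timestamp
           for k in range(len(valid) - 1)]
    nominal = float(np.median(dts)) if dts else 0.0
    # split into gap-free runs of consecutive valid samples
    runs, cur = [], [valid[0]]
    for k in range(1, len(valid)):
        gap = samples[valid[k]].timestamp - samples[valid[k - 1]].timestamp
        if valid[k] != valid[k - 1] + 1 or gap > config.gap_factor * nominal:
            runs.append(cur)
            cur = []
        cur.append(valid[k])
    runs.append(cur)
    events = []
    for run in runs:
        if len(run) == 1:
            labels[run[0]] = "fixation"
            continue
        vel = [None]
        for k in range(1, len(run)):
            a, b = samples[run[k - 1]], samples[run[k]]
            ang = visual_angle_error(b.gaze, a.gaze, screen)
            vel.append(ang / (b.timestamp - a.timestamp))
        for k, i in enumerate(run):
            v = vel[k] if k > 0 else vel[1]
            labels[i] = "saccade" if v > config.velocity_threshold_deg_s \
                else "fixation"
        # collect fixation events
        k = 0
        while k < len(run):
            if labels[run[k]] != "fixation":
                k += 1
                continue
            j = k
            while j + 1 < len(run) and labels[run[j + 1]] == "fixation":
                j += 1
            dur = samples[run[j]].timestamp - samples[run[k]].timestamp
            if dur >= config.min_fixation_s:
                events.append((samples[run[k]].timestamp,
                               samples[run[j]].timestamp, j - k + 1))
            k = j + 1
    return labels, events


class TestIVT:
    def test_stationary_stream_is_one_fixation(self):
        samples = make_samples([(500.0, 400.0)] * 60)
        labels, events = ivt_classify(samples, SCREEN)
        assert all(l == "fixation" for l in labels)
        assert len(events) == 1
        assert events[0].duration_s == pytest.approx(59 / 30)
        assert np.allclose(events[0].centroid, (500.0, 400.0))

    def test_two_clusters_with_jump(self):
        pts = [(400.0, 500.0)] * 30 + [(1000.0, 500.0)] * 30
        samples = make_samples(pts)
        labels, events = ivt_classify(samples, SCREEN)
        assert len(events) == 2
        assert labels[30] == "saccade"  # the first sample after the jump
        assert np.allclose(events[0].centroid, (400.0, 500.0))
        assert np.allclose(events[1].centroid, (1000.0, 500.0))

    def test_fast_sweep_has_no_fixations(self):
        # 3000 px/s = 750 mm/s at 0.25 mm/px -> far above 30 deg/s at 500 mm
        pts = [(100.0 + 100.0 * i, 500.0) for i in range(40)]
        samples = make_samples(pts)
        labels, events = ivt_classify(samples, SCREEN)
        assert events == []
        assert all(l == "saccade" for l in labels)

    def test_matches_brute_force_oracle_on_random_walks(self):
        config = IVTConfig()
        rng = np.random.default_rng(42)
        for _ in range(20):
            n = int(rng.integers(20, 90))
            steps = rng.normal(0, 12, size=(n, 2))
            # occasional large jumps to create saccades
            jumps = rng.random(n) < 0.08
            steps[jumps] += rng.normal(0, 400, size=(jumps.sum(), 2))
            pts = np.cumsum(steps, axis=0) + SCREEN.center_px
            valid = rng.random(n) > 0.05
            samples = make_samples(pts, valid=valid)
            labels, events = ivt_classify(samples, SCREEN, config)
            exp_labels, exp_events = brute_force_ivt(samples, SCREEN, config)
            assert labels == exp_labels
            assert len(events) == len(exp_events)
            for ev, (s, e, ns) in zip(events, exp_events):
                assert ev.start_s == pytest.approx(s)
                assert ev.end_s == pytest.approx(e)
                assert ev.n_samples == ns

    def test_threshold_monotonicity(self):
        rng = np.random.default_rng(7)
        pts = np.cumsum(rng.normal(0, 40, size=(150, 2)), axis=0) + 960.0
        samples = make_samples(pts)
        counts = []
        for thr in (5.0, 15.0, 30.0, 60.0, 120.0):
            labels, _ = ivt_classify(samples, SCREEN,
                                     IVTConfig(velocity_threshold_deg_s=thr))
            counts.append(labels.count("fixation"))
        assert all(b >= a for a, b in zip(counts, counts[1:]))

    def test_invariance_to_time_shift_and_translation(self):
        rng = np.random.default_rng(3)
        pts = np.cumsum(rng.normal(0, 30, size=(80, 2)), axis=0) + 960.0
        base, _ = ivt_classify(make_samples(pts), SCREEN)
        shifted, _ = ivt_classify(make_samples(pts, t0=1234.5), SCREEN)
        translated, _ = ivt_classify(make_samples(pts + (55.0, -20.0)), SCREEN)
        assert base == shifted == translated

    def test_fixation_count_and_stats(self):
        assert fixation_count([]) == 0
        samples = make_samples([(400.0, 500.0)] * 30 + [(1000.0, 500.0)] * 30)
        _, events = ivt_classify(samples, SCREEN)
        assert fixation_count(events) == 2
        stats = fixation_stats(events)
        assert stats["count"] == 2
        # first run spans samples 0..29, second 31..59 (30 is the saccade)
        assert stats["mean_duration_s"] == pytest.approx(
            (29 / 30 + 28 / 30) / 2, abs=1e-9)


class TestHeatmap:
    def test_normalized_mass(self):
        samples = make_samples([(300.0, 300.0)] * 5 + [(1500.0, 800.0)] * 3)
        grid = build_heatmap(samples, SCREEN, grid_downsample=4)
        assert grid.values.min() >= 0
        assert grid.values.sum() == pytest.approx(1.0, abs=1e-9)

    def test_single_point_argmax(self):
        samples = make_samples([(480.0, 270.0)] * 10)
        grid = build_heatmap(samples, SCREEN, grid_downsample=2)
        iy, ix = np.unravel_index(np.argmax(grid.values), grid.values.shape)
        assert ix == 240 and iy == 135

    def test_two_equal_clusters_equal_mass(self):
        samples = make_samples([(400.0, 540.0)] * 20 + [(1500.0, 540.0)] * 20)
        grid = build_heatmap(samples, SCREEN, sigma_px=30.0, grid_downsample=4)
        mid = grid.values.shape[1] // 2
        left, right = grid.values[:, :mid].sum(), grid.values[:, mid:].sum()
        assert abs(left - right) / max(left, right) < 0.01

    def test_concatenation_is_weighted_mixture(self):
        a = make_samples([(400.0, 400.0)] * 12)
        b = make_samples([(1400.0, 700.0)] * 36, t0=10.0)
        ua = build_heatmap(a, SCREEN, grid_downsample=8, normalize=False).values
        ub = build_heatmap(b, SCREEN, grid_downsample=8, normalize=False).values
        uab = build_heatmap(a + b, SCREEN, grid_downsample=8,
                            normalize=False).values
        # unnormalized heatmaps are additive
        assert np.allclose(uab, ua + ub, atol=1e-12)
        # normalized concatenation = mass-weighted mixture of the parts
        ga = build_heatmap(a, SCREEN, grid_downsample=8).values
        gb = build_heatmap(b, SCREEN, grid_downsample=8).values
        gab = build_heatmap(a + b, SCREEN, grid_downsample=8).values
        wa = ua.sum() / (ua.sum() + ub.sum())
        assert np.allclose(gab, wa * ga + (1 - wa) * gb, atol=1e-12)

    def test_empty_input_rejected(self):
        with pytest.raises(MetricsError):
            build_heatmap([], SCREEN)


class TestAccuracyReport:
    def test_perfect_predictions(self):
        pts = [(200.0, 200.0), (1700.0, 900.0), (960.0, 540.0)]
        samples = make_samples(pts)
        report = accuracy_report(samples, np.array(pts), SCREEN)
        o = report["overall"]
        assert o["mean_error_deg"] == 0.0
        assert o["rmse_x_px"] == 0.0 and o["rmse_y_px"] == 0.0

    def test_constant_x_offset(self):
        truth = np.array([(500.0, 500.0)] * 10)
        samples = make_samples(truth + (3.0, 0.0))
        report = accuracy_report(samples, truth, SCREEN)
        assert report["overall"]["rmse_x_px"] == pytest.approx(3.0)
        assert report["overall"]["rmse_y_px"] == 0.0

    def test_rmse_matches_direct_formula(self):
        rng = np.random.default_rng(5)
        truth = rng.uniform(100, 1800, size=(200, 2))
        resid = rng.normal(0, 12, size=(200, 2))
        samples = make_samples(truth + resid)
        report = accuracy_report(samples, truth, SCREEN)
        assert report["overall"]["rmse_x_px"] == pytest.approx(
            np.sqrt(np.mean(resid[:, 0] ** 2)), abs=1e-12)
        assert report["overall"]["rmse_y_px"] == pytest.approx(
            np.sqrt(np.mean(resid[:, 1] ** 2)), abs=1e-12)

    def test_region_assignment_uses_truth_quadrant(self):
        truth = np.array([(100.0, 100.0), (1800.0, 100.0),
                          (100.0, 1000.0), (1800.0, 1000.0)])
        samples = make_samples(truth)
        report = accuracy_report(samples, truth, SCREEN)
        assert sorted(report["per_region"]) == ["0", "1", "2", "3"]
        assert all(v["n_samples"] == 1 for v in report["per_region"].values())

    def test_empty_overlap_rejected(self):
        samples = make_samples([(100.0, 100.0)])
        samples[0].valid = False
        with pytest.raises(MetricsError):
            accuracy_report(samples, np.array([[100.0, 100.0]]), SCREEN)
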