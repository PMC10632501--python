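"""Evaluation statistics: center-based AP, mAP, MOTA bookkeeping, pose error, ACR."""

import numpy as np
import pandas as pd
import pytest

from synthrig.metrics import (
    APConfig, MOTAConfig, UndefinedMetricError, acr, average_precision,
    mean_average_precision, mota, pose_error, simulate_detections, simulate_tracks,
    tracks_to_gt_detections,
)


def ap_bruteforce(detections, gt, width, thresholds):
    """Independent AP oracle: explicit loop enumeration at every threshold."""
    tol = 0.05 * width
    ap, prev_r = 0.0, 0.0
    for tau in thresholds:
        dets = [(np.asarray(c), s) for c, s in detections if s >= tau]
        dets.sort(key=lambda t: -t[1])
        taken = [False] * len(gt)
        tp = 0
        for c, _ in dets:
            best, bd = -1, np.inf
            for j, g in enumerate(gt):
                if taken[j]:
                    continue
                d = float(np.linalg.norm(np.asarray(g) - c))
                if d < bd:
                    best, bd = j, d
            if best >= 0 and bd <= tol:
                taken[best] = True
                tp += 1
        p = tp / len(dets) if dets else 1.0
        r = tp / len(gt) if dets else 0.0
        ap += (r - prev_r) * p
        prev_r = r
    return ap


class TestAveragePrecision:
    def test_perfect_detections_score_unity(self):
        gt = np.array([[100.0, 100], [500, 500]])
        dets = [(g, 0.9) for g in gt]
        res = average_precision(dets, gt, 1000.0)
        assert res.ap == 1.0

    def test_no_detections_score_zero(self):
        res = average_precision([], np.array([[10.0, 10]]), 1000.0)
        assert res.ap == 0.0
        assert np.all(res.precision == 1.0)  # seed precision at empty thresholds

    def test_hand_enumerated_mixed_case(self):
        # 2 gt; TP at 0.7, FP at 0.7, TP at 0.3
        gt = np.array([[100.0, 100], [500, 500]])
        dets = [(np.array([101.0, 100]), 0.7), (np.array([900.0, 900]), 0.7),
                (np.array([501.0, 500]), 0.3)]
        res = average_precision(dets, gt, 1000.0)
        # thresholds > 0.7: P=1 (no dets), R=0; 0.7 >= tau > 0.3: P=1/2, R=1/2;
        # tau <= 0.3: P=2/3, R=1  ->  AP = 0.5*0.5 + 0.5*(2/3)
        assert np.isclose(res.ap, 0.25 + 0.5 * 2 / 3)

    def test_matches_bruteforce_oracle_on_random_instances(self):
        r = np.random.default_rng(123)
        cfg = APConfig()
        for _ in range(100):
            n_gt = int(r.integers(1, 11))
            n_det = int(r.integers(0, 21))
            gt = r.uniform(0, 1000, (n_gt, 2))
            dets = [(r.uniform(0, 1000, 2), float(r.uniform(0.1, 1.0))) for _ in range(n_det)]
            got = average_precision(dets, gt, 1000.0, cfg).ap
            expect = ap_bruteforce(dets, gt, 1000.0, cfg.thresholds)
            assert got == expect

    def test_detection_order_invariance(self, rng):
        gt = rng.uniform(0, 500, (5, 2))
        dets = [(rng.uniform(0, 500, 2), float(rng.uniform(0.2, 1))) for _ in range(12)]
        a = average_precision(dets, gt, 500.0).ap
        b = average_precision(dets[::-1], gt, 500.0).ap
        assert a == b

    def test_lowering_fp_confidence_below_thresholds_cannot_hurt(self, rng):
        gt = np.array([[100.0, 100]])
        dets = [(np.array([100.0, 100]), 0.9), (np.array([400.0, 400]), 0.5)]
        hi = average_precision(dets, gt, 1000.0).ap
        dets[1] = (dets[1][0], 0.05)  # drop the false positive below all thresholds
        lo = average_precision(dets, gt, 1000.0).ap
        assert lo >= hi

    def test_empty_ground_truth_rejected(self):
        with pytest.raises(UndefinedMetricError):
            average_precision([], np.zeros((0, 2)), 100.0)

    def test_recall_monotone_along_descending_thresholds(self, rng):
        gt = rng.uniform(0, 800, (6, 2))
        dets = [(rng.uniform(0, 800, 2), float(rng.uniform(0.2, 1))) for _ in range(15)]
        res = average_precision(dets, gt, 800.0)
        assert np.all(np.diff(res.recall) >= -1e-12)


class TestMAP:
    @pytest.mark.parametrize("aps,expect", [([1.0, 0.0], 0.5), ([0.7], 0.7), ([0.2, 0.4, 0.9], 0.5)])
    def test_arithmetic_mean(self, aps, expect):
        assert np.isclose(mean_average_precision(aps), expect)


def table(rows):
    return pd.DataFrame(rows, columns=["frame", "track_id", "cx", "cy"])


def two_target_passby(far=200.0, near=30.0):
    """Target 1 fixed at x=0; target 2 approaches within `near` for frames 8-11."""
    rows = []
    for t in range(20):
        x2 = near if 8 <= t <= 11 else far
        rows.append((t, 1, 0.0, 0.0))
        rows.append((t, 2, x2, 0.0))
    return table(rows)


class TestMOTA:
    def test_self_comparison_is_unity(self):
        gt = simulate_tracks(6, 40, np.random.default_rng(1))
        res = mota(gt, gt.copy())
        assert res.mota == 1.0 and res.fn == res.fp == res.ids == 0

    def test_one_missed_detection_among_100(self):
        gt = table([(t, i, 100.0 * i, 0.0) for t in range(50) for i in (1, 2)])
        inf = gt[~((gt.frame == 25) & (gt.track_id == 2))].copy()
        res = mota(gt, inf, MOTAConfig(d_max=50))
        assert res.fn == 1 and res.fp == 0 and res.ids == 0
        assert res.mota == 1 - 1 / 100

    def test_permanent_swap_after_overlap_counts_one_switch_per_reassigned_id(self):
        gt = two_target_passby()
        inf = gt.copy()
        # inferred ids swap from the overlap onward and stay swapped
        swap = inf.frame >= 8
        inf.loc[swap, "track_id"] = inf.loc[swap, "track_id"].map({1: 2, 2: 1})
        res = mota(gt, inf, MOTAConfig(d_max=50))
        assert res.fn == 0 and res.fp == 0
        assert res.ids == 2  # both ground-truth ids were reassigned

    def test_transient_swap_within_overlap_is_suppressed(self):
        gt = two_target_passby()
        inf = gt.copy()
        swap = (inf.frame >= 8) & (inf.frame <= 11)
        inf.loc[swap, "track_id"] = inf.loc[swap, "track_id"].map({1: 2, 2: 1})
        res = mota(gt, inf, MOTAConfig(d_max=50))
        assert res.ids == 0 and res.mota == 1.0
        assert res.overlap_frames == [8, 9, 10, 11]

    def test_fn_fp_still_counted_during_overlap(self):
        gt = two_target_passby()
        inf = gt[~((gt.frame == 9) & (gt.track_id == 2))].copy()
        res = mota(gt, inf, MOTAConfig(d_max=50))
        assert res.fn == 1

    def test_accounting_identity(self):
        rng = np.random.default_rng(7)
        gt = simulate_tracks(5, 50, rng)
        stream = simulate_detections(gt, rng, fn_rate=0.2, fp_rate=0.5, jitter_sigma=5.0)
        from synthrig.tracker import TrackerConfig, track_sequence
        inf = track_sequence(stream, TrackerConfig())
        res = mota(gt, inf)
        assert res.fn + res.fp + res.ids == round(res.gt_total * (1 - res.mota))

    def test_inferred_frames_outside_gt_rejected(self):
        gt = table([(0, 1, 0.0, 0.0)])
        inf = table([(0, 1, 0.0, 0.0), (5, 1, 0.0, 0.0)])
        with pytest.raises(ValueError, match="outside"):
            mota(gt, inf)

    def test_d_max_defaults(self):
        assert MOTAConfig(frame_width=3840.0).resolved_d_max() == 50.0
        assert MOTAConfig(frame_width=2500.0).resolved_d_max() == pytest.approx(50.0)
        assert MOTAConfig(frame_width=1000.0).resolved_d_max() == pytest.approx(20.0)
        assert MOTAConfig(d_max=40.0).resolved_d_max() == 40.0


class TestPoseError:
    def test_uniform_offset_with_known_body_length(self):
        gt = np.array([[0.0, 0], [10, 0], [20, 0], [30, 0]])
        inf = gt + np.array([3.0, 4.0])  # 5 px offset each
        res = pose_error(gt, inf, np.ones(4), body_length=100.0)
        assert res.mean_px_error == pytest.approx(5.0)
        assert res.relative_error_pct == pytest.approx(5.0)
        assert res.retained_fraction == 1.0

    def test_translation_invariance_and_linear_scaling(self, rng):
        gt = rng.uniform(0, 100, (8, 2))
        off = np.array([2.0, 1.0])
        a = pose_error(gt, gt + off, np.ones(8), 50.0)
        b = pose_error(gt + 10, gt + 10 + off, np.ones(8), 50.0)
        c = pose_error(gt, gt + 2 * off, np.ones(8), 50.0)
        assert a.relative_error_pct == pytest.approx(b.relative_error_pct)
        assert c.relative_error_pct == pytest.approx(2 * a.relative_error_pct)

    def test_low_confidence_points_excluded(self):
        gt = np.zeros((4, 2))
        inf = np.full((4, 2), 10.0)
        conf = np.array([0.9, 0.9, 0.1, 0.1])
        res = pose_error(gt, inf, conf, 100.0)
        assert res.n_retained == 2 and res.retained_fraction == 0.5

    def test_all_below_threshold_raises(self):
        with pytest.raises(UndefinedMetricError):
            pose_error(np.zeros((3, 2)), np.zeros((3, 2)), np.full(3, 0.5), 100.0)


class TestACR:
    def test_perfect_prediction_scores_100(self, rng):
        gt = (rng.random((64, 64)) > 0.5).astype(np.uint8)
        assert acr(gt, gt.copy(), [1]).acr == 100.0

    def test_constructed_error_counts(self):
        gt = np.zeros((32, 32), dtype=np.uint8)
        gt[:10, :20] = 1                       # y = 200 class-1 pixels
        pred = gt.copy()
        pred[0, :20] = 0                       # 20 FN
        pred[20, :10] = 1                      # 10 FP
        res = acr(gt, pred, [1])
        assert res.acr == pytest.approx(85.0)  # 100 * (200 - 30) / 200

    def test_all_background_prediction_scores_zero(self):
        gt = np.zeros((16, 16), dtype=np.uint8)
        gt[:4, :4] = 1
        assert acr(gt, np.zeros_like(gt), [1]).acr == pytest.approx(0.0)

    def test_class_absent_from_gt_rejected(self):
        gt = np.zeros((8, 8), dtype=np.uint8)
        with pytest.raises(ValueError, match="absent"):
            acr(gt, gt, [1])

    def test_multi_image_average(self):
        g1 = np.zeros((10, 10), dtype=np.uint8); g1[:5] = 1
        g2 = np.zeros((10, 10), dtype=np.uint8); g2[:2] = 1
        p1 = g1.copy()
        p2 = np.zeros_like(g2)  # image ratios 1.0 and 0.0
        assert acr([g1, g2], [p1, p2], [1]).acr == pytest.approx(50.0)


class TestSimulators:
    def test_noise_free_detections_score_perfect_ap(self):
        rng = np.random.default_rng(3)
        gt = simulate_tracks(5, 20, rng)
        stream = simulate_detections(gt, rng)
        per_frame = tracks_to_gt_detections(gt)
        for frame, dets in stream.items():
            centers = [(d.center, d.confidence) for d in dets]
            gt_centers = np.array([c for c, _ in per_frame[frame]])
            assert average_precision(centers, gt_centers, 3840.0).ap == 1.0

    def test_dropout_fraction_within_binomial_bound(self):
        rng = np.random.default_rng(11)
        gt = simulate_tracks(50, 200, rng)  # 10,000 gt detections
        stream = simulate_detections(gt, rng, fn_rate=0.1)
        emitted = sum(len(v) for v in stream.values())
        n = len(gt)
        sigma = np.sqrt(n * 0.1 * 0.9)
        assert abs(emitted - 0.9 * n) < 3 * sigma

    def test_track_counts(self):
        gt = simulate_tracks(10, 200, np.random.default_rng(0))
        assert len(gt) == 2000
        assert gt.track_id.nunique() == 10

    def test_seeded_streams_are_identical(self):
        gt = simulate_tracks(4, 30, np.random.default_rng(2))
        a = simulate_detections(gt, np.random.default_rng(9), fn_rate=0.2, fp_rate=1.0, jitter_sigma=3.0)
        b = simulate_detections(gt, np.random.default_rng(9), fn_rate=0.2, fp_rate=1.0, jitter_sigma=3.0)
        for f in a:
            assert len(a[f]) == len(b[f])
            for da, db in zip(a[f], b[f]):
                assert np.array_equal(da.box, db.box) and da.confidence == db.confidence

    def test_min_separation_prevents_overlap_events(self):
        gt = simulate_tracks(6, 50, np.random.default_rng(4), min_separation=300.0)
        res = mota(gt, gt.copy(), MOTAConfig(d_max=50))
        assert res.overlap_frames == []
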