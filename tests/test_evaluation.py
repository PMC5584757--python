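import numpy as np
import pytest

from boutondetect import benchmark
from boutondetect.evaluation import (
    EvaluationReport,
    MatchCounts,
    match_detections,
    metrics,
    threshold_sweep,
)
from boutondetect.imaging_io import BoxSet


@pytest.fixture
def frame_boxes():
    return BoxSet([(10, 10, 34, 34), (50, 50, 74, 74), (10, 60, 34, 84)], (100, 100))


class TestMatchDetections:
    def test_point_in_box_is_tp(self):
        boxes = BoxSet([(10, 10, 34, 34)], (100, 100))
        c = match_detections([(20, 20)], boxes)
        assert (c.tp, c.fp, c.fn) == (1, 0, 0)

    def test_second_point_in_same_box_is_fp(self):
        boxes = BoxSet([(10, 10, 34, 34)], (100, 100))
        c = match_detections([(20, 20), (22, 25)], boxes)
        assert (c.tp, c.fp, c.fn) == (1, 1, 0)

    def test_empty_boxes_count_fn(self, frame_boxes):
        c = match_detections([], frame_boxes)
        assert (c.tp, c.fp, c.fn) == (0, 0, 3)

    def test_point_outside_any_box_is_fp(self, frame_boxes):
        c = match_detections([(90, 5)], frame_boxes)
        assert (c.tp, c.fp, c.fn) == (0, 1, 3)

    def test_edge_inclusive_membership(self):
        boxes = BoxSet([(10, 10, 34, 34)], (100, 100))
        assert match_detections([(10, 34)], boxes).tp == 1

    def test_tp_plus_fn_equals_box_count(self, frame_boxes, rng):
        for _ in range(50):
            pts = [tuple(p) for p in rng.integers(0, 100, size=(rng.integers(0, 15), 2))]
            c = match_detections(pts, frame_boxes)
            assert c.tp + c.fn == len(frame_boxes)

    def test_strongest_detection_claims_the_box(self):
        boxes = BoxSet([(10, 10, 34, 34)], (100, 100))
        c = match_detections([(20, 20), (21, 21)], boxes, scores=[0.1, 0.9])
        assert (c.tp, c.fp) == (1, 1)

    def test_point_outside_frame_rejected(self, frame_boxes):
        with pytest.raises(ValueError):
            match_detections([(200, 200)], frame_boxes)

    def test_pixel_tn_mode_counts_unexcluded_pixels(self):
        boxes = BoxSet([(0, 0, 24, 24)], (100, 100))
        c = match_detections([(50, 50)], boxes, tn_mode="pixel")
        # Exclusions: the box (625 px) + 25x25 zone around the FP.
        assert c.tn == 100 * 100 - 625 - 625


class TestMetrics:
    @pytest.mark.parametrize(
        "p,r,f_expected", [(0.71, 1.00, 0.83), (0.45, 1.00, 0.62)]
    )
    def test_reference_rows_reproduce_f1_at_two_decimals(self, p, r, f_expected):
        # Counts realizing the given precision/recall exactly enough.
        tp = 9000
        fp = int(round(tp * (1 - p) / p))
        fn = int(round(tp * (1 - r) / r))
        _, _, f1 = metrics(MatchCounts(tp=tp, fp=fp, fn=fn))
        assert round(f1, 2) == f_expected

    def test_arithmetic_from_counts(self):
        p, r, f1 = metrics(MatchCounts(tp=10, fp=4, fn=0))
        assert p == pytest.approx(10 / 14)
        assert r == 1.0
        assert f1 == pytest.approx(2 * p / (p + 1))

    def test_zero_conventions(self):
        assert metrics(MatchCounts()) == (0.0, 0.0, 0.0)

    def test_f1_between_precision_and_recall(self, rng):
        for _ in range(100):
            c = MatchCounts(*(int(v) for v in rng.integers(0, 30, 3)), 0)
            p, r, f1 = metrics(c)
            if p + r > 0:
                assert min(p, r) - 1e-12 <= f1 <= max(p, r) + 1e-12


class TestThresholdSweep:
    def test_uniform_top_scores_keep_recall_flat(self, frame_boxes):
        pts = [(20, 20, 1.0), (60, 60, 1.0)]
        sweep = threshold_sweep(pts, frame_boxes, n_thresholds=11)
        assert np.all(sweep["recall"] == sweep["recall"][0])

    def test_no_points_yields_zero_curves(self, frame_boxes):
        sweep = threshold_sweep([], frame_boxes, n_thresholds=11)
        assert np.all(sweep["precision"] == 0) and np.all(sweep["recall"] == 0)

    def test_matches_per_threshold_rematching_oracle(self, frame_boxes, rng):
        pts = [
            (int(r), int(c), float(s))
            for (r, c), s in zip(
                rng.integers(0, 100, size=(30, 2)), rng.uniform(-1, 1, 30)
            )
        ]
        n = 101
        sweep = threshold_sweep(pts, frame_boxes, n_thresholds=n)
        for i, t in enumerate(np.linspace(-1, 1, n)):
            keep = [(r, c) for r, c, s in pts if s >= t]
            scores = [s for _, _, s in pts if s >= t]
            c = match_detections(keep, frame_boxes, scores)
            p, r, _ = metrics(c)
            assert sweep["precision"][i] == pytest.approx(p)
            assert sweep["recall"][i] == pytest.approx(r)

    def test_recall_monotone_nonincreasing_in_threshold(self, frame_boxes, rng):
        pts = [
            (int(r), int(c), float(s))
            for (r, c), s in zip(
                rng.integers(0, 100, size=(40, 2)), rng.uniform(-1, 1, 40)
            )
        ]
        sweep = threshold_sweep(pts, frame_boxes, n_thresholds=51)
        rec = sweep["recall"]
        assert all(a >= b - 1e-12 for a, b in zip(rec, rec[1:]))


class TestReport:
    def test_aggregate_mean_and_sample_std(self):
        report = EvaluationReport(
            counts=[MatchCounts(10, 4, 0), MatchCounts(8, 0, 2)],
            n_boutons=[10, 10],
        )
        agg = report.aggregate()
        m = np.array(report.per_image_metrics)
        assert agg["mean_f1"] == pytest.approx(m[:, 2].mean())
        assert agg["std_f1"] == pytest.approx(m[:, 2].std(ddof=1))

    def test_csv_has_average_and_std_rows(self, tmp_path):
        report = EvaluationReport(
            counts=[MatchCounts(10, 4, 0), MatchCounts(8, 0, 2)],
            n_boutons=[10, 10],
        )
        path = tmp_path / "m.csv"
        report.write_csv(path)
        lines = path.read_text().splitlines()
        assert lines[-2].startswith("Average") and lines[-1].startswith("STD")


class TestReferenceBenchmark:
    def test_detector_column_means(self):
        means = benchmark.column_means()
        assert round(means["f1"], 3) == 0.840
        assert round(means["recall"] * 100) == 95

    def test_baseline_column_means(self):
        means = benchmark.column_means()
        assert round(means["baseline_recall"], 2) == 0.31
        assert round(means["baseline_f1"], 2) == 0.41

    def test_every_row_f1_consistent_with_precision_recall(self):
        # Printed precision/recall are rounded to 2 dp, so the recomputed
        # F1 can differ from the printed one by one unit in the last digit.
        for recomputed, stored in benchmark.recompute_f1_rows():
            assert abs(round(recomputed, 2) - stored) <= 0.01 + 1e-9

    def test_named_rows_match_exactly_at_two_decimals(self):
        rows = benchmark.recompute_f1_rows()
        for idx in (0, 16):  # table rows 1 and 17
            recomputed, stored = rows[idx]
            assert round(recomputed, 2) == stored
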