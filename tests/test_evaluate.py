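import itertools

import numpy as np
import pytest

from disguisor.evaluate import (
    EvalReport,
    GTFace,
    Prediction,
    holistic_recall,
    iou,
    load_gt,
    load_predictions,
    match_frame,
    save_gt,
    save_predictions,
    ssim,
    summarize,
)


def optimal_matching_size(gt, pred, tau):
    """Exhaustive maximum-cardinality matching oracle (small inputs only)."""
    ok = {
        (i, j)
        for i, g in enumerate(gt)
        for j, p in enumerate(pred)
        if iou(g, p) >= tau
    }
    best = 0
    m = min(len(gt), len(pred))
    for k in range(m, 0, -1):
        for gs in itertools.permutations(range(len(gt)), k):
            for ps in itertools.permutations(range(len(pred)), k):
                if all((g, p) in ok for g, p in zip(gs, ps)):
                    return k
    return best


class TestIoU:
    def test_identical_boxes(self):
        assert iou((3, 4, 5, 6), (3, 4, 5, 6)) == 1.0

    def test_disjoint_boxes(self):
        assert iou((0, 0, 2, 2), (5, 5, 2, 2)) == 0.0

    def test_partial_overlap_exact_value(self):
        # overlap 1x1; union 4+4-1=7
        assert abs(iou((0, 0, 2, 2), (1, 1, 2, 2)) - 1 / 7) < 1e-12

    def test_pixel_count_oracle(self):
        """Continuous IoU agrees with a fine-grid pixel-count estimate."""
        a, b = (0.0, 0.0, 2.0, 2.0), (1.0, 1.0, 2.0, 2.0)
        res = 0.005
        xs = np.arange(0, 3.5, res) + res / 2
        ys = xs
        X, Y = np.meshgrid(xs, ys)

        def inside(box):
            x, y, w, h = box
            return (X >= x) & (X < x + w) & (Y >= y) & (Y < y + h)

        ia, ib = inside(a), inside(b)
        grid = (ia & ib).sum() / (ia | ib).sum()
        assert abs(iou(a, b) - grid) < 1e-3

    def test_symmetry_and_scale_invariance(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            a = tuple(rng.uniform(0, 10, 2)) + tuple(rng.uniform(0.5, 5, 2))
            b = tuple(rng.uniform(0, 10, 2)) + tuple(rng.uniform(0.5, 5, 2))
            assert abs(iou(a, b) - iou(b, a)) < 1e-12
            s = 3.7
            a2 = tuple(v * s for v in a)
            b2 = tuple(v * s for v in b)
            assert abs(iou(a, b) - iou(a2, b2)) < 1e-12

    def test_bad_box_rejected(self):
        with pytest.raises(ValueError):
            iou((0, 0, 0, 2), (0, 0, 2, 2))


class TestMatching:
    def test_single_pair_above_threshold(self):
        assert match_frame([(0, 0, 2, 2)], [(0, 1, 2, 2)], tau=0.3) == [(0, 0)]

    def test_one_to_one_with_duplicate_predictions(self):
        gt = [(0, 0, 4, 4)]
        pred = [(0, 0, 4, 4), (0.5, 0.5, 4, 4)]
        pairs = match_frame(gt, pred, tau=0.4)
        assert len(pairs) == 1

    def test_greedy_never_exceeds_optimal(self):
        rng = np.random.default_rng(1)
        at_least_equal = 0
        n = 100
        for _ in range(n):
            gt = [
                tuple(rng.uniform(0, 8, 2)) + tuple(rng.uniform(1, 4, 2))
                for _ in range(rng.integers(1, 4))
            ]
            pred = [
                tuple(rng.uniform(0, 8, 2)) + tuple(rng.uniform(1, 4, 2))
                for _ in range(rng.integers(1, 4))
            ]
            greedy = len(match_frame(gt, pred, tau=0.3))
            opt = optimal_matching_size(gt, pred, tau=0.3)
            assert greedy <= opt
            if greedy == opt:
                at_least_equal += 1
        assert at_least_equal >= 0.95 * n

    def test_deterministic_tie_break(self):
        gt = [(0, 0, 2, 2), (0, 0, 2, 2)]
        pred = [(0, 0, 2, 2)]
        assert match_frame(gt, pred, tau=0.4) == [(0, 0)]


class TestHolisticRecall:
    def test_detected_in_all_views_counts(self):
        gt = [
            GTFace("p", 0, "c1", (0, 0, 2, 2)),
            GTFace("p", 0, "c2", (0, 0, 2, 2)),
        ]
        assert holistic_recall(gt, {("p", 0, "c1"), ("p", 0, "c2")}) == 1.0

    def test_single_view_miss_fails_instance(self):
        gt = [
            GTFace("p", 0, "c1", (0, 0, 2, 2)),
            GTFace("p", 0, "c2", (0, 0, 2, 2)),
        ]
        assert holistic_recall(gt, {("p", 0, "c1")}) == 0.0

    def test_enumeration_example(self):
        gt = []
        matched = set()
        for k, full in enumerate([True, False, True]):
            for cam in ("c1", "c2"):
                gt.append(GTFace(f"p{k}", 0, cam, (0, 0, 2, 2)))
                if full or cam == "c1":
                    matched.add((f"p{k}", 0, cam))
        assert holistic_recall(gt, matched) == pytest.approx(2 / 3)

    def test_empty_denominator_is_missing(self):
        assert holistic_recall([], set()) is None
        invis = [GTFace("p", 0, "c1", (0, 0, 2, 2), partially_visible=False)]
        assert holistic_recall(invis, set()) is None

    def test_randomized_agreement_with_enumeration(self):
        rng = np.random.default_rng(3)
        for _ in range(100):
            instances = {}
            gt = []
            matched = set()
            for p in range(rng.integers(1, 5)):
                cams = list(
                    rng.choice(["c1", "c2", "c3"], size=rng.integers(1, 4), replace=False)
                )
                hit = {c: bool(rng.random() < 0.7) for c in cams}
                instances[f"p{p}"] = hit
                for c in cams:
                    gt.append(GTFace(f"p{p}", 0, c, (0, 0, 2, 2)))
                    if hit[c]:
                        matched.add((f"p{p}", 0, c))
            expect = np.mean([all(h.values()) for h in instances.values()])
            assert holistic_recall(gt, matched) == pytest.approx(expect)


class TestSummarize:
    def test_perfect_predictions(self):
        gt = [
            GTFace("p0", f, c, (10, 10, 5, 5))
            for f in range(3)
            for c in ("c1", "c2")
        ]
        preds = [Prediction("p0", g.frame_index, g.camera_id, g.bbox) for g in gt]
        rep = summarize(gt, preds)
        assert (rep.per_camera["recall"] == 1.0).all()
        assert (rep.per_camera["precision"] == 1.0).all()
        assert rep.holistic_recall == 1.0

    def test_zero_predictions_conventions(self):
        gt = [GTFace("p0", 0, "c1", (10, 10, 5, 5))]
        rep = summarize(gt, [])
        assert rep.per_camera.loc["c1", "recall"] == 0.0
        assert np.isnan(rep.per_camera.loc["c1", "precision"])
        assert rep.per_camera.loc["c1", "f1"] == 0.0

    def test_invisible_views_excluded_from_holistic(self):
        gt = [
            GTFace("p0", 0, "c1", (10, 10, 5, 5)),
            GTFace("p0", 0, "c2", (10, 10, 5, 5), partially_visible=False),
        ]
        preds = [Prediction("p0", 0, "c1", (10, 10, 5, 5))]
        rep = summarize(gt, preds)
        assert rep.holistic_recall == 1.0

    def test_rates_invariant_to_relabeling(self):
        rng = np.random.default_rng(5)
        gt, preds = [], []
        for f in range(3):
            for c in ("c1", "c2"):
                for p in range(2):
                    box = tuple(rng.uniform(0, 50, 2)) + (8.0, 8.0)
                    gt.append(GTFace(f"p{p}", f, c, box))
                    if rng.random() < 0.8:
                        jitter = tuple(np.array(box[:2]) + rng.uniform(-1, 1, 2))
                        preds.append(Prediction(f"p{p}", f, c, jitter + (8.0, 8.0)))
        rep1 = summarize(gt, preds)
        remap = {"p0": "zebra", "p1": "alpha"}
        gt2 = [
            GTFace(remap[g.person_id], g.frame_index, g.camera_id, g.bbox)
            for g in gt
        ]
        preds2 = [
            Prediction(remap[p.person_id], p.frame_index, p.camera_id, p.bbox)
            for p in preds
        ]
        rep2 = summarize(gt2, preds2)
        assert rep1.holistic_recall == pytest.approx(rep2.holistic_recall)
        assert np.allclose(
            rep1.per_camera["recall"].values, rep2.per_camera["recall"].values
        )

    def test_report_csv(self, tmp_path):
        gt = [GTFace("p0", 0, "c1", (10, 10, 5, 5))]
        preds = [Prediction("p0", 0, "c1", (10, 10, 5, 5))]
        rep = summarize(gt, preds)
        rep.to_csv(tmp_path / "report.csv")
        text = (tmp_path / "report.csv").read_text()
        assert "holistic_recall" in text and "c1" in text


class TestSSIM:
    def test_identical_images(self):
        rng = np.random.default_rng(6)
        img = rng.integers(0, 255, size=(32, 32)).astype(np.uint8)
        assert ssim(img, img) == pytest.approx(1.0)

    def test_constant_images_closed_form(self):
        mx, my = 80.0, 120.0
        a = np.full((24, 24), mx)
        b = np.full((24, 24), my)
        C1 = (0.01 * 255) ** 2
        expect = (2 * mx * my + C1) / (mx**2 + my**2 + C1)
        assert ssim(a, b) == pytest.approx(expect, abs=1e-12)

    def test_negative_image_below_one(self):
        rng = np.random.default_rng(7)
        img = rng.integers(0, 255, size=(32, 32)).astype(np.uint8)
        assert ssim(img, 255 - img) < 1.0

    def test_size_mismatch_rejected(self):
        with pytest.raises(ValueError):
            ssim(np.zeros((20, 20)), np.zeros((22, 22)))


class TestEvalIO:
    def test_gt_and_prediction_roundtrip(self, tmp_path):
        gt = [GTFace("p0", 1, "c1", (1.0, 2.0, 3.0, 4.0), partially_visible=False)]
        preds = [Prediction("p0", 1, "c1", (1.5, 2.5, 3.0, 4.0))]
        save_gt(gt, tmp_path / "gt.json")
        save_predictions(preds, tmp_path / "pred.json")
        assert load_gt(tmp_path / "gt.json") == gt
        assert load_predictions(tmp_path / "pred.json") == preds


from hypothesis import given, settings, strategies as st

box_strategy = st.tuples(
    st.floats(-50, 50), st.floats(-50, 50), st.floats(0.1, 20), st.floats(0.1, 20)
)


@settings(max_examples=200, derandomize=True)
@given(a=box_strategy, b=box_strategy)
def test_iou_properties(a, b):
    """IoU is symmetric, bounded in [0, 1], and 1 exactly on identical boxes."""
    v = iou(a, b)
    assert 0.0 <= v <= 1.0
    assert v == iou(b, a)
    assert iou(a, a) == pytest.approx(1.0)
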