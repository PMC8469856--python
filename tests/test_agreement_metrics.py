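import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from peckseg.agreement_metrics import (
    AgreementBand,
    BoundingBox,
    DetectionReport,
    aggregate_reports,
    landis_koch_band,
    mask_to_bbox,
    match_detections,
    pixel_iou,
    whole_image_iou,
)
from conftest import box_pixels, make_mask, make_set


class TestPixelIou:
    def test_identity(self):
        a = {(0, 0), (1, 1)}
        assert pixel_iou(a, a) == 1.0

    def test_disjoint(self):
        assert pixel_iou({(0, 0)}, {(5, 5)}) == 0.0

    def test_direct_count(self):
        assert pixel_iou({(0, 0), (0, 1)}, {(0, 1), (0, 2)}) == pytest.approx(1 / 3)

    def test_empty_conventions(self):
        assert pixel_iou(set(), set()) == 1.0
        assert pixel_iou(set(), {(0, 0)}) == 0.0

    @given(st.sets(st.tuples(st.integers(0, 8), st.integers(0, 8)), max_size=20),
           st.sets(st.tuples(st.integers(0, 8), st.integers(0, 8)), max_size=20))
    @settings(deadline=None, max_examples=100)
    def test_symmetric_and_bounded(self, a, b):
        v = pixel_iou(a, b)
        assert v == pixel_iou(b, a)
        assert 0.0 <= v <= 1.0


class TestWholeImageIou:
    def test_identical_sets(self):
        s = make_set([make_mask("a", box_pixels(0, 0, 2, 2))])
        assert whole_image_iou(s, s) == 1.0

    def test_one_empty(self):
        a = make_set([make_mask("a", {(0, 0)})])
        b = make_set([])
        assert whole_image_iou(a, b) == 0.0

    def test_matches_brute_force_union_count(self):
        a = make_set([make_mask("a1", box_pixels(0, 0, 3, 3)),
                      make_mask("a2", box_pixels(10, 10, 2, 2))])
        b = make_set([make_mask("b1", box_pixels(1, 1, 3, 3)),
                      make_mask("b2", box_pixels(10, 11, 2, 2))])
        ua = set().union(*[m.pixels for m in a.masks])
        ub = set().union(*[m.pixels for m in b.masks])
        expect = len(ua & ub) / len(ua | ub)
        assert whole_image_iou(a, b) == pytest.approx(expect)

    def test_image_mismatch_rejected(self):
        a = make_set([make_mask("a", {(0, 0)})], image_id="img")
        b = make_set([make_mask("b", {(0, 0)}, image_id="other")], image_id="other")
        with pytest.raises(ValueError, match="mismatch"):
            whole_image_iou(a, b)


class TestLandisKoch:
    @pytest.mark.parametrize("value,band", [
        (-0.1, AgreementBand.poor),
        (0.0, AgreementBand.slight),
        (0.20, AgreementBand.slight),
        (0.27, AgreementBand.fair),   # typical inter-observer agreement
        (0.41, AgreementBand.moderate),
        (0.56, AgreementBand.moderate),  # intra-observer reliability level
        (0.75, AgreementBand.substantial),
        (0.81, AgreementBand.almost_perfect),
        (1.0, AgreementBand.almost_perfect),
    ])
    def test_bands(self, value, band):
        assert landis_koch_band(value) == band

    def test_above_one_rejected(self):
        with pytest.raises(ValueError):
            landis_koch_band(1.01)

    def test_monotone(self):
        order = list(AgreementBand)
        grid = np.linspace(-0.2, 1.0, 121)
        idx = [order.index(landis_koch_band(float(v))) for v in grid]
        assert idx == sorted(idx)


class TestBbox:
    def test_single_pixel(self):
        assert mask_to_bbox(make_mask("m", {(3, 5)})) == BoundingBox(3, 5, 4, 6)

    def test_two_corners(self):
        assert mask_to_bbox(make_mask("m", {(0, 0), (2, 3)})) == BoundingBox(0, 0, 3, 4)

    @given(st.sets(st.tuples(st.integers(0, 15), st.integers(0, 15)),
                   min_size=1, max_size=25))
    @settings(deadline=None, max_examples=60)
    def test_tightness(self, pixels):
        box = mask_to_bbox(make_mask("m", pixels))
        rows = [p[0] for p in pixels]
        cols = [p[1] for p in pixels]
        assert all(box.row_min <= r < box.row_max and box.col_min <= c < box.col_max
                   for r, c in pixels)
        # each side touches a pixel: shrinking any side would exclude one
        assert box.row_min in rows and box.row_max - 1 in rows
        assert box.col_min in cols and box.col_max - 1 in cols


def brute_force_match(pred, ref, threshold=0.5):
    """Exhaustive one-to-one assignment maximizing TP count, ties by total IoU."""
    pb = [mask_to_bbox(m) for m in pred.masks]
    rb = [mask_to_bbox(m) for m in ref.masks]
    eligible = [(i, j, pb[i].iou(rb[j])) for i in range(len(pb)) for j in range(len(rb))
                if pb[i].iou(rb[j]) >= threshold]
    best = (0, 0.0)
    for size in range(len(eligible), -1, -1):
        for combo in itertools.combinations(eligible, size):
            if len({i for i, _, _ in combo}) < size or len({j for _, j, _ in combo}) < size:
                continue
            best = max(best, (size, sum(v for _, _, v in combo)))
        if best[0] == size:
            break
    return best[0]


def random_boxes(rng, tag, n):
    masks = []
    for k in range(n):
        r0, c0 = int(rng.integers(0, 40)), int(rng.integers(0, 40))
        h, w = int(rng.integers(2, 12)), int(rng.integers(2, 12))
        masks.append(make_mask(f"{tag}{k}", box_pixels(r0, c0, h, w)))
    return make_set(masks, annotator=tag)


class TestMatchDetections:
    def test_perfect_match(self):
        s = make_set([make_mask("a", box_pixels(2, 2, 4, 4))])
        rep = match_detections(s, s)
        assert (rep.true_positives, rep.false_positives, rep.false_negatives) == (1, 0, 0)
        assert rep.precision == rep.recall == rep.f1 == 1.0
        assert rep.mean_detection_iou == 1.0

    def test_disjoint_boxes(self):
        p = make_set([make_mask("p", box_pixels(0, 0, 3, 3))])
        r = make_set([make_mask("r", box_pixels(20, 20, 3, 3))])
        rep = match_detections(p, r)
        assert (rep.true_positives, rep.false_positives, rep.false_negatives) == (0, 1, 1)
        assert rep.f1 == 0.0

    def test_image_mismatch_rejected(self):
        p = make_set([make_mask("p", {(0, 0)})])
        r = make_set([make_mask("r", {(0, 0)}, image_id="other")], image_id="other")
        with pytest.raises(ValueError):
            match_detections(p, r)

    def test_conservation_and_oracle_equivalence(self):
        rng = np.random.default_rng(12345)
        for _ in range(100):
            p = random_boxes(rng, "p", int(rng.integers(0, 5)))
            r = random_boxes(rng, "r", int(rng.integers(0, 5)))
            rep = match_detections(p, r)
            assert rep.true_positives + rep.false_positives == len(p.masks)
            assert rep.true_positives + rep.false_negatives == len(r.masks)
            assert rep.true_positives == brute_force_match(p, r)

    def test_each_detection_matched_at_most_once(self):
        # two predictions over one reference: only one may match
        r = make_set([make_mask("r", box_pixels(0, 0, 6, 6))], annotator="r")
        p = make_set([make_mask("p0", box_pixels(0, 0, 6, 6)),
                      make_mask("p1", box_pixels(0, 1, 6, 6))], annotator="p")
        rep = match_detections(p, r)
        assert (rep.true_positives, rep.false_positives, rep.false_negatives) == (1, 1, 0)
        assert rep.matched_pairs[0][0] == "p0"  # higher IoU wins


class TestAggregate:
    def test_single_report_unchanged(self):
        rep = DetectionReport(3, 1, 2)
        agg = aggregate_reports([rep])
        assert agg.as_dict() == rep.as_dict()

    def test_f1_is_harmonic_mean(self):
        rep = DetectionReport(10, 5, 7)
        p, r = rep.precision, rep.recall
        assert rep.f1 == pytest.approx(2 * p * r / (p + r))

    def test_micro_pooling(self):
        reports = [DetectionReport(2, 1, 0), DetectionReport(0, 3, 4)]
        agg = aggregate_reports(reports)
        assert (agg.true_positives, agg.false_positives, agg.false_negatives) == (2, 4, 4)
        assert agg.precision == pytest.approx(2 / 6)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            aggregate_reports([])
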