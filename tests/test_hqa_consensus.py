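import numpy as np
import pytest

from peckseg import ImageFrame, Stage
from peckseg.hqa_consensus import (
    ConsensusPool,
    ConsensusStatus,
    ImagePiece,
    Location,
    OpinionRecord,
    Verdict,
    finalize_piece,
    make_pieces,
    tally,
)
from peckseg.synthetic_scenes import ObserverModel, simulate_observer, simulate_opinion
from conftest import box_pixels, make_mask, make_set


def big_frame(image_id="img", size=2000):
    arr = np.zeros((size, size, 3), dtype=np.uint8)
    return ImageFrame(image_id=image_id, channels=arr)


def piece(pid, image_id="img"):
    return ImagePiece(piece_id=pid, image_id=image_id, detection_id=f"det-{pid}",
                      crop_origin=(0, 0), crop_size=10)


def opinion(pid, obs, verdict=Verdict.injury, location=Location.plumage,
            rejected=False):
    loc = location if (verdict == Verdict.injury and not rejected) else None
    return OpinionRecord(piece_id=pid, observer_id=obs, verdict=verdict,
                        location=loc, rejected=rejected)


class TestMakePieces:
    def test_one_piece_per_mask(self):
        frame = big_frame()
        masks = [make_mask(f"m{k}", box_pixels(500 + 100 * k, 500, 10, 10))
                 for k in range(3)]
        pieces = make_pieces(frame, make_set(masks), crop_size=600)
        assert len(pieces) == 3
        assert all(p.crop_size == 600 for p in pieces)
        for p, m in zip(pieces, masks):
            r0, c0 = p.crop_origin
            # bbox center inside the crop
            assert r0 <= 500 + 100 * int(p.detection_id[-1]) + 5 < r0 + 600

    def test_origin_clamped_at_border(self):
        frame = big_frame()
        pieces = make_pieces(frame, make_set([make_mask("m", box_pixels(8, 8, 4, 4))]),
                             crop_size=600)
        assert pieces[0].crop_origin == (0, 0)

    def test_empty_annotations(self):
        assert make_pieces(big_frame(), make_set([])) == []

    def test_small_image_rejected(self):
        frame = ImageFrame("img", np.zeros((100, 100, 3), dtype=np.uint8))
        with pytest.raises(ValueError, match="smaller crop_size"):
            make_pieces(frame, make_set([make_mask("m", {(5, 5)})]), crop_size=600)


class TestScheduler:
    def test_prefers_pieces_closer_to_three_opinions(self):
        pool = ConsensusPool([piece("A"), piece("B")])
        pool.record_opinion(opinion("A", "x"))
        pool.record_opinion(opinion("A", "y"))
        assert pool.schedule_next("z").piece_id == "A"

    def test_never_reschedules_to_same_observer(self):
        pool = ConsensusPool([piece("A")])
        pool.record_opinion(opinion("A", "x"))
        assert pool.schedule_next("x") is None

    def test_none_when_only_blacklisted(self):
        pool = ConsensusPool([piece("A"), piece("B")])
        pool.record_opinion(opinion("A", "x", rejected=True,
                                    verdict=Verdict.no_injury, location=None))
        assert pool.schedule_next("y") is None

    def test_tie_broken_by_piece_id(self):
        pool = ConsensusPool([piece("B"), piece("A")])
        assert pool.schedule_next("x").piece_id == "A"

    def test_liveness_every_piece_finalized(self):
        pool = ConsensusPool([piece(f"p{k:02d}") for k in range(17)])
        observers = ["x", "y", "z", "w"]
        rng = np.random.default_rng(5)
        progressed = True
        while progressed:
            progressed = False
            for obs in observers:
                p = pool.schedule_next(obs)
                if p is None:
                    continue
                v = Verdict.injury if rng.uniform() < 0.7 else Verdict.no_injury
                pool.record_opinion(opinion(p.piece_id, obs, verdict=v))
                progressed = True
        assert len(pool.finished_results()) == 17
        assert all(len(r.verdicts) == 3 for r in pool.finished_results())


class TestRecordOpinion:
    def test_unanimous_injury(self):
        pool = ConsensusPool([piece("A")])
        pool.record_opinion(opinion("A", "x"))
        pool.record_opinion(opinion("A", "y"))
        res = pool.record_opinion(opinion("A", "z"))
        assert res.status == ConsensusStatus.agreed_injury
        assert res.majority_location == Location.plumage

    def test_disagreement(self):
        pool = ConsensusPool([piece("A")])
        pool.record_opinion(opinion("A", "x"))
        pool.record_opinion(opinion("A", "y", verdict=Verdict.no_injury))
        res = pool.record_opinion(opinion("A", "z"))
        assert res.status == ConsensusStatus.disagreement
        assert res.majority_verdict == Verdict.injury

    def test_location_tie_left_unresolved(self):
        res = finalize_piece(piece("A"), [
            opinion("A", "x", location=Location.head),
            opinion("A", "y", location=Location.snood),
            opinion("A", "z", verdict=Verdict.no_injury),
        ])
        assert res.status == ConsensusStatus.disagreement
        assert res.majority_location is None

    def test_rejection_blacklists_whole_image(self):
        pieces = [piece("A", "img1"), piece("B", "img1"), piece("C", "img2")]
        pool = ConsensusPool(pieces)
        for obs in ("x", "y", "z"):
            pool.record_opinion(opinion("A", obs))
        assert pool.results["A"].status == ConsensusStatus.agreed_injury
        pool.record_opinion(opinion("B", "x", rejected=True,
                                    verdict=Verdict.no_injury, location=None))
        assert "img1" in pool.blacklist
        assert pool.results["A"].status == ConsensusStatus.blacklisted
        assert pool.schedule_next("y").piece_id == "C"
        with pytest.raises(ValueError, match="blacklisted"):
            pool.record_opinion(opinion("B", "y"))

    def test_duplicate_opinion_rejected(self):
        pool = ConsensusPool([piece("A")])
        pool.record_opinion(opinion("A", "x"))
        with pytest.raises(ValueError, match="already rated"):
            pool.record_opinion(opinion("A", "x"))

    def test_location_required_iff_injury(self):
        with pytest.raises(ValueError):
            OpinionRecord("A", "x", Verdict.injury)
        with pytest.raises(ValueError):
            OpinionRecord("A", "x", Verdict.no_injury, location=Location.head)


class TestSimulatedEndToEnd:
    def test_zero_error_observers_give_perfect_consensus(self, scene):
        """True injuries come out agreed_injury, distractor annotations
        agreed_no_injury, when reviewers never err."""
        spec, frame, gt, meta = scene
        detections = list(gt.masks) + [
            make_mask(f"distr{k}", px, image_id=gt.image_id)
            for k, px in enumerate(meta["distractors"])
        ]
        aset = make_set(detections, image_id=gt.image_id)
        pool = ConsensusPool(make_pieces(frame, aset, crop_size=128))
        observers = [ObserverModel(f"o{k}", verdict_error_prob=0.0, seed=k)
                     for k in range(3)]
        pixels = {m.mask_id: m.pixels for m in detections}
        progressed = True
        while progressed:
            progressed = False
            for obs in observers:
                p = pool.schedule_next(obs.observer_id)
                if p is None:
                    continue
                rec = simulate_opinion(p.piece_id, pixels[p.detection_id], gt,
                                       meta["locations"], obs)
                pool.record_opinion(rec)
                progressed = True
        by_det = {r.detection_id: r for r in pool.finished_results()}
        for m in gt.masks:
            assert by_det[m.mask_id].status == ConsensusStatus.agreed_injury
            assert by_det[m.mask_id].majority_location == meta["locations"][m.mask_id]
        for k in range(len(meta["distractors"])):
            assert by_det[f"distr{k}"].status == ConsensusStatus.agreed_no_injury


def make_triples(n, verdicts_locations, start=0):
    """n finalized triples with the given (verdict, location) per observer."""
    out = []
    for i in range(n):
        pid = f"t{start + i:05d}"
        recs = [
            OpinionRecord(pid, f"obs{j}", v,
                          location=(l if v == Verdict.injury else None))
            for j, (v, l) in enumerate(verdicts_locations)
        ]
        out.append(finalize_piece(piece(pid, image_id=pid), recs))
    return out


class TestTally:
    def test_reported_marginals_on_constructed_review(self):
        """A review constructed with the printed marginals: 6895 finished
        triples, 5621 unanimous, majority split 6030 injury / 865 no-injury,
        locations 5339 plumage / 638 head / 53 snood."""
        I, N = Verdict.injury, Verdict.no_injury
        P, H, S = Location.plumage, Location.head, Location.snood
        results = []
        results += make_triples(4230, [(I, P)] * 3, start=0)
        results += make_triples(638, [(I, H)] * 3, start=10000)
        results += make_triples(53, [(I, S)] * 3, start=20000)
        results += make_triples(1109, [(I, P), (I, P), (N, None)], start=30000)
        results += make_triples(700, [(N, None)] * 3, start=40000)
        results += make_triples(165, [(I, P), (N, None), (N, None)], start=50000)
        opinions = [v for r in results for v in r.verdicts]
        s = tally(results, opinions)
        assert s.n_finished == 6895
        assert s.n_opinions == 3 * 6895
        assert (s.n_injury, s.n_no_injury) == (6030, 865)
        # one-decimal percentages of the printed counts; the conventional
        # report quotes 87.4/12.6, which differs by one rounding step
        assert s.pct_injury == pytest.approx(87.4, abs=0.11)
        assert s.pct_no_injury == pytest.approx(12.6, abs=0.11)
        assert (s.n_agree_all, s.n_disagree) == (5621, 1274)
        assert (s.pct_agree, s.pct_disagree) == (81.5, 18.5)
        assert s.location_counts == {"plumage": 5339, "head": 638, "snood": 53}
        assert sum(s.location_counts.values()) == s.n_injury
        assert s.n_location_unresolved == 0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            tally([], [])

    def test_unfinished_rejected(self):
        res = make_triples(1, [(Verdict.injury, Location.plumage)] * 3)[0]
        res.verdicts = res.verdicts[:2]
        with pytest.raises(ValueError, match="not finished"):
            tally([res], [])
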