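"""High-quality-annotation (HQA) consensus workflow.

Every first-pass ("naive") injury annotation is re-examined by three
independent observers.  The source image is cut into small pieces, each
showing exactly one labeled detection; an observer gives a binary verdict
(injury / no injury), a location class (plumage, head or snood) when the
verdict is injury, and may reject a piece for poor quality — which
blacklists *all* pieces of that source image.  A piece is "finished" once
three opinions exist.

Consensus semantics: a finished detection counts as an injury when the
majority (>=2 of 3) verdict is injury; "agreement" means all three verdicts
are identical.  The two partitions are reported side by side in the summary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .annotation_store import AnnotationSet, Blacklist, ImageFrame, InjuryMask
from .agreement_metrics import mask_to_bbox


class Verdict(str, Enum):
    injury = "injury"
    no_injury = "no_injury"


class Location(str, Enum):
    plumage = "plumage"
    head = "head"
    snood = "snood"


class ConsensusStatus(str, Enum):
    agreed_injury = "agreed_injury"
    agreed_no_injury = "agreed_no_injury"
    disagreement = "disagreement"
    blacklisted = "blacklisted"


@dataclass(frozen=True)
class ImagePiece:
    """A crop showing exactly one labeled detection, the unit of review."""

    piece_id: str
    image_id: str
    detection_id: str  # mask_id of the shown detection
    crop_origin: Tuple[int, int]
    crop_size: int

    def extract(self, image: ImageFrame) -> np.ndarray:
        r0, c0 = self.crop_origin
        return image.channels[r0 : r0 + self.crop_size, c0 : c0 + self.crop_size]


@dataclass(frozen=True)
class OpinionRecord:
    piece_id: str
    observer_id: str
    verdict: Verdict
    location: Optional[Location] = None
    rejected: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "verdict", Verdict(self.verdict))
        if self.location is not None:
            object.__setattr__(self, "location", Location(self.location))
        wants_location = self.verdict == Verdict.injury and not self.rejected
        if wants_location and self.location is None:
            raise ValueError("an injury verdict requires a location class")
        if not wants_location and self.location is not None:
            raise ValueError("location only accompanies a non-rejected injury verdict")


@dataclass
class ConsensusResult:
    detection_id: str
    piece_id: str
    image_id: str
    verdicts: List[OpinionRecord]
    status: ConsensusStatus
    majority_location: Optional[Location] = None

    @property
    def majority_verdict(self) -> Verdict:
        n_inj = sum(1 for v in self.verdicts if v.verdict == Verdict.injury)
        return Verdict.injury if n_inj >= 2 else Verdict.no_injury


@dataclass
class ConsensusSummary:
    n_opinions: int
    n_finished: int
    n_injury: int
    n_no_injury: int
    n_agree_all: int
    n_disagree: int
    location_counts: Dict[str, int]
    n_location_unresolved: int
    location_agreement: Dict[str, float]
    pct_injury: float
    pct_no_injury: float
    pct_agree: float
    pct_disagree: float


def make_pieces(
    image: ImageFrame, annotations: AnnotationSet, crop_size: int = 600
) -> List[ImagePiece]:
    """One piece per injury mask, centered on the mask's bbox center.

    The crop window is clamped to the image (shifted inward near borders);
    it never pads beyond the frame.
    """
    if annotations.image_id != image.image_id:
        raise ValueError("annotations do not reference the given image")
    if crop_size > image.height or crop_size > image.width:
        raise ValueError(
            f"image {image.image_id!r} ({image.height}x{image.width}) is smaller "
            f"than crop_size {crop_size}; use a smaller crop_size"
        )
    pieces = []
    for k, mask in enumerate(annotations.masks):
        box = mask_to_bbox(mask)
        cr = (box.row_min + box.row_max) // 2
        cc = (box.col_min + box.col_max) // 2
        r0 = min(max(cr - crop_size // 2, 0), image.height - crop_size)
        c0 = min(max(cc - crop_size // 2, 0), image.width - crop_size)
        pieces.append(
            ImagePiece(
                piece_id=f"{image.image_id}/{mask.mask_id}",
                image_id=image.image_id,
                detection_id=mask.mask_id,
                crop_origin=(r0, c0),
                crop_size=crop_size,
            )
        )
    return pieces


class ConsensusPool:
    """Mutable state of the review: pieces, opinions, blacklist, results."""

    def __init__(self, pieces: Sequence[ImagePiece] = ()) -> None:
        self.pieces: Dict[str, ImagePiece] = {}
        self.opinions: Dict[str, Dict[str, OpinionRecord]] = {}
        self.opinion_log: List[OpinionRecord] = []
        self.results: Dict[str, ConsensusResult] = {}  # keyed by piece_id
        self.blacklist = Blacklist()
        for p in pieces:
            self.add_piece(p)

    def add_piece(self, piece: ImagePiece) -> None:
        if piece.piece_id in self.pieces:
            raise ValueError(f"duplicate piece_id {piece.piece_id!r}")
        self.pieces[piece.piece_id] = piece
        self.opinions[piece.piece_id] = {}

    # -- scheduling --------------------------------------------------------

    def schedule_next(self, observer_id: str) -> Optional[ImagePiece]:
        """Next piece for this observer: fewest missing opinions first.

        A piece is eligible when its image is not blacklisted, it is not yet
        finished (<3 opinions) and this observer has not rated it.  Pieces
        with 2 existing opinions are served before 1 before 0 so that pieces
        reach three opinions at the earliest opportunity; ties are broken by
        piece_id order.
        """
        best: Optional[ImagePiece] = None
        best_key = None
        for pid in self.pieces:
            piece = self.pieces[pid]
            if piece.image_id in self.blacklist:
                continue
            ops = self.opinions[pid]
            if len(ops) >= 3 or observer_id in ops:
                continue
            key = (-len(ops), pid)
            if best_key is None or key < best_key:
                best_key = key
                best = piece
        return best

    # -- recording ---------------------------------------------------------

    def record_opinion(self, rec: OpinionRecord) -> Optional[ConsensusResult]:
        """Store an opinion; finalize the piece when the third one lands.

        A rejection blacklists the whole source image: every piece of that
        image is removed from scheduling and any already-finalized result is
        voided (status ``blacklisted``).
        """
        if rec.piece_id not in self.pieces:
            raise KeyError(f"unknown piece {rec.piece_id!r}")
        piece = self.pieces[rec.piece_id]
        if piece.image_id in self.blacklist:
            raise ValueError(f"piece {rec.piece_id!r} is blacklisted")
        ops = self.opinions[rec.piece_id]
        if rec.observer_id in ops:
            raise ValueError(
                f"observer {rec.observer_id!r} already rated piece {rec.piece_id!r}"
            )
        if len(ops) >= 3:
            raise ValueError(f"piece {rec.piece_id!r} is already finished")
        ops[rec.observer_id] = rec
        self.opinion_log.append(rec)

        if rec.rejected:
            self._blacklist_image(piece.image_id, f"rejected by {rec.observer_id}")
            return None
        if len(ops) == 3:
            result = finalize_piece(piece, list(ops.values()))
            self.results[piece.piece_id] = result
            return result
        return None

    def _blacklist_image(self, image_id: str, reason: str) -> None:
        self.blacklist.add(image_id, reason)
        for pid, piece in self.pieces.items():
            if piece.image_id == image_id and pid in self.results:
                self.results[pid].status = ConsensusStatus.blacklisted
                self.results[pid].majority_location = None

    def finished_results(self) -> List[ConsensusResult]:
        """Finalized, non-blacklisted results."""
        return [
            r
            for r in self.results.values()
            if r.status != ConsensusStatus.blacklisted
        ]

    def hqa_image_ids(self) -> List[str]:
        """Images qualifying as high-quality-annotated: every finished
        detection on the image is unanimous, none blacklisted."""
        by_image: Dict[str, List[ConsensusResult]] = {}
        for r in self.finished_results():
            by_image.setdefault(r.image_id, []).append(r)
        out = []
        for image_id, results in by_image.items():
            if all(
                r.status in (ConsensusStatus.agreed_injury, ConsensusStatus.agreed_no_injury)
                for r in results
            ):
                out.append(image_id)
        return sorted(out)


def finalize_piece(piece: ImagePiece, verdicts: List[OpinionRecord]) -> ConsensusResult:
    """Resolve three opinions on a piece into a ConsensusResult.

    Status is ``agreed_*`` only when all three verdicts are identical,
    ``disagreement`` otherwise.  The majority location is the modal location
    among injury verdicts; a tie leaves it unresolved (None).
    """
    kinds = {v.verdict for v in verdicts}
    if kinds == {Verdict.injury}:
        status = ConsensusStatus.agreed_injury
    elif kinds == {Verdict.no_injury}:
        status = ConsensusStatus.agreed_no_injury
    else:
        status = ConsensusStatus.disagreement
    majority_location = None
    locs = [v.location for v in verdicts if v.verdict == Verdict.injury]
    if len(locs) >= 2:
        counts: Dict[Location, int] = {}
        for l in locs:
            counts[l] = counts.get(l, 0) + 1
        top = max(counts.values())
        modal = [l for l, n in counts.items() if n == top]
        if len(modal) == 1:
            majority_location = modal[0]
    return ConsensusResult(
        detection_id=piece.detection_id,
        piece_id=piece.piece_id,
        image_id=piece.image_id,
        verdicts=verdicts,
        status=status,
        majority_location=majority_location,
    )


def _pct(count: int, total: int) -> float:
    return round(100.0 * count / total, 1) if total else 0.0


def tally(
    results: Sequence[ConsensusResult], opinions: Sequence[OpinionRecord]
) -> ConsensusSummary:
    """Summary counts and percentages over finished detections.

    ``n_injury`` / ``n_no_injury`` split the finished detections by
    *majority* verdict; ``n_agree_all`` counts unanimous triples.  Location
    counts are over majority-injury detections by modal location (a 1-1-1 or
    1-1 tie leaves the location unresolved and is counted separately).
    Percentages are relative to ``n_finished``, rounded to one decimal.
    """
    if not results:
        raise ValueError("tally requires at least one finalized result")
    finished = []
    for r in results:
        if r.status == ConsensusStatus.blacklisted:
            continue
        if len(r.verdicts) != 3:
            raise ValueError(f"result for {r.detection_id!r} is not finished (3 opinions)")
        finished.append(r)
    if not finished:
        raise ValueError("no non-blacklisted finalized results to tally")

    n_finished = len(finished)
    n_injury = sum(1 for r in finished if r.majority_verdict == Verdict.injury)
    n_no_injury = n_finished - n_injury
    n_agree = sum(
        1
        for r in finished
        if r.status in (ConsensusStatus.agreed_injury, ConsensusStatus.agreed_no_injury)
    )
    n_disagree = n_finished - n_agree

    location_counts = {loc.value: 0 for loc in Location}
    unresolved = 0
    agree_by_loc = {loc.value: 0 for loc in Location}
    for r in finished:
        if r.majority_verdict != Verdict.injury:
            continue
        if r.majority_location is None:
            unresolved += 1
            continue
        location_counts[r.majority_location.value] += 1
        if r.status == ConsensusStatus.agreed_injury:
            agree_by_loc[r.majority_location.value] += 1
    location_agreement = {
        loc: (agree_by_loc[loc] / location_counts[loc] if location_counts[loc] else 0.0)
        for loc in location_counts
    }

    return ConsensusSummary(
        n_opinions=len(opinions),
        n_finished=n_finished,
        n_injury=n_injury,
        n_no_injury=n_no_injury,
        n_agree_all=n_agree,
        n_disagree=n_disagree,
        location_counts=location_counts,
        n_location_unresolved=unresolved,
        location_agreement=location_agreement,
        pct_injury=_pct(n_injury, n_finished),
        pct_no_injury=_pct(n_no_injury, n_finished),
        pct_agree=_pct(n_agree, n_finished),
        pct_disagree=_pct(n_disagree, n_finished),
    )
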