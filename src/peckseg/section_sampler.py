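"""Disagreement-free training-section sampling.

After consensus review, each reviewed detection on an image is colored by
its outcome: unanimously confirmed injuries become positive label pixels,
non-unanimous detections become exclusion ("disagreement") zones, and
unanimously rejected detections revert to plain background — all three
observers agree nothing is there, so they are safe negatives.  Random
fixed-size sections are then drawn from the image; any section containing a
disagreement pixel is rejected and redrawn, so the training set contains
sections with and without injuries but never unsafe pixels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .annotation_store import AnnotationSet, ImageFrame
from .hqa_consensus import ConsensusResult, ConsensusStatus

logger = logging.getLogger(__name__)

# per-pixel states
BACKGROUND = 0
AGREED_INJURY = 1
DISAGREEMENT = 2


@dataclass
class AgreementMap:
    """Tri-state per-pixel map of consensus outcomes for one image."""

    image_id: str
    grid: np.ndarray  # (H, W) uint8 in {0, 1, 2}


@dataclass
class TrainingSection:
    image_id: str
    origin: Tuple[int, int]
    size: int
    image: np.ndarray  # (size, size, 3) uint8
    labels: np.ndarray  # (size, size) bool, True = agreed injury
    contains_injury: bool
    split: Optional[str] = None


def build_agreement_map(
    image: ImageFrame,
    annotations: AnnotationSet,
    results: Mapping[str, ConsensusResult],
) -> AgreementMap:
    """Color every reviewed detection by its consensus outcome.

    ``results`` maps detection_id (mask_id) to its finalized result.  A mask
    without a finalized result, or a blacklisted one, is an error — the
    caller must exclude blacklisted images entirely.  Disagreement takes
    precedence where annotation sources overlap.
    """
    if annotations.image_id != image.image_id:
        raise ValueError("annotations do not reference the given image")
    grid = np.zeros((image.height, image.width), dtype=np.uint8)
    for mask in annotations.masks:
        res = results.get(mask.mask_id)
        if res is None or len(res.verdicts) != 3:
            raise ValueError(f"detection {mask.mask_id!r} has no finalized consensus")
        if res.status == ConsensusStatus.blacklisted:
            raise ValueError(
                f"detection {mask.mask_id!r} is blacklisted; exclude the image"
            )
        idx = np.array(sorted(mask.pixels), dtype=np.intp)
        if res.status == ConsensusStatus.agreed_injury:
            vals = grid[idx[:, 0], idx[:, 1]]
            grid[idx[:, 0][vals != DISAGREEMENT], idx[:, 1][vals != DISAGREEMENT]] = AGREED_INJURY
        elif res.status == ConsensusStatus.disagreement:
            grid[idx[:, 0], idx[:, 1]] = DISAGREEMENT
        # agreed_no_injury -> background, leave as-is
    return AgreementMap(image_id=image.image_id, grid=grid)


def valid_origins(amap: AgreementMap, size: int) -> List[Tuple[int, int]]:
    """All window origins whose (size x size) crop is disagreement-free."""
    h, w = amap.grid.shape
    if size > h or size > w:
        return []
    bad = (amap.grid == DISAGREEMENT).astype(np.int64)
    # summed-area table for O(1) window queries
    sat = np.zeros((h + 1, w + 1), dtype=np.int64)
    sat[1:, 1:] = bad.cumsum(0).cumsum(1)
    out = []
    for r in range(h - size + 1):
        for c in range(w - size + 1):
            s = sat[r + size, c + size] - sat[r, c + size] - sat[r + size, c] + sat[r, c]
            if s == 0:
                out.append((r, c))
    return out


def sample_sections(
    amap: AgreementMap,
    image: ImageFrame,
    n: int,
    size: int = 256,
    seed: int = 0,
    max_retries: int = 1000,
) -> List[TrainingSection]:
    """Draw ``n`` disagreement-free sections uniformly over valid origins.

    Each draw picks a window origin uniformly at random; a window containing
    any disagreement pixel is rejected and redrawn, up to ``max_retries``
    times per section, after which the section is skipped with a logged
    warning (under-delivery is visible in the returned length).
    """
    if image.image_id != amap.image_id:
        raise ValueError("image does not match agreement map")
    if size > image.height or size > image.width:
        raise ValueError("section size exceeds image dimensions")
    rng = np.random.default_rng(seed)
    h, w = amap.grid.shape
    bad = amap.grid == DISAGREEMENT
    pos = amap.grid == AGREED_INJURY
    sections: List[TrainingSection] = []
    for _ in range(n):
        accepted = None
        for _try in range(max_retries):
            r = int(rng.integers(0, h - size + 1))
            c = int(rng.integers(0, w - size + 1))
            if not bad[r : r + size, c : c + size].any():
                accepted = (r, c)
                break
        if accepted is None:
            logger.warning(
                "no disagreement-free %dx%d section found in image %s after %d tries",
                size, size, amap.image_id, max_retries,
            )
            continue
        r, c = accepted
        labels = pos[r : r + size, c : c + size].copy()
        sections.append(
            TrainingSection(
                image_id=amap.image_id,
                origin=(r, c),
                size=size,
                image=image.channels[r : r + size, c : c + size].copy(),
                labels=labels,
                contains_injury=bool(labels.any()),
            )
        )
    return sections


def assemble_dataset(
    sections: Sequence[TrainingSection],
    train_fraction: float = 0.8,
    seed: int = 0,
) -> Tuple[List[TrainingSection], List[TrainingSection]]:
    """Split sections into train / validation by *source image*.

    All sections of one image land in the same split, preventing leakage
    between overlapping crops.  The split is deterministic given the seed
    and invariant to the input ordering.  Where possible both splits get at
    least one section with and one without an injury.
    """
    if not sections:
        raise ValueError("no sections to split")
    if not (0.0 < train_fraction < 1.0):
        raise ValueError("train_fraction must be in (0, 1); validation data are "
                         "required for early stopping")
    by_image: Dict[str, List[TrainingSection]] = {}
    for s in sections:
        by_image.setdefault(s.image_id, []).append(s)
    for group in by_image.values():
        group.sort(key=lambda s: (s.origin, s.size))
    image_ids = sorted(by_image)
    if len(image_ids) < 2:
        raise ValueError("need at least 2 source images to split")
    rng = np.random.default_rng(seed)
    order = [image_ids[i] for i in rng.permutation(len(image_ids))]
    n_train = int(round(train_fraction * len(order)))
    n_train = min(max(n_train, 1), len(order) - 1)
    train_ids, val_ids = order[:n_train], order[n_train:]

    def has_injury(ids: List[str]) -> bool:
        return any(s.contains_injury for i in ids for s in by_image[i])

    def has_clean(ids: List[str]) -> bool:
        return any(not s.contains_injury for i in ids for s in by_image[i])

    # best-effort mix: swap one image if a split lacks a class the other has twice
    for pred in (has_injury, has_clean):
        for a, b in ((train_ids, val_ids), (val_ids, train_ids)):
            if not pred(a) and sum(pred([i]) for i in b) >= 2:
                give = next(i for i in b if pred([i]))
                take = next((i for i in a if not pred([i])), None)
                b.remove(give)
                a.append(give)
                if take is not None:
                    a.remove(take)
                    b.append(take)

    train = [s for i in sorted(train_ids) for s in by_image[i]]
    val = [s for i in sorted(val_ids) for s in by_image[i]]
    for s in train:
        s.split = "train"
    for s in val:
        s.split = "val"
    return train, val
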