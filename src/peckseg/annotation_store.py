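"""Data model and file I/O for images, per-instance injury masks and blacklists.

An annotator marks each visible pecking injury as a separate "drawing layer":
one sparse set of pixels per injured animal.  This module holds those layers
(:class:`InjuryMask`), groups them per image and annotation source
(:class:`AnnotationSet`), and persists them as a 16-bit instance-label PNG
plus a JSON sidecar with run-length-encoded pixel lists.  The round trip is
lossless.

Coordinate convention: 0-based ``(row, col)``, origin top-left, half-open
ranges ``[0, height) x [0, width)``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Dict, FrozenSet, Iterable, List, Mapping, Optional, Tuple

import numpy as np
from PIL import Image

Pixel = Tuple[int, int]


class Stage(str, Enum):
    """Provenance of an annotation set within the pipeline."""

    ground_truth = "ground_truth"
    naive = "naive"
    network = "network"
    network_assisted = "network_assisted"
    hqa = "hqa"


class AnnotationFormatError(ValueError):
    """Raised when an on-disk annotation pair is malformed or inconsistent."""


@dataclass(frozen=True)
class ImageFrame:
    """A single video frame (or synthetic scene) to be annotated."""

    image_id: str
    channels: np.ndarray  # (H, W, 3) uint8 RGB
    source_tag: str = ""

    def __post_init__(self) -> None:
        arr = np.asarray(self.channels)
        if arr.ndim != 3 or arr.shape[2] != 3:
            raise ValueError("channels must be an (H, W, 3) RGB array")
        if arr.shape[0] <= 0 or arr.shape[1] <= 0:
            raise ValueError("image dimensions must be positive")
        if arr.dtype != np.uint8:
            raise ValueError("channels must be uint8")
        object.__setattr__(self, "channels", arr)

    @property
    def height(self) -> int:
        return int(self.channels.shape[0])

    @property
    def width(self) -> int:
        return int(self.channels.shape[1])


@dataclass(frozen=True)
class InjuryMask:
    """One drawing layer: the pixels one source assigned to one injury."""

    mask_id: str
    image_id: str
    pixels: FrozenSet[Pixel]
    layer_label: str = ""

    def __post_init__(self) -> None:
        px = frozenset((int(r), int(c)) for r, c in self.pixels)
        if not px:
            raise ValueError(f"mask {self.mask_id!r} has no pixels")
        object.__setattr__(self, "pixels", px)

    def check_bounds(self, height: int, width: int) -> None:
        for r, c in self.pixels:
            if not (0 <= r < height and 0 <= c < width):
                raise ValueError(
                    f"mask {self.mask_id!r} pixel ({r}, {c}) outside "
                    f"[0, {height}) x [0, {width})"
                )

    @property
    def area(self) -> int:
        return len(self.pixels)


@dataclass
class AnnotationSet:
    """All injury masks for one image from one source at one pipeline stage."""

    image_id: str
    masks: List[InjuryMask]
    annotator_id: str
    stage: Stage

    def __post_init__(self) -> None:
        self.stage = Stage(self.stage)
        for m in self.masks:
            if m.image_id != self.image_id:
                raise ValueError(
                    f"mask {m.mask_id!r} references image {m.image_id!r}, "
                    f"set references {self.image_id!r}"
                )

    def union_pixels(self) -> FrozenSet[Pixel]:
        out: set = set()
        for m in self.masks:
            out |= m.pixels
        return frozenset(out)


@dataclass
class Blacklist:
    """Images excluded from the consensus pool after a piece rejection."""

    image_ids: set = field(default_factory=set)
    reasons: Dict[str, str] = field(default_factory=dict)

    def add(self, image_id: str, reason: str = "") -> None:
        self.image_ids.add(image_id)
        self.reasons.setdefault(image_id, reason)

    def __contains__(self, image_id: str) -> bool:
        return image_id in self.image_ids

    def to_json(self, path) -> None:
        entries = [
            {"image_id": i, "reason": self.reasons.get(i, "")}
            for i in sorted(self.image_ids)
        ]
        Path(path).write_text(json.dumps(entries, indent=1))

    @classmethod
    def from_json(cls, path) -> "Blacklist":
        entries = json.loads(Path(path).read_text())
        bl = cls()
        for e in entries:
            bl.add(e["image_id"], e.get("reason", ""))
        return bl


# ---------------------------------------------------------------------------
# raster <-> sparse conversion

def rasterize(mask: InjuryMask, height: int, width: int) -> np.ndarray:
    """Render a sparse mask onto a (height, width) boolean grid."""
    mask.check_bounds(height, width)
    grid = np.zeros((height, width), dtype=bool)
    idx = np.array(sorted(mask.pixels), dtype=np.intp)
    grid[idx[:, 0], idx[:, 1]] = True
    return grid


def sparsify(grid: np.ndarray) -> FrozenSet[Pixel]:
    """Inverse of :func:`rasterize`: the set of True coordinates."""
    rows, cols = np.nonzero(np.asarray(grid))
    return frozenset(zip(rows.tolist(), cols.tolist()))


def pixels_to_rle(pixels: Iterable[Pixel]) -> List[List[int]]:
    """Row-major run-length encoding: ``[[row, col_start, run_len], ...]``."""
    runs: List[List[int]] = []
    for r, c in sorted(pixels):
        if runs and runs[-1][0] == r and runs[-1][1] + runs[-1][2] == c:
            runs[-1][2] += 1
        else:
            runs.append([r, c, 1])
    return runs


def rle_to_pixels(runs: Iterable[Iterable[int]]) -> FrozenSet[Pixel]:
    px = set()
    for r, c0, n in runs:
        if n <= 0:
            raise AnnotationFormatError(f"non-positive run length in RLE: {[r, c0, n]}")
        px.update((r, c) for c in range(c0, c0 + n))
    return frozenset(px)


# ---------------------------------------------------------------------------
# file pair I/O

def _paths(path) -> Tuple[Path, Path]:
    base = Path(path)
    if base.suffix in {".png", ".json"}:
        base = base.with_suffix("")
    return base.parent / (base.name + ".png"), base.parent / (base.name + ".json")


def write_annotation_set(aset: AnnotationSet, path, height: int, width: int) -> Tuple[Path, Path]:
    """Write ``<path>.png`` (16-bit instance labels) + ``<path>.json`` sidecar.

    Label value ``k`` marks the k-th mask (1-based); 0 is background.
    Overlapping instances cannot be represented in a label image and are
    rejected with the colliding mask ids.
    """
    label = np.zeros((height, width), dtype=np.uint16)
    owner: Dict[Pixel, str] = {}
    for k, m in enumerate(aset.masks, start=1):
        m.check_bounds(height, width)
        for p in m.pixels:
            if p in owner:
                raise ValueError(
                    f"overlapping instance pixels between masks "
                    f"{owner[p]!r} and {m.mask_id!r} at {p}"
                )
            owner[p] = m.mask_id
        idx = np.array(sorted(m.pixels), dtype=np.intp)
        label[idx[:, 0], idx[:, 1]] = k
    png_path, json_path = _paths(path)
    Image.fromarray(label).save(png_path)  # uint16 -> 16-bit grayscale PNG
    sidecar = {
        "image_id": aset.image_id,
        "annotator_id": aset.annotator_id,
        "stage": aset.stage.value,
        "height": height,
        "width": width,
        "instances": [
            {
                "mask_id": m.mask_id,
                "layer_label": m.layer_label,
                "rle": pixels_to_rle(m.pixels),
            }
            for m in aset.masks
        ],
    }
    json_path.write_text(json.dumps(sidecar))
    return png_path, json_path


def read_annotation_set(path) -> AnnotationSet:
    """Read a file pair written by :func:`write_annotation_set`.

    A bare third-party label image (missing sidecar) is accepted: each
    distinct positive label value becomes one mask, stage defaults to
    ``ground_truth`` and the annotator to ``"unknown"``.
    """
    png_path, json_path = _paths(path)
    label = np.array(Image.open(png_path), dtype=np.uint32)
    image_id = png_path.stem
    if not json_path.exists():
        masks = []
        for k in np.unique(label):
            if k == 0:
                continue
            masks.append(
                InjuryMask(
                    mask_id=f"{image_id}:{int(k)}",
                    image_id=image_id,
                    pixels=sparsify(label == k),
                    layer_label=str(int(k)),
                )
            )
        return AnnotationSet(image_id, masks, annotator_id="unknown", stage=Stage.ground_truth)

    try:
        sidecar = json.loads(json_path.read_text())
        instances = sidecar["instances"]
        image_id = sidecar["image_id"]
    except (json.JSONDecodeError, KeyError, TypeError) as exc:
        raise AnnotationFormatError(f"malformed sidecar {json_path}: {exc}") from exc

    present = set(int(v) for v in np.unique(label) if v != 0)
    declared = set(range(1, len(instances) + 1))
    if not present <= declared:
        raise AnnotationFormatError(
            f"label values {sorted(present - declared)} present in {png_path} "
            f"but absent from sidecar RLE"
        )
    masks = []
    for inst in instances:
        try:
            masks.append(
                InjuryMask(
                    mask_id=inst["mask_id"],
                    image_id=image_id,
                    pixels=rle_to_pixels(inst["rle"]),
                    layer_label=inst.get("layer_label", ""),
                )
            )
        except (KeyError, TypeError, ValueError) as exc:
            raise AnnotationFormatError(f"malformed instance in {json_path}: {exc}") from exc
    return AnnotationSet(
        image_id,
        masks,
        annotator_id=sidecar.get("annotator_id", "unknown"),
        stage=Stage(sidecar.get("stage", "ground_truth")),
    )
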