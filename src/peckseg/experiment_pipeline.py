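"""End-to-end comparison of naive vs. network-assisted annotation training.

Replicates the study design on synthetic scenes: one arm trains the
segmentation model directly on a single observer's naive annotations; the
other arm first passes those annotations (plus the naive-trained network's
own detections) through three-observer consensus review, trains an interim
model on disagreement-free sections, lets that model propose detections,
has a simulated reviewer edit them, and trains on the resulting
network-assisted annotations.  Both arms use the same number of annotated
training images and are evaluated on the same held-out scenes — against
both the synthetic ground truth (unavailable in a real barn) and a
simulated human annotator (the only reference the original setting has).
"""

from __future__ import annotations

import dataclasses
import zlib
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .annotation_store import AnnotationSet, ImageFrame, Stage
from .agreement_metrics import (
    DetectionReport,
    aggregate_reports,
    landis_koch_band,
    match_detections,
    whole_image_iou,
)
from .hqa_consensus import ConsensusPool, ConsensusSummary, make_pieces, tally
from .section_sampler import (
    AGREED_INJURY,
    AgreementMap,
    assemble_dataset,
    build_agreement_map,
    sample_sections,
)
from .seg_trainer import TrainConfig, TrainedModel, assist, predict, train
from .synthetic_scenes import (
    ObserverModel,
    SceneSpec,
    default_roster,
    simulate_observer,
    simulate_opinion,
    simulate_reviewer_edit,
)


@dataclass
class ExperimentConfig:
    scene: SceneSpec = field(default_factory=SceneSpec)
    observers: List[ObserverModel] = field(default_factory=default_roster)
    n_scenes: int = 60
    n_train_per_arm: int = 40
    iou_threshold: float = 0.5
    piece_size: int = 128
    section_size: int = 96
    sections_per_image: int = 6
    train_config: TrainConfig = field(default_factory=TrainConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.observers) < 3:
            raise ValueError("the consensus stage requires at least 3 observers")
        if not (0 < self.n_train_per_arm < self.n_scenes):
            raise ValueError("need n_train_per_arm < n_scenes (held-out images required)")


@dataclass
class ExperimentReport:
    """Side-by-side outcome of the two training arms."""

    arms: Dict[str, Dict[str, DetectionReport]]
    consensus_summary: ConsensusSummary
    n_hqa_images: int
    train_image_ids: List[str]
    heldout_image_ids: List[str]
    training_epochs: Dict[str, int]
    provenance: Dict[str, object]

    def as_dict(self) -> dict:
        return {
            "arms": {
                arm: {ref: rep.as_dict() for ref, rep in refs.items()}
                for arm, refs in self.arms.items()
            },
            "consensus_summary": dataclasses.asdict(self.consensus_summary),
            "n_hqa_images": self.n_hqa_images,
            "n_train_images": len(self.train_image_ids),
            "n_heldout_images": len(self.heldout_image_ids),
            "training_epochs": self.training_epochs,
            "provenance": self.provenance,
        }


def _naive_label_map(frame: ImageFrame, annotations: AnnotationSet) -> AgreementMap:
    """Treat every annotated pixel as positive label — no consensus filter."""
    grid = np.zeros((frame.height, frame.width), dtype=np.uint8)
    for m in annotations.masks:
        idx = np.array(sorted(m.pixels), dtype=np.intp)
        grid[idx[:, 0], idx[:, 1]] = AGREED_INJURY
    return AgreementMap(image_id=frame.image_id, grid=grid)


def _train_on_maps(
    scenes: Dict[str, ImageFrame],
    maps: Dict[str, AgreementMap],
    config: ExperimentConfig,
    seed: int,
) -> TrainedModel:
    sections = []
    for image_id in sorted(maps):
        sections.extend(
            sample_sections(
                maps[image_id],
                scenes[image_id],
                n=config.sections_per_image,
                size=config.section_size,
                seed=seed + (zlib.crc32(image_id.encode()) % 100_000),
            )
        )
    tr, va = assemble_dataset(sections, train_fraction=0.8, seed=seed)
    tc = replace(config.train_config, seed=seed)
    return train(tr, va, tc)


def run_experiment(config: ExperimentConfig) -> ExperimentReport:
    """Execute the full comparison; deterministic given ``config.seed``."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 77]))
    scene_seeds = set()
    while len(scene_seeds) < config.n_scenes:
        scene_seeds.add(int(rng.integers(2**31 - 1)))
    scene_seeds = sorted(scene_seeds)

    frames: Dict[str, ImageFrame] = {}
    gts: Dict[str, AnnotationSet] = {}
    metas: Dict[str, dict] = {}
    for s in scene_seeds:
        frame, gt, meta = _generate(config.scene, s)
        frames[frame.image_id] = frame
        gts[frame.image_id] = gt
        metas[frame.image_id] = meta
    ids = sorted(frames)
    order = [ids[i] for i in rng.permutation(len(ids))]
    train_ids = sorted(order[: config.n_train_per_arm])
    held_ids = sorted(order[config.n_train_per_arm :])
    shape = (config.scene.height, config.scene.width)
    primary = config.observers[0]

    # (2) naive annotations of the training images by the primary observer
    naive = {
        i: simulate_observer(gts[i], primary, shape, metas[i], jitter_seed=0)
        for i in train_ids
    }

    # (3) arm NA: train directly on the naive labels
    na_maps = {i: _naive_label_map(frames[i], naive[i]) for i in train_ids}
    na_model = _train_on_maps(frames, na_maps, config, seed=config.seed * 7 + 1)

    # (4) consensus review of naive + network detections
    combined: Dict[str, AnnotationSet] = {}
    pool = ConsensusPool()
    det_pixels: Dict[str, frozenset] = {}
    for i in train_ids:
        _, net = predict(na_model, frames[i])
        masks = list(naive[i].masks) + list(net.masks)
        combined[i] = AnnotationSet(i, masks, annotator_id="review_pool",
                                    stage=Stage.naive)
        for m in masks:
            det_pixels[m.mask_id] = m.pixels
        for piece in make_pieces(frames[i], combined[i], crop_size=config.piece_size):
            pool.add_piece(piece)

    progressed = True
    while progressed:
        progressed = False
        for obs in config.observers:
            piece = pool.schedule_next(obs.observer_id)
            if piece is None:
                continue
            rec = simulate_opinion(
                piece.piece_id,
                det_pixels[piece.detection_id],
                gts[piece.image_id],
                metas[piece.image_id]["locations"],
                obs,
            )
            pool.record_opinion(rec)
            progressed = True

    results_by_det = {r.detection_id: r for r in pool.finished_results()}
    summary = tally(pool.finished_results(), pool.opinion_log)

    # (5) interim model trained on disagreement-free HQA sections
    hqa_maps = {}
    for i in train_ids:
        if i in pool.blacklist:
            continue
        hqa_maps[i] = build_agreement_map(frames[i], combined[i], results_by_det)
    interim = _train_on_maps(frames, hqa_maps, config, seed=config.seed * 7 + 2)

    # (6) network-assisted annotations: proposals edited by the reviewer
    proposals = assist(interim, [frames[i] for i in train_ids])
    naa = {
        i: simulate_reviewer_edit(props, gts[i], primary, shape, jitter_seed=2000)
        for i, props in zip(train_ids, proposals)
    }

    # (7) arm NAA
    naa_maps = {i: _naive_label_map(frames[i], naa[i]) for i in train_ids}
    naa_model = _train_on_maps(frames, naa_maps, config, seed=config.seed * 7 + 3)

    # (8) held-out evaluation, against ground truth and a human annotator
    human_eval = {
        i: simulate_observer(gts[i], primary, shape, metas[i], jitter_seed=7)
        for i in held_ids
    }
    arms: Dict[str, Dict[str, DetectionReport]] = {}
    for arm_name, model in (("naive", na_model), ("network_assisted", naa_model)):
        vs_gt, vs_human = [], []
        for i in held_ids:
            _, pred = predict(model, frames[i])
            vs_gt.append(match_detections(pred, gts[i], config.iou_threshold))
            vs_human.append(match_detections(pred, human_eval[i], config.iou_threshold))
        arms[arm_name] = {
            "vs_ground_truth": aggregate_reports(vs_gt),
            "vs_human": aggregate_reports(vs_human),
        }

    return ExperimentReport(
        arms=arms,
        consensus_summary=summary,
        n_hqa_images=len(pool.hqa_image_ids()),
        train_image_ids=train_ids,
        heldout_image_ids=held_ids,
        training_epochs={
            "naive": na_model.stopped_epoch,
            "interim": interim.stopped_epoch,
            "network_assisted": naa_model.stopped_epoch,
        },
        provenance={
            "seed": config.seed,
            "scene_seeds": scene_seeds,
            "n_scenes": config.n_scenes,
            "n_train_per_arm": config.n_train_per_arm,
            "observers": [o.observer_id for o in config.observers],
            "iou_threshold": config.iou_threshold,
        },
    )


def _generate(spec: SceneSpec, seed: int):
    from .synthetic_scenes import generate_scene

    return generate_scene(replace(spec, seed=seed))


def observer_agreement_study(
    spec: SceneSpec,
    roster: Sequence[ObserverModel],
    n_images: int = 50,
    seed: int = 0,
    include_intra: bool = True,
) -> pd.DataFrame:
    """Reliability table: mean pairwise whole-image IoU over ``n_images``.

    Each observer annotates every scene once; for the intra-observer row the
    first observer annotates the same scenes a second time with a fresh
    session (jitter) seed.  Values come with their Landis-Koch band.
    """
    if len(roster) < 1:
        raise ValueError("need at least one observer")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 55]))
    scene_seeds = set()
    while len(scene_seeds) < n_images:
        scene_seeds.add(int(rng.integers(2**31 - 1)))
    annos: Dict[str, List[AnnotationSet]] = {o.observer_id: [] for o in roster}
    intra_key = f"{roster[0].observer_id}a"
    if include_intra:
        annos[intra_key] = []
    shape = (spec.height, spec.width)
    for s in sorted(scene_seeds):
        frame, gt, meta = _generate(spec, s)
        for o in roster:
            annos[o.observer_id].append(
                simulate_observer(gt, o, shape, meta, jitter_seed=0))
        if include_intra:
            annos[intra_key].append(
                simulate_observer(gt, roster[0], shape, meta, jitter_seed=1))

    rows = []
    for ia in range(len(roster)):
        for ib in range(ia + 1, len(roster)):
            a, b = roster[ia].observer_id, roster[ib].observer_id
            ious = [whole_image_iou(x, y) for x, y in zip(annos[a], annos[b])]
            rows.append((f"{a} vs {b}", "inter", float(np.mean(ious))))
    if include_intra:
        a = roster[0].observer_id
        ious = [whole_image_iou(x, y) for x, y in zip(annos[a], annos[intra_key])]
        rows.append((f"{a} vs {a}a", "intra", float(np.mean(ious))))
    df = pd.DataFrame(rows, columns=["comparison", "kind", "iou"])
    df["band"] = [landis_koch_band(v).value for v in df["iou"]]
    return df
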