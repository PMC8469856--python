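import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")

from peckseg import AnnotationSet, ImageFrame, InjuryMask, Stage
from peckseg.synthetic_scenes import SceneSpec, generate_scene


def make_mask(mask_id, pixels, image_id="img", layer=""):
    return InjuryMask(mask_id=mask_id, image_id=image_id,
                      pixels=frozenset(pixels), layer_label=layer)


def make_set(masks, image_id="img", annotator="obs", stage=Stage.naive):
    return AnnotationSet(image_id, list(masks), annotator_id=annotator, stage=stage)


def box_pixels(r0, c0, h, w):
    return frozenset((r, c) for r in range(r0, r0 + h) for c in range(c0, c0 + w))


@pytest.fixture(scope="session")
def scene():
    """One deterministic synthetic scene with injuries and distractors."""
    spec = SceneSpec(seed=77)
    frame, gt, meta = generate_scene(spec)
    assert gt.masks, "fixture scene must contain injuries"
    assert meta["distractors"], "fixture scene must contain distractors"
    return spec, frame, gt, meta


@pytest.fixture
def blank_frame():
    arr = np.zeros((64, 64, 3), dtype=np.uint8)
    return ImageFrame(image_id="img", channels=arr)
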