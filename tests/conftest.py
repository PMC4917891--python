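"""Shared fixtures: scaled-down generator configs and an on-disk cohort.

Most tests run on a 240 px / 10 um-per-pixel patch — the same 2.4 x 2.4 mm
field and 10x10 grid as the full geometry, with the area filter scaled by
pixel area (506 um^2 = 5 px at 10 um pitch).
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from hotspotmap import GeneratorConfig, generate_cohort
from hotspotmap.segmentation import SegmentationConfig

settings.register_profile("suite", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("suite")

SMALL_SIDE = 240
SMALL_MIN_AREA = 5  # 506 um^2 at 10 um pitch


def small_config(preset: str, **overrides) -> GeneratorConfig:
    side = overrides.pop("image_side_px", SMALL_SIDE)
    return GeneratorConfig.for_preset(preset, image_side_px=side, **overrides)


def small_seg_config(**overrides) -> SegmentationConfig:
    kw = dict(min_area_px=SMALL_MIN_AREA)
    kw.update(overrides)
    return SegmentationConfig(**kw)


@pytest.fixture(scope="session")
def flat_small_config() -> GeneratorConfig:
    return small_config("flat", seed=7)


@pytest.fixture(scope="session")
def cohort_dir(tmp_path_factory, flat_small_config):
    """A tiny flat-preset cohort written to disk (2 animals x 2 branches)."""
    out = tmp_path_factory.mktemp("cohort")
    generate_cohort(flat_small_config, n_animals=2, branches_per_animal=2, seed=11, out_dir=out)
    return out


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
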