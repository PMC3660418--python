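"""Shared fixtures: phantoms and pipeline runs reused across test modules.

Session scope keeps the expensive artifacts (phantom voxelization, the
4x-resolution oracle, projection/reconstruction) to one run each.
"""

import numpy as np
import pytest

from acinomorph.config import PipelineConfig
from acinomorph.phantoms import (PhantomSpec, boundary_mask_from_labels,
                                 make_terminal_unit_phantom)
from acinomorph.pipeline import run_pipeline
from acinomorph.segmentation import CannyParams


def small_spec(**overrides) -> PhantomSpec:
    """A 96-cube terminal unit that keeps brute-force oracles cheap."""
    kw = dict(
        grid_shape=(96, 96, 96),
        mother_radius_um=25.0,
        mother_length_um=36.0,
        daughter1_semiaxes_um=(32.0, 26.0, 26.0),
        daughter2_semiaxes_um=(28.0, 23.0, 23.0),
        mouth1_radius_um=17.0,
        mouth2_radius_um=14.0,
        septum_gap_um=5.0,
        neck_length_um=8.0,
        rng_seed=11,
    )
    kw.update(overrides)
    return PhantomSpec(**kw)


def tiny_spec(**overrides) -> PhantomSpec:
    """A 64-cube terminal unit for fast file/CLI round trips."""
    kw = dict(
        grid_shape=(64, 64, 64),
        mother_radius_um=18.0,
        mother_length_um=22.0,
        daughter1_semiaxes_um=(20.0, 17.0, 17.0),
        daughter2_semiaxes_um=(18.0, 15.0, 15.0),
        mouth1_radius_um=11.0,
        mouth2_radius_um=9.0,
        septum_gap_um=5.0,
        neck_length_um=5.0,
        rng_seed=23,
    )
    kw.update(overrides)
    return PhantomSpec(**kw)


@pytest.fixture(scope="session")
def unit128():
    """Default 128-cube phantom with oracle ground truth and truth mask."""
    spec = PhantomSpec(rng_seed=3)
    lv, gt, ann = make_terminal_unit_phantom(spec)
    mask = boundary_mask_from_labels(lv)
    return spec, lv, gt, ann, mask


@pytest.fixture(scope="session")
def unit96():
    """Small phantom (no imaging), for extraction/morphometry checks."""
    spec = small_spec()
    lv, gt, ann = make_terminal_unit_phantom(spec)
    mask = boundary_mask_from_labels(lv)
    return spec, lv, gt, ann, mask


@pytest.fixture(scope="session")
def imaged96():
    """Small phantom run through the full imaging chain (400 angles,
    fringes, noise, FBP, 3-axis Canny)."""
    config = PipelineConfig(
        n_projections=400,
        seed=5,
        segmentation_axes=(0, 1, 2),
        canny=CannyParams(),
    )
    return run_pipeline(small_spec(rng_seed=17), config, unit_id="imaged96")
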