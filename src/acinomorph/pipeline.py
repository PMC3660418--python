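"""The full simulation-and-measurement chain as one library call.

phantom -> line-integral projection -> edge enhancement -> photon noise
-> filtered back projection -> Canny boundary segmentation -> flood-fill
unit extraction -> morphometry.  Each stage's artifact is kept in the
returned :class:`PipelineResult` so tests and scripts can interrogate
intermediates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .config import PipelineConfig
from .extraction import TerminalUnitLabels, UnitAnnotation, extract_terminal_unit
from .morphometry import MorphometryRecord, measure_unit
from .phantoms import GroundTruth, LabeledVolume, PhantomSpec, make_terminal_unit_phantom
from .projection import (ProjectionSet, add_noise, apply_edge_enhancement,
                         default_angles, density_from_labels, forward_project)
from .recon import VoxelVolume, reconstruct_volume
from .segmentation import BoundaryMask, segment_stack

__all__ = ["PipelineResult", "run_pipeline"]

logger = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    spec: PhantomSpec
    phantom: LabeledVolume
    ground_truth: GroundTruth
    annotation: UnitAnnotation
    projections: ProjectionSet
    reconstruction: VoxelVolume
    boundary: BoundaryMask
    unit: TerminalUnitLabels
    record: MorphometryRecord


def run_pipeline(
    spec: PhantomSpec | None = None,
    config: PipelineConfig | None = None,
    unit_id: str = "unit",
) -> PipelineResult:
    """Run the whole chain on a synthetic terminal-unit phantom."""
    config = config or PipelineConfig()
    if spec is None:
        spec = PhantomSpec(voxel_size_um=config.voxel_size_um,
                           rng_seed=config.phantom_seed)
    logger.info("phantom: grid %s, voxel %.3g um", spec.grid_shape, spec.voxel_size_um)
    phantom, gt, ann = make_terminal_unit_phantom(spec)

    density = density_from_labels(phantom)
    angles = default_angles(config.n_projections, config.angular_range_deg)
    logger.info("projecting %d angles over %.0f deg", len(angles), config.angular_range_deg)
    ps = forward_project(density, angles)
    ps = apply_edge_enhancement(ps, config.edge_strength)
    ps = add_noise(ps, config.photons_per_pixel, config.noise_seed,
                   config.attenuation_per_unit)

    logger.info("reconstructing (%s filter)", config.filter_kind)
    recon = reconstruct_volume(ps, config.filter_kind)

    logger.info("segmenting, axes %s", config.segmentation_axes)
    boundary = segment_stack(recon, config.canny, axes=config.segmentation_axes)

    unit = extract_terminal_unit(
        boundary, ann, volume=recon.values, air_tissue_levels=(0.0, 1.0)
    )
    record = measure_unit(unit, unit_id)
    return PipelineResult(
        spec=spec, phantom=phantom, ground_truth=gt, annotation=ann,
        projections=ps, reconstruction=recon, boundary=boundary,
        unit=unit, record=record,
    )
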