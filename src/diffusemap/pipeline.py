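"""End-to-end map reconstruction: corrections -> masking -> background
removal -> accumulation -> symmetrization -> anisotropic isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import background as bg
from . import geometry as geom
from . import masking
from .mapping import (DiffuseMap, accumulate, positivity_offset,
                      subtract_radial_average, symmetrize)


@dataclass
class PipelineConfig:
    oversampling: int = 3
    extent: int = 8
    polarization: bool = True
    solid_angle: bool = True
    scale: bool = True
    mask_bragg: bool = False
    mask_radial: bool = False
    mask_config: masking.MaskConfig = field(default_factory=masking.MaskConfig)
    reference: object = None            # callable or RadialProfile, optional
    fit_range: tuple = (0.63, 1.88)
    pca_components: int = 0
    n_profile_bins: int = 100
    symmetrize: bool = True
    subtract_radial: bool = True
    add_positivity_offset: bool = True


def build_map(frames, geometry: geom.DetectorGeometry,
              crystal: geom.CrystalFrame, config: PipelineConfig,
              ) -> tuple[DiffuseMap, dict]:
    """Run the full reconstruction over a list of rotation frames.

    Returns the final map and a report dict with intermediate statistics
    (dropped pixels, masked-pixel counts per frame, background fits).
    """
    report: dict = {"masked_pixels": [], "background_fits": []}
    qn = np.linalg.norm(geom.frame_q_lab(geometry), axis=-1)
    q_range = (float(qn.min()), float(qn.max()))

    processed = []
    for frame in frames:
        f = geom.correct_frame(frame, geometry, polarization=config.polarization,
                               solid_angle=config.solid_angle,
                               scale=config.scale)
        n_valid0 = int(f.valid_mask.sum())
        if config.mask_bragg:
            spots = masking.predict_spot_pixels(f, geometry, crystal,
                                                config.mask_config)
            f = masking.mask_local_outliers(f, spots, config.mask_config)
        if config.mask_radial:
            f = masking.mask_radial_outliers(f, qn, config.mask_config)
        report["masked_pixels"].append(n_valid0 - int(f.valid_mask.sum()))
        if config.reference is not None:
            profile = bg.radial_profile(f, qn, config.n_profile_bins, q_range)
            params = bg.fit_reference_background(profile, config.reference,
                                                 config.fit_range)
            f = bg.subtract_reference(f, qn, params, config.reference)
            report["background_fits"].append(params)
        processed.append(f)

    if config.pca_components > 0 and len(processed) >= 2:
        profiles = [bg.radial_profile(f, qn, config.n_profile_bins, q_range)
                    for f in processed]
        comps, deviations = bg.pca_residual_correction(profiles,
                                                       config.pca_components)
        report["pca"] = comps
        processed = [bg.apply_radial_correction(f, qn, profiles[0].q_centers, dev)
                     for f, dev in zip(processed, deviations)]

    dmap, dropped = accumulate(processed, geometry, crystal,
                               config.oversampling, config.extent)
    report["dropped_pixels"] = dropped
    report["unsymmetrized"] = dmap.copy()
    if config.symmetrize:
        dmap = symmetrize(dmap)
    if config.subtract_radial:
        dmap = subtract_radial_average(dmap)
    if config.add_positivity_offset:
        dmap = positivity_offset(dmap)
    return dmap, report
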