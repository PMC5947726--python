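"""Bragg-peak removal: spot prediction plus local and radial outlier masks.

Masking is strictly "without replacement": pixels only ever flip from valid
to invalid; intensities are never altered or interpolated.  Downstream
merging ignores invalid pixels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np

from .geometry import (CrystalFrame, DetectorGeometry, DiffractionFrame,
                       frame_q_lab, hkl_from_q, rotate_q_to_crystal)

log = logging.getLogger(__name__)


@dataclass
class MaskConfig:
    window: int = 30                        # local-statistics window (pixels)
    local_sigma_cut: float = 3.0
    radial_mad_cut: float = 5.0
    contaminated_region_mad_cut: float = 2.5
    contaminated_region: np.ndarray | None = None   # boolean pixel map
    hkl_tolerance: float = 0.25             # fraction of a reciprocal spacing
    n_shells: int = 100

    def __post_init__(self):
        if min(self.local_sigma_cut, self.radial_mad_cut,
               self.contaminated_region_mad_cut) <= 0:
            raise ValueError("all cuts must be positive")
        if self.window < 3:
            raise ValueError("window must be at least 3 pixels")
        if self.hkl_tolerance < 0:
            raise ValueError("hkl_tolerance must be non-negative")


# --------------------------------------------------------------------------
# spot prediction


def predict_spot_pixels(frame: DiffractionFrame, geometry: DetectorGeometry,
                        crystal: CrystalFrame, config: MaskConfig) -> np.ndarray:
    """Boolean map of pixels predicted to be spanned by a Bragg reflection.

    A pixel is predicted if, at any of the start/mid/end angles of the
    frame's oscillation, its fractional Miller index lies within
    ``hkl_tolerance`` of an integer along every axis.
    """
    tol = config.hkl_tolerance
    predicted = np.zeros(frame.pixels.shape, dtype=bool)
    if tol == 0.0:
        return predicted
    ql = frame_q_lab(geometry)
    phis = (frame.phi_start, frame.phi_mid, frame.phi_start + frame.phi_width)
    for phi in phis:
        hkl = hkl_from_q(rotate_q_to_crystal(ql, geometry, phi), crystal)
        resid = np.abs(hkl - np.round(hkl))
        predicted |= np.all(resid < tol, axis=-1)
    return predicted


# --------------------------------------------------------------------------
# local (windowed) outliers


def _window_sums(arr: np.ndarray, window: int) -> np.ndarray:
    """Truncated box sums over a centered window, via integral images."""
    n_s, n_f = arr.shape
    c = np.zeros((n_s + 1, n_f + 1), dtype=float)
    np.cumsum(np.cumsum(arr, axis=0), axis=1, out=c[1:, 1:])
    lo = window // 2
    hi = window - lo
    i = np.arange(n_s)
    j = np.arange(n_f)
    i0 = np.clip(i - lo, 0, n_s)
    i1 = np.clip(i + hi, 0, n_s)
    j0 = np.clip(j - lo, 0, n_f)
    j1 = np.clip(j + hi, 0, n_f)
    return (c[np.ix_(i1, j1)] - c[np.ix_(i0, j1)]
            - c[np.ix_(i1, j0)] + c[np.ix_(i0, j0)])


def mask_local_outliers(frame: DiffractionFrame, spot_pixels: np.ndarray,
                        config: MaskConfig) -> DiffractionFrame:
    """Mask predicted pixels whose intensity exceeds the local background.

    A predicted pixel is masked iff I > mean + cut * std of the valid,
    non-predicted pixels inside the window around it.  If the window holds
    no such pixels the predicted pixel is masked unconditionally.
    """
    valid = frame.valid_mask
    neighbors = valid & ~spot_pixels
    # Center intensities on the global valid mean so a perfectly flat image
    # yields exactly zero window statistics (no cumulative-sum round-off).
    offset = frame.pixels[valid].mean() if valid.any() else 0.0
    pix = np.where(neighbors, frame.pixels - offset, 0.0)
    s0 = _window_sums(neighbors.astype(float), config.window)
    s1 = _window_sums(pix, config.window)
    s2 = _window_sums(pix**2, config.window)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = s1 / s0
        var = np.maximum(s2 / s0 - mean**2, 0.0)
    std = np.sqrt(var)
    intensity = frame.pixels - offset
    empty = s0 < 0.5
    outlier = intensity > mean + config.local_sigma_cut * std
    bad = spot_pixels & valid & (empty | np.where(empty, False, outlier))
    return replace(frame, pixels=frame.pixels.copy(),
                   valid_mask=valid & ~bad)


# --------------------------------------------------------------------------
# radial (resolution-shell) outliers


def mask_radial_outliers(frame: DiffractionFrame, q_per_pixel: np.ndarray,
                         config: MaskConfig) -> DiffractionFrame:
    """Mask pixels far above the median of their resolution shell.

    The threshold is median + cut * MAD per shell, with the stricter
    ``contaminated_region_mad_cut`` inside the configured contaminated
    region.  MAD is the raw median absolute deviation (no normality
    factor).  Shells with fewer than 10 valid pixels are skipped.

    The filter is iterated to a fixed point (statistics recomputed after
    each sweep) so that the operation as a whole is idempotent.
    """
    q_per_pixel = np.asarray(q_per_pixel, dtype=float)
    valid = frame.valid_mask.copy()
    q_lo, q_hi = q_per_pixel.min(), q_per_pixel.max()
    edges = np.linspace(q_lo, q_hi, config.n_shells + 1)
    shell = np.clip(np.digitize(q_per_pixel, edges) - 1, 0, config.n_shells - 1)
    cut = np.full(frame.pixels.shape, config.radial_mad_cut)
    if config.contaminated_region is not None:
        cut[np.asarray(config.contaminated_region, dtype=bool)] = \
            config.contaminated_region_mad_cut
    for _ in range(100):
        bad = np.zeros(frame.pixels.shape, dtype=bool)
        for s in range(config.n_shells):
            sel = (shell == s) & valid
            n = int(sel.sum())
            if n == 0:
                continue
            if n < 10:
                log.warning("resolution shell %d has only %d valid pixels; skipped",
                            s, n)
                continue
            vals = frame.pixels[sel]
            med = np.median(vals)
            mad = np.median(np.abs(vals - med))
            bad[sel] = vals > med + cut[sel] * mad
        if not bad.any():
            break
        valid &= ~bad
    return replace(frame, pixels=frame.pixels.copy(), valid_mask=valid)
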