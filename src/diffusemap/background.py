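"""Per-frame removal of radially symmetric non-crystalline scattering.

Two mechanisms, both operating on 1D radial intensity profiles and applied
to pixels by linear interpolation in |q|:

* a reference-profile fit (second-degree polynomial plus a scaled, shifted
  amorphous reference) whose reference component is subtracted; and
* principal-component removal of the residual radial variance between
  frames.

Corrections are functions of |q| only, so they can never alter the
anisotropy of a frame at fixed |q|.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .geometry import DiffractionFrame

# --------------------------------------------------------------------------
# radial profiles


@dataclass
class RadialProfile:
    q_centers: np.ndarray
    intensity: np.ndarray      # NaN where a bin holds no valid pixels
    n_pixels: np.ndarray

    def __post_init__(self):
        self.q_centers = np.asarray(self.q_centers, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        self.n_pixels = np.asarray(self.n_pixels, dtype=int)
        if np.any(np.diff(self.q_centers) <= 0):
            raise ValueError("q_centers must be strictly increasing")

    @property
    def defined(self) -> np.ndarray:
        return self.n_pixels > 0

    def __call__(self, q: np.ndarray) -> np.ndarray:
        """Linear interpolation over defined bins (edge-clamped)."""
        d = self.defined
        return np.interp(q, self.q_centers[d], self.intensity[d])


def radial_profile(frame: DiffractionFrame, q_per_pixel: np.ndarray,
                   n_bins: int = 100,
                   q_range: tuple[float, float] | None = None) -> RadialProfile:
    """Mean intensity of valid pixels in equal-width |q| bins."""
    q = np.asarray(q_per_pixel, dtype=float)
    valid = frame.valid_mask
    lo, hi = q_range if q_range is not None else (q.min(), q.max())
    edges = np.linspace(lo, hi, n_bins + 1)
    idx = np.clip(np.digitize(q[valid], edges) - 1, 0, n_bins - 1)
    counts = np.bincount(idx, minlength=n_bins)
    sums = np.bincount(idx, weights=frame.pixels[valid], minlength=n_bins)
    with np.errstate(invalid="ignore"):
        mean = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return RadialProfile(centers, mean, counts)


# --------------------------------------------------------------------------
# reference-profile (Paratone-like) fit


@dataclass
class BackgroundFitParams:
    """Coefficients of  a q^2 + b q + c + m * I_ref(q - q0)."""
    a: float
    b: float
    c: float
    m: float
    q0: float

    def polynomial(self, q: np.ndarray) -> np.ndarray:
        return self.a * np.asarray(q) ** 2 + self.b * np.asarray(q) + self.c

    def reference_component(self, q: np.ndarray, reference) -> np.ndarray:
        return self.m * _eval_reference(reference, np.asarray(q) - self.q0)


def _eval_reference(reference, q) -> np.ndarray:
    if callable(reference):
        return np.asarray(reference(q), dtype=float)
    d = reference.defined
    return np.interp(q, reference.q_centers[d], reference.intensity[d])


def synthetic_reference_profile(center: float = 1.3, width: float = 0.18,
                                amplitude: float = 1.0):
    """Bundled smooth amorphous-scatter stand-in: one broad Gaussian peak.

    Mimics the radially symmetric oil contaminant peaking near 1.3 1/A;
    a measured reference may be supplied instead as a two-column table.
    """
    def ref(q):
        return amplitude * np.exp(-0.5 * ((np.asarray(q) - center) / width) ** 2)
    return ref


def _golden_section(f, lo: float, hi: float, tol: float = 1e-5,
                    max_iter: int = 200) -> float:
    """Golden-section minimization of a unimodal scalar function."""
    invphi = (np.sqrt(5.0) - 1.0) / 2.0
    a, b = lo, hi
    c = b - invphi * (b - a)
    d = a + invphi * (b - a)
    fc, fd = f(c), f(d)
    for _ in range(max_iter):
        if b - a < tol:
            break
        if fc < fd:
            b, d, fd = d, c, fc
            c = b - invphi * (b - a)
            fc = f(c)
        else:
            a, c, fc = c, d, fd
            d = a + invphi * (b - a)
            fd = f(d)
    return 0.5 * (a + b)


def fit_reference_background(profile: RadialProfile, reference,
                             fit_range: tuple[float, float] = (0.63, 1.88),
                             q0_range: tuple[float, float] = (-0.05, 0.05),
                             ) -> BackgroundFitParams:
    """Least-squares fit of polynomial + shifted reference to a radial profile.

    The fit is linear in (a, b, c, m) with a golden-section search over the
    reference shift q0.  A negative fitted m is truncated to zero (the
    contaminant scale is physically non-negative).
    """
    sel = profile.defined & (profile.q_centers >= fit_range[0]) \
        & (profile.q_centers <= fit_range[1])
    qs = profile.q_centers[sel]
    ys = profile.intensity[sel]
    if qs.size < 5:
        raise ValueError(f"only {qs.size} defined bins in fit range; need >= 5")

    def solve(q0):
        design = np.column_stack([qs**2, qs, np.ones_like(qs),
                                  _eval_reference(reference, qs - q0)])
        coef, *_ = np.linalg.lstsq(design, ys, rcond=None)
        resid = ys - design @ coef
        return coef, float(resid @ resid)

    q0_best = _golden_section(lambda q0: solve(q0)[1], *q0_range)
    coef, _ = solve(q0_best)
    a, b, c, m = coef
    if m < 0:
        design = np.column_stack([qs**2, qs, np.ones_like(qs)])
        coef, *_ = np.linalg.lstsq(design, ys, rcond=None)
        a, b, c = coef
        m, q0_best = 0.0, 0.0
    return BackgroundFitParams(float(a), float(b), float(c), float(m),
                               float(q0_best))


def subtract_reference(frame: DiffractionFrame, q_per_pixel: np.ndarray,
                       params: BackgroundFitParams, reference) -> DiffractionFrame:
    """Subtract the fitted m * I_ref(|q| - q0) component from a frame."""
    corr = params.reference_component(np.asarray(q_per_pixel), reference)
    return replace(frame, pixels=frame.pixels - corr,
                   valid_mask=frame.valid_mask.copy())


# --------------------------------------------------------------------------
# PCA removal of residual radial variance


@dataclass
class VarianceComponents:
    components: np.ndarray      # (k, n_bins), orthonormal, zero in unused bins
    eigenvalues: np.ndarray     # non-increasing variances
    projections: np.ndarray     # (n_frames, k) per-frame coefficients

    def __post_init__(self):
        if self.components.shape[0] > 1:
            gram = self.components @ self.components.T
            if not np.allclose(gram, np.eye(len(gram)), atol=1e-8):
                raise ValueError("components must be mutually orthonormal")
        if np.any(np.diff(self.eigenvalues) > 1e-12):
            raise ValueError("eigenvalues must be non-increasing")


def pca_residual_correction(profiles: list[RadialProfile], n_components: int = 2,
                            ) -> tuple[VarianceComponents, np.ndarray]:
    """Identify and return the leading inter-frame radial variance modes.

    Profiles must share a common q grid.  Standard mean-centered PCA over
    the frame-by-bin matrix; the per-frame background deviation (to be
    subtracted from that frame, interpolated in |q|) is the projection of
    its centered profile onto the leading components.

    Returns (components, deviations) with ``deviations`` of shape
    (n_frames, n_bins); bins undefined in any frame get zero correction.
    """
    n_frames = len(profiles)
    if n_frames < 2:
        raise ValueError("need at least 2 frames for PCA")
    if not 0 <= n_components < n_frames:
        raise ValueError("n_components must satisfy 0 <= k < n_frames")
    q = profiles[0].q_centers
    for p in profiles[1:]:
        if not np.allclose(p.q_centers, q):
            raise ValueError("profiles must share a common q grid")
    mat = np.vstack([p.intensity for p in profiles])
    cols = np.all(np.isfinite(mat), axis=0)
    n_bins = mat.shape[1]
    deviations = np.zeros((n_frames, n_bins))
    if n_components == 0 or cols.sum() == 0:
        comps = VarianceComponents(np.zeros((0, n_bins)), np.zeros(0),
                                   np.zeros((n_frames, 0)))
        return comps, deviations
    x = mat[:, cols]
    xc = x - x.mean(axis=0)
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    k = min(n_components, len(s))
    eigenvalues = s[:k] ** 2 / (n_frames - 1)
    components = np.zeros((k, n_bins))
    components[:, cols] = vt[:k]
    projections = xc @ vt[:k].T
    deviations[:, cols] = projections @ vt[:k]
    comps = VarianceComponents(components, eigenvalues, projections)
    return comps, deviations


def apply_radial_correction(frame: DiffractionFrame, q_per_pixel: np.ndarray,
                            q_centers: np.ndarray, deviation: np.ndarray,
                            ) -> DiffractionFrame:
    """Subtract a binned radial deviation from a frame, interpolating in |q|."""
    corr = np.interp(np.asarray(q_per_pixel), np.asarray(q_centers),
                     np.asarray(deviation))
    return replace(frame, pixels=frame.pixels - corr,
                   valid_mask=frame.valid_mask.copy())
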