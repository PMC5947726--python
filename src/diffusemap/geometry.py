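"""Detector/crystal geometry: pixel-to-reciprocal-space mapping and
photometric corrections applied to rotation-series frames before merging.

Conventions
-----------
* Lab frame: the incident beam travels along +z; a flat detector sits
  perpendicular to the beam at ``distance`` mm, with the fast pixel axis
  along +x and the slow axis along +y.
* Scattering vectors use the crystallographic convention q = 2 pi s, so
  |q| = 4 pi sin(theta) / lambda = 2 pi / d.
* The orientation matrix has the reciprocal-cell vectors (times 2 pi, in
  1/Angstrom) as columns, so that q = A @ (h, k, l).
* Each frame is mapped at its mid-oscillation angle; intensities are
  treated as averaged, not integrated, so no Lorentz factor is applied
  anywhere.  The only photometric corrections are polarization, solid
  angle and the per-frame scale factor.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from . import symmetry


# --------------------------------------------------------------------------
# unit cell


def real_space_matrix(cell: tuple[float, ...]) -> np.ndarray:
    """3x3 matrix with the real-space cell vectors a, b, c as columns (A)."""
    a, b, c, al, be, ga = [float(x) for x in cell]
    if min(a, b, c) <= 0:
        raise ValueError("cell lengths must be positive")
    if not all(0.0 < ang < 180.0 for ang in (al, be, ga)):
        raise ValueError("cell angles must lie in (0, 180) degrees")
    al, be, ga = np.radians([al, be, ga])
    ca, cb, cg, sg = np.cos(al), np.cos(be), np.cos(ga), np.sin(ga)
    v = np.sqrt(1.0 - ca**2 - cb**2 - cg**2 + 2.0 * ca * cb * cg)
    return np.array([
        [a, b * cg, c * cb],
        [0.0, b * sg, c * (ca - cb * cg) / sg],
        [0.0, 0.0, c * v / sg],
    ])


def reciprocal_matrix(cell: tuple[float, ...]) -> np.ndarray:
    """Columns are the reciprocal-cell vectors scaled by 2 pi (1/A)."""
    return 2.0 * np.pi * np.linalg.inv(real_space_matrix(cell)).T


# --------------------------------------------------------------------------
# domain types


def _unit(v, name: str) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v)
    if abs(n - 1.0) > 1e-10:
        raise ValueError(f"{name} must be unit-norm (|v| = {n:.3g})")
    return v


@dataclass(frozen=True)
class DetectorGeometry:
    """Flat detector and beam parameters for one rotation series."""

    distance: float                     # mm, crystal-to-detector
    pixel_size: float                   # mm
    n_fast: int
    n_slow: int
    beam_center: tuple[float, float]    # (fast, slow) in pixels
    wavelength: float                   # Angstrom
    polarization_fraction: float = 0.5
    polarization_plane_normal: tuple[float, float, float] = (0.0, 1.0, 0.0)
    rotation_axis: tuple[float, float, float] = (1.0, 0.0, 0.0)

    def __post_init__(self):
        if self.distance <= 0 or self.pixel_size <= 0 or self.wavelength <= 0:
            raise ValueError("distance, pixel_size and wavelength must be positive")
        if not 0.0 <= self.polarization_fraction <= 1.0:
            raise ValueError("polarization_fraction must lie in [0, 1]")
        object.__setattr__(self, "polarization_plane_normal",
                           tuple(_unit(self.polarization_plane_normal,
                                       "polarization_plane_normal")))
        object.__setattr__(self, "rotation_axis",
                           tuple(_unit(self.rotation_axis, "rotation_axis")))

    @property
    def q_max(self) -> float:
        """Back-scattering limit 4 pi / lambda."""
        return 4.0 * np.pi / self.wavelength


@dataclass
class CrystalFrame:
    """Unit cell, setting matrix and reciprocal point-group of a crystal."""

    unit_cell: tuple[float, float, float, float, float, float]
    spacegroup_label: str = "P1"
    orientation: np.ndarray | None = None       # q = orientation @ hkl
    symmetry_ops: list[np.ndarray] | None = None  # reciprocal rotation parts

    def __post_init__(self):
        if self.orientation is None:
            self.orientation = reciprocal_matrix(self.unit_cell)
        self.orientation = np.asarray(self.orientation, dtype=float)
        if abs(np.linalg.det(self.orientation)) < 1e-12:
            raise ValueError("orientation matrix is singular")
        if self.symmetry_ops is None:
            self.symmetry_ops = symmetry.reciprocal_rotations(self.spacegroup_label)
        self.symmetry_ops = [np.asarray(m, dtype=int) for m in self.symmetry_ops]
        if not symmetry.is_closed(self.symmetry_ops):
            raise ValueError("symmetry_ops are not closed under composition")

    @property
    def laue_ops(self) -> list[np.ndarray]:
        return symmetry.laue_operators(self.symmetry_ops)


@dataclass
class DiffractionFrame:
    """One rotation frame: pixel counts, validity mask and oscillation."""

    pixels: np.ndarray
    valid_mask: np.ndarray
    phi_start: float        # degrees
    phi_width: float        # degrees
    scale_factor: float = 1.0

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=float)
        self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
        if self.pixels.shape != self.valid_mask.shape:
            raise ValueError("pixels and valid_mask must have congruent shapes")
        if self.phi_width <= 0:
            raise ValueError("phi_width must be positive")
        if self.scale_factor <= 0:
            raise ValueError("scale_factor must be positive")

    @property
    def phi_mid(self) -> float:
        return self.phi_start + 0.5 * self.phi_width


# --------------------------------------------------------------------------
# pixel -> q


def rotation_matrix(axis, phi_deg: float) -> np.ndarray:
    """Right-handed rotation by phi (degrees) about a unit axis."""
    axis = np.asarray(axis, dtype=float)
    phi = np.radians(phi_deg)
    k = axis / np.linalg.norm(axis)
    kx = np.array([[0, -k[2], k[1]], [k[2], 0, -k[0]], [-k[1], k[0], 0]])
    return np.eye(3) + np.sin(phi) * kx + (1 - np.cos(phi)) * (kx @ kx)


def pixel_positions(fast, slow, geometry: DetectorGeometry) -> np.ndarray:
    """Lab-frame positions (mm) of pixel centers; shape (..., 3)."""
    fast = np.asarray(fast, dtype=float)
    slow = np.asarray(slow, dtype=float)
    bc_f, bc_s = geometry.beam_center
    x = (fast - bc_f) * geometry.pixel_size
    y = (slow - bc_s) * geometry.pixel_size
    z = np.broadcast_to(geometry.distance, x.shape)
    return np.stack(np.broadcast_arrays(x, y, z), axis=-1)


def scattered_directions(fast, slow, geometry: DetectorGeometry) -> np.ndarray:
    pos = pixel_positions(fast, slow, geometry)
    return pos / np.linalg.norm(pos, axis=-1, keepdims=True)


def q_lab(fast, slow, geometry: DetectorGeometry) -> np.ndarray:
    """Lab-frame scattering vectors (1/A) before crystal rotation."""
    s1 = scattered_directions(fast, slow, geometry)
    s0 = np.array([0.0, 0.0, 1.0])
    return (2.0 * np.pi / geometry.wavelength) * (s1 - s0)


def pixel_to_q(pixel, geometry: DetectorGeometry,
               crystal: CrystalFrame | None = None, phi: float = 0.0) -> np.ndarray:
    """Scattering vector of one pixel, rotated into the crystal frame at phi.

    ``crystal`` is accepted for interface symmetry with the hkl helpers but
    does not influence q itself.  Raises IndexError for out-of-bounds pixels.
    """
    fast, slow = pixel
    if not (0 <= fast < geometry.n_fast and 0 <= slow < geometry.n_slow):
        raise IndexError(f"pixel {pixel} outside detector "
                         f"({geometry.n_fast} x {geometry.n_slow})")
    ql = q_lab(fast, slow, geometry)
    rot = rotation_matrix(geometry.rotation_axis, phi)
    return rot.T @ ql


def frame_q_lab(geometry: DetectorGeometry) -> np.ndarray:
    """Lab q for every pixel of the detector; shape (n_slow, n_fast, 3)."""
    fast, slow = np.meshgrid(np.arange(geometry.n_fast),
                             np.arange(geometry.n_slow))
    return q_lab(fast, slow, geometry)


def rotate_q_to_crystal(ql: np.ndarray, geometry: DetectorGeometry,
                        phi: float) -> np.ndarray:
    rot = rotation_matrix(geometry.rotation_axis, phi)
    return ql @ rot  # == (rot.T @ ql.T).T


def hkl_from_q(q: np.ndarray, crystal: CrystalFrame) -> np.ndarray:
    """Fractional Miller indices of crystal-frame q vectors; shape (..., 3)."""
    inv = np.linalg.inv(crystal.orientation)
    return np.asarray(q) @ inv.T


def q_lab_to_pixel(ql: np.ndarray, geometry: DetectorGeometry) -> np.ndarray:
    """Invert the pixel -> lab-q mapping (for vectors on the Ewald sphere)."""
    ql = np.asarray(ql, dtype=float)
    s1 = ql * geometry.wavelength / (2.0 * np.pi) + np.array([0.0, 0.0, 1.0])
    if np.any(s1[..., 2] <= 0):
        raise ValueError("scattered beam does not intersect the detector")
    t = geometry.distance / s1[..., 2:]
    xy = s1[..., :2] * t
    bc = np.asarray(geometry.beam_center)
    return xy / geometry.pixel_size + bc


# --------------------------------------------------------------------------
# photometric corrections


def polarization_correction(q: np.ndarray, geometry: DetectorGeometry) -> np.ndarray:
    """Kahn-style polarization factor P in (0, 1] for lab-frame q vectors.

    Observed intensities are *divided* by P.  ``polarization_fraction`` is
    the fraction of beam intensity with its E-field in the polarization
    plane (the plane containing the beam whose normal is
    ``polarization_plane_normal``); 0.5 reproduces the unpolarized Thomson
    factor (1 + cos^2 2theta) / 2.
    """
    q = np.asarray(q, dtype=float)
    s1 = q * geometry.wavelength / (2.0 * np.pi) + np.array([0.0, 0.0, 1.0])
    s1 = s1 / np.linalg.norm(s1, axis=-1, keepdims=True)
    n_hat = np.asarray(geometry.polarization_plane_normal)
    e_in_plane = np.cross(n_hat, [0.0, 0.0, 1.0])
    e_in_plane = e_in_plane / np.linalg.norm(e_in_plane)
    p = geometry.polarization_fraction
    proj_plane = (s1 @ e_in_plane) ** 2
    proj_normal = (s1 @ n_hat) ** 2
    return p * (1.0 - proj_plane) + (1.0 - p) * (1.0 - proj_normal)


def solid_angle_correction(pixel, geometry: DetectorGeometry) -> np.ndarray:
    """Relative solid angle Omega(pixel) / Omega(on-axis) = cos^3(psi) <= 1."""
    fast, slow = pixel
    pos = pixel_positions(fast, slow, geometry)
    cos_psi = geometry.distance / np.linalg.norm(pos, axis=-1)
    return cos_psi**3


def frame_correction_factors(geometry: DetectorGeometry) -> np.ndarray:
    """Per-pixel product P * Omega_rel for a whole frame (phi-independent)."""
    ql = frame_q_lab(geometry)
    fast, slow = np.meshgrid(np.arange(geometry.n_fast),
                             np.arange(geometry.n_slow))
    return polarization_correction(ql, geometry) * solid_angle_correction(
        (fast, slow), geometry)


def apply_frame_scale(frame: DiffractionFrame) -> DiffractionFrame:
    """Divide pixel intensities by the frame's scale factor."""
    return replace(frame, pixels=frame.pixels / frame.scale_factor,
                   valid_mask=frame.valid_mask.copy(), scale_factor=1.0)


def correct_frame(frame: DiffractionFrame, geometry: DetectorGeometry,
                  polarization: bool = True, solid_angle: bool = True,
                  scale: bool = True) -> DiffractionFrame:
    """Apply polarization, solid-angle and scale corrections to one frame.

    Intentionally the complete photometric treatment: no Lorentz factor.
    """
    factors = np.ones_like(frame.pixels)
    if polarization:
        factors = factors * polarization_correction(frame_q_lab(geometry), geometry)
    if solid_angle:
        fast, slow = np.meshgrid(np.arange(geometry.n_fast),
                                 np.arange(geometry.n_slow))
        factors = factors * solid_angle_correction((fast, slow), geometry)
    out = replace(frame, pixels=frame.pixels / factors,
                  valid_mask=frame.valid_mask.copy())
    if scale:
        out = apply_frame_scale(out)
    return out
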