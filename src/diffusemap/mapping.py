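"""Merging corrected pixels into a 3D oversampled reciprocal-space map,
symmetrization, and isolation of the anisotropic component.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import (CrystalFrame, DetectorGeometry, DiffractionFrame,
                       frame_q_lab, hkl_from_q, rotate_q_to_crystal)
from .symmetry import laue_operators


@dataclass(eq=False)
class MapGrid:
    """Reciprocal-space grid oversampling Miller indices.

    Nodes sit at fractional indices m / oversampling with integer
    m in [-M, M]^3, M = oversampling * extent; odd oversampling guarantees
    that nodes coincide with the integral Miller indices.
    """

    crystal: CrystalFrame
    oversampling: int = 3
    extent: int = 8

    def __post_init__(self):
        if self.oversampling < 1 or self.oversampling % 2 == 0:
            raise ValueError("oversampling must be a positive odd integer")
        if self.extent < 1:
            raise ValueError("extent must be >= 1")

    @property
    def half_size(self) -> int:
        return self.oversampling * self.extent

    @property
    def size(self) -> int:
        return 2 * self.half_size + 1

    @property
    def shape(self) -> tuple[int, int, int]:
        n = self.size
        return (n, n, n)

    @property
    def n_voxels(self) -> int:
        return self.size**3

    @property
    def A(self) -> np.ndarray:
        """Matrix mapping fractional hkl to q (1/A)."""
        return self.crystal.orientation

    def index_vectors(self) -> np.ndarray:
        """Integer node vectors m, shape (n_voxels, 3), C-ordered."""
        m = self.half_size
        ax = np.arange(-m, m + 1)
        g = np.stack(np.meshgrid(ax, ax, ax, indexing="ij"), axis=-1)
        return g.reshape(-1, 3)

    def hkl(self) -> np.ndarray:
        return self.index_vectors() / self.oversampling

    def q_vectors(self) -> np.ndarray:
        return self.hkl() @ self.A.T

    def q_norms(self) -> np.ndarray:
        return np.linalg.norm(self.q_vectors(), axis=1)

    def nodes_from_hkl(self, hkl: np.ndarray) -> np.ndarray:
        """Nearest node m for fractional hkl; half-distance ties go to the
        lexicographically smaller (lower-index) node."""
        return np.ceil(np.asarray(hkl) * self.oversampling - 0.5).astype(int)

    def in_bounds(self, m: np.ndarray) -> np.ndarray:
        return np.all(np.abs(m) <= self.half_size, axis=-1)

    def flat_index(self, m: np.ndarray) -> np.ndarray:
        n, h = self.size, self.half_size
        m = np.asarray(m) + h
        return (m[..., 0] * n + m[..., 1]) * n + m[..., 2]

    def miller_node_mask(self) -> np.ndarray:
        """Flat boolean mask of nodes coinciding with integral Miller indices."""
        return np.all(self.index_vectors() % self.oversampling == 0, axis=1)


@dataclass
class DiffuseMap:
    """3D diffuse intensity map with per-voxel observation statistics."""

    grid: MapGrid
    intensity: np.ndarray          # flat (n_voxels,), NaN where undefined
    n_obs: np.ndarray
    multiplicity: np.ndarray = None
    snr: np.ndarray = None

    def __post_init__(self):
        self.intensity = np.asarray(self.intensity, dtype=float).ravel()
        self.n_obs = np.asarray(self.n_obs, dtype=float).ravel()
        if self.multiplicity is None:
            self.multiplicity = np.ones_like(self.n_obs)
        if self.snr is None:
            self.snr = np.full_like(self.intensity, np.nan)
        for arr in (self.n_obs, self.multiplicity, self.snr):
            if arr.shape != self.intensity.shape:
                raise ValueError("per-voxel arrays must share one shape")

    @property
    def defined(self) -> np.ndarray:
        return np.isfinite(self.intensity) & (self.n_obs > 0)

    def as_3d(self) -> np.ndarray:
        return self.intensity.reshape(self.grid.shape)

    def copy(self) -> "DiffuseMap":
        return DiffuseMap(self.grid, self.intensity.copy(), self.n_obs.copy(),
                          self.multiplicity.copy(), self.snr.copy())


def map_from_array(arr: np.ndarray, grid: MapGrid) -> DiffuseMap:
    """Wrap a dense model prediction as a fully observed DiffuseMap."""
    flat = np.asarray(arr, dtype=float).ravel()
    if flat.size != grid.n_voxels:
        raise ValueError("array does not match grid")
    return DiffuseMap(grid, flat, np.ones_like(flat))


# --------------------------------------------------------------------------
# accumulation


def accumulate_points(hkl: np.ndarray, values: np.ndarray, grid: MapGrid,
                      ) -> tuple[DiffuseMap, int]:
    """Merge scattered observations at fractional hkl into the grid.

    Each observation is assigned to its nearest node; voxel intensity is
    the plain mean, SNR the mean over the sample standard deviation
    (ddof=1; undefined below two observations).  Returns the map and the
    number of observations dropped for falling outside the grid.
    """
    hkl = np.asarray(hkl, dtype=float).reshape(-1, 3)
    values = np.asarray(values, dtype=float).ravel()
    nodes = grid.nodes_from_hkl(hkl)
    inb = grid.in_bounds(nodes)
    dropped = int((~inb).sum())
    flat = grid.flat_index(nodes[inb])
    v = values[inb]
    n = grid.n_voxels
    counts = np.bincount(flat, minlength=n).astype(float)
    sums = np.bincount(flat, weights=v, minlength=n)
    sq = np.bincount(flat, weights=v * v, minlength=n)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
        var = (sq - counts * mean**2) / np.maximum(counts - 1, 1)
        std = np.sqrt(np.maximum(var, 0.0))
        snr = np.where((counts > 1) & (std > 0), mean / np.where(std > 0, std, 1),
                       np.nan)
    return DiffuseMap(grid, mean, counts, np.ones(n), snr), dropped


def accumulate(frames: list[DiffractionFrame], geometry: DetectorGeometry,
               crystal: CrystalFrame, oversampling: int = 3, extent: int = 8,
               ) -> tuple[DiffuseMap, int]:
    """Map every valid pixel of every (corrected) frame into a DiffuseMap.

    Frames are mapped at their mid-oscillation angle.
    """
    grid = MapGrid(crystal, oversampling, extent)
    ql = frame_q_lab(geometry)
    all_hkl = []
    all_val = []
    for frame in frames:
        qc = rotate_q_to_crystal(ql, geometry, frame.phi_mid)
        hkl = hkl_from_q(qc, crystal)
        sel = frame.valid_mask
        all_hkl.append(hkl[sel])
        all_val.append(frame.pixels[sel])
    return accumulate_points(np.concatenate(all_hkl), np.concatenate(all_val),
                             grid)


# --------------------------------------------------------------------------
# symmetrization


def symmetrize(dmap: DiffuseMap) -> DiffuseMap:
    """Average intensities over Laue- and Friedel-equivalent voxels.

    Each orbit under {Laue rotations} x {+-1} carries the n_obs-weighted
    mean of its defined members; multiplicity records how many (possibly
    op-duplicated) defined members were averaged into each voxel.
    """
    grid = dmap.grid
    ops = laue_operators(grid.crystal.symmetry_ops)
    idx = grid.index_vectors()
    defined = dmap.defined
    w = np.where(defined, np.maximum(dmap.n_obs, 0), 0.0)
    wi = np.where(defined, w * dmap.intensity, 0.0)
    sum_wi = np.zeros(grid.n_voxels)
    sum_w = np.zeros(grid.n_voxels)
    mult = np.zeros(grid.n_voxels)
    for op in ops:
        mm = idx @ np.asarray(op).T
        inb = grid.in_bounds(mm)
        flat = grid.flat_index(mm[inb])
        sum_wi[inb] += wi[flat]
        sum_w[inb] += w[flat]
        mult[inb] += defined[flat]
    with np.errstate(invalid="ignore", divide="ignore"):
        intensity = np.where(sum_w > 0, sum_wi / np.maximum(sum_w, 1e-300),
                             np.nan)
    n_obs = np.where(sum_w > 0, np.maximum(dmap.n_obs, (sum_w > 0) * 1.0), 0.0)
    return DiffuseMap(grid, intensity, n_obs, mult, dmap.snr.copy())


def symmetry_cc(dmap: DiffuseMap, op_set: str = "both") -> float:
    """Pearson correlation between intensities of symmetry-related voxels.

    ``op_set`` selects the pairing operators: 'friedel' (inversion only),
    'laue' (non-identity rotations) or 'both'.  Each unordered voxel pair
    enters once.  Raises if fewer than 10 defined pairs exist.
    """
    grid = dmap.grid
    rots = [np.asarray(r) for r in grid.crystal.symmetry_ops]
    eye = np.eye(3, dtype=int)
    if op_set == "friedel":
        ops = [-eye]
    elif op_set == "laue":
        ops = [r for r in rots if not np.array_equal(r, eye)]
    elif op_set == "both":
        ops = [r for r in laue_operators(rots) if not np.array_equal(r, eye)]
    else:
        raise ValueError("op_set must be 'friedel', 'laue' or 'both'")
    idx = grid.index_vectors()
    defined = dmap.defined
    pair_list = []
    for op in ops:
        mm = idx @ np.asarray(op).T
        inb = grid.in_bounds(mm)
        src = np.flatnonzero(inb)
        dst = grid.flat_index(mm[inb])
        ok = defined[src] & defined[dst] & (src != dst)
        a, b = src[ok], dst[ok]
        lo, hi = np.minimum(a, b), np.maximum(a, b)
        pair_list.append(np.column_stack([lo, hi]))
    if not pair_list:
        raise ValueError("no pairing operators for this symmetry")
    pairs = np.unique(np.vstack(pair_list), axis=0)
    if len(pairs) < 10:
        raise ValueError(f"only {len(pairs)} defined symmetry pairs; need >= 10")
    x = dmap.intensity[pairs[:, 0]]
    y = dmap.intensity[pairs[:, 1]]
    return float(np.corrcoef(x, y)[0, 1])


# --------------------------------------------------------------------------
# radial average and offset


def radial_shell_table(q_norms: np.ndarray, values: np.ndarray,
                       n_shells: int = 100) -> tuple[np.ndarray, np.ndarray]:
    """Shell centers and mean values over equal-width |q| shells."""
    lo, hi = float(q_norms.min()), float(q_norms.max())
    edges = np.linspace(lo, hi, n_shells + 1)
    idx = np.clip(np.digitize(q_norms, edges) - 1, 0, n_shells - 1)
    counts = np.bincount(idx, minlength=n_shells)
    sums = np.bincount(idx, weights=values, minlength=n_shells)
    centers = 0.5 * (edges[:-1] + edges[1:])
    good = counts > 0
    return centers[good], sums[good] / counts[good]


def subtract_radial_average(dmap: DiffuseMap, n_shells: int = 100) -> DiffuseMap:
    """Subtract the interpolated radial (shell-mean) intensity profile.

    After the linear-interpolation pass the small residual per-shell means
    (interpolation vs. bin-mean mismatch) are removed as well, so the
    output's shell means vanish to round-off.
    """
    out = dmap.copy()
    d = dmap.defined
    qn = dmap.grid.q_norms()
    centers, means = radial_shell_table(qn[d], dmap.intensity[d], n_shells)
    resid = dmap.intensity - np.interp(qn, centers, means)
    lo, hi = float(qn[d].min()), float(qn[d].max())
    edges = np.linspace(lo, hi, n_shells + 1)
    idx = np.clip(np.digitize(qn, edges) - 1, 0, n_shells - 1)
    r = np.where(d, resid, 0.0)
    counts = np.bincount(idx[d], minlength=n_shells)
    sums = np.bincount(idx[d], weights=r[d], minlength=n_shells)
    shell_mean = np.where(counts > 0, sums / np.maximum(counts, 1), 0.0)
    out.intensity = np.where(d, resid - shell_mean[idx], np.nan)
    return out


def radial_average_of_array(arr: np.ndarray, grid: MapGrid,
                            n_shells: int = 100) -> np.ndarray:
    """Anisotropic part of a dense model map (radial shell mean removed)."""
    flat = np.asarray(arr, dtype=float).ravel()
    qn = grid.q_norms()
    centers, means = radial_shell_table(qn, flat, n_shells)
    return (flat - np.interp(qn, centers, means)).reshape(np.shape(arr))


def positivity_offset(dmap: DiffuseMap) -> DiffuseMap:
    """Shift intensities so the minimum defined voxel is strictly positive."""
    out = dmap.copy()
    d = dmap.defined
    vals = dmap.intensity[d]
    if vals.size == 0:
        return out
    eps = 1e-6 * (vals.max() - vals.min() if vals.max() > vals.min() else
                  max(abs(vals.max()), 1.0))
    out.intensity = np.where(d, dmap.intensity - vals.min() + eps, np.nan)
    return out
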