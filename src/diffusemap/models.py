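"""Analytic diffuse-scattering predictions under five crystal-disorder models.

All predictions are evaluated on a :class:`~diffusemap.mapping.MapGrid` and
returned as dense 3D arrays.  The asymmetric-unit-confined models share the
symmetrized molecular transform -- the squared molecular transform summed
incoherently over the crystallographic orientations -- as their basis; the
extended liquid-like motions variant uses the crystal transform instead,
which is nonzero only at integral Miller indices.

Intensity Debye-Waller convention: exp(-sigma^2 |q|^2) with B = 8 pi^2
sigma^2 (per-axis sigma).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy.signal import fftconvolve
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import pdist, squareform

from . import symmetry
from .formfactors import form_factor
from .geometry import CrystalFrame, real_space_matrix
from .mapping import MapGrid

EIGHT_PI_SQ = 8.0 * np.pi**2


# --------------------------------------------------------------------------
# atomic models


@dataclass
class AtomicModel:
    """Atoms of one asymmetric unit in a unit cell with symmetry operators."""

    elements: list[str]
    xyz: np.ndarray                 # (n, 3) Cartesian Angstrom
    occupancy: np.ndarray = None
    b_iso: np.ndarray = None
    cell: tuple = (1.0, 1.0, 1.0, 90.0, 90.0, 90.0)
    spacegroup: str = "P1"

    def __post_init__(self):
        self.xyz = np.atleast_2d(np.asarray(self.xyz, dtype=float))
        n = len(self.xyz)
        if self.occupancy is None:
            self.occupancy = np.ones(n)
        if self.b_iso is None:
            self.b_iso = np.zeros(n)
        self.occupancy = np.asarray(self.occupancy, dtype=float)
        self.b_iso = np.asarray(self.b_iso, dtype=float)
        if not (len(self.elements) == n == len(self.occupancy) == len(self.b_iso)):
            raise ValueError("inconsistent atom array lengths")
        if np.any((self.occupancy < 0) | (self.occupancy > 1)):
            raise ValueError("occupancies must lie in [0, 1]")
        if np.any(self.b_iso < 0):
            raise ValueError("B factors must be non-negative")
        if not np.all(np.isfinite(self.xyz)):
            raise ValueError("coordinates must be finite")

    @property
    def n_atoms(self) -> int:
        return len(self.xyz)

    @property
    def centroid(self) -> np.ndarray:
        return self.xyz.mean(axis=0)

    @property
    def real_ops(self):
        return symmetry.real_space_ops(self.spacegroup)

    @property
    def recip_rotations(self):
        return symmetry.reciprocal_rotations(self.spacegroup)

    def crystal_frame(self) -> CrystalFrame:
        return CrystalFrame(self.cell, spacegroup_label=self.spacegroup)

    def expand_to_unit_cell(self) -> "AtomicModel":
        """All symmetry copies of the asymmetric unit, as a P1 model."""
        m_real = real_space_matrix(self.cell)
        frac = self.xyz @ np.linalg.inv(m_real).T
        coords = []
        for rot, trans in self.real_ops:
            coords.append((frac @ rot.T + trans) @ m_real.T)
        ncop = len(coords)
        return AtomicModel(list(self.elements) * ncop, np.vstack(coords),
                           np.tile(self.occupancy, ncop),
                           np.tile(self.b_iso, ncop), self.cell, "P1")

    def with_xyz(self, xyz: np.ndarray) -> "AtomicModel":
        return replace(self, xyz=np.asarray(xyz, dtype=float))


def form_factor_matrix(model: AtomicModel, q_norm: np.ndarray,
                       apply_b: bool = False) -> np.ndarray:
    """Occupancy-weighted form factors, shape (n_q, n_atoms)."""
    q_norm = np.asarray(q_norm, dtype=float)
    cols = []
    for i, el in enumerate(model.elements):
        f = form_factor(el, q_norm) * model.occupancy[i]
        if apply_b:
            f = f * np.exp(-model.b_iso[i] * (q_norm / (4 * np.pi)) ** 2)
        cols.append(f)
    return np.stack(cols, axis=-1)


# --------------------------------------------------------------------------
# molecular and crystal transforms


def molecular_transform(model: AtomicModel, q: np.ndarray,
                        apply_b: bool = False) -> np.ndarray:
    """Complex F(q) = sum_i occ_i f_i(|q|) exp(i q . r_i), shape (n_q,).

    No B-factor damping by default: the disorder models own the blurring.
    """
    q = np.asarray(q, dtype=float).reshape(-1, 3)
    famp = form_factor_matrix(model, np.linalg.norm(q, axis=1), apply_b=apply_b)
    phase = q @ model.xyz.T
    return (famp * np.exp(1j * phase)).sum(axis=1)


def _op_q_sets(model: AtomicModel, grid: MapGrid):
    hkl = grid.hkl()
    a_mat = grid.A
    for rot in model.recip_rotations:
        yield (hkl @ np.asarray(rot).T) @ a_mat.T


def symmetrized_molecular_transform(model: AtomicModel, grid: MapGrid,
                                    ) -> np.ndarray:
    """Sum of |F|^2 over the crystallographic orientations of the molecule."""
    out = np.zeros(grid.n_voxels)
    for q in _op_q_sets(model, grid):
        out += np.abs(molecular_transform(model, q)) ** 2
    return out.reshape(grid.shape)


def crystal_transform(model: AtomicModel, grid: MapGrid,
                      apply_b: bool = False) -> np.ndarray:
    """Unit-cell |F|^2 concentrated at the integral-Miller nodes of the grid."""
    cellmod = model.expand_to_unit_cell()
    mask = grid.miller_node_mask()
    q = grid.q_vectors()[mask]
    out = np.zeros(grid.n_voxels)
    out[mask] = np.abs(molecular_transform(cellmod, q, apply_b=apply_b)) ** 2
    return out.reshape(grid.shape)


# --------------------------------------------------------------------------
# rigid-body models


def predict_rigid_translations(model: AtomicModel, grid: MapGrid,
                               sigma: float) -> np.ndarray:
    """Diffuse intensity of isotropic rigid-body translational disorder.

    I_D(q) = T_sym(q) * [1 - exp(-sigma^2 |q|^2)].
    """
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    t_sym = symmetrized_molecular_transform(model, grid)
    q2 = (grid.q_norms() ** 2).reshape(grid.shape)
    return t_sym * (1.0 - np.exp(-sigma**2 * q2))


def _random_rotations(sigma_rot_deg: float, n: int, rng) -> np.ndarray:
    """Rotation matrices about isotropic axes with Normal(0, sigma) angles."""
    axes = rng.standard_normal((n, 3))
    axes /= np.linalg.norm(axes, axis=1, keepdims=True)
    angles = rng.normal(0.0, np.radians(sigma_rot_deg), n)
    rotvec = axes * angles[:, None]
    theta = np.abs(angles)
    # Rodrigues, vectorized
    k = np.where(theta[:, None] > 1e-12, rotvec / np.maximum(theta[:, None], 1e-12),
                 np.array([1.0, 0.0, 0.0]))
    kx = np.zeros((n, 3, 3))
    kx[:, 0, 1], kx[:, 0, 2] = -k[:, 2], k[:, 1]
    kx[:, 1, 0], kx[:, 1, 2] = k[:, 2], -k[:, 0]
    kx[:, 2, 0], kx[:, 2, 1] = -k[:, 1], k[:, 0]
    st = np.sin(theta)[:, None, None]
    ct = (1 - np.cos(theta))[:, None, None]
    return np.eye(3) + st * kx + ct * (kx @ kx)


def predict_rigid_rotations(model: AtomicModel, grid: MapGrid,
                            sigma_rot: float, n_samples: int = 2000,
                            seed: int = 0, chunk: int = 256) -> np.ndarray:
    """Monte-Carlo diffuse intensity of isotropic rigid-body rotations.

    The molecule rotates as a unit about its centroid around random,
    isotropically oriented axes with normally distributed angles (degrees);
    the intensity is the variance of the rotated structure factors,
    orientation-symmetrized.
    """
    if sigma_rot < 0:
        raise ValueError("sigma_rot must be non-negative")
    if sigma_rot == 0:
        return np.zeros(grid.shape)
    if n_samples < 100:
        raise ValueError("n_samples must be >= 100")
    rng = np.random.default_rng(seed)
    rots = _random_rotations(sigma_rot, n_samples, rng)
    center = model.centroid
    centered = model.xyz - center
    out = np.zeros(grid.n_voxels)
    for q in _op_q_sets(model, grid):
        famp = form_factor_matrix(model, np.linalg.norm(q, axis=1))
        sum_f = np.zeros(len(q), dtype=complex)
        sum_i = np.zeros(len(q))
        for k0 in range(0, n_samples, chunk):
            batch = rots[k0:k0 + chunk]
            for rot in batch:
                coords = centered @ rot.T + center
                fk = (famp * np.exp(1j * (q @ coords.T))).sum(axis=1)
                sum_f += fk
                sum_i += np.abs(fk) ** 2
        out += sum_i / n_samples - np.abs(sum_f / n_samples) ** 2
    return out.reshape(grid.shape)


# --------------------------------------------------------------------------
# liquid-like motions


def llm_kernel(dq, gamma: float):
    """3D Fourier transform of exp(-r / gamma): 8 pi gamma^3 / (1 + gamma^2 dq^2)^2."""
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    dq = np.asarray(dq, dtype=float)
    return 8.0 * np.pi * gamma**3 / (1.0 + gamma**2 * dq**2) ** 2


def _kernel_array(grid: MapGrid, gamma: float, rel_cutoff: float = 1e-4,
                  ) -> np.ndarray:
    """Discrete LLM kernel on the grid's offset lattice, unit discrete mass.

    Truncated where the kernel falls below ``rel_cutoff`` of its peak; if
    that support exceeds the grid it is capped (with a warning) and the
    discrete normalization keeps the convolution's DC gain exactly one.
    """
    step = grid.A / grid.oversampling          # columns: node steps in q
    step_norms = np.linalg.norm(step, axis=0)
    dq_cut = np.sqrt(1.0 / np.sqrt(rel_cutoff) - 1.0) / gamma
    half = np.ceil(dq_cut / step_norms).astype(int)
    cap = grid.size // 2
    if np.any(half > cap):
        warnings.warn("LLM kernel support exceeds the map grid; truncating "
                      "(consider a larger grid extent)", stacklevel=2)
        half = np.minimum(half, cap)
    axes = [np.arange(-h, h + 1) for h in half]
    dm = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
    dq = np.linalg.norm(dm @ step.T, axis=1)
    ker = llm_kernel(dq, gamma).reshape([2 * h + 1 for h in half])
    return ker / ker.sum()


def _blurred_molecular_basis(model: AtomicModel, grid: MapGrid,
                             gamma: float) -> np.ndarray:
    """[T_sym (*) Gamma_gamma](q) evaluated exactly in real space.

    The continuous convolution of |F|^2 with the normalized kernel equals
    the interatomic cosine sum with each pair damped by exp(-r_ij/gamma)
    (the kernel is the Fourier transform of that decay), which avoids the
    edge bias a discrete convolution suffers on a finite grid.
    """
    from scipy.spatial.distance import pdist, squareform

    decay = np.exp(-squareform(pdist(model.xyz)) / gamma)
    out = np.zeros(grid.n_voxels)
    for q in _op_q_sets(model, grid):
        famp = form_factor_matrix(model, np.linalg.norm(q, axis=1))
        e = famp * np.exp(1j * (q @ model.xyz.T))
        out += np.real(((e @ decay) * e.conj()).sum(axis=1))
    return np.maximum(out, 0.0).reshape(grid.shape)


def predict_llm(model: AtomicModel, grid: MapGrid, sigma: float, gamma: float,
                extended: bool = False) -> np.ndarray:
    """Liquid-like motions diffuse intensity.

    I_D(q) = sigma^2 |q|^2 exp(-sigma^2 |q|^2) * [I_basis (*) Gamma_gamma](q),
    where the basis is the symmetrized molecular transform (correlations
    confined to the asymmetric unit) or the crystal transform (the
    conventional model with correlations across neighboring molecules).
    The confined convolution is evaluated through its exact real-space
    pair-sum form; the extended one spreads the integral-node crystal
    transform with the discrete kernel.
    """
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    blurred = llm_blurred_basis(model, grid, gamma, extended)
    q2 = (grid.q_norms() ** 2).reshape(grid.shape)
    return sigma**2 * q2 * np.exp(-sigma**2 * q2) * blurred


def llm_blurred_basis(model: AtomicModel, grid: MapGrid, gamma: float,
                      extended: bool = False) -> np.ndarray:
    """The gamma-dependent, sigma-independent factor of the LLM prediction."""
    if extended:
        basis = crystal_transform(model, grid)
        ker = _kernel_array(grid, gamma)
        return np.maximum(fftconvolve(basis, ker, mode="same"), 0.0)
    return _blurred_molecular_basis(model, grid, gamma)


def make_llm_predictor(model: AtomicModel, grid: MapGrid,
                       extended: bool = False):
    """Parameter-scan-friendly LLM predictor caching the basis per gamma."""
    cache: dict[float, np.ndarray] = {}
    q2 = (grid.q_norms() ** 2).reshape(grid.shape)

    def predictor(sigma: float, gamma: float) -> np.ndarray:
        key = float(gamma)
        if key not in cache:
            cache[key] = llm_blurred_basis(model, grid, gamma, extended)
        return sigma**2 * q2 * np.exp(-sigma**2 * q2) * cache[key]

    return predictor


def make_rbt_predictor(model: AtomicModel, grid: MapGrid):
    """Rigid-body-translation predictor with the basis transform cached."""
    t_sym = symmetrized_molecular_transform(model, grid)
    q2 = (grid.q_norms() ** 2).reshape(grid.shape)

    def predictor(sigma: float) -> np.ndarray:
        return t_sym * (1.0 - np.exp(-sigma**2 * q2))

    return predictor


# --------------------------------------------------------------------------
# ensembles (Guinier)


def predict_ensemble(states: list[AtomicModel], weights, grid: MapGrid,
                     ) -> np.ndarray:
    """Guinier diffuse intensity of probability-weighted discrete states.

    I_D(q) = sum_s w_s |F_s|^2 - |sum_s w_s F_s|^2, orientation-symmetrized.
    """
    weights = np.asarray(weights, dtype=float)
    if len(states) != len(weights):
        raise ValueError("states and weights must have equal length")
    if np.any(weights < 0) or abs(weights.sum() - 1.0) > 1e-8:
        raise ValueError("weights must be non-negative and sum to 1")
    ref = states[0]
    out = np.zeros(grid.n_voxels)
    for q in _op_q_sets(ref, grid):
        mean_f = np.zeros(len(q), dtype=complex)
        mean_i = np.zeros(len(q))
        for w, state in zip(weights, states):
            f = molecular_transform(state, q)
            mean_f += w * f
            mean_i += w * np.abs(f) ** 2
        out += mean_i - np.abs(mean_f) ** 2
    return np.maximum(out, 0.0).reshape(grid.shape)


# --------------------------------------------------------------------------
# elastic network / general Gaussian covariance


@dataclass
class CovarianceModel:
    """Per-atom-pair 3x3 displacement covariance blocks (A^2)."""

    blocks: np.ndarray      # (n, n, 3, 3)

    def __post_init__(self):
        self.blocks = np.asarray(self.blocks, dtype=float)
        n = self.blocks.shape[0]
        if self.blocks.shape != (n, n, 3, 3):
            raise ValueError("blocks must have shape (n, n, 3, 3)")

    @property
    def n_atoms(self) -> int:
        return self.blocks.shape[0]

    def full_matrix(self) -> np.ndarray:
        n = self.n_atoms
        return self.blocks.transpose(0, 2, 1, 3).reshape(3 * n, 3 * n)

    def implied_b(self) -> np.ndarray:
        """Per-atom isotropic B implied by the diagonal blocks."""
        per_axis = np.trace(self.blocks[np.arange(self.n_atoms),
                                        np.arange(self.n_atoms)],
                            axis1=-2, axis2=-1) / 3.0
        return EIGHT_PI_SQ * per_axis


def build_enm_covariance(model: AtomicModel, cutoff: float = 10.5,
                         b_targets: np.ndarray | None = None) -> CovarianceModel:
    """Isotropic elastic-network covariance renormalized to target B factors.

    A uniform-spring Gaussian network over all atom pairs within ``cutoff``
    gives pairwise covariances from the pseudo-inverse of the network
    Laplacian; atom scalings s_i = sqrt(B_i / (8 pi^2 G_ii)) then make the
    per-atom variances reproduce ``b_targets`` exactly.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    n = model.n_atoms
    if n < 2:
        raise ValueError("need at least two atoms for a network")
    b = model.b_iso if b_targets is None else np.asarray(b_targets, dtype=float)
    d = squareform(pdist(model.xyz))
    adj = (d < cutoff) & ~np.eye(n, dtype=bool)
    ncomp, labels = connected_components(adj, directed=False)
    if ncomp > 1:
        sizes = np.bincount(labels)
        raise ValueError(f"elastic network is disconnected at cutoff {cutoff} A: "
                         f"{ncomp} components of sizes {sizes.tolist()}")
    lap = np.diag(adj.sum(axis=1)) - adj.astype(float)
    # pseudo-inverse via eigendecomposition, dropping the null mode
    evals, evecs = np.linalg.eigh(lap)
    inv = np.where(evals > 1e-10 * evals.max(), 1.0 / np.where(evals > 0, evals, 1),
                   0.0)
    g = (evecs * inv) @ evecs.T
    diag = np.diag(g).copy()
    if np.any(diag <= 0):
        raise ValueError("degenerate network variances")
    s = np.sqrt(b / (EIGHT_PI_SQ * diag))
    c = np.outer(s, s) * g
    blocks = c[:, :, None, None] * np.eye(3)
    return CovarianceModel(blocks)


def predict_gaussian_disorder(model: AtomicModel, grid: MapGrid,
                              covariance: CovarianceModel,
                              linearized: bool = False) -> np.ndarray:
    """Diffuse intensity of general small Gaussian correlated displacements.

    I_D(q) = sum_ij f_i f_j exp(-q.V_ii.q / 2) exp(-q.V_jj.q / 2)
             [exp(q.V_ij.q) - 1] cos(q . (r_i - r_j)),
    orientation-symmetrized.  ``linearized`` replaces exp(x) - 1 by x.
    """
    v = covariance.blocks
    n = model.n_atoms
    if covariance.n_atoms != n:
        raise ValueError("covariance does not match model")
    out = np.zeros(grid.n_voxels)
    for q in _op_q_sets(model, grid):
        famp = form_factor_matrix(model, np.linalg.norm(q, axis=1))
        phase = q @ model.xyz.T                            # (N, n)
        qvq_diag = np.einsum("nd,ide,ne->ni", q, v[np.arange(n), np.arange(n)], q)
        pref = famp * np.exp(-0.5 * qvq_diag)
        acc = np.zeros(len(q))
        for i in range(n):
            qvq = np.einsum("nd,jde,ne->nj", q, v[i], q)
            gfun = qvq if linearized else np.expm1(qvq)
            cosm = np.cos(phase[:, [i]] - phase)
            acc += pref[:, i] * (pref * gfun * cosm).sum(axis=1)
        out += acc
    return out.reshape(grid.shape)


# --------------------------------------------------------------------------
# Wilson B


def wilson_b_to_sigma(b: float) -> float:
    """Per-axis RMS displacement implied by an isotropic B: sigma = sqrt(B / 8 pi^2)."""
    if b < 0:
        raise ValueError("B must be non-negative")
    return float(np.sqrt(b / EIGHT_PI_SQ))
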