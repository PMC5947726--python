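"""Synthetic inputs for the whole pipeline: toy crystals, brute-force
disorder-ensemble oracles, and rendered rotation-series diffraction images
with known ground truth.

Everything here is bit-reproducible given (spec, seed).  The ensemble
oracles realize each disorder model by explicit sampling of perturbed
structures -- the variance of the sampled structure factors is the model's
diffuse intensity -- and serve as the independent cross-check for the
analytic predictions in :mod:`diffusemap.models`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import (CrystalFrame, DetectorGeometry, DiffractionFrame,
                       frame_correction_factors, frame_q_lab, hkl_from_q,
                       real_space_matrix, rotate_q_to_crystal)
from .mapping import DiffuseMap, MapGrid
from .models import (AtomicModel, CovarianceModel, form_factor_matrix,
                     molecular_transform)

# --------------------------------------------------------------------------
# toy crystals


@dataclass
class ToyCrystalSpec:
    n_atoms: int
    cell: tuple = (25.0, 25.0, 25.0, 90.0, 90.0, 90.0)
    spacegroup: str = "P1"
    elements: tuple = ("C", "N", "O")
    b_range: tuple = (10.0, 20.0)
    min_distance: float = 1.5
    frac_box: tuple = ((0.05, 0.40), (0.05, 0.40), (0.05, 0.40))
    seed: int = 0


def make_toy_crystal(spec: ToyCrystalSpec) -> AtomicModel:
    """Random atoms inside one asymmetric-unit box, min 1.5 A apart.

    Deterministic given the seed; raises if the distance constraint cannot
    be satisfied in 1000 attempts per atom.
    """
    rng = np.random.default_rng(spec.seed)
    m_real = real_space_matrix(spec.cell)
    lo = np.array([b[0] for b in spec.frac_box])
    hi = np.array([b[1] for b in spec.frac_box])
    placed: list[np.ndarray] = []
    for _ in range(spec.n_atoms):
        for attempt in range(1000):
            frac = lo + (hi - lo) * rng.random(3)
            cart = m_real @ frac
            if all(np.linalg.norm(cart - p) >= spec.min_distance for p in placed):
                placed.append(cart)
                break
        else:
            raise RuntimeError("could not satisfy the minimum-distance "
                               "constraint in 1000 tries")
    elements = [spec.elements[i % len(spec.elements)]
                for i in range(spec.n_atoms)]
    b_iso = rng.uniform(*spec.b_range, size=spec.n_atoms)
    return AtomicModel(elements, np.array(placed), np.ones(spec.n_atoms),
                       b_iso, spec.cell, spec.spacegroup)


# --------------------------------------------------------------------------
# ensemble oracles


@dataclass
class OracleConfig:
    disorder: dict                  # {"kind": ..., model parameters ...}
    n_samples: int = 20000
    seed: int = 0
    supercell: tuple = (1, 1, 1)
    chunk: int = 512

    def __post_init__(self):
        if self.n_samples < 100:
            raise ValueError("n_samples must be >= 100")
        if any(s < 1 for s in self.supercell):
            raise ValueError("supercell factors must be >= 1")


def _variance_over_samples(q: np.ndarray, famp: np.ndarray,
                           coords_iter, n_samples: int) -> np.ndarray:
    """mean |F_k|^2 - |mean F_k|^2 over sampled coordinate sets."""
    sum_f = np.zeros(len(q), dtype=complex)
    sum_i = np.zeros(len(q))
    for coords in coords_iter:
        fk = (famp * np.exp(1j * (q @ coords.T))).sum(axis=1)
        sum_f += fk
        sum_i += np.abs(fk) ** 2
    return sum_i / n_samples - np.abs(sum_f / n_samples) ** 2


def _exponential_covariance_sampler(xyz: np.ndarray, sigma: float, gamma: float,
                                    rng, jitter: float = 1e-10):
    """Draw per-atom displacements with Cov(u_i, u_j) = sigma^2 exp(-r_ij/gamma) I3."""
    from scipy.spatial.distance import pdist, squareform
    n = len(xyz)
    cov = sigma**2 * np.exp(-squareform(pdist(xyz)) / gamma)
    chol = np.linalg.cholesky(cov + jitter * np.eye(n))

    def draw(count: int) -> np.ndarray:
        z = rng.standard_normal((count, n, 3))
        return np.einsum("ij,cjd->cid", chol, z)
    return draw


def _supercell_model(model: AtomicModel, supercell: tuple) -> AtomicModel:
    """Tile the expanded unit cell into an n_a x n_b x n_c block (P1)."""
    cellmod = model.expand_to_unit_cell()
    m_real = real_space_matrix(model.cell)
    shifts = [m_real @ np.array([i, j, k], dtype=float)
              for i in range(supercell[0])
              for j in range(supercell[1])
              for k in range(supercell[2])]
    coords = np.vstack([cellmod.xyz + s for s in shifts])
    reps = len(shifts)
    return AtomicModel(list(cellmod.elements) * reps, coords,
                       np.tile(cellmod.occupancy, reps),
                       np.tile(cellmod.b_iso, reps), model.cell, "P1")


def oracle_diffuse_map(model: AtomicModel, config: OracleConfig,
                       grid: MapGrid) -> np.ndarray:
    """Brute-force diffuse map from an explicit sampled disorder ensemble.

    Supported kinds: ``rbt`` (sigma), ``rbr`` (sigma_rot), ``llm`` (sigma,
    gamma; add ``extended=True`` for supercell-wide correlated draws),
    ``ensemble`` (states, weights; exhaustively weighted, no sampling) and
    ``gaussian`` (covariance: CovarianceModel).  Confined models are
    orientation-symmetrized over the crystal's point group.
    """
    kind = config.disorder.get("kind")
    rng = np.random.default_rng(config.seed)
    par = config.disorder
    n_s = config.n_samples

    if kind == "ensemble":
        from .models import predict_ensemble
        return predict_ensemble(par["states"], par["weights"], grid)

    if kind is None or kind not in {"rbt", "rbr", "llm", "gaussian"}:
        raise ValueError(f"unsupported disorder kind: {kind!r}")

    extended = kind == "llm" and par.get("extended", False)
    base = _supercell_model(model, config.supercell) if extended else model
    hkl = grid.hkl()
    rotations = [np.eye(3, dtype=int)] if extended else model.recip_rotations
    out = np.zeros(grid.n_voxels)

    for rot in rotations:
        q = (hkl @ np.asarray(rot).T) @ grid.A.T
        famp = form_factor_matrix(base, np.linalg.norm(q, axis=1))

        if kind == "rbt":
            sigma = par["sigma"]
            if sigma == 0:
                continue
            # rigid shifts factor out of the structure factor
            f0 = (famp * np.exp(1j * (q @ base.xyz.T))).sum(axis=1)
            shifts = rng.normal(0.0, sigma, size=(n_s, 3))
            carrier = np.exp(1j * (q @ shifts.T)).mean(axis=1)
            out += np.abs(f0) ** 2 * (1.0 - np.abs(carrier) ** 2)
            continue

        if kind == "rbr":
            from .models import _random_rotations
            sigma_rot = par["sigma_rot"]
            if sigma_rot == 0:
                continue
            rots = _random_rotations(sigma_rot, n_s, rng)
            center = base.centroid
            centered = base.xyz - center

            def coords_iter():
                for mat in rots:
                    yield centered @ mat.T + center
            out += _variance_over_samples(q, famp, coords_iter(), n_s)
            continue

        sigma = par.get("sigma", 0.0)
        if kind == "llm":
            if sigma == 0:
                continue
            draw = _exponential_covariance_sampler(base.xyz, sigma,
                                                   par["gamma"], rng)

            def coords_iter():
                done = 0
                while done < n_s:
                    count = min(config.chunk, n_s - done)
                    for u in draw(count):
                        yield base.xyz + u
                    done += count
            out += _variance_over_samples(q, famp, coords_iter(), n_s)
            continue

        if kind == "gaussian":
            cov: CovarianceModel = par["covariance"]
            full = cov.full_matrix()
            if np.allclose(full, 0.0):
                continue
            chol = np.linalg.cholesky(full + 1e-10 * np.eye(len(full)))

            def coords_iter():
                done = 0
                n_at = base.n_atoms
                while done < n_s:
                    count = min(config.chunk, n_s - done)
                    z = rng.standard_normal((count, 3 * n_at))
                    disp = (z @ chol.T).reshape(count, n_at, 3)
                    for u in disp:
                        yield base.xyz + u
                    done += count
            out += _variance_over_samples(q, famp, coords_iter(), n_s)
    return out.reshape(grid.shape)


# --------------------------------------------------------------------------
# image rendering


@dataclass
class ImageSimConfig:
    geometry: DetectorGeometry
    n_frames: int = 36
    phi_width: float = 10.0
    diffuse_scale: float = 1.0
    bragg_scale: float = 0.0
    bragg_width: float = 0.06        # Gaussian footprint, fractional hkl
    bragg_partiality_jitter: float = 0.0   # lognormal sd per (frame, reflection)
    background: object = None        # callable |q| -> intensity, or None
    contaminant: object = None       # callable |q| -> intensity, or None
    contaminant_scales: np.ndarray | None = None   # per-frame m
    contaminant_shifts: np.ndarray | None = None   # per-frame q0
    scale_jitter: float = 0.0        # lognormal sd of per-frame scales
    poisson: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.diffuse_scale < 0 or self.bragg_scale < 0:
            raise ValueError("scales must be non-negative")


@dataclass
class FrameStack:
    frames: list[DiffractionFrame]
    geometry: DetectorGeometry
    crystal: CrystalFrame
    truth: dict = field(default_factory=dict)


def render_images(map_diffuse: DiffuseMap, model: AtomicModel,
                  config: ImageSimConfig) -> FrameStack:
    """Render a rotation series from a diffuse map plus optional Bragg spots,
    radial backgrounds, a shifted contaminant profile, per-frame scale
    jitter and Poisson noise.

    Diffuse intensities are sampled at the nearest map node of each pixel's
    mid-oscillation q, and the polarization/solid-angle factors are applied
    forward, so that the noiseless pipeline round-trip is exact.  Ground
    truth (input map, per-frame Bragg spot cores, per-frame scales) is
    returned in ``truth``.
    """
    grid = map_diffuse.grid
    geometry = config.geometry
    crystal = grid.crystal
    rng = np.random.default_rng(config.seed)
    ql = frame_q_lab(geometry)
    qn_lab = np.linalg.norm(ql, axis=-1)
    corr = frame_correction_factors(geometry)
    map_vals = map_diffuse.intensity
    map_def = map_diffuse.defined

    if config.scale_jitter > 0:
        scales = np.exp(rng.normal(0.0, config.scale_jitter, config.n_frames))
    else:
        scales = np.ones(config.n_frames)

    cellmod = model.expand_to_unit_cell() if config.bragg_scale > 0 else None
    fcell_cache: dict[bytes, float] = {}

    def bragg_intensity(h0: np.ndarray) -> np.ndarray:
        flatkeys = np.ascontiguousarray(h0.astype(np.int32))
        uniq, inverse = np.unique(flatkeys.reshape(-1, 3), axis=0,
                                  return_inverse=True)
        vals = np.empty(len(uniq))
        for i, h in enumerate(uniq):
            key = h.tobytes()
            if key not in fcell_cache:
                q = grid.A @ h.astype(float)
                f = molecular_transform(cellmod, q[None, :], apply_b=True)[0]
                fcell_cache[key] = float(np.abs(f) ** 2)
            vals[i] = fcell_cache[key]
        if config.bragg_partiality_jitter > 0:
            # mimics partiality/mosaicity: each reflection's recorded
            # intensity fluctuates independently from frame to frame
            vals = vals * np.exp(rng.normal(0.0, config.bragg_partiality_jitter,
                                            len(vals)))
        return vals[inverse]

    frames = []
    spot_cores = []
    dropped = 0
    for idx in range(config.n_frames):
        phi_start = idx * config.phi_width
        phi_mid = phi_start + 0.5 * config.phi_width
        qc = rotate_q_to_crystal(ql, geometry, phi_mid)
        hkl = hkl_from_q(qc, crystal)
        nodes = grid.nodes_from_hkl(hkl)
        inb = grid.in_bounds(nodes)
        flat = grid.flat_index(np.where(inb[..., None], nodes, 0))
        covered = inb & map_def[flat]
        dropped += int((~inb).sum())
        total = np.where(covered, config.diffuse_scale * map_vals[flat], 0.0)

        core_mask = np.zeros(total.shape, dtype=bool)
        if config.bragg_scale > 0:
            h0 = np.round(hkl).astype(int)
            resid = hkl - h0
            near = np.max(np.abs(resid), axis=-1) < 3 * config.bragg_width
            if near.any():
                icell = np.zeros(total.shape)
                icell[near] = bragg_intensity(h0[near])
                foot = np.zeros(total.shape)
                foot[near] = np.exp(-0.5 * (resid[near] ** 2).sum(-1)
                                    / config.bragg_width**2)
                ibragg = config.bragg_scale * icell * foot
                total = total + ibragg
                core_mask = (np.max(np.abs(resid), axis=-1) < config.bragg_width) \
                    & (ibragg > 10.0 * (np.abs(total - ibragg) + 1.0))
        if config.background is not None:
            total = total + config.background(qn_lab)
        if config.contaminant is not None:
            m = (config.contaminant_scales[idx]
                 if config.contaminant_scales is not None else 1.0)
            q0 = (config.contaminant_shifts[idx]
                  if config.contaminant_shifts is not None else 0.0)
            total = total + m * config.contaminant(qn_lab - q0)

        total = total * corr * scales[idx]
        if config.poisson:
            total = rng.poisson(np.maximum(total, 0.0)).astype(float)
        frames.append(DiffractionFrame(total, np.ones_like(total, dtype=bool),
                                       phi_start, config.phi_width,
                                       float(scales[idx])))
        spot_cores.append(np.argwhere(core_mask))

    truth = {
        "map": map_diffuse,
        "diffuse_scale": config.diffuse_scale,
        "scales": scales,
        "spot_cores": spot_cores,
        "dropped_pixels": dropped,
    }
    return FrameStack(frames, geometry, crystal, truth)
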