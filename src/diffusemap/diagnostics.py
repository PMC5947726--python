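"""Speckle and correlation-length diagnostics for diffuse maps.

Two complementary probes of disorder extending past one unit cell:

* the intensity fall-off as a function of the distance dq to the nearest
  reciprocal-lattice node, fitted by the single-phonon 1/dq^2 form and the
  liquid-like motions kernel 8 pi gamma^3 / (1 + gamma^2 dq^2)^2; and
* the map autocorrelation, whose peaks at unit-cell translation vectors
  flag intermolecular correlations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .mapping import DiffuseMap, MapGrid
from .models import llm_kernel


# --------------------------------------------------------------------------
# delta-q fall-off profiles


@dataclass
class FalloffProfile:
    """Median intensity vs distance to the nearest lattice node, per shell.

    ``values[s, d]`` is the median intensity of shell s in dq bin d,
    normalized so the dq = 0 bin of each shell equals one.
    """

    shell_edges: np.ndarray        # (n_shells + 1,) |q| edges
    dq_centers: np.ndarray         # (n_dq,) nominal bin centers
    values: np.ndarray             # (n_shells, n_dq), NaN where empty
    counts: np.ndarray
    dq_means: np.ndarray = None    # (n_shells, n_dq) mean |dq| of bin members

    def __post_init__(self):
        if self.dq_means is None:
            self.dq_means = np.broadcast_to(self.dq_centers,
                                            self.values.shape).copy()

    @property
    def n_shells(self) -> int:
        return len(self.shell_edges) - 1


def _dq_per_voxel(grid: MapGrid) -> np.ndarray:
    hkl = grid.hkl()
    frac = hkl - np.round(hkl)
    return np.linalg.norm(frac @ grid.A.T, axis=1)


def deltaq_profile(dmap: DiffuseMap, n_shells: int = 20) -> FalloffProfile:
    """Bin voxel intensities by resolution shell and distance to the nearest
    integral-Miller node, normalizing each shell to its dq = 0 bin."""
    grid = dmap.grid
    if grid.oversampling < 5:
        warnings.warn("oversampling below 5 under-resolves the fall-off near "
                      "lattice nodes", stacklevel=2)
    d = dmap.defined
    qn = grid.q_norms()
    dq = _dq_per_voxel(grid)
    width = np.linalg.norm(grid.A, axis=0).min() / 10.0
    # first bin centered on zero so on-node voxels normalize the shell
    n_dq = int(np.ceil((dq[d].max() - 0.5 * width) / width)) + 1
    dq_edges = np.concatenate([[0.0, 0.5 * width],
                               0.5 * width + width * np.arange(1, n_dq)])
    # equal-count shells so every shell holds enough lattice nodes
    shell_edges = np.unique(np.quantile(qn[d], np.linspace(0, 1, n_shells + 1)))
    n_shells = len(shell_edges) - 1
    s_idx = np.clip(np.digitize(qn, shell_edges) - 1, 0, n_shells - 1)
    d_idx = np.clip(np.digitize(dq, dq_edges) - 1, 0, n_dq - 1)
    frame = pd.DataFrame({"shell": s_idx[d], "dq": d_idx[d],
                          "i": dmap.intensity[d], "dqv": dq[d]})
    grouped = frame.groupby(["shell", "dq"])
    med = grouped["i"].median()
    cnt = grouped["i"].size()
    dqm = grouped["dqv"].mean()
    values = np.full((n_shells, n_dq), np.nan)
    counts = np.zeros((n_shells, n_dq), dtype=int)
    dq_means = np.full((n_shells, n_dq), np.nan)
    rows = med.index.get_level_values(0)
    cols = med.index.get_level_values(1)
    values[rows, cols] = med
    counts[rows, cols] = cnt
    dq_means[rows, cols] = dqm
    with np.errstate(invalid="ignore", divide="ignore"):
        norm = values[:, [0]]
        values = np.where(np.abs(norm) > 0, values / norm, np.nan)
    centers = np.concatenate([[0.0], 0.5 * (dq_edges[1:-1] + dq_edges[2:])])
    return FalloffProfile(shell_edges, centers, values, counts, dq_means)


def fit_falloff(profile: FalloffProfile, shell_index: int = 0,
                platform: bool = True) -> dict:
    """Fit the chosen shell's fall-off with the phonon and LLM forms.

    Fits ``a / dq^2 (+ c)`` and ``A * Gamma_gamma(dq)/Gamma_gamma(0) (+ c)``
    to the normalized profile.  The optional constant platform absorbs the
    overlapping-tail floor that neighboring lattice nodes contribute far
    from any node.  Returns ``{"phonon": {"amplitude", "residual"},
    "llm": {"gamma", "amplitude", "residual"}}`` where residuals are sums
    of squares over the dq > 0 bins (the 1/dq^2 form diverges at dq = 0,
    so the on-node bin is excluded from the comparison for both models).
    """
    y_all = profile.values[shell_index]
    # abscissa: actual mean |dq| of each bin's members, not the nominal
    # center (discrete 3D offsets cluster away from bin centers)
    x_all = np.where(np.isfinite(profile.dq_means[shell_index]),
                     profile.dq_means[shell_index], profile.dq_centers)
    ok = np.isfinite(y_all)
    n_par = 3 if platform else 2
    if ok.sum() < max(4, n_par + 1):
        raise ValueError(f"shell {shell_index} has only {int(ok.sum())} defined "
                         "dq bins; too few for the fit")
    x, y = x_all[ok], y_all[ok]
    pos = x > 0
    if pos.sum() < n_par:
        raise ValueError("too few off-node dq bins")
    xp, yp = x[pos], y[pos]

    u = 1.0 / xp**2
    if platform:
        design = np.column_stack([u, np.ones_like(u)])
        coef = np.linalg.lstsq(design, yp, rcond=None)[0]
        amp_phonon = float(coef[0])
        res_phonon = float(np.sum((yp - design @ coef) ** 2))
    else:
        amp_phonon = float((yp @ u) / (u @ u))
        res_phonon = float(np.sum((yp - amp_phonon * u) ** 2))

    def llm_curve(params, dq):
        amp, gamma = params[:2]
        c = params[2] if platform else 0.0
        return amp * llm_kernel(dq, gamma) / llm_kernel(0.0, gamma) + c

    # coarse gamma grid with linear (amplitude, platform), then refinement
    best = None
    for gamma in np.geomspace(0.05 / xp.min(), 50.0 / xp.min(), 40):
        shape = llm_kernel(x, gamma) / llm_kernel(0.0, gamma)
        cols = [shape] + ([np.ones_like(shape)] if platform else [])
        coef = np.linalg.lstsq(np.column_stack(cols), y, rcond=None)[0]
        rss = float(np.sum((y - np.column_stack(cols) @ coef) ** 2))
        if best is None or rss < best[-1]:
            best = (float(coef[0]), gamma,
                    float(coef[1]) if platform else 0.0, rss)
    x0 = list(best[:n_par])
    lb = [0.0, 1e-6] + ([-np.inf] if platform else [])
    ub = [np.inf] * n_par
    sol = least_squares(lambda p: llm_curve(p, x) - y, x0=np.maximum(x0, lb),
                        bounds=(lb, ub))
    res_llm = float(np.sum((llm_curve(sol.x, xp) - yp) ** 2))
    return {
        "phonon": {"amplitude": amp_phonon, "residual": res_phonon},
        "llm": {"gamma": float(sol.x[1]), "amplitude": float(sol.x[0]),
                "residual": res_llm},
    }


# --------------------------------------------------------------------------
# autocorrelation


@dataclass
class AutocorrMap:
    """Real-space autocorrelation of a diffuse map (origin-normalized)."""

    values: np.ndarray             # centered (fftshifted) 3D array
    grid: MapGrid
    fill_fraction: float           # fraction of voxels zero-filled

    @property
    def center(self) -> tuple[int, int, int]:
        return tuple(s // 2 for s in self.values.shape)

    def cell_translation_offset(self) -> float:
        """Index offset (per axis, in voxels) of one unit-cell translation."""
        return self.values.shape[0] / self.grid.oversampling


def autocorrelation(dmap: DiffuseMap) -> AutocorrMap:
    """Inverse Fourier transform of the (offset-removed) intensity map.

    The uniform positivity offset is undone by subtracting the minimum
    defined intensity; undefined voxels are zero-filled (fraction
    reported) and the result is normalized to one at the origin.
    """
    grid = dmap.grid
    d = dmap.defined
    filled = 1.0 - d.mean()
    vals = np.where(d, dmap.intensity, np.nan)
    if d.any():
        vals = vals - np.nanmin(vals)
    arr = np.where(d, vals, 0.0).reshape(grid.shape)
    ac = np.fft.fftshift(np.real(np.fft.ifftn(np.fft.ifftshift(arr))))
    origin = ac[tuple(s // 2 for s in ac.shape)]
    if origin != 0:
        ac = ac / origin
    return AutocorrMap(ac, grid, float(filled))


def lattice_peak_report(acorr: AutocorrMap, mad_cut: float = 3.0,
                        min_height: float = 0.02, core_radius: int = 1,
                        shell_radius: int = 4) -> pd.DataFrame:
    """Autocorrelation values at the six +-primitive cell translations.

    Each row reports the autocorrelation at one cell-translation vector,
    the median and MAD of a surrounding background shell, and whether the
    peak clears background + mad_cut * MAD.  ``min_height`` additionally
    requires the peak to reach that fraction of the origin value, which
    suppresses flags on FFT truncation ringing.  Translations outside the
    grid yield undefined entries.
    """
    vals = acorr.values
    center = np.array(acorr.center)
    offset = acorr.cell_translation_offset()
    rows = []
    labels = [("+a", (1, 0, 0)), ("-a", (-1, 0, 0)), ("+b", (0, 1, 0)),
              ("-b", (0, -1, 0)), ("+c", (0, 0, 1)), ("-c", (0, 0, -1))]
    rng = np.arange(-shell_radius, shell_radius + 1)
    box = np.stack(np.meshgrid(rng, rng, rng, indexing="ij"), axis=-1).reshape(-1, 3)
    radius = np.abs(box).max(axis=1)
    shell_sel = radius > core_radius
    for label, direction in labels:
        pos = center + np.round(np.asarray(direction) * offset).astype(int)
        if np.any(pos - 1 < 0) or np.any(pos + 1 >= np.array(vals.shape)):
            rows.append({"translation": label, "value": np.nan,
                         "background": np.nan, "mad": np.nan, "flagged": False,
                         "in_grid": False})
            continue
        # peak: allow one voxel of slack for the non-integer node position
        core = vals[pos[0] - 1:pos[0] + 2, pos[1] - 1:pos[1] + 2,
                    pos[2] - 1:pos[2] + 2]
        peak = float(core.max())
        pts = pos + box[shell_sel]
        inb = np.all((pts >= 0) & (pts < np.array(vals.shape)), axis=1)
        ring = vals[tuple(pts[inb].T)]
        bg = float(np.median(ring))
        mad = float(np.median(np.abs(ring - bg)))
        rows.append({"translation": label, "value": peak, "background": bg,
                     "mad": mad,
                     "flagged": bool(peak > bg + mad_cut * mad
                                     and peak > min_height),
                     "in_grid": True})
    return pd.DataFrame(rows)
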