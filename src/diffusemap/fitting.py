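"""Comparison of predicted and experimental maps and disorder-parameter scans."""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .mapping import DiffuseMap, radial_average_of_array

log = logging.getLogger(__name__)


def weighted_cc(map_a, map_b, weights=None) -> float:
    """Weighted Pearson correlation over co-defined voxels.

    Accepts dense arrays or :class:`DiffuseMap` objects; NaN voxels in
    either input are excluded pairwise.  Default weights are uniform.
    """
    a = map_a.intensity if isinstance(map_a, DiffuseMap) else np.asarray(map_a, float)
    b = map_b.intensity if isinstance(map_b, DiffuseMap) else np.asarray(map_b, float)
    a, b = a.ravel(), b.ravel()
    if a.shape != b.shape:
        raise ValueError("maps must have equal numbers of voxels")
    w = np.ones_like(a) if weights is None else np.asarray(weights, float).ravel()
    ok = np.isfinite(a) & np.isfinite(b) & np.isfinite(w) & (w > 0)
    if isinstance(map_a, DiffuseMap):
        ok &= map_a.defined
    if isinstance(map_b, DiffuseMap):
        ok &= map_b.defined
    if ok.sum() < 10:
        raise ValueError(f"only {int(ok.sum())} co-defined voxels; need >= 10")
    a, b, w = a[ok], b[ok], w[ok]
    w = w / w.sum()
    am = a - w @ a
    bm = b - w @ b
    va = w @ am**2
    vb = w @ bm**2
    # relative guard: round-off can leave ~1e-32 where the variance is zero
    if va <= 1e-24 * max(w @ a**2, 1e-300) or vb <= 1e-24 * max(w @ b**2, 1e-300):
        raise ValueError("zero weighted variance in at least one map")
    return float((w @ (am * bm)) / np.sqrt(va * vb))


def multiplicity_weights(dmap: DiffuseMap, convention: str = "inverse",
                         ) -> np.ndarray:
    """Per-voxel downweighting by symmetry multiplicity (1/m or 1/sqrt(m))."""
    m = np.maximum(dmap.multiplicity, 1.0)
    if convention == "inverse":
        return 1.0 / m
    if convention == "inverse_sqrt":
        return 1.0 / np.sqrt(m)
    raise ValueError("convention must be 'inverse' or 'inverse_sqrt'")


def scale_to_experiment(predicted, experimental, weights=None,
                        ) -> tuple[float, float]:
    """Weighted least-squares (scale, platform) minimizing
    sum w (scale * pred + platform - exp)^2.  CC is unchanged by this map.
    """
    p = predicted.intensity if isinstance(predicted, DiffuseMap) \
        else np.asarray(predicted, float)
    e = experimental.intensity if isinstance(experimental, DiffuseMap) \
        else np.asarray(experimental, float)
    p, e = p.ravel(), e.ravel()
    w = np.ones_like(p) if weights is None else np.asarray(weights, float).ravel()
    ok = np.isfinite(p) & np.isfinite(e) & (w > 0)
    if isinstance(predicted, DiffuseMap):
        ok &= predicted.defined
    if isinstance(experimental, DiffuseMap):
        ok &= experimental.defined
    if ok.sum() < 2:
        raise ValueError("need at least 2 co-defined voxels")
    p, e, w = p[ok], e[ok], w[ok]
    w = w / w.sum()
    pm, em = w @ p, w @ e
    var_p = w @ (p - pm) ** 2
    if var_p <= 1e-24 * max(w @ p**2, 1e-300):
        raise ValueError("predicted map is constant; scale is degenerate")
    scale = (w @ ((p - pm) * (e - em))) / var_p
    platform = em - scale * pm
    return float(scale), float(platform)


@dataclass
class FitResult:
    model_tag: str
    best_params: dict
    cc: float
    scale: float
    platform: float
    scan_table: pd.DataFrame = field(repr=False, default=None)

    def __post_init__(self):
        if self.scan_table is not None and len(self.scan_table):
            best = np.nanmax(self.scan_table["cc"].to_numpy())
            if self.cc < best - 1e-12:
                raise ValueError("best cc must dominate the scan table")


def _axis_fine_grid(values: np.ndarray, best_idx: int, n_fine: int = 21,
                    ) -> np.ndarray:
    """Local refinement grid around the coarse maximizer, 10x finer step."""
    values = np.asarray(values, dtype=float)
    if len(values) == 1:
        return values
    lo = values[max(best_idx - 1, 0)]
    hi = values[min(best_idx + 1, len(values) - 1)]
    if np.all(values > 0) and hi / max(lo, 1e-300) > 3.0:
        return np.geomspace(lo, hi, n_fine)     # log-spaced axes stay log
    return np.linspace(lo, hi, n_fine)


def scan_parameters(experimental: DiffuseMap, predictor, scan_axes: dict,
                    weights=None, model_tag: str = "",
                    subtract_radial: bool = True, refine: bool = True,
                    n_shells: int = 100) -> FitResult:
    """Maximize the multiplicity-weighted CC over a grid of disorder params.

    ``predictor`` maps keyword parameters to a dense model map on the
    experimental grid; predictions are compared through their anisotropic
    parts (radial shell average removed) when ``subtract_radial``.  A
    coarse scan over the cartesian product of ``scan_axes`` is followed by
    one refinement pass at 10x finer per-axis step around the maximum;
    ties break toward smaller parameter values.
    """
    if not scan_axes or any(len(np.atleast_1d(v)) == 0 for v in scan_axes.values()):
        raise ValueError("scan_axes must be non-empty")
    if weights is None:
        weights = multiplicity_weights(experimental)
    grid = experimental.grid
    names = list(scan_axes)
    axes = [np.sort(np.atleast_1d(np.asarray(scan_axes[k], float))) for k in names]

    records = []

    def evaluate(params: dict) -> float:
        try:
            pred = predictor(**params)
        except Exception as exc:           # noqa: BLE001 - record and skip
            log.warning("prediction failed at %s: %s", params, exc)
            records.append({**params, "cc": np.nan})
            return np.nan
        pred = np.asarray(pred, dtype=float)
        if subtract_radial:
            pred = radial_average_of_array(pred, grid, n_shells)
        cc = weighted_cc(experimental, pred, weights)
        records.append({**params, "cc": cc})
        return cc

    def run_grid(axis_values) -> tuple[dict, float, tuple[int, ...]]:
        best, best_cc, best_idx = None, -np.inf, None
        for idx in itertools.product(*[range(len(a)) for a in axis_values]):
            params = {k: float(axis_values[i][j])
                      for i, (k, j) in enumerate(zip(names, idx))}
            cc = evaluate(params)
            if np.isfinite(cc) and cc > best_cc:      # strict: first/low wins ties
                best, best_cc, best_idx = params, cc, idx
        if best is None:
            raise ValueError("every scan point failed")
        return best, best_cc, best_idx

    best, best_cc, best_idx = run_grid(axes)
    if refine:
        fine_axes = [_axis_fine_grid(a, i) for a, i in zip(axes, best_idx)]
        fine_best, fine_cc, _ = run_grid(fine_axes)
        if fine_cc >= best_cc:
            best, best_cc = fine_best, fine_cc
    pred = predictor(**best)
    if subtract_radial:
        pred = radial_average_of_array(pred, grid, n_shells)
    scale, platform = scale_to_experiment(pred, experimental, weights)
    return FitResult(model_tag, best, best_cc, scale, platform,
                     pd.DataFrame.from_records(records))
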