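import numpy as np
import pytest

from diffusemap.fitting import (FitResult, multiplicity_weights,
                                scale_to_experiment, scan_parameters,
                                weighted_cc)
from diffusemap.mapping import (DiffuseMap, MapGrid, map_from_array,
                                radial_average_of_array)
from diffusemap.models import make_llm_predictor, make_rbt_predictor


def test_cc_self_is_one():
    rng = np.random.default_rng(0)
    a = rng.normal(0, 1, 200)
    assert weighted_cc(a, a) == pytest.approx(1.0)
    assert weighted_cc(a, -a) == pytest.approx(-1.0)


def test_cc_matches_brute_force_sums():
    """Unit weights reduce to the plain Pearson sum formula (hand toy)."""
    a = np.array([1.0, 2.0, 4.0] + [0.0] * 7)
    b = np.array([1.0, 3.0, 2.0] + [0.0] * 7)
    n = len(a)
    num = n * (a @ b) - a.sum() * b.sum()
    den = np.sqrt((n * (a @ a) - a.sum() ** 2) * (n * (b @ b) - b.sum() ** 2))
    assert weighted_cc(a, b) == pytest.approx(num / den)


def test_cc_affine_invariance():
    rng = np.random.default_rng(1)
    a = rng.normal(0, 1, 500)
    b = rng.normal(0, 1, 500)
    w = rng.uniform(0.5, 2.0, 500)
    base = weighted_cc(a, b, w)
    assert weighted_cc(3.0 * a + 7.0, b, w) == pytest.approx(base)
    assert weighted_cc(a, -2.0 * b + 1.0, w) == pytest.approx(-base)


def test_cc_excludes_nan_pairwise():
    a = np.array([1.0, 2.0, 3.0, np.nan] + list(range(10)))
    b = np.array([np.nan, 2.0, 3.0, 4.0] + list(range(10)))
    cc = weighted_cc(a, b)
    mask = np.isfinite(a) & np.isfinite(b)
    assert cc == pytest.approx(np.corrcoef(a[mask], b[mask])[0, 1])


def test_cc_errors():
    with pytest.raises(ValueError, match="voxels"):
        weighted_cc(np.ones(5), np.ones(5))
    with pytest.raises(ValueError, match="variance"):
        weighted_cc(np.ones(20), np.arange(20.0))


def test_multiplicity_weights(p1_crystal):
    grid = MapGrid(p1_crystal, 3, 2)
    dmap = map_from_array(np.ones(grid.shape), grid)
    dmap.multiplicity = np.full(grid.n_voxels, 4.0)
    assert np.allclose(multiplicity_weights(dmap), 0.25)
    assert np.allclose(multiplicity_weights(dmap, "inverse_sqrt"), 0.5)


# --------------------------------------------------------------------------
# scaling


def test_scale_identity():
    rng = np.random.default_rng(2)
    p = rng.normal(0, 1, 100)
    s, c = scale_to_experiment(p, p)
    assert s == pytest.approx(1.0) and c == pytest.approx(0.0, abs=1e-12)


def test_scale_affine():
    rng = np.random.default_rng(3)
    p = rng.normal(0, 1, 100)
    s, c = scale_to_experiment(p, 2.0 * p + 7.0)
    assert s == pytest.approx(2.0) and c == pytest.approx(7.0)


def test_scale_weighted_closed_form():
    p = np.array([1.0, 2.0, 4.0])
    e = np.array([3.0, 5.0, 10.0])
    w = np.array([1.0, 2.0, 3.0])
    wn = w / w.sum()
    pm, em = wn @ p, wn @ e
    s_expect = (wn @ ((p - pm) * (e - em))) / (wn @ (p - pm) ** 2)
    c_expect = em - s_expect * pm
    s, c = scale_to_experiment(p, e, w)
    assert s == pytest.approx(s_expect) and c == pytest.approx(c_expect)


def test_scale_degenerate_prediction():
    with pytest.raises(ValueError, match="constant"):
        scale_to_experiment(np.ones(10), np.arange(10.0))


def test_cc_unchanged_by_scaling():
    rng = np.random.default_rng(4)
    p = rng.normal(0, 1, 300)
    e = rng.normal(0, 1, 300)
    s, c = scale_to_experiment(p, e)
    assert weighted_cc(s * p + c, e) == pytest.approx(weighted_cc(p, e))


# --------------------------------------------------------------------------
# parameter scans


@pytest.fixture(scope="module")
def rbt_setup(p1_toy):
    grid = MapGrid(p1_toy.crystal_frame(), oversampling=3, extent=4)
    return grid, make_rbt_predictor(p1_toy, grid)


def test_scan_single_point(rbt_setup):
    grid, pred = rbt_setup
    dmap = map_from_array(radial_average_of_array(pred(0.5), grid), grid)
    res = scan_parameters(dmap, pred, {"sigma": [0.5]}, refine=False)
    assert res.best_params == {"sigma": 0.5}
    assert res.cc == pytest.approx(1.0)


def test_scan_recovers_planted_sigma(rbt_setup):
    """Noiseless fixture at the study's rigid-translation value 0.68 A."""
    grid, pred = rbt_setup
    truth = pred(0.68)
    dmap = map_from_array(radial_average_of_array(truth, grid), grid)
    res = scan_parameters(dmap, pred, {"sigma": np.arange(0.05, 1.51, 0.05)})
    assert abs(res.best_params["sigma"] - 0.68) <= 0.005 + 1e-9
    assert res.cc > 0.9999


def test_scan_llm_joint_recovery():
    """Extended-LLM fixture at the AP values sigma=0.40, gamma=118 A."""
    from diffusemap.synthetic import ToyCrystalSpec, make_toy_crystal
    spec = ToyCrystalSpec(n_atoms=6, cell=(150.0, 150.0, 150.0, 90, 90, 90),
                          frac_box=((0.02, 0.12),) * 3, seed=2)
    model = make_toy_crystal(spec)
    grid = MapGrid(model.crystal_frame(), oversampling=3, extent=5)
    pred = make_llm_predictor(model, grid, extended=True)
    truth = pred(sigma=0.40, gamma=118.0)
    dmap = map_from_array(radial_average_of_array(truth, grid), grid)
    sig_axis = np.arange(0.05, 1.51, 0.05)
    gam_axis = np.geomspace(2.0, 150.0, 20)
    res = scan_parameters(dmap, pred, {"sigma": sig_axis, "gamma": gam_axis})
    # within one fine-grid step per axis
    assert abs(res.best_params["sigma"] - 0.40) <= 0.005 + 1e-9
    i = np.argmin(np.abs(gam_axis - 118.0))
    fine_step = (gam_axis[i + 1] - gam_axis[i - 1]) / 20
    assert abs(res.best_params["gamma"] - 118.0) <= fine_step + 1e-9


def test_scan_table_dominated_by_best(rbt_setup):
    grid, pred = rbt_setup
    rng = np.random.default_rng(5)
    truth = pred(0.4)
    noisy = truth + rng.normal(0, truth.mean(), truth.shape)
    dmap = map_from_array(radial_average_of_array(noisy, grid), grid)
    res = scan_parameters(dmap, pred, {"sigma": np.arange(0.1, 1.01, 0.1)})
    assert res.cc >= np.nanmax(res.scan_table["cc"].to_numpy()) - 1e-12


def test_scan_skips_failing_points(rbt_setup):
    grid, pred = rbt_setup
    dmap = map_from_array(radial_average_of_array(pred(0.5), grid), grid)

    def flaky(sigma):
        if sigma < 0.3:
            raise RuntimeError("boom")
        return pred(sigma)

    res = scan_parameters(dmap, flaky, {"sigma": [0.2, 0.5, 0.8]},
                          refine=False)
    assert res.best_params == {"sigma": 0.5}
    assert np.isnan(res.scan_table["cc"]).sum() == 1


def test_scan_empty_axes(rbt_setup):
    grid, pred = rbt_setup
    dmap = map_from_array(pred(0.5), grid)
    with pytest.raises(ValueError):
        scan_parameters(dmap, pred, {})


def test_fit_result_invariant():
    import pandas as pd
    with pytest.raises(ValueError):
        FitResult("m", {"sigma": 1.0}, 0.1, 1.0, 0.0,
                  pd.DataFrame({"sigma": [1.0], "cc": [0.5]}))


def test_oversampling_consistency():
    """LLM gamma fits agree between 3x and 5x oversampled maps."""
    from diffusemap.synthetic import ToyCrystalSpec, make_toy_crystal
    spec = ToyCrystalSpec(n_atoms=5, cell=(25.0, 25.0, 25.0, 90, 90, 90),
                          seed=1)
    model = make_toy_crystal(spec)
    gammas = np.geomspace(2.0, 60.0, 15)
    best = {}
    for os_factor in (3, 5):
        grid = MapGrid(model.crystal_frame(), oversampling=os_factor, extent=4)
        pred = make_llm_predictor(model, grid, extended=True)
        truth = pred(sigma=0.4, gamma=12.0)
        dmap = map_from_array(radial_average_of_array(truth, grid), grid)
        res = scan_parameters(dmap, pred, {"sigma": [0.4], "gamma": gammas})
        best[os_factor] = res.best_params["gamma"]
    assert abs(best[3] - best[5]) / best[5] < 0.15
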