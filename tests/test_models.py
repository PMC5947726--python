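import numpy as np
import pytest
from scipy.integrate import quad

from diffusemap.mapping import MapGrid, radial_average_of_array
from diffusemap.fitting import weighted_cc
from diffusemap.models import (AtomicModel, build_enm_covariance,
                               crystal_transform, llm_kernel,
                               molecular_transform, predict_ensemble,
                               predict_gaussian_disorder, predict_llm,
                               predict_rigid_rotations,
                               predict_rigid_translations,
                               symmetrized_molecular_transform,
                               wilson_b_to_sigma)
from diffusemap.geometry import real_space_matrix
from diffusemap.synthetic import OracleConfig, oracle_diffuse_map


CELL = (20.0, 20.0, 20.0, 90.0, 90.0, 90.0)


def _model(xyz, elements=None, **kw):
    xyz = np.atleast_2d(xyz)
    elements = elements or ["X"] * len(xyz)
    return AtomicModel(elements, xyz, cell=kw.pop("cell", CELL), **kw)


# --------------------------------------------------------------------------
# molecular transform


def test_single_atom_flat_intensity(p1_grid):
    model = _model([[3.0, 4.0, 5.0]])
    q = p1_grid.q_vectors()
    assert np.allclose(np.abs(molecular_transform(model, q)) ** 2, 1.0)


def test_two_atom_cosine_fringes(p1_grid):
    d = 4.0
    model = _model([[0.0, 0, 0], [d, 0, 0]])
    q = p1_grid.q_vectors()
    intensity = np.abs(molecular_transform(model, q)) ** 2
    expect = 4.0 * np.cos(q[:, 0] * d / 2.0) ** 2
    assert np.allclose(intensity, expect, atol=1e-10)


def test_translation_leaves_intensity(p1_toy, p1_grid):
    q = p1_grid.q_vectors()
    f0 = molecular_transform(p1_toy, q)
    f1 = molecular_transform(p1_toy.with_xyz(p1_toy.xyz + [1.7, -0.3, 2.2]), q)
    assert np.allclose(np.abs(f0) ** 2, np.abs(f1) ** 2, rtol=1e-10)
    assert not np.allclose(f0, f1)


def test_unknown_element_named():
    model = AtomicModel(["Qq"], [[0.0, 0, 0]], cell=CELL)
    with pytest.raises(ValueError, match="Qq"):
        molecular_transform(model, np.zeros((1, 3)))


def test_p1_symmetrized_equals_squared_transform(p1_toy, p1_grid):
    t = symmetrized_molecular_transform(p1_toy, p1_grid)
    q = p1_grid.q_vectors()
    assert np.allclose(t.ravel(),
                       np.abs(molecular_transform(p1_toy, q)) ** 2)


def test_symmetrized_matches_rotated_copies(ortho_toy, ortho_grid):
    """Brute-force oracle: sum |F|^2 of explicitly rotated copies."""
    t = symmetrized_molecular_transform(ortho_toy, ortho_grid)
    q = ortho_grid.q_vectors()
    m_real = real_space_matrix(ortho_toy.cell)
    m_inv = np.linalg.inv(m_real)
    brute = np.zeros(len(q))
    for rot, _ in ortho_toy.real_ops:
        cart_rot = m_real @ rot @ m_inv
        rotated = ortho_toy.with_xyz(ortho_toy.xyz @ cart_rot.T)
        brute += np.abs(molecular_transform(rotated, q)) ** 2
    assert np.allclose(t.ravel(), brute, rtol=1e-8)


def test_symmetrized_laue_invariant(ortho_toy, ortho_grid):
    from diffusemap.symmetry import laue_operators
    t = symmetrized_molecular_transform(ortho_toy, ortho_grid).ravel()
    idx = ortho_grid.index_vectors()
    for op in laue_operators(ortho_grid.crystal.symmetry_ops):
        mm = idx @ op.T
        inb = ortho_grid.in_bounds(mm)
        assert np.allclose(t[ortho_grid.flat_index(mm[inb])], t[inb],
                           rtol=1e-10)


# --------------------------------------------------------------------------
# rigid translations


def test_rbt_zero_sigma(p1_toy, p1_grid):
    assert np.allclose(predict_rigid_translations(p1_toy, p1_grid, 0.0), 0.0)


def test_rbt_closed_form(p1_toy, p1_grid):
    sigma = 0.37
    pred = predict_rigid_translations(p1_toy, p1_grid, sigma)
    q = p1_grid.q_vectors()
    i0 = np.abs(molecular_transform(p1_toy, q)) ** 2
    dw = np.exp(-sigma**2 * np.sum(q**2, axis=1))
    assert np.allclose(pred.ravel(), i0 * (1.0 - dw), rtol=1e-10)
    # at |q| sigma = 1 the factor is 1 - 1/e
    qn = np.linalg.norm(q, axis=1)
    pick = np.argmin(np.abs(qn - 1.0 / sigma))
    if abs(qn[pick] * sigma - 1) < 1e-9:
        assert pred.ravel()[pick] == pytest.approx(i0[pick] * (1 - np.exp(-1)))


def test_rbt_nonnegative_and_friedel(p1_toy, p1_grid):
    pred = predict_rigid_translations(p1_toy, p1_grid, 0.5).ravel()
    assert np.all(pred >= -1e-12)
    idx = p1_grid.index_vectors()
    assert np.allclose(pred[p1_grid.flat_index(-idx)], pred, rtol=1e-10)


# --------------------------------------------------------------------------
# rigid rotations


def test_rbr_zero_sigma(p1_toy, p1_grid):
    assert np.allclose(
        predict_rigid_rotations(p1_toy, p1_grid, 0.0, seed=0), 0.0)


def test_rbr_seed_stability(p1_grid, p1_toy):
    a = predict_rigid_rotations(p1_toy, p1_grid, 2.0, n_samples=10000, seed=1)
    b = predict_rigid_rotations(p1_toy, p1_grid, 2.0, n_samples=10000, seed=2)
    assert weighted_cc(a, b) > 0.99


def test_rbr_blurs_tangentially(p1_toy, p1_grid):
    """Rotational disorder correlates better with a tangentially smeared
    transform than with a radially smeared one of matched magnitude."""
    sigma_rot = 4.0
    pred = predict_rigid_rotations(p1_toy, p1_grid, sigma_rot,
                                   n_samples=4000, seed=0)
    pred = radial_average_of_array(pred, p1_grid)
    q = p1_grid.q_vectors()
    base = np.abs(molecular_transform(p1_toy, q)) ** 2

    def smeared(transform):
        out = np.zeros(len(q))
        n = 0
        for factor in (-1.0, -0.5, 0.5, 1.0):
            out += np.abs(molecular_transform(p1_toy, transform(factor))) ** 2
            n += 1
        return radial_average_of_array((out / n).reshape(p1_grid.shape),
                                       p1_grid)

    ang = np.radians(sigma_rot)
    rotm = lambda f: np.array([[np.cos(f * ang), -np.sin(f * ang), 0],
                               [np.sin(f * ang), np.cos(f * ang), 0],
                               [0, 0, 1.0]])
    tangential = smeared(lambda f: q @ rotm(f).T)
    radial = smeared(lambda f: q * (1.0 + f * ang))
    assert weighted_cc(pred, tangential) > weighted_cc(pred, radial)


# --------------------------------------------------------------------------
# LLM kernel


def test_kernel_peak_value():
    for gamma in (5.0, 18.0, 118.0):
        assert llm_kernel(0.0, gamma) == pytest.approx(8 * np.pi * gamma**3)


def test_kernel_normalization_quadrature():
    for gamma in (5.0, 18.0, 118.0):
        val, _ = quad(lambda dq: llm_kernel(dq, gamma) * 4 * np.pi * dq**2
                      / (2 * np.pi) ** 3, 0, np.inf, limit=300)
        assert val == pytest.approx(1.0, abs=0.01)


def test_kernel_half_maximum():
    gamma = 7.0
    dq_half = np.sqrt(np.sqrt(2.0) - 1.0) / gamma
    assert llm_kernel(dq_half, gamma) == pytest.approx(
        0.5 * llm_kernel(0.0, gamma))


def test_kernel_validation():
    with pytest.raises(ValueError):
        llm_kernel(0.1, 0.0)


# --------------------------------------------------------------------------
# LLM predictions


def test_llm_long_gamma_converges_to_rbt(p1_toy):
    grid = MapGrid(p1_toy.crystal_frame(), oversampling=3, extent=4)
    diameter = 2 * np.linalg.norm(p1_toy.xyz - p1_toy.centroid, axis=1).max()
    sigma = 0.2
    llm = predict_llm(p1_toy, grid, sigma, 10 * diameter)
    rbt = predict_rigid_translations(p1_toy, grid, sigma)
    assert weighted_cc(llm, rbt) > 0.999


def test_extended_llm_speckles_at_nodes(p1_toy):
    grid = MapGrid(p1_toy.crystal_frame(), oversampling=3, extent=4)
    ext = predict_llm(p1_toy, grid, 0.4, 12.0, extended=True).ravel()
    conf = predict_llm(p1_toy, grid, 0.4, 12.0, extended=False).ravel()
    nodes = grid.miller_node_mask()
    # exclude the origin node (zero amplitude factor there)
    nodes = nodes & (grid.q_norms() > 1e-9)
    off = ~grid.miller_node_mask()

    def contrast(arr):
        return np.median(arr[nodes]) / np.median(arr[off])

    assert contrast(ext) > 5 * contrast(conf)


def test_extended_minus_confined_concentrates_at_nodes(p1_toy):
    grid = MapGrid(p1_toy.crystal_frame(), oversampling=5, extent=3)
    ext = predict_llm(p1_toy, grid, 0.4, 12.0, extended=True)
    conf = predict_llm(p1_toy, grid, 0.4, 12.0, extended=False)
    diff = np.abs(ext / ext.sum() - conf / conf.sum()).ravel()
    hkl = grid.hkl()
    frac = hkl - np.round(hkl)
    dq = np.linalg.norm(frac @ grid.A.T, axis=1)
    order = np.argsort(dq)
    lo = diff[order[: len(order) // 4]].mean()
    hi = diff[order[-len(order) // 4:]].mean()
    assert lo > hi


def test_llm_validation(p1_toy, p1_grid):
    with pytest.raises(ValueError):
        predict_llm(p1_toy, p1_grid, -0.1, 10.0)
    with pytest.raises(ValueError):
        predict_llm(p1_toy, p1_grid, 0.1, -1.0)


# --------------------------------------------------------------------------
# ensembles


def test_identical_states_zero(p1_toy, p1_grid):
    pred = predict_ensemble([p1_toy, p1_toy], [0.5, 0.5], p1_grid)
    assert np.allclose(pred, 0.0, atol=1e-10)


def test_two_state_identity(p1_toy, p1_grid):
    other = p1_toy.with_xyz(p1_toy.xyz + np.array([0.8, 0.2, -0.5])
                            * np.linspace(0, 1, p1_toy.n_atoms)[:, None])
    w = (0.7, 0.3)
    pred = predict_ensemble([p1_toy, other], w, p1_grid)
    q = p1_grid.q_vectors()
    f1 = molecular_transform(p1_toy, q)
    f2 = molecular_transform(other, q)
    expect = w[0] * w[1] * np.abs(f1 - f2) ** 2
    assert np.allclose(pred.ravel(), expect, rtol=1e-8, atol=1e-10)


def test_three_state_enumeration_oracle(p1_toy, p1_grid):
    rng = np.random.default_rng(0)
    states = [p1_toy,
              p1_toy.with_xyz(p1_toy.xyz + rng.normal(0, 0.5, p1_toy.xyz.shape)),
              p1_toy.with_xyz(p1_toy.xyz + rng.normal(0, 0.5, p1_toy.xyz.shape))]
    w = np.array([0.5, 0.3, 0.2])
    pred = predict_ensemble(states, w, p1_grid)
    q = p1_grid.q_vectors()
    fs = np.stack([molecular_transform(s, q) for s in states])
    expect = (w[:, None] * np.abs(fs) ** 2).sum(0) \
        - np.abs((w[:, None] * fs).sum(0)) ** 2
    assert np.allclose(pred.ravel(), expect, rtol=1e-8, atol=1e-10)


def test_ensemble_weight_validation(p1_toy, p1_grid):
    with pytest.raises(ValueError):
        predict_ensemble([p1_toy, p1_toy], [0.6, 0.6], p1_grid)


# --------------------------------------------------------------------------
# elastic network / Gaussian covariance


def _chain(n=8, spacing=3.0, b=15.0):
    xyz = np.column_stack([np.arange(n) * spacing, np.zeros(n), np.zeros(n)])
    return AtomicModel(["X"] * n, xyz, b_iso=np.full(n, b),
                       cell=(40.0, 40.0, 40.0, 90, 90, 90))


def test_enm_b_renormalization_exact():
    model = _chain()
    cov = build_enm_covariance(model, cutoff=3.5)
    assert np.allclose(cov.implied_b(), model.b_iso, atol=1e-8)


def test_enm_matches_explicit_pseudo_inverse():
    model = _chain(n=6)
    cov = build_enm_covariance(model, cutoff=3.5)
    d = np.abs(np.subtract.outer(np.arange(6), np.arange(6)))
    adj = (d == 1)
    lap = np.diag(adj.sum(1)) - adj.astype(float)
    g = np.linalg.pinv(lap)
    s = np.sqrt(model.b_iso / (8 * np.pi**2 * np.diag(g)))
    expect = np.outer(s, s) * g
    assert np.allclose(cov.blocks[:, :, 0, 0], expect, atol=1e-10)
    assert np.allclose(cov.blocks[:, :, 0, 1], 0.0)


def test_enm_covariance_decays_along_chain():
    cov = build_enm_covariance(_chain(), cutoff=3.5)
    row = cov.blocks[0, :, 0, 0]
    assert np.all(np.diff(row[1:6]) < 0)    # signed decay away from atom 0


def test_enm_psd():
    cov = build_enm_covariance(_chain(), cutoff=6.5)
    evals = np.linalg.eigvalsh(cov.full_matrix())
    assert evals.min() >= -1e-8 * evals.max()


def test_enm_disconnected_error():
    xyz = np.vstack([np.zeros((2, 3)) + [[0, 0, 0], [2, 0, 0]],
                     np.zeros((2, 3)) + [[30, 0, 0], [32, 0, 0]]])
    model = AtomicModel(["X"] * 4, xyz, b_iso=np.full(4, 10.0),
                        cell=(40, 40, 40, 90, 90, 90))
    with pytest.raises(ValueError, match="disconnected"):
        build_enm_covariance(model, cutoff=5.0)


def test_gaussian_disorder_rigid_limit(p1_toy, p1_grid):
    """V_ij = sigma^2 I for every pair reduces exactly to rigid translations."""
    sigma = 0.4
    n = p1_toy.n_atoms
    blocks = np.tile(sigma**2 * np.eye(3), (n, n, 1, 1))
    from diffusemap.models import CovarianceModel
    pred = predict_gaussian_disorder(p1_toy, p1_grid, CovarianceModel(blocks))
    rbt = predict_rigid_translations(p1_toy, p1_grid, sigma)
    assert np.allclose(pred, rbt, rtol=1e-8, atol=1e-10)


def test_uncorrelated_disorder_is_isotropic():
    """Diagonal-only covariance gives a map depending on |q| alone."""
    model = _model([[2.0, 3.0, 4.0], [6.0, 3.5, 5.0]])
    grid = MapGrid(model.crystal_frame(), oversampling=3, extent=2)
    n = model.n_atoms
    blocks = np.zeros((n, n, 3, 3))
    for i in range(n):
        blocks[i, i] = 0.2 * np.eye(3)
    from diffusemap.models import CovarianceModel
    pred = predict_gaussian_disorder(model, grid, CovarianceModel(blocks)).ravel()
    # cubic cell: axis-permuted voxels share |q| and must agree exactly
    idx = grid.index_vectors()
    perm = idx[:, [1, 2, 0]]
    assert np.allclose(pred[grid.flat_index(perm)], pred, atol=1e-10)


def test_gaussian_disorder_linearized_close_for_small_disp(p1_toy, p1_grid):
    cov = build_enm_covariance(p1_toy, cutoff=15.0,
                               b_targets=np.full(p1_toy.n_atoms, 2.0))
    full = predict_gaussian_disorder(p1_toy, p1_grid, cov)
    lin = predict_gaussian_disorder(p1_toy, p1_grid, cov, linearized=True)
    assert weighted_cc(full, lin) > 0.99


# --------------------------------------------------------------------------
# Wilson B


@pytest.mark.parametrize("b,sigma", [(16.1, 0.45), (31.4, 0.63), (0.0, 0.0)])
def test_wilson_b_examples(b, sigma):
    assert round(wilson_b_to_sigma(b), 2) == sigma


def test_wilson_b_formula():
    assert wilson_b_to_sigma(8 * np.pi**2) == pytest.approx(1.0)


def test_wilson_b_negative_rejected():
    with pytest.raises(ValueError):
        wilson_b_to_sigma(-1.0)


# --------------------------------------------------------------------------
# shared invariants


@pytest.mark.parametrize("maker", [
    lambda m, g: predict_rigid_translations(m, g, 0.4),
    lambda m, g: predict_llm(m, g, 0.4, 8.0),
    lambda m, g: predict_llm(m, g, 0.4, 8.0, extended=True),
    lambda m, g: predict_gaussian_disorder(
        m, g, build_enm_covariance(m, cutoff=20.0)),
])
def test_predictions_nonnegative_and_laue_invariant(ortho_toy, ortho_grid,
                                                    maker):
    from diffusemap.symmetry import laue_operators
    pred = maker(ortho_toy, ortho_grid).ravel()
    assert np.all(pred >= -1e-9 * max(pred.max(), 1))
    idx = ortho_grid.index_vectors()
    scale = pred.max()
    for op in laue_operators(ortho_grid.crystal.symmetry_ops):
        mm = idx @ op.T
        inb = ortho_grid.in_bounds(mm)
        assert np.allclose(pred[ortho_grid.flat_index(mm[inb])], pred[inb],
                           atol=1e-9 * scale)
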