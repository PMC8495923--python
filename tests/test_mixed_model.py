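"""mixed_model: REML, projection operators, BLUP, and the GLS/Wald engine."""

import numpy as np
import pytest

from gblupgwas import (
    PhenotypeTable,
    blup_random,
    gls_wald,
    projection_operator,
    reml_one_kernel,
    reml_two_kernel,
    restricted_loglik,
)

from conftest import (
    fitted_operator,
    gls_oracle,
    manual_vc_one,
    manual_vc_two,
    random_instance,
    random_psd,
)


# -- restricted_loglik -------------------------------------------------------

def _reml_ll_oracle(y, X, Sigma):
    """Direct dense evaluation of Harville's restricted log-likelihood."""
    n, k = X.shape
    Si = np.linalg.inv(Sigma)
    XtSiX = X.T @ Si @ X
    beta = np.linalg.solve(XtSiX, X.T @ Si @ y)
    r = y - X @ beta
    quad = float(r @ Si @ r)
    return -0.5 * (
        (n - k) * np.log(2 * np.pi)
        + np.linalg.slogdet(Sigma)[1]
        + np.linalg.slogdet(XtSiX)[1]
        - np.linalg.slogdet(X.T @ X)[1]
        + quad
    )


def test_restricted_loglik_matches_dense_oracle():
    rng = np.random.default_rng(4)
    for _ in range(5):
        n, k = 25, 3
        X = np.column_stack([np.ones(n), rng.standard_normal((n, k - 1))])
        y = rng.standard_normal(n)
        Sigma = random_psd(n, rng)
        np.testing.assert_allclose(
            restricted_loglik(y, X, Sigma),
            _reml_ll_oracle(y, X, Sigma),
            rtol=1e-10,
        )


def test_restricted_loglik_invariant_to_X_reparametrization():
    # REML is defined through error contrasts: replacing X by XB (B invertible)
    # must not change the value under the +1/2 log|X'X| convention... it does
    # change by log|B|-independent terms only when the convention cancels.
    rng = np.random.default_rng(8)
    n = 20
    X = np.column_stack([np.ones(n), rng.standard_normal(n)])
    B = np.array([[2.0, 0.3], [0.0, -1.5]])
    y = rng.standard_normal(n)
    Sigma = random_psd(n, rng)
    np.testing.assert_allclose(
        restricted_loglik(y, X, Sigma),
        restricted_loglik(y, X @ B, Sigma),
        rtol=1e-10,
    )


# -- one-kernel REML ---------------------------------------------------------

def test_reml_one_kernel_is_at_an_optimum():
    # instance with a real genetic component so the optimum is interior
    rng = np.random.default_rng(17)
    n = 60
    G = random_psd(n, rng)
    L = np.linalg.cholesky(G + 1e-10 * np.eye(n))
    X = np.column_stack([np.ones(n), rng.standard_normal(n)])
    y = L @ rng.standard_normal(n) + 0.7 * rng.standard_normal(n)
    ph = PhenotypeTable([f"s{i}" for i in range(n)], y, X)
    vc = reml_one_kernel(ph, G)
    assert vc.converged
    ll0 = restricted_loglik(ph.y, ph.X, vc.sigma_g2 * G + vc.sigma_e2 * np.eye(ph.n))
    for fac_g, fac_e in ((1.2, 1.0), (0.8, 1.0), (1.0, 1.2), (1.0, 0.8)):
        ll = restricted_loglik(
            ph.y, ph.X,
            fac_g * vc.sigma_g2 * G + fac_e * vc.sigma_e2 * np.eye(ph.n),
        )
        assert ll <= ll0 + 1e-6


def test_reml_one_kernel_recovers_simulated_components():
    rng = np.random.default_rng(100)
    n = 300
    G = random_psd(n, rng)
    L = np.linalg.cholesky(G + 1e-10 * np.eye(n))
    sg2_true, se2_true = 2.0, 1.0
    X = np.column_stack([np.ones(n), rng.standard_normal(n)])
    reps = []
    for seed in range(5):
        r = np.random.default_rng(seed)
        y = (X @ np.array([1.0, 0.5])
             + np.sqrt(sg2_true) * (L @ r.standard_normal(n))
             + np.sqrt(se2_true) * r.standard_normal(n))
        ph = PhenotypeTable([f"s{i}" for i in range(n)], y, X)
        vc = reml_one_kernel(ph, G)
        reps.append((vc.sigma_g2, vc.sigma_e2))
    mean_g = np.mean([a for a, _ in reps])
    mean_e = np.mean([b for _, b in reps])
    assert abs(mean_g - sg2_true) < 0.6
    assert abs(mean_e - se2_true) < 0.3


def test_reml_one_kernel_scale_equivariance():
    ph, gm, G = random_instance(23, n=50)
    vc1 = reml_one_kernel(ph, G)
    ph2 = PhenotypeTable(ph.samples, 3.0 * ph.y, ph.X)
    vc2 = reml_one_kernel(ph2, G)
    np.testing.assert_allclose(vc2.sigma_g2, 9.0 * vc1.sigma_g2, rtol=1e-4)
    np.testing.assert_allclose(vc2.sigma_e2, 9.0 * vc1.sigma_e2, rtol=1e-4)


def test_reml_requires_enough_samples():
    n = 3
    ph = PhenotypeTable([f"s{i}" for i in range(n)], np.arange(n, dtype=float),
                        np.column_stack([np.ones(n), np.arange(n, dtype=float) ** 2]))
    with pytest.raises(ValueError, match="REML"):
        reml_one_kernel(ph, np.eye(n))


# -- two-kernel REML ---------------------------------------------------------

def _two_kernel_instance(seed, n=60):
    rng = np.random.default_rng(seed)
    G = random_psd(n, rng)
    H = random_psd(n, rng)
    X = np.ones((n, 1))
    LG = np.linalg.cholesky(G + 1e-10 * np.eye(n))
    LH = np.linalg.cholesky(H + 1e-10 * np.eye(n))
    y = (LG @ rng.standard_normal(n) + LH @ rng.standard_normal(n)
         + rng.standard_normal(n))
    ph = PhenotypeTable([f"s{i}" for i in range(n)], y, X)
    return ph, G, H


def test_reml_two_kernel_is_at_an_optimum():
    ph, G, H = _two_kernel_instance(31)
    vc = reml_two_kernel(ph, G, H)
    I = np.eye(ph.n)
    ll0 = restricted_loglik(ph.y, ph.X,
                            vc.sigma_A2 * G + vc.sigma_AA2 * H + vc.sigma_e2 * I)
    for fA, fAA, fe in ((1.3, 1, 1), (0.7, 1, 1), (1, 1.3, 1),
                        (1, 0.7, 1), (1, 1, 1.3), (1, 1, 0.7)):
        ll = restricted_loglik(
            ph.y, ph.X,
            fA * vc.sigma_A2 * G + fAA * vc.sigma_AA2 * H + fe * vc.sigma_e2 * I,
        )
        assert ll <= ll0 + 1e-5


def test_reml_two_kernel_grid_and_multistart_agree():
    ph, G, H = _two_kernel_instance(5)
    vg = reml_two_kernel(ph, G, H, algorithm="grid")
    vm = reml_two_kernel(ph, G, H, algorithm="multistart")
    np.testing.assert_allclose(vg.restricted_loglik, vm.restricted_loglik,
                               rtol=1e-6)
    np.testing.assert_allclose(vg.sigma_e2, vm.sigma_e2, rtol=1e-2)


def test_reml_two_kernel_recovers_simulated_components():
    rng = np.random.default_rng(200)
    n = 300
    G = random_psd(n, rng)
    H = random_psd(n, rng)
    LG = np.linalg.cholesky(G + 1e-10 * np.eye(n))
    LH = np.linalg.cholesky(H + 1e-10 * np.eye(n))
    X = np.ones((n, 1))
    sA_t, sAA_t, se_t = 1.5, 0.8, 1.0
    ests = []
    for seed in range(4):
        r = np.random.default_rng(seed + 1)
        y = (np.sqrt(sA_t) * (LG @ r.standard_normal(n))
             + np.sqrt(sAA_t) * (LH @ r.standard_normal(n))
             + np.sqrt(se_t) * r.standard_normal(n))
        ph = PhenotypeTable([f"s{i}" for i in range(n)], y, X)
        vc = reml_two_kernel(ph, G, H)
        ests.append((vc.sigma_A2, vc.sigma_AA2, vc.sigma_e2))
    means = np.mean(ests, axis=0)
    assert abs(means[0] - sA_t) < 0.7
    assert abs(means[1] - sAA_t) < 0.5
    assert abs(means[2] - se_t) < 0.4


def test_reml_two_kernel_identical_kernels_rejected():
    ph, G, _ = _two_kernel_instance(3)
    with pytest.raises(ValueError, match="unidentified"):
        reml_two_kernel(ph, G, G)


# -- variance-component bookkeeping ------------------------------------------

def test_vc_properties():
    vc = manual_vc_one(2.0, 1.0)
    assert vc.lam == 2.0
    np.testing.assert_allclose(vc.h2, 2.0 / 3.0)
    with pytest.raises(AttributeError):
        vc.ratio
    vc2 = manual_vc_two(3.0, 1.5, 0.5)
    assert vc2.ratio == 2.0
    np.testing.assert_allclose(vc2.h2, 4.5 / 5.0)
    with pytest.raises(AttributeError):
        vc2.lam
    df = vc2.to_frame()
    assert list(df["component"])[:3] == ["sigma_A2", "sigma_AA2", "sigma_e2"]


# -- projection operator -----------------------------------------------------

def test_operator_annihilates_X_and_is_V_projection():
    ph, gm, G = random_instance(41)
    vc, op = fitted_operator(ph, G)
    np.testing.assert_allclose(op.T @ ph.X, 0.0, atol=1e-9)
    np.testing.assert_allclose(op.T @ op.V @ op.T, op.T, atol=1e-8)
    np.testing.assert_allclose(op.T, op.T.T, atol=1e-12)
    np.testing.assert_allclose(op.S @ ph.X, 0.0, atol=1e-10)


def test_operator_equals_sigma_e2_times_reml_projection():
    # T = se2 * P with P = Sigma^-1 - Sigma^-1 X (X' Sigma^-1 X)^-1 X' Sigma^-1
    ph, gm, G = random_instance(43)
    vc, op = fitted_operator(ph, G)
    from gblupgwas.kinship import add_ridge
    Sigma = vc.sigma_g2 * add_ridge(G) + vc.sigma_e2 * np.eye(ph.n)
    Si = np.linalg.inv(Sigma)
    SiX = Si @ ph.X
    P = Si - SiX @ np.linalg.solve(ph.X.T @ SiX, SiX.T)
    np.testing.assert_allclose(op.T, vc.sigma_e2 * P, atol=1e-8)


def test_operator_two_kernel_context():
    ph, G, H = _two_kernel_instance(19)
    vc = reml_two_kernel(ph, G, H)
    op = projection_operator(ph, (G, H), vc, force=True)
    assert op.context == "epistatic_null"
    np.testing.assert_allclose(op.T @ ph.X, 0.0, atol=1e-8)


def test_operator_refuses_unconverged_without_force():
    ph, gm, G = random_instance(7)
    vc = manual_vc_one(1.0, 1.0)
    vc.converged = False
    with pytest.raises(ValueError, match="force"):
        projection_operator(ph, G, vc)
    projection_operator(ph, G, vc, force=True)  # no raise


# -- BLUP --------------------------------------------------------------------

def test_blup_matches_dense_formula():
    ph, gm, G = random_instance(53)
    vc, op = fitted_operator(ph, G)
    res = blup_random(ph, op, vc, component="g", kernel=G)
    P = op.T / vc.sigma_e2
    np.testing.assert_allclose(res.ghat, vc.sigma_g2 * (G @ P @ ph.y),
                               atol=1e-9)
    np.testing.assert_allclose(res.var_ghat,
                               vc.sigma_g2 ** 2 * (G @ P @ G), atol=1e-8)


def test_blup_zero_variance_component():
    ph, gm, G = random_instance(57)
    vc = manual_vc_one(0.0, 1.0)
    op = projection_operator(ph, G, vc, force=True)
    res = blup_random(ph, op, vc, component="g", kernel=G)
    np.testing.assert_array_equal(res.ghat, 0.0)


# -- GLS / Wald --------------------------------------------------------------

def test_gls_wald_matches_dense_oracle():
    rng = np.random.default_rng(61)
    for seed in range(4):
        ph, gm, G = random_instance(seed, n=30, p=5)
        vc, op = fitted_operator(ph, G)
        extra = gm.codings[:, :2]
        res = gls_wald(ph, extra, op, vc, test_cols=[0, 1])
        from gblupgwas.kinship import add_ridge
        Sigma = vc.sigma_e2 * (np.eye(ph.n) + vc.lam * add_ridge(G))
        Xstar = np.column_stack([ph.X, extra])
        beta_o, cov_o, wald_o = gls_oracle(ph.y, Xstar, Sigma,
                                           [ph.k, ph.k + 1])
        assert res.ok
        np.testing.assert_allclose(res.estimates, beta_o, rtol=1e-8)
        np.testing.assert_allclose(res.covariance, cov_o, rtol=1e-7)
        np.testing.assert_allclose(res.wald, wald_o, rtol=1e-8)


def test_gls_wald_collinear_returns_na():
    ph, gm, G = random_instance(67)
    vc, op = fitted_operator(ph, G)
    extra = np.column_stack([ph.X[:, 0], gm.codings[:, 0]])  # dup intercept
    res = gls_wald(ph, extra, op, vc, test_cols=[0, 1])
    assert not res.ok
    assert res.reason == "collinear"
    assert np.isnan(res.wald)
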