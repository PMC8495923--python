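"""Shared fixtures and oracle helpers for the test suite.

All fixtures are generated programmatically from fixed seeds; no binary or
data files are shipped.  Oracles here deliberately use different numerical
routes (dense GLS via explicit covariance inversion, brute-force loops)
from the library's implementations.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from gblupgwas import (
    GenotypeMatrix,
    PhenotypeTable,
    build_additive_grm,
    build_epistatic_grm,
    reml_one_kernel,
)
from gblupgwas.mixed_model import VarianceComponents, projection_operator


def random_psd(n: int, rng: np.random.Generator) -> np.ndarray:
    """A random well-conditioned PSD matrix with mean diagonal ~1."""
    A = rng.standard_normal((n, max(n // 2, 2)))
    K = A @ A.T / A.shape[1]
    return K + 0.1 * np.eye(n)


def random_instance(seed: int, n: int = 40, p: int = 8, k: int = 2):
    """A seeded (ph, gm, G) triple with covariates and {0,1,2} dosages."""
    rng = np.random.default_rng(seed)
    M = rng.integers(0, 3, size=(n, p)).astype(float)
    markers = [f"m{j}" for j in range(p)]
    samples = [f"s{i}" for i in range(n)]
    gm = GenotypeMatrix(samples=samples, markers=markers, codings=M,
                        imputed=True)
    X = np.column_stack([np.ones(n)] +
                        [rng.standard_normal(n) for _ in range(k - 1)])
    y = rng.standard_normal(n) + M @ rng.normal(0, 0.2, p)
    ph = PhenotypeTable(samples, y, X)
    G = random_psd(n, rng)
    return ph, gm, G


def fitted_operator(ph, G):
    """One-kernel REML fit and operator for a given instance."""
    vc = reml_one_kernel(ph, G)
    op = projection_operator(ph, G, vc, force=True)
    return vc, op


def manual_vc_one(sigma_g2: float, sigma_e2: float) -> VarianceComponents:
    return VarianceComponents(kind="one_kernel", sigma_g2=sigma_g2,
                              sigma_e2=sigma_e2, restricted_loglik=0.0,
                              converged=True)


def manual_vc_two(sA2: float, sAA2: float, se2: float) -> VarianceComponents:
    return VarianceComponents(kind="two_kernel", sigma_A2=sA2,
                              sigma_AA2=sAA2, sigma_e2=se2,
                              restricted_loglik=0.0, converged=True)


def gls_oracle(y, Xstar, Sigma, test_cols):
    """Dense GLS by explicit inversion: estimates, covariance, Wald."""
    Si = np.linalg.inv(Sigma)
    A = Xstar.T @ Si @ Xstar
    beta = np.linalg.solve(A, Xstar.T @ Si @ y)
    cov = np.linalg.inv(A)
    t = np.asarray(test_cols)
    bt = beta[t]
    wald = float(bt @ np.linalg.solve(cov[np.ix_(t, t)], bt))
    return beta, cov, wald


def genotype_tsv(path, gm: GenotypeMatrix) -> None:
    df = pd.DataFrame(gm.codings, index=pd.Index(gm.samples, name="sample"),
                      columns=gm.markers)
    df.to_csv(path, sep="\t")


@pytest.fixture
def small_panel():
    """30-sample, 12-marker inbred-style panel with kernels (module scope ok)."""
    from gblupgwas.simulator import SimulationConfig, simulate_genotypes

    cfg = SimulationConfig(n=30, p=12, seed=11)
    gm = simulate_genotypes(cfg)
    ks = build_epistatic_grm(build_additive_grm(gm, scaling="vanraden"))
    return gm, ks
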