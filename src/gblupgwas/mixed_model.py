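"""REML fitting, projection operators, BLUPs, and the P3D GLS/Wald engine.

One-kernel model (the GBLUP null):  y = X beta + g + e,  g ~ N(0, G sg2),
e ~ N(0, I se2).  REML over lambda = sg2/se2 is done by spectral profiling:
the likelihood of the error contrasts is expressed through the eigenvalues of
G projected onto the orthogonal complement of X, so each candidate lambda
costs O(n) after a single eigendecomposition.

Two-kernel model (the EGBLUP null):  y = X beta + gA + gAA + e with
gA ~ N(0, G sA2), gAA ~ N(0, H sAA2).  REML maximizes the restricted
likelihood over the two variance ratios (sA2/se2, sAA2/se2) on the log scale
by Nelder-Mead from five deterministic starts, with se2 profiled out in
closed form.

All downstream P3D tests are driven by the projection operator

    T = V^-1 - V^-1 X (X' V^-1 X)^-1 X' V^-1,

where V = Var(y)/se2, so that T = se2 * P with P the REML projection matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize
from scipy.linalg import cho_factor, cho_solve, eigh, qr, solve_triangular

from .data_io import PhenotypeTable
from .kinship import add_ridge

__all__ = [
    "VarianceComponents",
    "ProjectionOperator",
    "BlupResult",
    "reml_one_kernel",
    "reml_two_kernel",
    "restricted_loglik",
    "projection_operator",
    "blup_random",
    "gls_wald",
    "GLSResult",
]

LOG2PI = float(np.log(2.0 * np.pi))


@dataclass
class VarianceComponents:
    """REML variance-component estimates for one- or two-kernel models."""

    kind: str  # "one_kernel" | "two_kernel"
    sigma_e2: float
    restricted_loglik: float
    converged: bool
    sigma_g2: float | None = None  # one_kernel
    sigma_A2: float | None = None  # two_kernel
    sigma_AA2: float | None = None

    @property
    def lam(self) -> float:
        """lambda = sigma_g2 / sigma_e2 (one-kernel)."""
        if self.kind != "one_kernel":
            raise AttributeError("lambda defined for one-kernel fits only")
        return self.sigma_g2 / self.sigma_e2 if self.sigma_e2 > 0 else np.inf

    @property
    def ratio(self) -> float:
        """sigma_A2 / sigma_AA2 (two-kernel)."""
        if self.kind != "two_kernel":
            raise AttributeError("ratio defined for two-kernel fits only")
        return self.sigma_A2 / self.sigma_AA2 if self.sigma_AA2 > 0 else np.inf

    @property
    def h2(self) -> float:
        if self.kind == "one_kernel":
            tot = self.sigma_g2 + self.sigma_e2
            return self.sigma_g2 / tot if tot > 0 else 0.0
        gen = self.sigma_A2 + self.sigma_AA2
        tot = gen + self.sigma_e2
        return gen / tot if tot > 0 else 0.0

    def to_frame(self):
        import pandas as pd

        rows = [("sigma_e2", self.sigma_e2)]
        if self.kind == "one_kernel":
            rows.insert(0, ("sigma_g2", self.sigma_g2))
        else:
            rows = [("sigma_A2", self.sigma_A2),
                    ("sigma_AA2", self.sigma_AA2)] + rows
        rows += [("h2", self.h2), ("restricted_loglik", self.restricted_loglik)]
        return pd.DataFrame(rows, columns=["component", "estimate"])


@dataclass
class ProjectionOperator:
    """V, T and S matrices driving every P3D test.

    ``V`` is Var(y)/sigma_e2 so that T = sigma_e2 * P identically in both the
    one-kernel (V = I + lambda G) and the epistatic-null context
    (V = (sA2 G + sAA2 H)/se2 + I).
    """

    V: np.ndarray
    T: np.ndarray
    S: np.ndarray
    context: str  # "one_kernel" | "epistatic_null"
    X: np.ndarray
    Vinv: np.ndarray


@dataclass
class BlupResult:
    ghat: np.ndarray
    var_ghat: np.ndarray
    component: str


@dataclass
class GLSResult:
    estimates: np.ndarray | None
    covariance: np.ndarray | None
    wald: float
    df: int
    ok: bool = True
    reason: str | None = None


def _complement_basis(X: np.ndarray) -> np.ndarray:
    """Orthonormal basis of the orthogonal complement of col(X)."""
    n, k = X.shape
    Qfull, _ = qr(X, mode="full")
    return Qfull[:, k:]


def restricted_loglik(
    y: np.ndarray, X: np.ndarray, Sigma: np.ndarray
) -> float:
    """Harville's restricted log-likelihood for y ~ N(X beta, Sigma).

    Uses the convention including + 1/2 log|X'X|, which matches the likelihood
    of orthonormal error contrasts; constant offsets cancel between models
    sharing the same X.
    """
    n, k = X.shape
    c, low = cho_factor(Sigma, lower=True)
    logdet_S = 2.0 * np.sum(np.log(np.diag(c)))
    Si_y = cho_solve((c, low), y)
    Si_X = cho_solve((c, low), X)
    XtSiX = X.T @ Si_X
    cx, lowx = cho_factor(XtSiX, lower=True)
    logdet_XSX = 2.0 * np.sum(np.log(np.diag(cx)))
    XtSiy = X.T @ Si_y
    quad = float(y @ Si_y - XtSiy @ cho_solve((cx, lowx), XtSiy))
    sign, logdet_XX = np.linalg.slogdet(X.T @ X)
    return -0.5 * ((n - k) * LOG2PI + logdet_S + logdet_XSX - logdet_XX + quad)


def reml_one_kernel(
    ph: PhenotypeTable,
    G: np.ndarray,
    log_lambda_bounds: tuple[float, float] = (-10.0, 10.0),
    grid_points: int = 100,
    tol: float = 1e-8,
) -> VarianceComponents:
    """Spectral-profile REML for the one-kernel (GBLUP) model.

    Eigendecomposes G on the orthogonal complement of X once, grids the
    profiled restricted likelihood over log(lambda), and refines the best
    bracket by bounded scalar minimization to ``tol`` in log(lambda).
    """
    y, X = ph.y, ph.X
    n, k = X.shape
    if n <= k + 1:
        raise ValueError("need n > k + 1 for REML")
    Gr = add_ridge(np.asarray(G, dtype=float))
    Qc = _complement_basis(X)
    A = Qc.T @ Gr @ Qc
    xi, U = eigh(0.5 * (A + A.T))
    xi = np.clip(xi, 0.0, None)
    eta2 = (U.T @ (Qc.T @ y)) ** 2
    m = n - k

    tot = float(eta2.sum())
    if tot <= 1e-12 * max(1.0, float(y @ y)):
        # y lies (numerically) in the column space of X: no residual variation
        warnings.warn("phenotype is in the covariate span; degenerate fit",
                      stacklevel=2)
        return VarianceComponents(
            kind="one_kernel", sigma_g2=0.0, sigma_e2=tot / m,
            restricted_loglik=np.nan, converged=False,
        )

    def neg_prof(loglam: float) -> float:
        lam = np.exp(loglam)
        d = lam * xi + 1.0
        se2 = float(np.sum(eta2 / d)) / m
        return 0.5 * (m * (np.log(se2) + LOG2PI + 1.0) + np.sum(np.log(d)))

    lo, hi = log_lambda_bounds
    grid = np.linspace(lo, hi, grid_points)
    vals = np.array([neg_prof(g) for g in grid])
    i = int(np.argmin(vals))
    a = grid[max(i - 1, 0)]
    b = grid[min(i + 1, grid_points - 1)]
    res = optimize.minimize_scalar(
        neg_prof, bounds=(a, b), method="bounded",
        options={"xatol": tol},
    )
    loglam = float(res.x)
    converged = bool(res.success)
    if i == 0 or i == grid_points - 1:
        warnings.warn("lambda estimate at search boundary", stacklevel=2)
        converged = False
        loglam = grid[i]
    lam = float(np.exp(loglam))
    d = lam * xi + 1.0
    se2 = float(np.sum(eta2 / d)) / m
    sg2 = lam * se2
    # report on Harville's scale for comparability with the two-kernel fit
    ll = restricted_loglik(y, X, sg2 * Gr + se2 * np.eye(n))
    if not np.isfinite(ll):
        raise FloatingPointError("restricted likelihood non-finite at optimum")
    return VarianceComponents(
        kind="one_kernel", sigma_g2=sg2, sigma_e2=se2,
        restricted_loglik=ll, converged=converged,
    )


# deterministic multistarts: (thetaA, thetaAA) spanning A/AA ratios
_TWO_KERNEL_STARTS = ((0.1, 1.0), (0.5, 1.0), (1.0, 1.0), (2.0, 1.0), (10.0, 1.0))
_LOG_THETA_BOUND = 14.0
_GRID_NODES = np.linspace(-6.0, 6.0, 5)


def reml_two_kernel(
    ph: PhenotypeTable,
    G: np.ndarray,
    H: np.ndarray,
    max_evals: int = 2000,
    tol: float = 1e-8,
    algorithm: str = "grid",
) -> VarianceComponents:
    """REML for the two-kernel (EGBLUP) model y = X beta + gA + gAA + e.

    Derivative-free (Nelder-Mead) search over the log variance ratios
    (sA2/se2, sAA2/se2) with sigma_e2 profiled analytically.  The default
    ``grid`` algorithm scans a coarse 5 x 5 log grid and polishes the best
    node by Nelder-Mead; ``multistart`` instead runs Nelder-Mead from five
    deterministic starting points spanning A/AA ratios {0.1, 0.5, 1, 2, 10}.
    Both find the same optimum on well-posed problems (asserted in the test
    suite); ``grid`` needs far fewer likelihood evaluations.
    """
    y, X = ph.y, ph.X
    n, k = X.shape
    if n <= k + 1:
        raise ValueError("need n > k + 1 for REML")
    Gr = add_ridge(np.asarray(G, dtype=float))
    Hmat = np.asarray(H, dtype=float)
    if np.allclose(Gr, Hmat, atol=1e-12):
        raise ValueError("G and H are identical: two-kernel model unidentified")
    if np.abs(Hmat).max() == 0.0:
        # epistatic kernel vanishes: the model collapses to one kernel
        vc1 = reml_one_kernel(ph, G)
        return VarianceComponents(
            kind="two_kernel", sigma_A2=vc1.sigma_g2, sigma_AA2=0.0,
            sigma_e2=vc1.sigma_e2, restricted_loglik=vc1.restricted_loglik,
            converged=vc1.converged,
        )
    Hr = add_ridge(Hmat)
    m = n - k
    sign, logdet_XX = np.linalg.slogdet(X.T @ X)
    yX = np.column_stack([y, X])

    def neg_prof(logtheta: np.ndarray) -> float:
        lt = np.clip(logtheta, -_LOG_THETA_BOUND, _LOG_THETA_BOUND)
        thA, thAA = np.exp(lt)
        V = thA * Gr
        V += thAA * Hr
        V.flat[:: n + 1] += 1.0
        try:
            L = np.linalg.cholesky(V)
        except np.linalg.LinAlgError:
            return np.inf
        logdet_V = 2.0 * float(np.sum(np.log(np.diag(L))))
        Z = solve_triangular(L, yX, lower=True, check_finite=False)
        zy, ZX = Z[:, 0], Z[:, 1:]
        XtViX = ZX.T @ ZX
        try:
            cx = np.linalg.cholesky(XtViX)
        except np.linalg.LinAlgError:
            return np.inf
        logdet_XVX = 2.0 * float(np.sum(np.log(np.diag(cx))))
        XtViy = ZX.T @ zy
        u = solve_triangular(cx, XtViy, lower=True, check_finite=False)
        quad = float(zy @ zy - u @ u)
        if quad <= 0:
            return np.inf
        se2 = quad / m
        return 0.5 * (
            m * (np.log(se2) + LOG2PI + 1.0)
            + logdet_V + logdet_XVX - logdet_XX
        )

    f0 = neg_prof(np.log(_TWO_KERNEL_STARTS[2]))
    fatol = tol * (1.0 + abs(f0))  # relative -> absolute likelihood tolerance
    if algorithm == "grid":
        nodes = [(la, lb) for la in _GRID_NODES for lb in _GRID_NODES]
        vals = [neg_prof(np.array(nd)) for nd in nodes]
        x0 = np.array(nodes[int(np.argmin(vals))])
        starts = [x0]
        evals_per_start = max(max_evals - len(nodes), 100)
    elif algorithm == "multistart":
        starts = [np.log(s) for s in _TWO_KERNEL_STARTS]
        evals_per_start = max(max_evals // len(starts), 100)
    else:
        raise ValueError(f"unknown algorithm {algorithm!r}")
    best = None
    for x0 in starts:
        res = optimize.minimize(
            neg_prof, x0, method="Nelder-Mead",
            options={"maxfev": evals_per_start, "xatol": 1e-3,
                     "fatol": fatol, "adaptive": False},
        )
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun):
        raise FloatingPointError("two-kernel REML failed from every start")
    lt = np.clip(best.x, -_LOG_THETA_BOUND, _LOG_THETA_BOUND)
    converged = bool(np.all(np.abs(lt) < _LOG_THETA_BOUND - 1e-6))
    if not converged:
        warnings.warn("two-kernel REML variance ratio at search boundary",
                      stacklevel=2)
    thA, thAA = np.exp(lt)
    V = thA * Gr + thAA * Hr + np.eye(n)
    c, low = cho_factor(V, lower=True)
    Vi_y = cho_solve((c, low), y)
    Vi_X = cho_solve((c, low), X)
    XtViX = X.T @ Vi_X
    XtViy = X.T @ Vi_y
    quad = float(y @ Vi_y - XtViy @ np.linalg.solve(XtViX, XtViy))
    se2 = quad / m
    sA2, sAA2 = thA * se2, thAA * se2
    ll = restricted_loglik(y, X, se2 * V)
    return VarianceComponents(
        kind="two_kernel", sigma_A2=sA2, sigma_AA2=sAA2, sigma_e2=se2,
        restricted_loglik=ll, converged=converged,
    )


def projection_operator(
    ph: PhenotypeTable,
    kernels,
    vc: VarianceComponents,
    force: bool = False,
) -> ProjectionOperator:
    """Build the V, T, S matrices for P3D testing under the fitted null.

    ``kernels`` is G for a one-kernel fit or (G, H) for a two-kernel fit.
    V is scaled so Var(y) = sigma_e2 * V, hence T = sigma_e2 * P in both
    contexts.
    """
    if not vc.converged and not force:
        raise ValueError(
            "variance components did not converge; pass force=True to proceed"
        )
    X = ph.X
    n = ph.n
    if vc.kind == "one_kernel":
        G = np.asarray(kernels, dtype=float)
        V = np.eye(n) + vc.lam * add_ridge(G)
        context = "one_kernel"
    else:
        G, H = (np.asarray(K, dtype=float) for K in kernels)
        if vc.sigma_e2 <= 0:
            raise ValueError("sigma_e2 must be positive for the P3D operator")
        V = (vc.sigma_A2 * add_ridge(G) + vc.sigma_AA2 * add_ridge(H)) / vc.sigma_e2 + np.eye(n)
        context = "epistatic_null"
    c, low = cho_factor(V, lower=True)
    Vinv = cho_solve((c, low), np.eye(n))
    Vinv = 0.5 * (Vinv + Vinv.T)
    ViX = Vinv @ X
    XtViX = X.T @ ViX
    try:
        middle = np.linalg.solve(XtViX, ViX.T)
    except np.linalg.LinAlgError as exc:
        raise ValueError("X' V^-1 X singular: rank-deficient covariates") from exc
    T = Vinv - ViX @ middle
    T = 0.5 * (T + T.T)
    XtX_inv_Xt = np.linalg.solve(X.T @ X, X.T)
    S = np.eye(n) - X @ XtX_inv_Xt
    S = 0.5 * (S + S.T)
    return ProjectionOperator(V=V, T=T, S=S, context=context, X=X, Vinv=Vinv)


def blup_random(
    ph: PhenotypeTable,
    op: ProjectionOperator,
    vc: VarianceComponents,
    component: str = "g",
    kernel: np.ndarray | None = None,
) -> BlupResult:
    """BLUP of a random genetic component and its Henderson-sense variance.

    With P = T / sigma_e2:  ghat = s2 K P y,  Var(ghat) = s2^2 K P K, where
    s2 and K are the component's variance and kernel.  ``component`` is one of
    "g" (one-kernel), "g_A", "g_AA", or "g_T" (requires ``kernel`` =
    sA2*G + sAA2*H passed pre-combined or computed internally).
    """
    if kernel is None:
        raise ValueError("pass the component's kernel matrix")
    K = np.asarray(kernel, dtype=float)
    if component == "g":
        s2 = vc.sigma_g2
    elif component == "g_A":
        s2 = vc.sigma_A2
    elif component == "g_AA":
        s2 = vc.sigma_AA2
    elif component == "g_T":
        s2 = 1.0  # caller passes sA2*G + sAA2*H as the kernel
    else:
        raise ValueError(f"unknown component {component!r}")
    P = op.T / vc.sigma_e2
    if s2 == 0.0:
        n = ph.n
        return BlupResult(np.zeros(n), np.zeros((n, n)), component)
    ghat = s2 * (K @ (P @ ph.y))
    KP = K @ P
    var_ghat = s2 * s2 * (KP @ K)
    var_ghat = 0.5 * (var_ghat + var_ghat.T)
    return BlupResult(ghat=ghat, var_ghat=var_ghat, component=component)


def gls_wald(
    ph: PhenotypeTable,
    extra_fixed: np.ndarray,
    op: ProjectionOperator,
    vc: VarianceComponents,
    test_cols,
    rank_rtol: float = 1e-10,
) -> GLSResult:
    """GLS fit of y on [X | extra_fixed] under Cov(y) = sigma_e2 V; Wald test.

    ``test_cols`` indexes columns of ``extra_fixed`` whose joint nullity is
    tested; Wald = g' [Var(g)_tt]^-1 g with df = |test_cols|.  Collinearity
    involving the tested columns yields an NA result (ok=False) rather than an
    exception, so genome scans never abort.
    """
    extra = np.atleast_2d(np.asarray(extra_fixed, dtype=float))
    if extra.shape[0] != ph.n:
        extra = extra.T
    Xstar = np.column_stack([op.X, extra])
    q = extra.shape[1]
    k = op.X.shape[1]
    test_idx = np.asarray(test_cols, dtype=int) + k

    ViXs = op.Vinv @ Xstar
    A = Xstar.T @ ViXs
    # rank check on the normal-equations matrix
    w = np.linalg.eigvalsh(0.5 * (A + A.T))
    if w.min() <= rank_rtol * max(w.max(), 1.0):
        return GLSResult(None, None, np.nan, len(test_idx), ok=False,
                         reason="collinear")
    gamma = np.linalg.solve(A, ViXs.T @ ph.y)
    cov = vc.sigma_e2 * np.linalg.inv(A)
    gt = gamma[test_idx]
    ct = cov[np.ix_(test_idx, test_idx)]
    try:
        wald = float(gt @ np.linalg.solve(ct, gt))
    except np.linalg.LinAlgError:
        return GLSResult(gamma, cov, np.nan, len(test_idx), ok=False,
                         reason="singular_test_block")
    return GLSResult(estimates=gamma, covariance=cov, wald=wald,
                     df=len(test_idx))
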