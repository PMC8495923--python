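"""Additive-effect genome scans.

Two P3D routes with identical test statistics (the package's central additive
identity):

* ``scan_additive_p3d`` — the Q+K route: the marker enters as a fixed effect,
  a_hat = m'Ty / (m'Tm), Var = se2 / (m'Tm), z = m'Ty / (se * sqrt(m'Tm)).
* ``scan_additive_gblup`` — the GWAS-by-GBLUP route: marker effects are
  back-solved from the fitted GBLUP null, a_hat = (sa2/se2) m'Ty, with the
  Henderson-sense variance Var(a_hat)_ii = (sa2^2/se2) m'Tm (or, optionally,
  the full p x p closed form sa2 I - se2 (se2/sa2 I + M'SM)^-1).

Both z statistics refer to a t distribution with n - k - 1 degrees of
freedom.  ``scan_additive_exact`` re-estimates variance components per marker
(the exact, non-P3D Q+K test) and ``test_window`` tests a group of markers
jointly by a Wald statistic, again via two algebraically equal routes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .data_io import GenotypeMatrix, PhenotypeTable
from .mixed_model import (
    ProjectionOperator,
    VarianceComponents,
    projection_operator,
    reml_one_kernel,
)

__all__ = [
    "ScanResult",
    "scan_additive_p3d",
    "scan_additive_gblup",
    "scan_additive_exact",
    "test_window",
]

#: markers whose projected self-product falls below this are untestable
TESTABILITY_EPS = 1e-12


@dataclass
class ScanResult:
    """Per-marker (or per-pair, or per-window) test results."""

    method: str
    table: pd.DataFrame = field(repr=False)

    def to_frame(self) -> pd.DataFrame:
        return self.table.copy()

    @property
    def statistic(self) -> np.ndarray:
        return self.table["statistic"].to_numpy()

    @property
    def p(self) -> np.ndarray:
        return self.table["p"].to_numpy()

    def neglog10p(self) -> np.ndarray:
        with np.errstate(divide="ignore"):
            return -np.log10(np.clip(self.table["p"].to_numpy(), 1e-300, None))


def _t_pvalue(z: np.ndarray, df: int) -> np.ndarray:
    return 2.0 * stats.t.sf(np.abs(z), df)


def _assemble(method, keys, key_names, est, var, stat, df, p, reason):
    data = {}
    if isinstance(key_names, str):
        data[key_names] = keys
    else:
        for i, name in enumerate(key_names):
            data[name] = [k[i] for k in keys]
    data.update(estimate=est, variance=var, statistic=stat, df=df, p=p,
                reason=reason)
    return ScanResult(method=method, table=pd.DataFrame(data))


def _scan_core(ph, gm, op, vc):
    """Shared projected quantities: m'Ty and m'Tm for every marker."""
    M = gm.codings
    Ty = op.T @ ph.y
    TM = op.T @ M
    mTy = M.T @ Ty
    mTm = np.einsum("ij,ij->j", M, TM)
    return mTy, mTm


def scan_additive_p3d(
    ph: PhenotypeTable,
    gm: GenotypeMatrix,
    op: ProjectionOperator,
    vc: VarianceComponents,
) -> ScanResult:
    """Single-marker P3D Q+K scan (marker as fixed effect, null-model vc)."""
    if op.context != "one_kernel":
        raise ValueError("additive scans need the one-kernel null operator")
    mTy, mTm = _scan_core(ph, gm, op, vc)
    se2 = vc.sigma_e2
    df = ph.n - ph.k - 1
    ok = mTm > TESTABILITY_EPS
    est = np.where(ok, mTy / np.where(ok, mTm, 1.0), np.nan)
    var = np.where(ok, se2 / np.where(ok, mTm, 1.0), np.nan)
    z = np.where(ok, mTy / (np.sqrt(se2) * np.sqrt(np.where(ok, mTm, 1.0))),
                 np.nan)
    p = np.where(ok, _t_pvalue(z, df), np.nan)
    reason = np.where(ok, None, "untestable")
    return _assemble("QK_P3D", list(gm.markers), "marker",
                     est, var, z, df, p, reason)


def scan_additive_gblup(
    ph: PhenotypeTable,
    gm: GenotypeMatrix,
    op: ProjectionOperator,
    vc: VarianceComponents,
    c: float = 1.0,
    variance: str = "shortcut",
) -> ScanResult:
    """GWAS by GBLUP: back-solved marker effects with Henderson variances.

    ``c`` is the GRM scaling (G = MM'/c), so sa2 = sg2 / c.  ``variance``
    selects the per-marker shortcut (sa2^2/se2) m'Tm or the full closed form
    diag(sa2 I - se2 (se2/sa2 I + M'SM)^-1); the two agree identically.
    """
    if op.context != "one_kernel":
        raise ValueError("additive scans need the one-kernel null operator")
    M = gm.codings
    sa2 = vc.sigma_g2 / c  # sigma_a2 = sigma_g2 / c for G = MM'/c
    se2 = vc.sigma_e2
    Ty = op.T @ ph.y
    mTy = M.T @ Ty
    ahat = (sa2 / se2) * mTy
    if variance == "shortcut":
        TM = op.T @ M
        mTm = np.einsum("ij,ij->j", M, TM)
        var_a = (sa2 * sa2 / se2) * mTm
    elif variance == "henderson_full":
        var_a = np.diag(henderson_variance_full(M, op.S, sa2, se2))
        TM = op.T @ M
        mTm = np.einsum("ij,ij->j", M, TM)
    else:
        raise ValueError(f"unknown variance mode {variance!r}")
    df = ph.n - ph.k - 1
    ok = (mTm > TESTABILITY_EPS) & (var_a > 0)
    z = np.where(ok, ahat / np.sqrt(np.where(ok, var_a, 1.0)), np.nan)
    p = np.where(ok, _t_pvalue(z, df), np.nan)
    reason = np.where(ok, None, "untestable")
    return _assemble("GBLUP", list(gm.markers), "marker",
                     ahat, var_a, z, df, p, reason)


def henderson_variance_full(
    M: np.ndarray, S: np.ndarray, sa2: float, se2: float
) -> np.ndarray:
    """Full p x p Henderson-sense Var(a_hat) = sa2 I - se2 (se2/sa2 I + M'SM)^-1.

    S is the fixed-effect projection I - X(X'X)^-1 X'.  Exact closed form from
    the mixed-model equations of the marker-effects (RR-BLUP) formulation;
    intended for small p.
    """
    p = M.shape[1]
    inner = (se2 / sa2) * np.eye(p) + M.T @ S @ M
    return sa2 * np.eye(p) - se2 * np.linalg.inv(inner)


def scan_additive_exact(
    ph: PhenotypeTable,
    gm: GenotypeMatrix,
    G: np.ndarray,
) -> ScanResult:
    """Exact (non-P3D) Q+K scan: variance components re-estimated per marker.

    For each marker, REML is rerun with the marker appended to the fixed
    effects, and the t statistic uses the marker-specific variance estimates.
    Markers collinear with X (or failing REML) get NA with a reason code.
    """
    rows_est, rows_var, rows_z, rows_p, rows_reason = [], [], [], [], []
    df = ph.n - ph.k - 1
    for j in range(gm.p):
        m = gm.codings[:, j]
        Xj = np.column_stack([ph.X, m])
        if np.linalg.matrix_rank(Xj) < Xj.shape[1]:
            rows_est.append(np.nan); rows_var.append(np.nan)
            rows_z.append(np.nan); rows_p.append(np.nan)
            rows_reason.append("collinear")
            continue
        try:
            phj = PhenotypeTable(ph.samples, ph.y, Xj)
            vcj = reml_one_kernel(phj, G)
            opj = projection_operator(ph, G, vcj, force=True)
        except (ValueError, FloatingPointError) as exc:
            rows_est.append(np.nan); rows_var.append(np.nan)
            rows_z.append(np.nan); rows_p.append(np.nan)
            rows_reason.append(f"reml_failed:{exc}")
            continue
        mTy = float(m @ (opj.T @ ph.y))
        mTm = float(m @ (opj.T @ m))
        if mTm <= TESTABILITY_EPS:
            rows_est.append(np.nan); rows_var.append(np.nan)
            rows_z.append(np.nan); rows_p.append(np.nan)
            rows_reason.append("untestable")
            continue
        est = mTy / mTm
        var = vcj.sigma_e2 / mTm
        z = mTy / (np.sqrt(vcj.sigma_e2) * np.sqrt(mTm))
        rows_est.append(est); rows_var.append(var)
        rows_z.append(z); rows_p.append(float(_t_pvalue(np.array([z]), df)[0]))
        rows_reason.append(None)
    return _assemble("QK_EXACT", list(gm.markers), "marker",
                     rows_est, rows_var, rows_z, df, rows_p, rows_reason)


def test_window(
    ph: PhenotypeTable,
    W: np.ndarray,
    op: ProjectionOperator,
    vc: VarianceComponents,
    window_id: str = "window",
    rank_rtol: float = 1e-10,
) -> ScanResult:
    """Joint Wald test of a window of s markers, by two equal routes.

    Fixed route: GLS of y on [X | W], Wald = a_w' Var(a_w)^-1 a_w on the
    window block.  Random route: back-solved effects (sa2/se2) W'Ty with
    Henderson variance (sa2^2/se2) W'TW, same quadratic form.  Both are
    computed; their agreement is asserted and the fixed-route value reported,
    referred to chi-square with df = rank of the tested block.
    """
    W = np.atleast_2d(np.asarray(W, dtype=float))
    if W.shape[0] != ph.n:
        W = W.T
    se2 = vc.sigma_e2
    WTy = W.T @ (op.T @ ph.y)
    WTW = W.T @ (op.T @ W)
    WTW = 0.5 * (WTW + WTW.T)
    evals, evecs = np.linalg.eigh(WTW)
    rank = int(np.sum(evals > rank_rtol * max(evals.max(), 1.0)))
    reason = None
    if rank == 0:
        tab = pd.DataFrame({
            "window": [window_id], "estimate": [np.nan], "variance": [np.nan],
            "statistic": [np.nan], "df": [0], "p": [np.nan],
            "reason": ["untestable"],
        })
        return ScanResult(method="WINDOW", table=tab)
    if rank < W.shape[1]:
        reason = "rank_deficient"
    # pseudo-inverse quadratic form on the T metric (both routes collapse to it)
    keep = evals > rank_rtol * max(evals.max(), 1.0)
    inv_evals = np.where(keep, 1.0 / np.where(keep, evals, 1.0), 0.0)
    u = evecs.T @ WTy
    wald_fixed = float(u @ (inv_evals * u)) / se2

    # random route, spelled out independently: a_w = (sa2/se2) W'Ty,
    # Var = (sa2^2/se2) W'TW; Wald = a_w' Var^+ a_w
    sa2 = vc.sigma_g2 if vc.sigma_g2 and vc.sigma_g2 > 0 else 1.0
    aw = (sa2 / se2) * WTy
    var_aw = (sa2 * sa2 / se2) * WTW
    ev2, U2 = np.linalg.eigh(var_aw)
    keep2 = ev2 > rank_rtol * max(ev2.max(), 1.0)
    inv2 = np.where(keep2, 1.0 / np.where(keep2, ev2, 1.0), 0.0)
    u2 = U2.T @ aw
    wald_random = float(u2 @ (inv2 * u2))
    if not np.isclose(wald_fixed, wald_random, rtol=1e-8, atol=1e-8):
        raise FloatingPointError(
            f"window-test routes disagree: {wald_fixed} vs {wald_random}"
        )
    p = float(stats.chi2.sf(wald_fixed, rank))
    tab = pd.DataFrame({
        "window": [window_id],
        "estimate": [np.nan],
        "variance": [np.nan],
        "statistic": [wald_fixed],
        "df": [rank],
        "p": [p],
        "reason": [reason],
    })
    return ScanResult(method="WINDOW", table=tab)
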