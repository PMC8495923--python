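"""Pairwise additive-by-additive epistasis scans.

Three models are compared throughout the package:

* extended Q+K  — fixed terms [m_i, m_j, m_i o m_j] under the one-kernel
  covariance se2 (I + lambda G); tests the product column.
* Q+2K          — the same fixed terms under the two-kernel covariance
  sA2 G + sAA2 H + se2 I.
* REMMA         — the product effect back-solved from a single EGBLUP null
  fit: with q = m_i o m_j and P the REML projection of the two-kernel null,
  aa_hat = sAA2 q'Py, Var = sAA2^2 q'Pq, w = (q'Py)^2 / (q'Pq).

The auxiliary statistic (fixed product term only, no marginal additive fixed
effects, two-kernel covariance) is algebraically identical to REMMA; the
package computes it through the generic GLS engine as an independent route.
All Wald statistics refer to chi-square with one degree of freedom.

REMMA is implemented inversion-free through P.  When H is invertible the
printed back-transform aa_hat = Q' H^-1 ghat_AA gives the same numbers; the
P route never requires H to be full rank.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .data_io import GenotypeMatrix, PhenotypeTable
from .gwas_additive import ScanResult, TESTABILITY_EPS
from .mixed_model import ProjectionOperator, VarianceComponents, gls_wald

__all__ = [
    "enumerate_pairs",
    "scan_epistasis_qk",
    "scan_epistasis_q2k",
    "scan_epistasis_remma",
    "scan_epistasis_auxiliary",
]


def enumerate_pairs(
    p: int, restrict: list[int] | None = None
) -> list[tuple[int, int]]:
    """All marker index pairs (i, j), i < j, in lexicographic order.

    ``restrict`` limits pairs to those whose BOTH members are in the list.
    Indices are 0-based column indices.
    """
    if p < 2:
        raise ValueError("need at least 2 markers to form pairs")
    if restrict is not None:
        allowed = sorted(set(restrict))
        if any(i < 0 or i >= p for i in allowed):
            raise ValueError("restriction index out of range")
        return [(i, j) for a, i in enumerate(allowed)
                for j in allowed[a + 1:]]
    return [(i, j) for i in range(p) for j in range(i + 1, p)]


def _pair_table(method, gm, pairs, est, var, stat, p_vals, reason):
    return ScanResult(method=method, table=pd.DataFrame({
        "marker1": [gm.markers[i] for i, _ in pairs],
        "marker2": [gm.markers[j] for _, j in pairs],
        "estimate": est, "variance": var, "statistic": stat,
        "df": 1, "p": p_vals, "reason": reason,
    }))


def _fixed_triple_scan(method, ph, gm, pairs, op, vc):
    """Shared engine for the extended Q+K and Q+2K scans.

    Per pair the fixed effects [m_i, m_j, m_i o m_j] are added and the product
    column tested.  Because T annihilates X, the Wald statistic reduces to a
    3x3 GLS on the T metric: gamma = (C'TC)^-1 C'Ty, Var = se2 (C'TC)^-1 —
    identical to the full [X | C] GLS but a single pass over pairs.
    """
    M = gm.codings
    n, p = M.shape
    T = op.T
    se2 = vc.sigma_e2
    Ty = T @ ph.y
    TM = T @ M
    MTy = M.T @ Ty           # p
    MTM = M.T @ TM           # p x p
    est = np.full(len(pairs), np.nan)
    var = np.full(len(pairs), np.nan)
    wald = np.full(len(pairs), np.nan)
    reason = np.full(len(pairs), None, dtype=object)
    # batch the product columns to keep memory flat
    chunk = max(1, int(2e6) // max(n, 1))
    for lo in range(0, len(pairs), chunk):
        sub = pairs[lo:lo + chunk]
        Qb = np.empty((n, len(sub)))
        for c, (i, j) in enumerate(sub):
            Qb[:, c] = M[:, i] * M[:, j]
        TQ = T @ Qb
        qTy = Qb.T @ Ty
        qTq = np.einsum("ij,ij->j", Qb, TQ)
        MTQ = M.T @ TQ       # p x chunk
        for c, (i, j) in enumerate(sub):
            A = np.array([
                [MTM[i, i], MTM[i, j], MTQ[i, c]],
                [MTM[j, i], MTM[j, j], MTQ[j, c]],
                [MTQ[i, c], MTQ[j, c], qTq[c]],
            ])
            b = np.array([MTy[i], MTy[j], qTy[c]])
            w_eig = np.linalg.eigvalsh(A)
            if w_eig.min() <= TESTABILITY_EPS * max(w_eig.max(), 1.0):
                reason[lo + c] = "collinear"
                continue
            gamma = np.linalg.solve(A, b)
            cov = se2 * np.linalg.inv(A)
            est[lo + c] = gamma[2]
            var[lo + c] = cov[2, 2]
            wald[lo + c] = gamma[2] ** 2 / cov[2, 2]
    pv = np.where(np.isfinite(wald), stats.chi2.sf(wald, 1), np.nan)
    return _pair_table(method, gm, pairs, est, var, wald, pv, reason)


def scan_epistasis_qk(
    ph: PhenotypeTable,
    gm: GenotypeMatrix,
    pairs: list[tuple[int, int]],
    op: ProjectionOperator,
    vc: VarianceComponents,
) -> ScanResult:
    """Extended Q+K pair scan (additive polygenic control only)."""
    if op.context != "one_kernel":
        raise ValueError("extended Q+K needs the one-kernel null operator")
    return _fixed_triple_scan("QK_EPI", ph, gm, pairs, op, vc)


def scan_epistasis_q2k(
    ph: PhenotypeTable,
    gm: GenotypeMatrix,
    pairs: list[tuple[int, int]],
    op: ProjectionOperator,
    vc: VarianceComponents,
) -> ScanResult:
    """Q+2K pair scan (additive + epistatic polygenic control)."""
    if op.context != "epistatic_null":
        raise ValueError("Q+2K needs the epistatic-null operator")
    return _fixed_triple_scan("Q2K_EPI", ph, gm, pairs, op, vc)


def scan_epistasis_remma(
    ph: PhenotypeTable,
    gm: GenotypeMatrix,
    pairs: list[tuple[int, int]],
    op: ProjectionOperator,
    vc: VarianceComponents,
) -> ScanResult:
    """REMMA: all pair statistics from one EGBLUP null fit.

    aa_hat = sAA2 q'Py, Var = sAA2^2 q'Pq, w = (q'Py)^2/(q'Pq) with
    P = T/se2 from the epistatic-null operator; chi-square, 1 df.
    """
    if op.context != "epistatic_null":
        raise ValueError("REMMA needs the epistatic-null operator")
    M = gm.codings
    n = M.shape[0]
    se2 = vc.sigma_e2
    sAA2 = vc.sigma_AA2
    Py = (op.T @ ph.y) / se2
    est = np.full(len(pairs), np.nan)
    var = np.full(len(pairs), np.nan)
    wald = np.full(len(pairs), np.nan)
    reason = np.full(len(pairs), None, dtype=object)
    chunk = max(1, int(2e6) // max(n, 1))
    P = op.T / se2
    for lo in range(0, len(pairs), chunk):
        sub = pairs[lo:lo + chunk]
        Qb = np.empty((n, len(sub)))
        for c, (i, j) in enumerate(sub):
            Qb[:, c] = M[:, i] * M[:, j]
        qPy = Qb.T @ Py
        PQ = P @ Qb
        qPq = np.einsum("ij,ij->j", Qb, PQ)
        ok = qPq > TESTABILITY_EPS
        sl = slice(lo, lo + len(sub))
        est[sl] = np.where(ok, sAA2 * qPy, np.nan)
        var[sl] = np.where(ok, sAA2 ** 2 * qPq, np.nan)
        wald[sl] = np.where(ok, qPy ** 2 / np.where(ok, qPq, 1.0), np.nan)
        reason[sl] = np.where(ok, None, "untestable")
    pv = np.where(np.isfinite(wald), stats.chi2.sf(wald, 1), np.nan)
    return _pair_table("REMMA", gm, pairs, est, var, wald, pv, reason)


def remma_via_h_inverse(
    ph: PhenotypeTable,
    gm: GenotypeMatrix,
    pairs: list[tuple[int, int]],
    op: ProjectionOperator,
    vc: VarianceComponents,
    H: np.ndarray,
) -> np.ndarray:
    """Wald statistics via the explicit back-transform aa_hat = Q' H^-1 g_AA.

    Requires H invertible; serves as an independent numerical route for the
    inversion-free implementation in :func:`scan_epistasis_remma`.
    """
    from .kinship import build_pair_design
    from .mixed_model import blup_random

    pd_design = build_pair_design(gm)
    col_of = {pair: c for c, pair in enumerate(pd_design.pairs)}
    cols = [col_of[p_] for p_ in pairs]
    Q = pd_design.Q[:, cols]
    blup = blup_random(ph, op, vc, component="g_AA", kernel=H)
    Hinv = np.linalg.inv(H)
    aa = Q.T @ (Hinv @ blup.ghat)
    var_aa = np.einsum("ij,jk,ki->i", Q.T @ Hinv, blup.var_ghat, Hinv @ Q)
    return aa ** 2 / var_aa


def scan_epistasis_auxiliary(
    ph: PhenotypeTable,
    gm: GenotypeMatrix,
    pairs: list[tuple[int, int]],
    op: ProjectionOperator,
    vc: VarianceComponents,
) -> ScanResult:
    """Auxiliary-model scan: fixed product term only, two-kernel covariance.

    Computed pair-by-pair through the generic GLS/Wald engine (an independent
    route from the REMMA back-solve, to which it is algebraically equal).
    """
    if op.context != "epistatic_null":
        raise ValueError("the auxiliary scan needs the epistatic-null operator")
    M = gm.codings
    est = np.full(len(pairs), np.nan)
    var = np.full(len(pairs), np.nan)
    wald = np.full(len(pairs), np.nan)
    reason = np.full(len(pairs), None, dtype=object)
    for c, (i, j) in enumerate(pairs):
        q = (M[:, i] * M[:, j])[:, None]
        res = gls_wald(ph, q, op, vc, test_cols=[0])
        if not res.ok:
            reason[c] = res.reason
            continue
        est[c] = res.estimates[-1]
        var[c] = res.covariance[-1, -1]
        wald[c] = res.wald
    pv = np.where(np.isfinite(wald), stats.chi2.sf(wald, 1), np.nan)
    return _pair_table("AUX", gm, pairs, est, var, wald, pv, reason)
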