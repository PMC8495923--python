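"""Genomic relationship matrices.

The additive GRM is G = MM'/c for a marker matrix M; with VanRaden scaling,
M is centered by twice the allele frequency and c = 2 * sum_j p_j (1 - p_j).
The pairwise additive-by-additive (epistatic) GRM is

    H = (1/2) * (G o G - (M o M)(M o M)')

where "o" is the elementwise (Hadamard) product.  H equals QQ' for the
explicit pairwise design Q whose columns are the products m_i o m_j of all
distinct marker pairs — an exact algebraic identity for any real coding of M.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data_io import GenotypeMatrix

__all__ = [
    "KinshipSet",
    "PairDesign",
    "build_additive_grm",
    "build_epistatic_grm",
    "build_pair_design",
    "standardize_kernel",
    "add_ridge",
]

#: relative eigenvalue tolerance for the PSD check
PSD_RTOL = 1e-8
#: default cap on explicit pairwise design columns
PAIR_DESIGN_CAP = 200_000


@dataclass
class KinshipSet:
    """Additive GRM G, epistatic GRM H and the scaling applied to G."""

    G: np.ndarray
    c: float
    H: np.ndarray | None = None
    coding_note: str = "raw"
    M_used: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        _check_symmetric_psd(self.G, "G")
        if self.H is not None:
            _check_symmetric_psd(self.H, "H")


@dataclass
class PairDesign:
    """Explicit n x p(p-1)/2 pairwise product design Q with its pair index."""

    Q: np.ndarray
    pairs: list[tuple[int, int]]
    marker_ids: list[str]


def _check_symmetric_psd(K: np.ndarray, name: str) -> None:
    if K.ndim != 2 or K.shape[0] != K.shape[1]:
        raise ValueError(f"{name} must be square")
    if not np.allclose(K, K.T, atol=1e-10 * (1.0 + np.abs(K).max())):
        raise ValueError(f"{name} is not symmetric")
    w = np.linalg.eigvalsh(K)
    scale = max(w.max(), 1.0)
    if w.min() < -PSD_RTOL * scale:
        raise ValueError(
            f"{name} is not positive semidefinite (min eig {w.min():.3e})"
        )


def build_additive_grm(
    gm: GenotypeMatrix, scaling: str = "raw"
) -> KinshipSet:
    """Construct the additive GRM.

    ``raw``: G = MM' with M exactly as coded, c = 1 (the coding used by the
    theory around the RR-BLUP equivalence).  ``vanraden``: columns centered by
    2 p_j with p_j the allele frequency, c = 2 * sum_j p_j (1 - p_j).
    """
    if gm.p == 0:
        raise ValueError("no markers")
    M = gm.codings
    if np.isnan(M).any():
        raise ValueError("impute genotypes before building a GRM")
    if scaling == "raw":
        Mc, c = M, 1.0
    elif scaling == "vanraden":
        freq = M.mean(axis=0) / 2.0
        Mc = M - 2.0 * freq
        c = float(2.0 * np.sum(freq * (1.0 - freq)))
        if c <= 0:
            raise ValueError("all markers monomorphic: VanRaden scaling undefined")
    else:
        raise ValueError(f"unknown scaling {scaling!r}")
    G = (Mc @ Mc.T) / c
    G = 0.5 * (G + G.T)
    return KinshipSet(G=G, c=c, coding_note=scaling, M_used=Mc / np.sqrt(c) if scaling == "vanraden" else Mc)


def build_epistatic_grm(ks: KinshipSet) -> KinshipSet:
    """Add the epistatic GRM H = 1/2 (G o G - (M o M)(M o M)') to a KinshipSet.

    Uses the very marker matrix (including any centering/scaling) that built G,
    so that the identity H = QQ' holds for the matching pair design.
    """
    if ks.M_used is None:
        raise ValueError("KinshipSet lacks the marker matrix used for G")
    M = ks.M_used
    if M.shape[0] != ks.G.shape[0]:
        raise ValueError("dimension mismatch between G and M")
    M2 = M * M
    H = 0.5 * (ks.G * ks.G - M2 @ M2.T)
    H = 0.5 * (H + H.T)
    ks.H = H
    _check_symmetric_psd(H, "H")
    return ks


def build_pair_design(
    gm_or_M, marker_ids: list[str] | None = None, cap: int = PAIR_DESIGN_CAP
) -> PairDesign:
    """Explicit pairwise product design Q (columns m_i o m_j, i < j, lex order).

    Intended for small p as an exact oracle; raises when p(p-1)/2 exceeds
    ``cap`` (use the implicit REMMA path instead).
    """
    if isinstance(gm_or_M, GenotypeMatrix):
        M = gm_or_M.codings
        marker_ids = list(gm_or_M.markers)
    else:
        M = np.asarray(gm_or_M, dtype=float)
        if marker_ids is None:
            marker_ids = [f"m{j+1}" for j in range(M.shape[1])]
    n, p = M.shape
    if p < 2:
        raise ValueError("pair design requires at least 2 markers")
    npairs = p * (p - 1) // 2
    if npairs > cap:
        raise ValueError(
            f"{npairs} pairs exceed the explicit-design cap ({cap}); "
            "use the implicit REMMA path"
        )
    pairs = [(i, j) for i in range(p) for j in range(i + 1, p)]
    Q = np.empty((n, npairs))
    for col, (i, j) in enumerate(pairs):
        Q[:, col] = M[:, i] * M[:, j]
    return PairDesign(Q=Q, pairs=pairs, marker_ids=marker_ids)


def standardize_kernel(Kmat: np.ndarray) -> np.ndarray:
    """Rescale a kernel so its mean diagonal is 1 (K * n / trace(K))."""
    Kmat = np.asarray(Kmat, dtype=float)
    tr = float(np.trace(Kmat))
    if tr == 0.0:
        raise ValueError("kernel has zero trace")
    return Kmat * (Kmat.shape[0] / tr)


def add_ridge(K: np.ndarray, rel: float = 1e-8) -> np.ndarray:
    """Return K + rel * meandiag(K) * I (PSD repair before factorization)."""
    d = float(np.mean(np.diag(K)))
    if d <= 0:
        d = 1.0
    return K + rel * d * np.eye(K.shape[0])
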