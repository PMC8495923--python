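"""Synthetic genotypes and phenotypes for the model-comparison study.

Phenotypes follow y = g_A + g_AA + e with g_A ~ N(0, G sA2),
g_AA ~ N(0, H sAA2), e ~ N(0, I se2); no individual QTL effects are placed.
Given a target additive-to-epistatic variance ratio and broad-sense
heritability h2 = (sA2 + sAA2)/(sA2 + sAA2 + se2), the components are

    sA2 = h2 * ratio / (1 + ratio),   sAA2 = h2 / (1 + ratio),
    se2 = 1 - h2,

so the phenotypic variance is 1 when G and H are standardized to mean
diagonal 1.

Because G and H are correlated (LD makes additive and epistatic kinship
overlap), REML cannot always rediscover the simulated components; the study
therefore keeps only replicates whose two-kernel REML estimates fall inside
acceptance intervals around the simulated ratio (on the log2 scale) and h2,
and simulates until each grid cell has the required number of accepted
replicates.

Genotypes emulate a structured, fully inbred diversity panel: samples belong
to ``n_subpops`` subpopulations whose allele frequencies diverge from a
shared ancestral frequency (drawn uniformly from ``maf_range``) by a
Balding-Nichols model with differentiation ``fst``; dosages are {0, 2} with
first-order autocorrelation ``ld_rho`` between adjacent markers (Gaussian
copula), on a synthetic map with 10 kb spacing.  The subpopulation structure
gives the additive and epistatic kinship matrices the substantial positive
correlation seen in real diversity panels; without it H is nearly a scaled
identity and the epistatic variance is confounded with the residual.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .data_io import GenotypeMatrix, PhenotypeTable
from .kinship import build_additive_grm, build_epistatic_grm, standardize_kernel
from .mixed_model import reml_two_kernel

__all__ = [
    "SimulationConfig",
    "SimulatedDataset",
    "simulate_genotypes",
    "simulate_phenotype",
    "variance_components_for",
    "run_accept_reject",
]

#: the full simulation grid: 7 variance ratios x 9 heritabilities
DEFAULT_RATIOS = (0.25, 0.5, 1.0, 2.0, 4.0, 8.0, 16.0)
DEFAULT_H2 = tuple(np.round(np.arange(0.1, 0.95, 0.1), 1))


@dataclass
class SimulationConfig:
    """Study conditions for the accept-reject simulation.

    Defaults mirror the emulated diversity panel (383 inbred genotypes,
    1732 markers) and the 63-cell grid with five accepted replicates per
    cell; reduce ``n``/``p`` for desk-scale runs.
    """

    n: int = 383
    p: int = 1732
    ratio_grid: tuple = DEFAULT_RATIOS
    h2_grid: tuple = DEFAULT_H2
    reps_per_cell: int = 5
    ratio_tol: float = 2.0    # half-width on log2(sA2/sAA2)
    h2_tol: float = 0.2       # half-width on h2
    seed: int = 0
    maf_range: tuple = (0.1, 0.5)
    ld_rho: float = 0.5
    n_subpops: int = 8
    fst: float = 0.35
    max_attempts_per_cell: int = 500
    marker_spacing_bp: int = 10_000

    def __post_init__(self) -> None:
        if self.n < 2 or self.p < 1:
            raise ValueError("need n >= 2 samples and p >= 1 markers")
        if any(r <= 0 for r in self.ratio_grid):
            raise ValueError("variance ratios must be positive")
        if any(not 0.0 < h < 1.0 for h in self.h2_grid):
            raise ValueError("heritabilities must lie in (0, 1)")
        if self.reps_per_cell < 1:
            raise ValueError("reps_per_cell must be >= 1")
        if self.ratio_tol <= 0 or self.h2_tol <= 0:
            raise ValueError("acceptance tolerances must be positive")


@dataclass
class SimulatedDataset:
    genotypes: GenotypeMatrix
    y: np.ndarray
    true_ratio: float
    true_h2: float
    est_ratio: float
    est_h2: float
    accepted: bool
    seed_used: int


def simulate_genotypes(cfg: SimulationConfig, seed: int | None = None) -> GenotypeMatrix:
    """Structured inbred-panel {0, 2} dosages with AR(1) LD on a 10 kb map.

    Ancestral allele frequencies are uniform on ``maf_range``; each of
    ``n_subpops`` subpopulations draws marker frequencies from the
    Balding-Nichols beta distribution with differentiation ``fst``.  A
    per-sample AR(1) Gaussian latent series (coefficient ``ld_rho``) is
    thresholded at the quantile of the sample's subpopulation frequency, so
    adjacent markers are positively correlated in LD while frequencies keep
    their subpopulation values in expectation.
    """
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    n, p = cfg.n, cfg.p
    anc = rng.uniform(cfg.maf_range[0], cfg.maf_range[1], size=p)
    fst = float(cfg.fst)
    if fst > 0 and cfg.n_subpops > 1:
        a = anc * (1.0 - fst) / fst
        b = (1.0 - anc) * (1.0 - fst) / fst
        sub_freq = np.clip(rng.beta(a, b, size=(cfg.n_subpops, p)), 0.01, 0.99)
        membership = rng.integers(0, cfg.n_subpops, size=n)
        freqs = sub_freq[membership, :]
    else:
        freqs = np.broadcast_to(anc, (n, p))
    rho = float(cfg.ld_rho)
    z = np.empty((n, p))
    z[:, 0] = rng.standard_normal(n)
    if p > 1:
        innov = rng.standard_normal((n, p - 1))
        scale = np.sqrt(1.0 - rho * rho)
        for j in range(1, p):
            z[:, j] = rho * z[:, j - 1] + scale * innov[:, j - 1]
    thresh = stats.norm.ppf(freqs)
    M = np.where(z < thresh, 2.0, 0.0)
    markers = [f"snp{j+1}" for j in range(p)]
    gmap = pd.DataFrame(
        {"chrom": "1",
         "pos": np.arange(1, p + 1, dtype=np.int64) * cfg.marker_spacing_bp},
        index=pd.Index(markers, name="marker"),
    )
    return GenotypeMatrix(
        samples=[f"s{i+1}" for i in range(n)],
        markers=markers, codings=M, map=gmap, imputed=True,
    )


def variance_components_for(ratio: float, h2: float) -> tuple[float, float, float]:
    """(sA2, sAA2, se2) giving the requested ratio and h2 with unit total."""
    if not 0.0 < h2 < 1.0:
        raise ValueError("h2 must lie in (0, 1)")
    if ratio <= 0:
        raise ValueError("ratio must be positive")
    sA2 = h2 * ratio / (1.0 + ratio)
    sAA2 = h2 / (1.0 + ratio)
    return sA2, sAA2, 1.0 - h2


def _mvn_factor(K: np.ndarray) -> np.ndarray:
    """Symmetric square-root factor for sampling N(0, K) (K PSD)."""
    w, U = np.linalg.eigh(0.5 * (K + K.T))
    w = np.clip(w, 0.0, None)
    return U * np.sqrt(w)


def simulate_phenotype(
    G: np.ndarray,
    H: np.ndarray,
    ratio: float,
    h2: float,
    seed: int,
    factors: tuple[np.ndarray, np.ndarray] | None = None,
) -> np.ndarray:
    """Draw y = g_A + g_AA + e for standardized kernels G, H.

    ``factors`` may carry precomputed square-root factors of (G, H) to avoid
    refactorizing across replicates.
    """
    sA2, sAA2, se2 = variance_components_for(ratio, h2)
    n = G.shape[0]
    if factors is None:
        factors = (_mvn_factor(G), _mvn_factor(H))
    LG, LH = factors
    rng = np.random.default_rng(seed)
    gA = np.sqrt(sA2) * (LG @ rng.standard_normal(LG.shape[1]))
    gAA = np.sqrt(sAA2) * (LH @ rng.standard_normal(LH.shape[1]))
    e = np.sqrt(se2) * rng.standard_normal(n)
    return gA + gAA + e


def run_accept_reject(
    cfg: SimulationConfig,
    genotypes: GenotypeMatrix | None = None,
    keep_rejected: bool = False,
    reml_max_evals: int = 1200,
) -> list[SimulatedDataset]:
    """Simulate until every (ratio, h2) cell has ``reps_per_cell`` accepted sets.

    One genotype panel (and hence one G, H pair) underlies the whole study, as
    when phenotypes are re-simulated on a fixed diversity panel.  A replicate
    is accepted when the two-kernel REML estimates satisfy
    |log2(est_ratio) - log2(true_ratio)| <= ratio_tol and
    |est_h2 - true_h2| <= h2_tol.  Seeds for phenotype draws are spawned
    deterministically from ``cfg.seed``.
    """
    if genotypes is None:
        genotypes = simulate_genotypes(cfg)
    ks = build_epistatic_grm(build_additive_grm(genotypes, scaling="vanraden"))
    G = standardize_kernel(ks.G)
    H = standardize_kernel(ks.H)
    factors = (_mvn_factor(G), _mvn_factor(H))
    X = np.ones((genotypes.n, 1))
    samples = list(genotypes.samples)

    out: list[SimulatedDataset] = []
    base = np.random.default_rng(cfg.seed).integers(0, 2**31 - 1)
    counter = 0
    for ratio in cfg.ratio_grid:
        for h2 in cfg.h2_grid:
            accepted = 0
            attempts = 0
            while accepted < cfg.reps_per_cell:
                attempts += 1
                if attempts > cfg.max_attempts_per_cell:
                    raise RuntimeError(
                        f"attempt cap ({cfg.max_attempts_per_cell}) exceeded "
                        f"in cell ratio={ratio}, h2={h2}"
                    )
                counter += 1
                seed_i = int((base + counter * 1_000_003) % (2**31 - 1))
                y = simulate_phenotype(G, H, ratio, h2, seed_i, factors)
                ph = PhenotypeTable(samples, y, X)
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    vc = reml_two_kernel(ph, G, H, max_evals=reml_max_evals)
                est_ratio = vc.ratio
                est_h2 = vc.h2
                ok = (
                    np.isfinite(est_ratio) and est_ratio > 0
                    and abs(np.log2(est_ratio) - np.log2(ratio)) <= cfg.ratio_tol
                    and abs(est_h2 - h2) <= cfg.h2_tol
                )
                ds = SimulatedDataset(
                    genotypes=genotypes, y=y, true_ratio=ratio, true_h2=h2,
                    est_ratio=est_ratio, est_h2=est_h2, accepted=bool(ok),
                    seed_used=seed_i,
                )
                if ok:
                    accepted += 1
                    out.append(ds)
                elif keep_rejected:
                    out.append(ds)
    return out
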