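"""The three pairwise epistasis scans, their one identity and one non-identity.

* REMMA and the auxiliary fixed-product model are algebraically identical.
* REMMA and Q+2K are NOT equivalent: Q+2K adjusts the product for the pair's
  marginal additive effects, REMMA does not.  With strong marginal effects on
  a pair in LD with its product, the two statistics diverge dramatically.
"""

import numpy as np

from gblupgwas import (
    PhenotypeTable,
    enumerate_pairs,
    reml_two_kernel,
    scan_epistasis_auxiliary,
    scan_epistasis_q2k,
    scan_epistasis_qk,
    scan_epistasis_remma,
    reml_one_kernel,
)
from gblupgwas.kinship import (
    add_ridge,
    build_additive_grm,
    build_epistatic_grm,
    standardize_kernel,
)
from gblupgwas.mixed_model import VarianceComponents, projection_operator
from gblupgwas.simulator import SimulationConfig, simulate_genotypes

gm = simulate_genotypes(SimulationConfig(n=80, p=12, seed=5, ld_rho=0.7))
ks = build_epistatic_grm(build_additive_grm(gm, scaling="vanraden"))
G, H = standardize_kernel(ks.G), standardize_kernel(ks.H)
X = np.ones((gm.n, 1))
pairs = enumerate_pairs(gm.p)

# -- a phenotype with additive, epistatic and residual components -------------
rng = np.random.default_rng(3)
LG = np.linalg.cholesky(add_ridge(G))
LH = np.linalg.cholesky(add_ridge(H))
y = (0.8 * LG @ rng.standard_normal(gm.n)
     + 0.6 * LH @ rng.standard_normal(gm.n)
     + 0.7 * rng.standard_normal(gm.n))
ph = PhenotypeTable(list(gm.samples), y, X)

vc2 = reml_two_kernel(ph, G, H)
op2 = projection_operator(ph, (G, H), vc2, force=True)
vc1 = reml_one_kernel(ph, G)
op1 = projection_operator(ph, G, vc1, force=True)
print(f"two-kernel null: sigma_A2={vc2.sigma_A2:.3f} "
      f"sigma_AA2={vc2.sigma_AA2:.3f} sigma_e2={vc2.sigma_e2:.3f}")

remma = scan_epistasis_remma(ph, gm, pairs, op2, vc2)
aux = scan_epistasis_auxiliary(ph, gm, pairs, op2, vc2)
q2k = scan_epistasis_q2k(ph, gm, pairs, op2, vc2)
qk = scan_epistasis_qk(ph, gm, pairs, op1, vc1)

ok = np.isfinite(remma.statistic) & np.isfinite(aux.statistic)
print(f"max |w_REMMA - w_AUX| over {ok.sum()} testable pairs: "
      f"{np.max(np.abs(remma.statistic[ok] - aux.statistic[ok])):.3e} "
      "(identical)")
ok2 = np.isfinite(remma.statistic) & np.isfinite(q2k.statistic)
print(f"max |w_REMMA - w_Q2K|: "
      f"{np.max(np.abs(remma.statistic[ok2] - q2k.statistic[ok2])):.3f} "
      "(different tests)")

# -- the non-equivalence, isolated -------------------------------------------
# Fix the population parameters (P3D) and inject strong marginal additive
# effects on markers 0 and 1: REMMA's product statistic at pair (0, 1) is
# contaminated by the unadjusted marginals, Q+2K's is not.
vc_fix = VarianceComponents(kind="two_kernel", sigma_A2=0.3, sigma_AA2=0.3,
                            sigma_e2=0.4, restricted_loglik=0.0,
                            converged=True)
Mc = gm.codings - gm.codings.mean(axis=0)
e = 0.6 * np.random.default_rng(400).standard_normal(gm.n)
for label, y_demo in (("strong marginal effects", 2 * Mc[:, 0] + 2 * Mc[:, 1] + e),
                      ("null additive effects  ", e)):
    ph_d = PhenotypeTable(list(gm.samples), y_demo, X)
    op_d = projection_operator(ph_d, (G, H), vc_fix, force=True)
    wr = scan_epistasis_remma(ph_d, gm, [(0, 1)], op_d, vc_fix).statistic[0]
    w2 = scan_epistasis_q2k(ph_d, gm, [(0, 1)], op_d, vc_fix).statistic[0]
    print(f"{label}: w_REMMA={wr:8.3f}  w_Q2K={w2:6.3f}  "
          f"gap={abs(wr - w2):8.3f}")
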