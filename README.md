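# gblupgwas

Mixed-model GWAS for additive and pairwise additive-by-additive (epistatic)
effects, built around one central identity: the marker effects back-solved
from a fitted GBLUP model yield *exactly* the same test statistics as the
P3D Q+K fixed-effect scan. The package implements

- **Additive scans** — P3D Q+K (marker as a fixed effect, null variance
  components reused for every marker), GWAS-by-GBLUP (effects back-solved
  from one GBLUP fit, with Henderson-sense variances), and the exact
  per-marker-REML Q+K test.
- **Epistasis scans** — the extended Q+K test (pair + product as fixed
  effects under the additive-kinship covariance), Q+2K (the same fixed
  terms under the additive + epistatic two-kernel covariance), REMMA
  (all pair statistics back-solved from one two-kernel null fit), and the
  auxiliary fixed-product model, which is algebraically identical to REMMA.
  REMMA is *not* equivalent to Q+2K: Q+2K adjusts for the pair's marginal
  effects, REMMA does not.
- **Kinship** — additive GRM (raw or VanRaden scaling) and the epistatic
  GRM H = ½(G∘G − (M∘M)(M∘M)′), which equals QQ′ for the explicit pairwise
  product design Q (an exact identity, tested to 1e−12).
- **REML** — spectral-profiled one-kernel REML and profiled two-kernel REML
  over the log variance ratios.
- **Simulator** — structured inbred panels (Balding–Nichols subpopulations,
  AR(1) LD) and phenotypes y = g_A + g_AA + e on a (variance ratio × h²)
  grid, with accept–reject filtering on the re-estimated components.
- **Comparison** — threshold-filtered correlations of −log10(p) between
  scans, heritability classes, and Pearson trends of similarity in
  log2(σ²_A/σ²_AA).

## Library quick start

```python
import numpy as np
from gblupgwas import (
    read_genotype_matrix, read_phenotype_table, impute_and_code,
    build_additive_grm, reml_one_kernel, scan_additive_p3d,
    scan_additive_gblup,
)
from gblupgwas.mixed_model import projection_operator

gm = impute_and_code(read_genotype_matrix("genotypes.tsv"))
ph = read_phenotype_table("phenotypes.tsv", trait="y", genotypes=gm)
ks = build_additive_grm(gm, scaling="vanraden")
vc = reml_one_kernel(ph, ks.G)
op = projection_operator(ph, ks.G, vc, force=True)
z_qk = scan_additive_p3d(ph, gm, op, vc).statistic
z_gblup = scan_additive_gblup(ph, gm, op, vc, c=ks.c).statistic
assert np.nanmax(np.abs(z_qk - z_gblup)) < 1e-8   # the equivalence theorem
```

## Command line

```sh
gblupgwas scan-additive  --geno g.tsv --pheno p.tsv --trait y \
                         --method p3d --method gblup --out results
gblupgwas scan-epistasis --geno g.tsv --pheno p.tsv --trait y \
                         --method remma --method q2k --out results
gblupgwas compare results/scan_epistasis_remma.tsv \
                  results/scan_epistasis_q2k.tsv --d 2
gblupgwas simulate --config study.yaml --seed 1 --out sims   # datasets only
gblupgwas study    --config study.yaml --seed 1 --out study  # + scans/trends
```

Exit codes: 0 success, 2 configuration error, 3 data error, 4 numerical
failure. A YAML config holds a `simulation:` block with `SimulationConfig`
fields (`n`, `p`, `ratio_grid`, `h2_grid`, `reps_per_cell`, …).

## Repository layout

- `src/gblupgwas/` — the library (`data_io`, `kinship`, `mixed_model`,
  `gwas_additive`, `gwas_epistasis`, `simulator`, `comparison`, `pipeline`,
  `cli`).
- `examples/` — narrative scripts walking through the identities and the
  simulation study.
- `tests/` — pytest suite; `tests/test_acceptance.py` holds the acceptance
  criteria. All fixtures are generated programmatically from fixed seeds.
- `scripts/acceptance.py` — recomputes the headline quantities and writes a
  JSON report: `python scripts/acceptance.py --seed 1 --out report.json`.
- `docs/methods.md` — statistical methods and the package's design choices.

## Known limitation

In the simulation study, the similarity between REMMA and Q+2K
(threshold-filtered correlation of −log10(p)) trends *positively* in
log2(σ²_A/σ²_AA) under this generator, for every panel geometry we tested;
see `docs/methods.md` for the analysis. The acceptance test asserting a
negative trend is expected to fail and is left failing by design.
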