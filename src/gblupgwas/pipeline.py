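"""End-to-end orchestration: configured GWAS runs and the simulation study.

Two entry points mirror the two workflows of the package:

* :func:`run_gwas` — read genotypes/phenotypes, optionally LD-prune, fit the
  required null model(s) once (P3D), run the requested additive or epistatic
  scans, and write one results TSV per method plus a variance-component TSV
  and a plain-text log.
* :func:`run_simulation_study` — generate accepted datasets by the
  accept-reject simulator, run the three epistatic scans (extended Q+K, Q+2K,
  REMMA) on every dataset, compute per-dataset threshold-filtered
  correlations between method pairs, and summarize the trend of similarity
  in log2 of the estimated additive-to-epistatic variance ratio, per
  heritability class.

All randomness flows from the single config seed; two runs with equal
configs produce equal outputs.  Failures carry a stage name and map onto
distinct CLI exit codes: :class:`ConfigError` (2), :class:`DataError` (3),
:class:`NumericalError` (4).
"""

from __future__ import annotations

import dataclasses
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .comparison import (
    classify_by_h2,
    filtered_correlation,
    significance_stars,
    trend_analysis,
)
from .data_io import (
    GenotypeFormatError,
    GenotypeMatrix,
    PhenotypeTable,
    impute_and_code,
    ld_prune,
    read_genotype_matrix,
    read_phenotype_table,
    write_scan_results,
)
from .gwas_additive import scan_additive_exact, scan_additive_gblup, scan_additive_p3d
from .gwas_epistasis import (
    enumerate_pairs,
    scan_epistasis_auxiliary,
    scan_epistasis_q2k,
    scan_epistasis_qk,
    scan_epistasis_remma,
)
from .kinship import build_additive_grm, build_epistatic_grm, standardize_kernel
from .mixed_model import projection_operator, reml_one_kernel, reml_two_kernel
from .simulator import SimulationConfig, run_accept_reject

__all__ = [
    "RunConfig",
    "ConfigError",
    "DataError",
    "NumericalError",
    "run_gwas",
    "run_simulation_study",
    "run_trend_study",
]

#: default -log10(p) thresholds for the comparison analysis (Figs. 1-3 range)
DEFAULT_THRESHOLDS = (1.0, 2.0, 3.0, 4.0)

ADDITIVE_METHODS = ("p3d", "gblup", "exact")
EPISTASIS_METHODS = ("qk", "q2k", "remma", "aux")


class ConfigError(ValueError):
    """Invalid or inconsistent run configuration (CLI exit code 2)."""


class DataError(ValueError):
    """Input data could not be read or is unusable (CLI exit code 3)."""


class NumericalError(RuntimeError):
    """A model-fitting or scanning stage failed numerically (CLI exit 4)."""


@dataclass
class RunConfig:
    """Configuration for :func:`run_gwas` / :func:`run_simulation_study`.

    ``scan`` selects the workflow flavor of :func:`run_gwas` ("additive" or
    "epistasis"); ``methods`` lists the scan methods to run.  ``sim`` carries
    the simulation block for :func:`run_simulation_study`.
    """

    geno: str | None = None
    map: str | None = None
    pheno: str | None = None
    trait: str | None = None
    covariates: tuple = ()
    dialect: str = "tsv"
    scan: str = "additive"
    methods: tuple = ("p3d",)
    prune_r2: float | None = None
    prune_window_kb: float = 1000.0
    prune_step_kb: float = 10.0
    sim: SimulationConfig | None = None
    thresholds: tuple = DEFAULT_THRESHOLDS
    seeds: tuple = (1,)
    out_dir: str = "results"
    seed: int = 0
    log_level: str = "INFO"


def _logger(out: Path, level: str) -> logging.Logger:
    log = logging.getLogger(f"gblupgwas.{out}")
    log.setLevel(level.upper())
    log.handlers.clear()
    fh = logging.FileHandler(out / "run.log")
    fh.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(fh)
    sh = logging.StreamHandler()
    sh.setLevel("WARNING")
    log.addHandler(sh)
    return log


def _validate_gwas_config(cfg: RunConfig) -> None:
    if cfg.scan not in ("additive", "epistasis"):
        raise ConfigError(f"unknown scan kind {cfg.scan!r}")
    allowed = ADDITIVE_METHODS if cfg.scan == "additive" else EPISTASIS_METHODS
    bad = [m for m in cfg.methods if m not in allowed]
    if bad:
        raise ConfigError(f"unknown method(s) {bad} for scan={cfg.scan}")
    if not cfg.methods:
        raise ConfigError("no scan methods requested")
    for flag, path in (("--geno", cfg.geno), ("--pheno", cfg.pheno)):
        if path is None:
            raise ConfigError(f"{flag} is required")
        if not Path(path).exists():
            raise ConfigError(f"{flag}: no such file: {path}")
    if cfg.map is not None and not Path(cfg.map).exists():
        raise ConfigError(f"--map: no such file: {cfg.map}")
    if cfg.trait is None:
        raise ConfigError("--trait is required")
    if cfg.prune_r2 is not None and not 0.0 < cfg.prune_r2 <= 1.0:
        raise ConfigError("--prune-r2 must lie in (0, 1]")


def _write_vc(vc, path: Path) -> None:
    vc.to_frame().to_csv(path, sep="\t", index=False, float_format="%.12g")


def run_gwas(cfg: RunConfig) -> Path:
    """Run the configured scans; returns the output directory."""
    _validate_gwas_config(cfg)
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log = _logger(out, cfg.log_level)
    log.info("seed=%d scan=%s methods=%s", cfg.seed, cfg.scan, cfg.methods)

    stage = "read-genotypes"
    try:
        gm = read_genotype_matrix(cfg.geno, dialect=cfg.dialect,
                                  map_path=cfg.map)
        gm = impute_and_code(gm)
        stage = "read-phenotypes"
        ph = read_phenotype_table(cfg.pheno, cfg.trait,
                                  covariates=list(cfg.covariates),
                                  genotypes=gm)
        gm = gm if ph.n == gm.n else _align_genotypes(gm, ph)
    except (GenotypeFormatError, OSError, ValueError) as exc:
        raise DataError(f"stage {stage}: {exc}") from exc

    if cfg.prune_r2 is not None:
        stage = "ld-prune"
        try:
            kept = ld_prune(gm, r2_threshold=cfg.prune_r2,
                            window=int(cfg.prune_window_kb * 1000),
                            step=int(cfg.prune_step_kb * 1000))
            log.info("LD pruning kept %d of %d markers", len(kept), gm.p)
            gm = gm.subset_markers(kept)
        except ValueError as exc:
            raise DataError(f"stage {stage}: {exc}") from exc

    stage = "kinship"
    try:
        ks = build_additive_grm(gm, scaling="vanraden")
        need_h = cfg.scan == "epistasis" and any(
            m in ("q2k", "remma", "aux") for m in cfg.methods)
        if need_h:
            ks = build_epistatic_grm(ks)
    except ValueError as exc:
        raise DataError(f"stage {stage}: {exc}") from exc

    t0 = time.time()
    try:
        if cfg.scan == "additive":
            _run_additive(cfg, gm, ph, ks, out, log)
        else:
            _run_epistasis(cfg, gm, ph, ks, out, log)
    except (np.linalg.LinAlgError, FloatingPointError, RuntimeError) as exc:
        raise NumericalError(f"stage scan: {exc}") from exc
    log.info("scans finished in %.1f s", time.time() - t0)
    return out


def _align_genotypes(gm: GenotypeMatrix, ph: PhenotypeTable) -> GenotypeMatrix:
    idx = [gm.samples.index(s) for s in ph.samples]
    return GenotypeMatrix(samples=list(ph.samples), markers=list(gm.markers),
                          codings=gm.codings[idx, :], map=gm.map,
                          monomorphic=list(gm.monomorphic), imputed=gm.imputed)


def _run_additive(cfg, gm, ph, ks, out: Path, log) -> None:
    vc = reml_one_kernel(ph, ks.G)
    log.info("one-kernel REML: sigma_g2=%.6g sigma_e2=%.6g lambda=%.6g "
             "restricted_loglik=%.6g converged=%s", vc.sigma_g2, vc.sigma_e2,
             vc.lam, vc.restricted_loglik, vc.converged)
    _write_vc(vc, out / "variance_components.tsv")
    op = projection_operator(ph, ks.G, vc, force=True)
    for method in cfg.methods:
        if method == "p3d":
            res = scan_additive_p3d(ph, gm, op, vc)
        elif method == "gblup":
            res = scan_additive_gblup(ph, gm, op, vc, c=ks.c)
        else:
            res = scan_additive_exact(ph, gm, ks.G)
        write_scan_results(res, out / f"scan_additive_{method}.tsv")
        log.info("wrote scan_additive_%s.tsv (%d markers)", method, gm.p)


def _run_epistasis(cfg, gm, ph, ks, out: Path, log) -> None:
    pairs = enumerate_pairs(gm.p)
    need_one = "qk" in cfg.methods
    need_two = any(m in ("q2k", "remma", "aux") for m in cfg.methods)
    op1 = vc1 = op2 = vc2 = None
    if need_one:
        vc1 = reml_one_kernel(ph, ks.G)
        log.info("one-kernel REML: lambda=%.6g restricted_loglik=%.6g",
                 vc1.lam, vc1.restricted_loglik)
        _write_vc(vc1, out / "variance_components_one_kernel.tsv")
        op1 = projection_operator(ph, ks.G, vc1, force=True)
    if need_two:
        vc2 = reml_two_kernel(ph, ks.G, ks.H)
        log.info("two-kernel REML: sigma_A2=%.6g sigma_AA2=%.6g "
                 "sigma_e2=%.6g restricted_loglik=%.6g converged=%s",
                 vc2.sigma_A2, vc2.sigma_AA2, vc2.sigma_e2,
                 vc2.restricted_loglik, vc2.converged)
        _write_vc(vc2, out / "variance_components_two_kernel.tsv")
        op2 = projection_operator(ph, (ks.G, ks.H), vc2, force=True)
    runners = {
        "qk": lambda: scan_epistasis_qk(ph, gm, pairs, op1, vc1),
        "q2k": lambda: scan_epistasis_q2k(ph, gm, pairs, op2, vc2),
        "remma": lambda: scan_epistasis_remma(ph, gm, pairs, op2, vc2),
        "aux": lambda: scan_epistasis_auxiliary(ph, gm, pairs, op2, vc2),
    }
    for method in cfg.methods:
        res = runners[method]()
        write_scan_results(res, out / f"scan_epistasis_{method}.tsv")
        log.info("wrote scan_epistasis_%s.tsv (%d pairs)", method, len(pairs))


# ---------------------------------------------------------------------------
# simulation study


def _write_genotype_tsv(gm: GenotypeMatrix, path: Path) -> None:
    df = pd.DataFrame(gm.codings, index=pd.Index(gm.samples, name="sample"),
                      columns=gm.markers)
    df.to_csv(path, sep="\t", float_format="%.12g")


def _scan_dataset(ds, gm, G, H, pairs):
    """Fit both nulls and run the three compared epistatic scans."""
    ph = PhenotypeTable(list(gm.samples), ds.y, np.ones((gm.n, 1)))
    vc1 = reml_one_kernel(ph, G)
    op1 = projection_operator(ph, G, vc1, force=True)
    vc2 = reml_two_kernel(ph, G, H)
    op2 = projection_operator(ph, (G, H), vc2, force=True)
    return {
        "QK": scan_epistasis_qk(ph, gm, pairs, op1, vc1),
        "Q2K": scan_epistasis_q2k(ph, gm, pairs, op2, vc2),
        "REMMA": scan_epistasis_remma(ph, gm, pairs, op2, vc2),
    }


METHOD_PAIRS = (("REMMA", "Q2K"), ("QK", "Q2K"))


def run_trend_study(
    sim_cfg: SimulationConfig,
    seeds: tuple = (1,),
    thresholds: tuple = DEFAULT_THRESHOLDS,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """The Figs. 2-3 analysis on synthetic data, for one or more seeds.

    For every seed, generate accepted datasets by accept-reject, run the
    extended Q+K, Q+2K, and REMMA scans, and compute threshold-filtered
    correlations of -log10(p) per dataset and method pair.  Returns
    ``(records, trends)``: per-dataset correlation records and, per
    (seed, method pair, threshold, h2 class incl. pooled "all"), the Pearson
    trend of the per-dataset correlation in log2 of the estimated variance
    ratio with its t-transform p-value and significance stars.
    """
    records = []
    for seed in seeds:
        cfg = dataclasses.replace(sim_cfg, seed=seed)
        datasets = run_accept_reject(cfg)
        gm = datasets[0].genotypes
        ks = build_epistatic_grm(build_additive_grm(gm, scaling="vanraden"))
        G = standardize_kernel(ks.G)
        H = standardize_kernel(ks.H)
        pairs = enumerate_pairs(gm.p)
        for k, ds in enumerate(datasets):
            scans = _scan_dataset(ds, gm, G, H, pairs)
            h2c = str(classify_by_h2([ds.est_h2])[0])
            for a, b in METHOD_PAIRS:
                for d in thresholds:
                    r, n_used = filtered_correlation(scans[a], scans[b], d)
                    records.append({
                        "seed": seed, "dataset": f"s{seed}_d{k}",
                        "method_pair": f"{a}_vs_{b}", "d": d,
                        "true_ratio": ds.true_ratio, "true_h2": ds.true_h2,
                        "est_ratio": ds.est_ratio, "est_h2": ds.est_h2,
                        "est_log2_ratio": float(np.log2(ds.est_ratio)),
                        "h2_class": h2c, "r": r, "n_pairs": n_used,
                    })
    rec = pd.DataFrame(records)
    trends = []
    for (seed, mp, d), grp in rec.groupby(["seed", "method_pair", "d"]):
        for h2c in ("all", "high", "mid", "low"):
            sub = grp if h2c == "all" else grp[grp["h2_class"] == h2c]
            tr = trend_analysis(sub)
            trends.append({
                "seed": seed, "method_pair": mp, "d": d, "h2_class": h2c,
                "trend_r": tr.r, "trend_p": tr.p,
                "stars": significance_stars(tr.p), "n_datasets": tr.n,
            })
    return rec, pd.DataFrame(trends)


def run_simulation_study(cfg: RunConfig, with_scans: bool = True) -> Path:
    """Simulate, scan, compare, and summarize; returns the output directory.

    With ``with_scans=False`` only the accepted datasets (genotype,
    phenotype, metadata TSVs) are written — the ``simulate`` subcommand.
    """
    if cfg.sim is None:
        raise ConfigError("simulation block (sim) is required for the study")
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log = _logger(out, cfg.log_level)
    sim_cfg = dataclasses.replace(cfg.sim, seed=cfg.seed)
    log.info("simulation study: n=%d p=%d grid=%dx%d reps=%d seed=%d",
             sim_cfg.n, sim_cfg.p, len(sim_cfg.ratio_grid),
             len(sim_cfg.h2_grid), sim_cfg.reps_per_cell, cfg.seed)

    stage = "simulate"
    try:
        datasets = run_accept_reject(sim_cfg)
    except RuntimeError as exc:
        raise NumericalError(f"stage {stage}: {exc}") from exc

    gm = datasets[0].genotypes
    ks = build_epistatic_grm(build_additive_grm(gm, scaling="vanraden"))
    G = standardize_kernel(ks.G)
    H = standardize_kernel(ks.H)
    pairs = enumerate_pairs(gm.p)

    records = []
    stage = "scan"
    try:
        for k, ds in enumerate(datasets):
            dset_dir = out / f"dataset_{k:03d}"
            dset_dir.mkdir(exist_ok=True)
            _write_genotype_tsv(gm, dset_dir / "genotypes.tsv")
            pd.DataFrame({"sample": gm.samples, "y": ds.y}).to_csv(
                dset_dir / "phenotypes.tsv", sep="\t", index=False,
                float_format="%.12g")
            meta = pd.DataFrame([{
                "true_ratio": ds.true_ratio, "true_h2": ds.true_h2,
                "est_ratio": ds.est_ratio, "est_h2": ds.est_h2,
                "seed_used": ds.seed_used, "study_seed": cfg.seed,
            }])
            meta.to_csv(dset_dir / "metadata.tsv", sep="\t", index=False,
                        float_format="%.12g")
            if not with_scans:
                log.info("dataset_%03d written (no scans requested)", k)
                continue
            scans = _scan_dataset(ds, gm, G, H, pairs)
            for name, res in scans.items():
                write_scan_results(res, dset_dir / f"scan_{name.lower()}.tsv")
            h2c = str(classify_by_h2([ds.est_h2])[0])
            for a, b in METHOD_PAIRS:
                for d in cfg.thresholds:
                    r, n_used = filtered_correlation(scans[a], scans[b], d)
                    records.append({
                        "dataset": f"dataset_{k:03d}",
                        "method_pair": f"{a}_vs_{b}", "d": d,
                        "true_ratio": ds.true_ratio, "true_h2": ds.true_h2,
                        "est_ratio": ds.est_ratio, "est_h2": ds.est_h2,
                        "est_log2_ratio": float(np.log2(ds.est_ratio)),
                        "h2_class": h2c, "r": r, "n_pairs": n_used,
                    })
            log.info("dataset_%03d: true ratio=%g h2=%g est ratio=%.3g "
                     "h2=%.3g", k, ds.true_ratio, ds.true_h2, ds.est_ratio,
                     ds.est_h2)
    except (np.linalg.LinAlgError, FloatingPointError) as exc:
        raise NumericalError(f"stage {stage}: {exc}") from exc

    if not with_scans:
        return out

    rec = pd.DataFrame(records)
    rec.to_csv(out / "correlations.tsv", sep="\t", index=False,
               float_format="%.12g", na_rep="NA")

    trends = []
    for (mp, d), grp in rec.groupby(["method_pair", "d"]):
        for h2c in ("all", "high", "mid", "low"):
            sub = grp if h2c == "all" else grp[grp["h2_class"] == h2c]
            tr = trend_analysis(sub)
            trends.append({
                "method_pair": mp, "d": d, "h2_class": h2c,
                "trend_r": tr.r, "trend_p": tr.p,
                "stars": significance_stars(tr.p), "n_datasets": tr.n,
            })
    tdf = pd.DataFrame(trends)
    tdf.to_csv(out / "trend_summary.tsv", sep="\t", index=False,
               float_format="%.12g", na_rep="NA")
    log.info("wrote correlations.tsv (%d rows) and trend_summary.tsv "
             "(%d rows)", len(rec), len(tdf))
    return out
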