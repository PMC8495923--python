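"""Genotype, phenotype and scan-result I/O, imputation, and LD pruning.

Genotypes are held as a samples x markers dosage matrix together with an
optional marker map (chromosome, base-pair position).  Missing calls are
NaN until :func:`impute_and_code` replaces them by column means.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

MISSING_TOKENS = ("NA", "nan", "NaN", "-9", "")

__all__ = [
    "GenotypeMatrix",
    "PhenotypeTable",
    "GenotypeFormatError",
    "read_genotype_matrix",
    "read_marker_map",
    "read_phenotype_table",
    "impute_and_code",
    "ld_prune",
    "write_scan_results",
]


class GenotypeFormatError(ValueError):
    """Raised for malformed genotype / map / phenotype files."""


@dataclass
class GenotypeMatrix:
    """n x p marker dosages with sample/marker identifiers and optional map.

    ``codings`` may contain NaN (missing) before imputation.  The map, when
    present, is a DataFrame indexed by marker ID with columns ``chrom`` and
    ``pos`` (1-based base pairs).
    """

    samples: list[str]
    markers: list[str]
    codings: np.ndarray
    map: pd.DataFrame | None = None
    monomorphic: list[str] = field(default_factory=list)
    imputed: bool = False

    def __post_init__(self) -> None:
        self.codings = np.asarray(self.codings, dtype=float)
        n, p = self.codings.shape
        if n < 2:
            raise ValueError(f"need at least 2 samples, got {n}")
        if p < 1:
            raise ValueError("need at least 1 marker")
        if len(self.samples) != n or len(self.markers) != p:
            raise ValueError("identifier lengths do not match codings shape")
        if len(set(self.markers)) != p:
            raise GenotypeFormatError("duplicate marker IDs")
        if self.map is not None:
            missing = set(self.markers) - set(self.map.index)
            if missing:
                raise GenotypeFormatError(
                    f"markers absent from map: {sorted(missing)[:5]} ..."
                )
            self.map = self.map.loc[self.markers]
            for chrom, sub in self.map.groupby("chrom", sort=False):
                pos = sub["pos"].to_numpy()
                if np.any(np.diff(pos) < 0):
                    raise GenotypeFormatError(
                        f"positions on chromosome {chrom} not non-decreasing"
                    )

    @property
    def n(self) -> int:
        return self.codings.shape[0]

    @property
    def p(self) -> int:
        return self.codings.shape[1]

    def subset_markers(self, marker_ids: list[str]) -> "GenotypeMatrix":
        idx = [self.markers.index(m) for m in marker_ids]
        return GenotypeMatrix(
            samples=list(self.samples),
            markers=list(marker_ids),
            codings=self.codings[:, idx].copy(),
            map=None if self.map is None else self.map.loc[marker_ids].copy(),
            monomorphic=[m for m in self.monomorphic if m in marker_ids],
            imputed=self.imputed,
        )


@dataclass
class PhenotypeTable:
    """Phenotype vector y and fixed-covariate design X (intercept first)."""

    samples: list[str]
    y: np.ndarray
    X: np.ndarray
    covariate_names: list[str] = field(default_factory=lambda: ["intercept"])

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float).ravel()
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        n = self.y.shape[0]
        if self.X.shape[0] != n:
            raise ValueError("y and X have different numbers of rows")
        if self.X.shape[1] < 1:
            raise ValueError("X must include at least the intercept")
        if np.linalg.matrix_rank(self.X) < self.X.shape[1]:
            raise ValueError("fixed-covariate matrix X is rank deficient")

    @property
    def n(self) -> int:
        return self.y.shape[0]

    @property
    def k(self) -> int:
        return self.X.shape[1]


def _parse_cell(tok: str) -> float:
    tok = tok.strip()
    if tok in MISSING_TOKENS:
        return np.nan
    return float(tok)


def read_genotype_matrix(
    path, dialect: str = "tsv", map_path=None
) -> GenotypeMatrix:
    """Read a genotype dosage matrix.

    ``tsv``: tab-separated, header row of marker IDs, first column sample IDs.
    ``plink_raw``: whitespace-separated PLINK ``--recode A`` output; the six
    leading standard columns are ignored except IID (used as sample ID) and
    the ``_ALLELE`` suffix is stripped from marker names.
    """
    if dialect not in ("tsv", "plink_raw"):
        raise ValueError(f"unknown dialect {dialect!r}")
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if not lines:
        raise GenotypeFormatError(f"{path}: empty file")
    sep = "\t" if dialect == "tsv" else None

    header = lines[0].split(sep)
    if dialect == "tsv":
        markers = [h.strip() for h in header[1:]]
        first_data_col = 1
    else:
        std = header[:6]
        if std[:2] != ["FID", "IID"]:
            raise GenotypeFormatError(
                f"{path}: not a PLINK .raw header (expected FID IID ...)"
            )
        markers = [h.rsplit("_", 1)[0] if "_" in h else h for h in header[6:]]
        first_data_col = 6
    if len(set(markers)) != len(markers):
        raise GenotypeFormatError(f"{path}: duplicate marker IDs in header")

    samples, rows = [], []
    expected = first_data_col + len(markers)
    for lineno, ln in enumerate(lines[1:], start=2):
        fields = ln.split(sep)
        if dialect == "tsv" and ln.endswith("\t"):
            fields = ln.split(sep)  # keep trailing empty cell as missing
        if len(fields) != expected:
            raise GenotypeFormatError(
                f"{path}: line {lineno} has {len(fields)} fields, "
                f"expected {expected}"
            )
        sid = fields[1] if dialect == "plink_raw" else fields[0]
        samples.append(sid.strip())
        try:
            rows.append([_parse_cell(t) for t in fields[first_data_col:]])
        except ValueError as exc:
            raise GenotypeFormatError(f"{path}: line {lineno}: {exc}") from exc

    gmap = read_marker_map(map_path) if map_path is not None else None
    return GenotypeMatrix(samples, markers, np.array(rows, dtype=float), map=gmap)


def read_marker_map(path) -> pd.DataFrame:
    """Read a marker map TSV with columns marker, chrom, pos (1-based bp)."""
    df = pd.read_csv(path, sep="\t", dtype={"marker": str, "chrom": str})
    required = {"marker", "chrom", "pos"}
    if not required.issubset(df.columns):
        raise GenotypeFormatError(
            f"{path}: map must have columns {sorted(required)}"
        )
    df["pos"] = df["pos"].astype(np.int64)
    if (df["pos"] < 0).any():
        raise GenotypeFormatError(f"{path}: negative positions in map")
    return df.set_index("marker")[["chrom", "pos"]]


def read_phenotype_table(
    path,
    trait: str,
    covariates: list[str] | None = None,
    genotypes: GenotypeMatrix | None = None,
    sample_col: str | None = None,
) -> PhenotypeTable:
    """Read phenotypes and build the fixed-effect design [1 | covariates].

    Numeric covariates enter as-is; categorical covariates are expanded to
    treatment-coded dummies (first level dropped).  When a genotype matrix is
    supplied, samples are reordered to match it; phenotyped samples with no
    genotype are dropped with a warning.
    """
    covariates = list(covariates or [])
    df = pd.read_csv(path, sep="\t", dtype="object")
    if sample_col is None:
        sample_col = df.columns[0]
    df[sample_col] = df[sample_col].astype(str).str.strip()
    df = df.set_index(sample_col)

    if trait not in df.columns:
        raise GenotypeFormatError(f"{path}: trait column {trait!r} not found")
    try:
        y = df[trait].astype(float)
    except ValueError as exc:
        raise GenotypeFormatError(
            f"{path}: trait column {trait!r} is not numeric: {exc}"
        ) from exc
    keep = y.notna()
    df, y = df[keep], y[keep]

    if genotypes is not None:
        geno_ids = list(genotypes.samples)
        extra = [s for s in df.index if s not in set(geno_ids)]
        if extra:
            warnings.warn(
                f"{len(extra)} phenotyped sample(s) absent from genotypes; dropped",
                stacklevel=2,
            )
        order = [s for s in geno_ids if s in set(df.index)]
        if not order:
            raise GenotypeFormatError(
                "no overlap between phenotype and genotype samples"
            )
        df, y = df.loc[order], y.loc[order]

    cols = [np.ones(len(df))]
    names = ["intercept"]
    for cov in covariates:
        if cov not in df.columns:
            raise GenotypeFormatError(f"{path}: covariate {cov!r} not found")
        col = df[cov]
        try:
            cols.append(col.astype(float).to_numpy())
            names.append(cov)
        except ValueError:
            dummies = pd.get_dummies(col, prefix=cov, drop_first=True)
            for name in dummies.columns:
                cols.append(dummies[name].to_numpy(dtype=float))
                names.append(name)
    X = np.column_stack(cols)
    return PhenotypeTable(list(df.index), y.to_numpy(), X, names)


def impute_and_code(gm: GenotypeMatrix, center: bool = False) -> GenotypeMatrix:
    """Replace missing dosages by column means; optionally mean-center columns.

    Constant (monomorphic) columns are retained and listed in ``monomorphic``.
    Idempotent: a second application is a no-op (up to centering already done).
    """
    M = gm.codings.copy()
    all_missing = np.all(np.isnan(M), axis=0)
    if all_missing.any():
        bad = [gm.markers[j] for j in np.flatnonzero(all_missing)]
        raise ValueError(f"all-missing marker column(s): {bad}")
    col_mean = np.nanmean(M, axis=0)
    nan_r, nan_c = np.nonzero(np.isnan(M))
    M[nan_r, nan_c] = col_mean[nan_c]
    mono = [gm.markers[j] for j in np.flatnonzero(np.ptp(M, axis=0) == 0)]
    if center:
        M = M - M.mean(axis=0)
    return replace(
        gm, codings=M, monomorphic=mono, imputed=True,
        map=None if gm.map is None else gm.map.copy(),
    )


def _minor_allele_freq(col: np.ndarray) -> float:
    # dosage coding on [0, 2]: allele frequency = mean/2
    af = float(np.mean(col)) / 2.0
    return min(af, 1.0 - af)


def ld_prune(
    gm: GenotypeMatrix,
    r2_threshold: float = 0.2,
    window: int = 1_000_000,
    step: int = 10_000,
) -> list[str]:
    """Greedy LD pruning within sliding windows; returns surviving marker IDs.

    Within each half-open window [start, start+window) on a chromosome, while
    any retained pair of markers has squared Pearson correlation above the
    threshold, the pair with the largest r-squared is found (ties: first in
    lexicographic column order) and the member with lower minor-allele
    frequency is removed (ties: the later column).  The window then advances
    by ``step``.  Survivors are returned in map order.
    """
    if gm.map is None:
        raise ValueError("ld_prune requires a marker map")
    if not 0.0 < r2_threshold <= 1.0:
        raise ValueError("r2_threshold must be in (0, 1]")
    if window < step:
        warnings.warn("window smaller than step: some pairs never co-windowed",
                      stacklevel=2)
    M = gm.codings
    if np.isnan(M).any():
        raise ValueError("impute genotypes before LD pruning")

    keep = np.ones(gm.p, dtype=bool)
    maf = np.array([_minor_allele_freq(M[:, j]) for j in range(gm.p)])
    chroms = gm.map["chrom"].to_numpy()
    pos = gm.map["pos"].to_numpy()

    for chrom in pd.unique(chroms):
        on_chr = np.flatnonzero(chroms == chrom)
        cpos = pos[on_chr]
        start = int(cpos.min())
        last = int(cpos.max())
        while start <= last:
            in_win = on_chr[(cpos >= start) & (cpos < start + window)]
            idx = [j for j in in_win if keep[j]]
            if len(idx) >= 2:
                sub = M[:, idx]
                sd = sub.std(axis=0)
                ok = sd > 0
                with np.errstate(invalid="ignore"):
                    r2 = np.corrcoef(sub, rowvar=False) ** 2
                r2[~ok, :] = 0.0
                r2[:, ~ok] = 0.0
                np.fill_diagonal(r2, 0.0)
                alive = np.ones(len(idx), dtype=bool)
                while True:
                    masked = np.where(
                        np.outer(alive, alive), r2, 0.0
                    )
                    a, b = np.unravel_index(np.argmax(masked), masked.shape)
                    if masked[a, b] <= r2_threshold:
                        break
                    a, b = min(a, b), max(a, b)
                    ja, jb = idx[a], idx[b]
                    if maf[ja] < maf[jb]:
                        drop = a
                    elif maf[jb] < maf[ja]:
                        drop = b
                    else:
                        drop = b  # tie: remove the larger column index
                    alive[drop] = False
                    keep[idx[drop]] = False
            start += step
    return [gm.markers[j] for j in np.flatnonzero(keep)]


def write_scan_results(res, path) -> None:
    """Write a ScanResult to TSV (adds a neglog10p column; NA for skips)."""
    df = res.to_frame()
    with np.errstate(divide="ignore"):
        df["neglog10p"] = -np.log10(np.clip(df["p"], 1e-300, None))
    df.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.12g")


def read_scan_results(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=["NA"], dtype={"marker": str})
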