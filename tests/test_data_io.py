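"""data_io: parsing, imputation, LD pruning, and result round-trips."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gblupgwas import (
    GenotypeMatrix,
    PhenotypeTable,
    impute_and_code,
    ld_prune,
    read_genotype_matrix,
    read_phenotype_table,
    read_scan_results,
    write_scan_results,
)
from gblupgwas.data_io import GenotypeFormatError
from gblupgwas.gwas_additive import ScanResult


def _write(path, text):
    path.write_text(text)
    return str(path)


# -- read_genotype_matrix ----------------------------------------------------

def test_read_tsv_basic(tmp_path):
    p = _write(tmp_path / "g.tsv",
               "sample\tm1\tm2\ns1\t0\t1\ns2\t1\t2\ns3\t2\t0\n")
    gm = read_genotype_matrix(p)
    assert gm.n == 3 and gm.p == 2
    assert gm.markers == ["m1", "m2"]
    assert gm.codings[2, 0] == 2.0


def test_read_tsv_missing_token(tmp_path):
    p = _write(tmp_path / "g.tsv",
               "sample\tm1\tm2\ns1\tNA\t1\ns2\t1\t2\n")
    gm = read_genotype_matrix(p)
    assert np.isnan(gm.codings[0, 0])
    assert gm.codings[0, 1] == 1.0


def test_read_tsv_ragged_row_names_line(tmp_path):
    p = _write(tmp_path / "g.tsv",
               "sample\tm1\tm2\ns1\t0\t1\ns2\t1\t2\t9\n")
    with pytest.raises(GenotypeFormatError, match="line 3"):
        read_genotype_matrix(p)


def test_read_tsv_duplicate_markers(tmp_path):
    p = _write(tmp_path / "g.tsv",
               "sample\tm1\tm1\ns1\t0\t1\ns2\t1\t2\n")
    with pytest.raises(GenotypeFormatError, match="duplicate"):
        read_genotype_matrix(p)


def test_read_plink_raw(tmp_path):
    p = _write(
        tmp_path / "g.raw",
        "FID IID PAT MAT SEX PHENOTYPE m1_A m2_C\n"
        "f1 s1 0 0 1 -9 0 2\n"
        "f2 s2 0 0 1 -9 1 NA\n",
    )
    gm = read_genotype_matrix(p, dialect="plink_raw")
    assert gm.samples == ["s1", "s2"]
    assert gm.p == 2
    assert np.isnan(gm.codings[1, 1])


# -- read_phenotype_table ----------------------------------------------------

def test_read_phenotypes_basic(tmp_path):
    p = _write(tmp_path / "p.tsv",
               "sample\ty\ns1\t1.5\ns2\t-0.5\ns3\t2.0\n")
    ph = read_phenotype_table(p, "y")
    assert ph.n == 3 and ph.k == 1
    np.testing.assert_allclose(ph.X, np.ones((3, 1)))


def test_read_phenotypes_categorical_covariate(tmp_path):
    p = _write(tmp_path / "p.tsv",
               "sample\ty\tblock\ns1\t1\ta\ns2\t2\tb\ns3\t3\ta\n")
    ph = read_phenotype_table(p, "y", covariates=["block"])
    assert ph.k == 2  # intercept + one dummy for 2 levels


def test_read_phenotypes_text_trait_error(tmp_path):
    p = _write(tmp_path / "p.tsv",
               "sample\ty\ns1\thigh\ns2\tlow\ns3\tmid\n")
    with pytest.raises(ValueError):
        read_phenotype_table(p, "y")


def test_read_phenotypes_sample_alignment(tmp_path):
    geno = _write(tmp_path / "g.tsv",
                  "sample\tm1\ns1\t0\ns2\t1\ns3\t2\n")
    gm = read_genotype_matrix(geno)
    p = _write(tmp_path / "p.tsv",
               "sample\ty\ns3\t3\ns1\t1\nsX\t9\n")
    with pytest.warns(UserWarning, match="dropped"):
        ph = read_phenotype_table(p, "y", genotypes=gm)
    # reordered to genotype order; sX dropped
    assert ph.samples == ["s1", "s3"]
    np.testing.assert_allclose(ph.y, [1.0, 3.0])


def test_read_phenotypes_zero_overlap(tmp_path):
    geno = _write(tmp_path / "g.tsv", "sample\tm1\ns1\t0\ns2\t1\n")
    gm = read_genotype_matrix(geno)
    p = _write(tmp_path / "p.tsv", "sample\ty\nsA\t1\nsB\t2\n")
    with pytest.raises(ValueError, match="overlap"):
        read_phenotype_table(p, "y", genotypes=gm)


# -- impute_and_code ---------------------------------------------------------

def _gm(M, markers=None):
    n, p = np.asarray(M).shape
    return GenotypeMatrix(samples=[f"s{i}" for i in range(n)],
                          markers=markers or [f"m{j}" for j in range(p)],
                          codings=np.asarray(M, dtype=float))


def test_impute_column_mean():
    gm = impute_and_code(_gm([[0, 1], [2, 1], [np.nan, 1]]))
    assert gm.codings[2, 0] == 1.0  # mean of (0, 2)


def test_impute_center():
    gm = impute_and_code(_gm([[0, 0], [1, 0], [2, 0]]), center=True)
    np.testing.assert_allclose(gm.codings[:, 0], [-1, 0, 1])


def test_impute_monomorphic_flagged():
    gm = impute_and_code(_gm([[2, 0], [2, 1], [2, 2]]))
    assert gm.monomorphic == ["m0"]


def test_impute_all_missing_error():
    with pytest.raises(ValueError, match="m1"):
        impute_and_code(_gm([[0, np.nan], [1, np.nan]]))


def test_impute_idempotent():
    rng = np.random.default_rng(3)
    M = rng.integers(0, 3, (10, 4)).astype(float)
    M[rng.random((10, 4)) < 0.2] = np.nan
    once = impute_and_code(_gm(M))
    twice = impute_and_code(once)
    np.testing.assert_array_equal(once.codings, twice.codings)


# -- ld_prune ----------------------------------------------------------------

def _gm_with_map(M, pos, chrom="1"):
    n, p = np.asarray(M).shape
    markers = [f"m{j}" for j in range(p)]
    gmap = pd.DataFrame({"chrom": chrom, "pos": pos},
                        index=pd.Index(markers, name="marker"))
    return GenotypeMatrix(samples=[f"s{i}" for i in range(n)],
                          markers=markers, codings=np.asarray(M, float),
                          map=gmap, imputed=True)


def test_prune_duplicated_column():
    rng = np.random.default_rng(0)
    col = rng.integers(0, 3, 20).astype(float)
    gm = _gm_with_map(np.column_stack([col, col]), [1000, 2000])
    kept = ld_prune(gm, r2_threshold=0.2)
    assert len(kept) == 1


def test_prune_orthogonal_columns_survive():
    M = np.array([[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1.0]])
    # columns mutually uncorrelated
    C = np.corrcoef(M.T)
    assert np.allclose(C - np.eye(3), 0, atol=1e-12)
    gm = _gm_with_map(M, [1000, 2000, 3000])
    kept = ld_prune(gm, r2_threshold=0.2)
    assert kept == ["m0", "m1", "m2"]


def _brute_force_greedy(M, maf, thr):
    """Oracle: repeatedly drop the lower-MAF member of the max-r2 pair."""
    alive = list(range(M.shape[1]))
    while True:
        best = None
        for a in range(len(alive)):
            for b in range(a + 1, len(alive)):
                i, j = alive[a], alive[b]
                r2 = np.corrcoef(M[:, i], M[:, j])[0, 1] ** 2
                if r2 > thr and (best is None or r2 > best[0]):
                    best = (r2, i, j)
        if best is None:
            return alive
        _, i, j = best
        if maf[i] < maf[j] or (maf[i] == maf[j] and i > j):
            alive.remove(i)
        else:
            alive.remove(j)


def test_prune_matches_brute_force_oracle():
    rng = np.random.default_rng(7)
    base = rng.integers(0, 3, 40).astype(float)
    M = np.column_stack([
        base,
        base + (rng.random(40) < 0.2),
        rng.integers(0, 3, 40),
        base * -1 + 2,
        rng.integers(0, 3, 40),
    ])
    # all markers inside a single window
    gm = _gm_with_map(M, [1000, 2000, 3000, 4000, 5000])
    from gblupgwas.data_io import _minor_allele_freq
    maf = [_minor_allele_freq(M[:, j]) for j in range(5)]
    expect = _brute_force_greedy(M, maf, 0.2)
    kept = ld_prune(gm, r2_threshold=0.2)
    assert kept == [f"m{j}" for j in expect]


def test_prune_invariant_to_sample_order():
    rng = np.random.default_rng(12)
    M = rng.integers(0, 3, (30, 6)).astype(float)
    pos = (np.arange(6) + 1) * 1000
    gm = _gm_with_map(M, pos)
    kept = ld_prune(gm, r2_threshold=0.3)
    perm = rng.permutation(30)
    gm2 = _gm_with_map(M[perm], pos)
    assert ld_prune(gm2, r2_threshold=0.3) == kept


def test_prune_requires_map():
    gm = _gm([[0, 1], [1, 0], [2, 2]])
    with pytest.raises(ValueError, match="map"):
        ld_prune(gm)


# -- scan result round trip --------------------------------------------------

def _toy_result():
    return ScanResult(method="QK_P3D", table=pd.DataFrame({
        "marker": ["m1", "m2", "m3"],
        "estimate": [0.123456789012345, -1.0, np.nan],
        "variance": [0.5, 0.25, np.nan],
        "statistic": [1.23456789, -2.0, np.nan],
        "df": [10, 10, 10],
        "p": [0.2467, 1.0, np.nan],
        "reason": [None, None, "untestable"],
    }))


def test_write_scan_results_columns_and_na(tmp_path):
    res = _toy_result()
    path = tmp_path / "res.tsv"
    write_scan_results(res, path)
    lines = path.read_text().strip().split("\n")
    header = lines[0].split("\t")
    assert header[:7] == ["marker", "estimate", "variance", "statistic",
                          "df", "p", "reason"]
    assert "neglog10p" in header
    assert len(lines) == 4          # header + 3 rows (NA row retained)
    assert "NA" in lines[3]


def test_p_equal_one_gives_zero_neglog10(tmp_path):
    res = _toy_result()
    path = tmp_path / "res.tsv"
    write_scan_results(res, path)
    df = read_scan_results(path)
    assert df.loc[1, "neglog10p"] == 0.0


def test_round_trip_12_significant_digits(tmp_path):
    res = _toy_result()
    path = tmp_path / "res.tsv"
    write_scan_results(res, path)
    df = read_scan_results(path)
    # %.12g keeps 12 significant digits
    np.testing.assert_allclose(df["estimate"][0],
                               0.123456789012345, rtol=1e-10)
    np.testing.assert_allclose(df["statistic"][0], 1.23456789, rtol=1e-10)


# -- properties --------------------------------------------------------------

@settings(max_examples=25, deadline=None)
@given(st.integers(0, 2**31 - 1))
def test_impute_idempotent_property(seed):
    rng = np.random.default_rng(seed)
    M = rng.integers(0, 3, (6, 3)).astype(float)
    M[rng.random((6, 3)) < 0.3] = np.nan
    if np.all(np.isnan(M), axis=0).any():
        return
    once = impute_and_code(_gm(M))
    twice = impute_and_code(once)
    np.testing.assert_array_equal(once.codings, twice.codings)


def test_phenotype_requires_full_rank():
    n = 5
    X = np.column_stack([np.ones(n), np.ones(n)])
    with pytest.raises(ValueError, match="rank"):
        PhenotypeTable([f"s{i}" for i in range(n)], np.zeros(n), X)
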