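"""Model-comparison analysis: threshold-filtered correlations and trends.

For two epistasis scans over the same marker pairs, similarity is the Pearson
correlation of -log10(p) over the pairs whose -log10(p) exceeds a threshold d
in at least one of the two scans.  Per-dataset similarities are then
stratified by estimated heritability class (h2 >= 0.7, 0.4 <= h2 < 0.7,
h2 < 0.4) and regressed (Pearson, with the t-transform p-value) against
log2 of the estimated additive-to-epistatic variance ratio, giving the trend
of model similarity in the relative additive contribution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .gwas_additive import ScanResult

__all__ = [
    "filtered_correlation",
    "classify_by_h2",
    "trend_analysis",
    "TrendResult",
    "significance_stars",
]

#: minimum marker pairs required for a non-NA correlation
MIN_PAIRS = 10

H2_CLASSES = ("high", "mid", "low")


def _pair_keys(res: ScanResult) -> pd.Index:
    t = res.table
    if "marker1" in t.columns:
        return pd.Index(zip(t["marker1"], t["marker2"]))
    return pd.Index(t["marker"] if "marker" in t.columns else t.index)


def filtered_correlation(
    resA: ScanResult, resB: ScanResult, d: float, min_pairs: int = MIN_PAIRS
) -> tuple[float, int]:
    """Pearson r of -log10(p) over pairs exceeding d in at least one scan.

    Pairs with NA p in either scan are excluded listwise.  Returns
    (r, n_pairs_used); r is NaN when fewer than ``min_pairs`` pairs qualify.
    """
    keysA, keysB = _pair_keys(resA), _pair_keys(resB)
    if len(keysA) != len(keysB) or not keysA.equals(keysB):
        raise ValueError("scan results have different pair keys")
    nlpA, nlpB = resA.neglog10p(), resB.neglog10p()
    ok = np.isfinite(nlpA) & np.isfinite(nlpB)
    include = ok & (np.maximum(nlpA, nlpB) > d)
    n_used = int(include.sum())
    if n_used < min_pairs:
        return np.nan, n_used
    a, b = nlpA[include], nlpB[include]
    if np.std(a) == 0 or np.std(b) == 0:
        return np.nan, n_used
    return float(np.corrcoef(a, b)[0, 1]), n_used


def classify_by_h2(est_h2) -> np.ndarray:
    """Heritability classes: 'high' h2>=0.7, 'mid' 0.4<=h2<0.7, 'low' h2<0.4."""
    h2 = np.asarray(est_h2, dtype=float)
    out = np.where(h2 >= 0.7, "high", np.where(h2 >= 0.4, "mid", "low"))
    return out


@dataclass
class TrendResult:
    r: float
    p: float
    stars: str
    n: int
    h2_class: str


def significance_stars(p: float) -> str:
    """Significance key: * P<0.1, ** P<0.05, *** P<0.01."""
    if not np.isfinite(p):
        return ""
    if p < 0.01:
        return "***"
    if p < 0.05:
        return "**"
    if p < 0.1:
        return "*"
    return ""


def trend_analysis(records: pd.DataFrame, h2_class: str | None = None) -> TrendResult:
    """Pearson trend of per-dataset similarity against log2(est_ratio).

    ``records`` needs columns ``r`` (per-dataset correlation of -log10(p))
    and ``est_log2_ratio``; optionally ``h2_class`` to filter one class.
    The p-value comes from the exact t transform of the Pearson correlation.
    """
    df = records
    if h2_class is not None:
        if "h2_class" not in df.columns:
            raise ValueError("records lack an h2_class column")
        df = df[df["h2_class"] == h2_class]
    df = df.dropna(subset=["r", "est_log2_ratio"])
    n = len(df)
    if n < 3:
        return TrendResult(np.nan, np.nan, "", n, h2_class or "all")
    x = df["est_log2_ratio"].to_numpy(dtype=float)
    y = df["r"].to_numpy(dtype=float)
    if np.std(x) == 0 or np.std(y) == 0:
        return TrendResult(np.nan, np.nan, "", n, h2_class or "all")
    r, p = stats.pearsonr(x, y)
    return TrendResult(float(r), float(p), significance_stars(p), n,
                       h2_class or "all")
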