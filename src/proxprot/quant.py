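"""Normalization and two-group differential abundance testing.

Raw intensities are normalized to total intensity within each sample and
log2-transformed with a pseudocount of 1:

    a_i = log2( X_i / sum_n(X_n) * 1e6 + 1 )

so that a non-detection (X_i = 0) maps to abundance 0 and each sample's
normalized linear-scale abundances sum to 1e6. Differential abundance is
Welch's unequal-variance t-test per protein with Benjamini-Hochberg
control of the false discovery rate across all proteins of a comparison.

Non-detections enter the t-test as 0 log-abundance; no imputation is done.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import IntensityMatrix

#: parts-per-million scale of the total-intensity normalization
NORM_SCALE = 1e6


def normalize_log2(m: IntensityMatrix) -> pd.DataFrame:
    """Total-intensity normalize and log2-transform an intensity matrix.

    Returns a proteins x samples DataFrame of log2 abundances. Each sample
    column is scaled so its linear normalized abundances sum to ``1e6``;
    a raw intensity of 0 maps to log2 abundance 0.

    Raises
    ------
    ValueError
        If any sample column is entirely zero (total intensity 0).
    """
    totals = m.values.sum(axis=0)
    zero = totals[totals <= 0]
    if len(zero) > 0:
        raise ValueError(
            f"sample(s) with zero total intensity: {list(zero.index)}"
        )
    return np.log2(m.values / totals * NORM_SCALE + 1.0)


def welch_test(a: np.ndarray, b: np.ndarray) -> tuple[float, float, float]:
    """Welch's unequal-variance t-test, two-sided.

    Returns ``(t, df, p)`` with Welch-Satterthwaite degrees of freedom.
    Degenerate inputs (both groups zero variance) return t=0, p=1 when the
    means are equal and p=0 (with a warning) when they differ; the t
    distribution is undefined there and these are the documented
    conventions.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs >=2 observations")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0.0 and vb == 0.0:
        if a.mean() == b.mean():
            return 0.0, float(a.size + b.size - 2), 1.0
        warnings.warn(
            "zero variance in both groups with unequal means; p set to 0",
            RuntimeWarning,
            stacklevel=2,
        )
        return np.inf if a.mean() > b.mean() else -np.inf, float(
            a.size + b.size - 2
        ), 0.0
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def differential(
    log_abund: pd.DataFrame,
    group_a: list[str],
    group_b: list[str],
) -> pd.DataFrame:
    """Per-protein Welch test of group_a vs group_b with BH correction.

    Parameters
    ----------
    log_abund : DataFrame
        proteins x samples log2 abundances (from :func:`normalize_log2`).
    group_a, group_b : list of sample ids
        Disjoint groups, each with at least two samples.

    Returns
    -------
    DataFrame indexed by protein with columns mean_a, mean_b, log2fc
    (mean_a - mean_b), t_stat, df, p, q, n_a, n_b. BH is applied across
    all proteins of the matrix.
    """
    ga, gb = list(group_a), list(group_b)
    if set(ga) & set(gb):
        raise ValueError("groups overlap")
    if len(ga) < 2 or len(gb) < 2:
        raise ValueError("each group needs >=2 samples")
    missing = [s for s in ga + gb if s not in log_abund.columns]
    if missing:
        raise ValueError(f"sample ids not in matrix: {missing}")

    A = log_abund[ga].to_numpy(dtype=float)
    B = log_abund[gb].to_numpy(dtype=float)
    mean_a = A.mean(axis=1)
    mean_b = B.mean(axis=1)
    va = A.var(axis=1, ddof=1)
    vb = B.var(axis=1, ddof=1)

    with np.errstate(divide="ignore", invalid="ignore"):
        res = stats.ttest_ind(A, B, axis=1, equal_var=False)
        t = np.array(res.statistic, dtype=float)
        df = np.array(res.df, dtype=float)
        p = np.array(res.pvalue, dtype=float)

    # degenerate rows: zero variance in both groups -> documented convention
    degen = (va == 0) & (vb == 0)
    eq = degen & (mean_a == mean_b)
    ne = degen & (mean_a != mean_b)
    t[eq], p[eq], df[eq] = 0.0, 1.0, len(ga) + len(gb) - 2
    if ne.any():
        warnings.warn(
            f"{int(ne.sum())} protein(s) with zero variance and unequal "
            "means; p set to 0",
            RuntimeWarning,
            stacklevel=2,
        )
        t[ne] = np.where(mean_a[ne] > mean_b[ne], np.inf, -np.inf)
        p[ne], df[ne] = 0.0, len(ga) + len(gb) - 2

    out = pd.DataFrame(
        {
            "mean_a": mean_a,
            "mean_b": mean_b,
            "log2fc": mean_a - mean_b,
            "t_stat": t,
            "df": df,
            "p": p,
            "q": bh_adjust(p),
            "n_a": len(ga),
            "n_b": len(gb),
        },
        index=log_abund.index,
    )
    return out


def count_enriched(
    de: pd.DataFrame, q_max: float = 0.05, direction: str = "up"
) -> int:
    """Number of proteins passing the FDR cut in the given direction.

    direction "up" requires log2fc > 0, "down" log2fc < 0, "any" ignores
    the sign.
    """
    sig = de["q"] < q_max
    if direction == "up":
        sig &= de["log2fc"] > 0
    elif direction == "down":
        sig &= de["log2fc"] < 0
    elif direction != "any":
        raise ValueError(f"unknown direction {direction!r}")
    return int(sig.sum())
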