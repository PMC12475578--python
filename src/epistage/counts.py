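"""Negative-binomial differential testing for peak (DAR) and gene (DEG)
count matrices: median-of-ratios normalization, moment dispersion with
trend shrinkage, Wald tests and Benjamini-Hochberg adjustment.

One engine serves both modalities; only the significance thresholds differ:
differentially accessible regions use |log2FC| > 2 with raw p < 0.001,
differentially expressed genes use |log2FC| > 0.58 with BH-adjusted
p < 0.05 (both strict inequalities).
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .tabular import CountMatrix

__all__ = [
    "size_factors",
    "nb_test",
    "bh_adjust",
    "call_differential",
    "call_dars",
    "call_degs",
    "DAR_LFC", "DAR_P", "DEG_LFC", "DEG_Q",
]

DAR_LFC, DAR_P = 2.0, 1e-3
DEG_LFC, DEG_Q = 0.58, 0.05

_PSEUDOCOUNT = 0.5
_DISP_FLOOR = 1e-8


def _as_frame(counts) -> pd.DataFrame:
    return counts.counts if isinstance(counts, CountMatrix) else counts


def size_factors(counts) -> pd.Series:
    """Median-of-ratios per-sample size factors, geometric mean 1.

    Ratios are taken to the per-feature geometric mean over features nonzero
    in every sample.  With no universally nonzero feature, falls back to
    total-count ratios (with a warning).
    """
    df = _as_frame(counts)
    arr = df.to_numpy(dtype=float)
    if (arr.sum(axis=0) <= 0).any():
        raise ValueError("every sample needs at least one nonzero count")
    allpos = (arr > 0).all(axis=1)
    if allpos.any():
        sub = arr[allpos]
        ref = np.exp(np.log(sub).mean(axis=1, keepdims=True))  # geometric mean
        fac = np.median(sub / ref, axis=0)
    else:
        warnings.warn("no feature nonzero in all samples; using total-count ratios")
        fac = arr.sum(axis=0)
    fac = fac / np.exp(np.mean(np.log(fac)))
    return pd.Series(fac, index=df.columns, name="size_factor")


def _dispersion(norm: np.ndarray, case_idx, ctl_idx) -> np.ndarray:
    """Per-feature NB dispersion: within-group method-of-moments estimate,
    shrunk 50/50 toward a log-linear mean-dispersion trend; floor 1e-8."""
    n1, n2 = len(case_idx), len(ctl_idx)
    mu1 = norm[:, case_idx].mean(axis=1)
    mu2 = norm[:, ctl_idx].mean(axis=1)
    v1 = norm[:, case_idx].var(axis=1, ddof=1)
    v2 = norm[:, ctl_idx].var(axis=1, ddof=1)
    pooled_var = ((n1 - 1) * v1 + (n2 - 1) * v2) / max(n1 + n2 - 2, 1)
    m = (n1 * mu1 + n2 * mu2) / (n1 + n2)
    with np.errstate(invalid="ignore", divide="ignore"):
        alpha_mom = (pooled_var - m) / np.maximum(m, 1e-300) ** 2
    alpha_mom = np.where(np.isfinite(alpha_mom), alpha_mom, 0.0)
    usable = (alpha_mom > 0) & (m > 0)
    if usable.sum() >= 10:
        x = np.log(m[usable])
        y = np.log(alpha_mom[usable])
        slope, intercept = np.polyfit(x, y, 1)
        with np.errstate(invalid="ignore", divide="ignore"):
            trend = np.exp(intercept + slope * np.log(np.maximum(m, 1e-300)))
        trend = np.where(m > 0, trend, _DISP_FLOOR)
    elif usable.any():
        trend = np.full(norm.shape[0], float(np.mean(alpha_mom[usable])))
    else:
        trend = np.full(norm.shape[0], _DISP_FLOOR)
    alpha = 0.5 * np.maximum(alpha_mom, 0.0) + 0.5 * trend
    return np.maximum(alpha, _DISP_FLOOR)


def nb_test(counts, case_samples: Sequence[str],
            ctl_samples: Sequence[str]) -> pd.DataFrame:
    """Per-feature NB Wald test of case vs control.

    Counts are normalized by median-of-ratios size factors; the log2 fold
    change of normalized group means uses a 0.5 pseudocount; the Wald
    statistic uses the NB variance mu + alpha*mu^2 with the trend-shrunk
    moment dispersion and a Student-t reference with n1+n2-2 degrees of
    freedom.  Deterministic.  Features at zero in every sample are flagged
    (p = 1, log2fc = 0).

    Returns a DataFrame indexed by feature with columns log2fc, p_value,
    q_value, direction, mean_case, mean_ctl, dispersion, all_zero.
    """
    df = _as_frame(counts)
    if len(case_samples) < 2 or len(ctl_samples) < 2:
        raise ValueError("need >= 2 samples per group")
    fac = size_factors(df)
    norm = df.to_numpy(dtype=float) / fac.to_numpy()
    col = {s: i for i, s in enumerate(df.columns)}
    ci = np.array([col[s] for s in case_samples])
    ki = np.array([col[s] for s in ctl_samples])
    n1, n2 = len(ci), len(ki)

    mu1 = norm[:, ci].mean(axis=1)
    mu2 = norm[:, ki].mean(axis=1)
    alpha = _dispersion(norm, ci, ki)
    log2fc = np.log2(mu1 + _PSEUDOCOUNT) - np.log2(mu2 + _PSEUDOCOUNT)

    var1 = (mu1 + alpha * mu1**2) / n1
    var2 = (mu2 + alpha * mu2**2) / n2
    se = np.sqrt(var1 / (mu1 + _PSEUDOCOUNT) ** 2 + var2 / (mu2 + _PSEUDOCOUNT) ** 2)
    z = np.log(mu1 + _PSEUDOCOUNT) - np.log(mu2 + _PSEUDOCOUNT)
    with np.errstate(invalid="ignore", divide="ignore"):
        wald = np.where(se > 0, z / np.maximum(se, 1e-300), 0.0)
    p = 2.0 * stats.t.sf(np.abs(wald), df=n1 + n2 - 2)

    all_zero = df.to_numpy().sum(axis=1) == 0
    p = np.where(all_zero, 1.0, p)
    log2fc = np.where(all_zero, 0.0, log2fc)
    q = bh_adjust(p)
    direction = np.where(log2fc > 0, "up", np.where(log2fc < 0, "down", "none"))
    return pd.DataFrame(
        {
            "log2fc": log2fc,
            "p_value": p,
            "q_value": q,
            "direction": direction,
            "mean_case": mu1,
            "mean_ctl": mu2,
            "dispersion": alpha,
            "all_zero": all_zero,
        },
        index=df.index,
    )


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if (p < 0).any() or (p > 1).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def call_differential(results: pd.DataFrame,
                      lfc_threshold: float,
                      p_mode: str,
                      p_threshold: float) -> pd.DataFrame:
    """Select significant features: |log2fc| > lfc_threshold (strict) and
    raw p (``p_mode='raw'``) or BH q (``p_mode='adjusted'``) < p_threshold
    (strict)."""
    if lfc_threshold <= 0 or p_threshold <= 0:
        raise ValueError("thresholds must be positive")
    if p_mode not in ("raw", "adjusted"):
        raise ValueError(f"unknown p_mode {p_mode!r}")
    pcol = "p_value" if p_mode == "raw" else "q_value"
    keep = (results["log2fc"].abs() > lfc_threshold) & (results[pcol] < p_threshold)
    return results.loc[keep]


def call_dars(results: pd.DataFrame) -> pd.DataFrame:
    """Differentially accessible regions: |log2FC| > 2, raw p < 0.001."""
    return call_differential(results, DAR_LFC, "raw", DAR_P)


def call_degs(results: pd.DataFrame) -> pd.DataFrame:
    """Differentially expressed genes: |log2FC| > 0.58, adjusted p < 0.05."""
    return call_differential(results, DEG_LFC, "adjusted", DEG_Q)
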