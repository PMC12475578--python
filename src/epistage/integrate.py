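"""Methylation-accessibility integration: peak-level Kendall correlation,
within-sample sampled correlations, the srDMR-srDAR panel with its three
per-sample metrics, and TF-gene co-expression calls.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .counts import size_factors
from .intervals import intersect_intervals, GenomicInterval
from .methylation import region_methylation
from .tabular import CountMatrix, MethylationMatrix

__all__ = [
    "kendall_tau",
    "pearson_r",
    "classify_peak_correlations",
    "sample_level_correlation",
    "Panel",
    "build_panel",
    "metric_correlations",
    "coexpression",
]


def kendall_tau(x, y) -> tuple[float, float]:
    """Kendall tau-b with tie correction and its two-sided p-value.

    Exact p by enumeration for n <= 8 without ties, otherwise the normal
    approximation.  A constant vector makes tau undefined: returns
    (nan, nan).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length vectors")
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    if np.unique(x).size < 2 or np.unique(y).size < 2:
        return (float("nan"), float("nan"))
    ties = np.unique(x).size < len(x) or np.unique(y).size < len(y)
    method = "exact" if (len(x) <= 8 and not ties) else "asymptotic"
    res = stats.kendalltau(x, y, variant="b", method=method)
    return float(res.statistic), float(res.pvalue)


def pearson_r(x, y) -> tuple[float, float]:
    """Pearson r with t-transform p-value; (nan, nan) on degenerate input."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    if np.std(x) == 0 or np.std(y) == 0:
        return (float("nan"), float("nan"))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def _classify(stat: float, p: float, p_threshold: float) -> str:
    if not np.isfinite(stat) or not np.isfinite(p) or p >= p_threshold or stat == 0:
        return "none"
    return "positive" if stat > 0 else "negative"


def classify_peak_correlations(acc: pd.DataFrame, meth_in_peak: pd.DataFrame,
                               p_threshold: float = 0.05) -> pd.DataFrame:
    """Per-peak Kendall correlation between accessibility and methylation
    across samples, classified by sign at p < ``p_threshold``.

    ``acc`` is normalized accessibility (peak x sample) and ``meth_in_peak``
    the methylation level of each peak interval (same shape).  Peaks whose
    methylation is undefined in fewer than 3 samples (e.g. no CpGs) are
    class ``none`` and flagged via ``usable``.
    """
    if list(acc.columns) != list(meth_in_peak.columns) or \
            list(acc.index) != list(meth_in_peak.index):
        raise ValueError("acc and meth_in_peak must share index and columns")
    rows = []
    for peak in acc.index:
        a = acc.loc[peak].to_numpy(dtype=float)
        m = meth_in_peak.loc[peak].to_numpy(dtype=float)
        ok = np.isfinite(a) & np.isfinite(m)
        if ok.sum() < 3:
            rows.append((peak, np.nan, np.nan, "none", False))
            continue
        tau, p = kendall_tau(a[ok], m[ok])
        rows.append((peak, tau, p, _classify(tau, p, p_threshold), True))
    return pd.DataFrame(
        rows, columns=["feature", "tau", "p_value", "cls", "usable"]
    ).set_index("feature")


def sample_level_correlation(acc_vec, meth_vec, n_subsample: int,
                             n_repeats: int, rng) -> tuple[float, float]:
    """Within-one-sample correlation estimated by repeated subsampling.

    Draws ``n_subsample`` peaks without replacement ``n_repeats`` times and
    computes Kendall tau across peaks between the sample's accessibility and
    methylation; returns (mean, SD) over the repeats.
    """
    acc_vec = np.asarray(acc_vec, dtype=float)
    meth_vec = np.asarray(meth_vec, dtype=float)
    ok = np.isfinite(acc_vec) & np.isfinite(meth_vec)
    if ok.sum() < 3:
        raise ValueError("fewer than 3 peaks with defined metrics")
    if n_subsample > ok.sum():
        raise ValueError("n_subsample exceeds usable peaks")
    a, m = acc_vec[ok], meth_vec[ok]
    taus = np.empty(n_repeats)
    for r in range(n_repeats):
        idx = rng.choice(len(a), size=n_subsample, replace=False)
        taus[r], _ = kendall_tau(a[idx], m[idx])
    return float(np.mean(taus)), float(np.std(taus))


@dataclass
class Panel:
    """The srDMR-srDAR intersection panel.

    ``records`` holds one row per overlapping (srDMR, srDAR) pair;
    ``srdmr_meth``/``srdar_meth``/``srdar_acc`` are record x sample metric
    matrices (methylation level of the srDMR, methylation level of the
    srDAR, and log2(size-factor-normalized count + 1) accessibility of the
    srDAR).
    """

    records: pd.DataFrame
    srdmr_meth: pd.DataFrame
    srdar_meth: pd.DataFrame
    srdar_acc: pd.DataFrame

    def __len__(self) -> int:
        return len(self.records)

    def unique_srdars(self) -> pd.DataFrame:
        """Per-srDAR deduplicated view (first overlapping srDMR kept)."""
        return self.records.drop_duplicates(subset="srdar_id", keep="first")


def _df_to_intervals(df: pd.DataFrame) -> list[GenomicInterval]:
    return [GenomicInterval(c, s, e)
            for c, s, e in zip(df["chrom"], df["start"], df["end"])]


def build_panel(srdmrs: pd.DataFrame, srdars: pd.DataFrame,
                meth: MethylationMatrix, acc: CountMatrix) -> Panel:
    """Intersect srDMRs with srDARs and attach the three per-sample metrics.

    ``srdmrs`` needs columns chrom, start, end, category; ``srdars``
    additionally a ``feature`` column naming its row in ``acc``.  One srDAR
    overlapping several srDMRs yields one record per pair (deduplicate with
    :meth:`Panel.unique_srdars`).
    """
    for col in ("chrom", "start", "end", "category"):
        if col not in srdmrs.columns or col not in srdars.columns:
            raise ValueError(f"missing column {col!r}")
    if "feature" not in srdars.columns:
        raise ValueError("srdars needs a 'feature' column keyed to acc rows")
    dmr_iv = _df_to_intervals(srdmrs)
    dar_iv = _df_to_intervals(srdars)
    pairs = intersect_intervals(dmr_iv, dar_iv)
    if not pairs:
        warnings.warn("srDMRs and srDARs do not overlap; empty panel")
        empty = pd.DataFrame(columns=list(acc.samples))
        return Panel(pd.DataFrame(columns=[
            "srdmr_id", "srdmr_category", "srdar_id", "srdar_category",
            "feature"]), empty, empty, empty)

    fac = size_factors(acc)
    norm_acc = np.log2(acc.counts.to_numpy(dtype=float) / fac.to_numpy() + 1.0)
    norm_acc = pd.DataFrame(norm_acc, index=acc.counts.index,
                            columns=acc.counts.columns)
    dmr_lev = region_methylation(meth, dmr_iv)
    dar_lev = region_methylation(meth, dar_iv)

    rec_rows, m_dmr, m_dar, a_dar = [], [], [], []
    for di, ai, _ in pairs:
        dmr_id = f"{dmr_iv[di].chrom}:{dmr_iv[di].start}-{dmr_iv[di].end}"
        dar_id = f"{dar_iv[ai].chrom}:{dar_iv[ai].start}-{dar_iv[ai].end}"
        feature = srdars["feature"].iloc[ai]
        rec_rows.append((dmr_id, srdmrs["category"].iloc[di],
                         dar_id, srdars["category"].iloc[ai], feature))
        m_dmr.append(dmr_lev.iloc[di])
        m_dar.append(dar_lev.iloc[ai])
        a_dar.append(norm_acc.loc[feature])
    records = pd.DataFrame(rec_rows, columns=[
        "srdmr_id", "srdmr_category", "srdar_id", "srdar_category", "feature"])
    idx = pd.RangeIndex(len(records))
    return Panel(
        records,
        pd.DataFrame(np.vstack(m_dmr), index=idx, columns=meth.samples),
        pd.DataFrame(np.vstack(m_dar), index=idx, columns=meth.samples),
        pd.DataFrame(np.vstack(a_dar), index=idx, columns=list(acc.samples)),
    )


_METRIC_PAIRS = (
    ("srdmr_meth", "srdar_meth"),
    ("srdmr_meth", "srdar_acc"),
    ("srdar_meth", "srdar_acc"),
)


def metric_correlations(panel: Panel) -> pd.DataFrame:
    """Per-sample Pearson correlations between the three panel metrics.

    For each sample, r and p are computed across panel records for the
    pairs (srDMR meth, srDAR meth), (srDMR meth, srDAR accessibility) and
    (srDAR meth, srDAR accessibility); degenerate variance yields NaN.
    """
    mats = {"srdmr_meth": panel.srdmr_meth, "srdar_meth": panel.srdar_meth,
            "srdar_acc": panel.srdar_acc}
    samples = list(panel.srdmr_meth.columns)
    out = {}
    for a, b in _METRIC_PAIRS:
        rs, ps = [], []
        for s in samples:
            x = mats[a][s].to_numpy(dtype=float)
            y = mats[b][s].to_numpy(dtype=float)
            ok = np.isfinite(x) & np.isfinite(y)
            if ok.sum() < 3:
                rs.append(np.nan)
                ps.append(np.nan)
                continue
            r, p = pearson_r(x[ok], y[ok])
            rs.append(r)
            ps.append(p)
        out[f"r_{a}_vs_{b}"] = rs
        out[f"p_{a}_vs_{b}"] = ps
    return pd.DataFrame(out, index=samples)


def coexpression(tf_expression: pd.DataFrame, gene_expression: pd.DataFrame,
                 p_threshold: float = 0.05) -> pd.DataFrame:
    """Pearson co-expression calls for every (TF, gene) pair across samples.

    A pair is co-expressed when p < ``p_threshold``; positive class for
    r > 0, negative for r < 0.  Constant expression yields class ``none``.
    """
    if list(tf_expression.columns) != list(gene_expression.columns):
        raise ValueError("TF and gene matrices must share samples")
    if tf_expression.shape[1] < 3:
        raise ValueError("need >= 3 shared samples")
    rows = []
    for tf in tf_expression.index:
        x = tf_expression.loc[tf].to_numpy(dtype=float)
        for gene in gene_expression.index:
            y = gene_expression.loc[gene].to_numpy(dtype=float)
            r, p = pearson_r(x, y)
            rows.append((tf, gene, r, p, _classify(r, p, p_threshold)))
    return pd.DataFrame(rows, columns=["tf", "gene", "r", "p_value", "cls"])
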