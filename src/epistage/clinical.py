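"""Clinical endpoints of the panel: ROC/AUC, random-forest staging
classifiers, sample clustering, and survival stratification by panel
methylation with the log-rank test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import train_test_split

__all__ = [
    "roc_auc",
    "ClassifierReport",
    "train_eval_classifier",
    "SampleClustering",
    "hierarchical_cluster_samples",
    "SurvivalStratification",
    "km_split_logrank",
]


def roc_auc(scores, labels) -> tuple[pd.DataFrame, float]:
    """ROC curve and AUC for binary labels.

    AUC is the Mann-Whitney probability that a random positive outscores a
    random negative, ties credited 1/2 (computed from average ranks).  The
    ROC is a threshold sweep over descending unique scores, starting at
    (0, 0).  Raises on single-class labels.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    if s.shape != y.shape or s.ndim != 1:
        raise ValueError("scores and labels must be equal-length vectors")
    if not np.isin(y, [0, 1]).all():
        raise ValueError("labels must be 0/1")
    n_pos = int(y.sum())
    n_neg = len(y) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    ranks = stats.rankdata(s)
    auc = (ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)
    order = np.argsort(-s, kind="mergesort")
    tp = fp = 0
    pts = [(0.0, 0.0)]
    i = 0
    while i < len(s):
        j = i
        while j < len(s) and s[order[j]] == s[order[i]]:
            tp += int(y[order[j]] == 1)
            fp += int(y[order[j]] == 0)
            j += 1
        pts.append((fp / n_neg, tp / n_pos))
        i = j
    roc = pd.DataFrame(pts, columns=["fpr", "tpr"])
    return roc, float(auc)


@dataclass
class ClassifierReport:
    """Train/test evaluation of a panel-based staging classifier."""

    mode: str
    seed: int
    train_samples: list[str]
    test_samples: list[str]
    auc_train: dict[str, float]
    auc_test: dict[str, float]
    macro_auc_train: float
    macro_auc_test: float
    roc_test: dict[str, pd.DataFrame] = field(repr=False, default_factory=dict)


def _ovr_aucs(model, X, y, classes) -> tuple[dict[str, float], dict[str, pd.DataFrame]]:
    proba = model.predict_proba(X)
    aucs, rocs = {}, {}
    for ci, cls in enumerate(classes):
        roc, auc = roc_auc(proba[:, ci], (y == cls).astype(int))
        aucs[str(cls)] = auc
        rocs[str(cls)] = roc
    return aucs, rocs


def train_eval_classifier(features: pd.DataFrame, labels: pd.Series,
                          mode: str = "binary",
                          split_fraction: float = 0.7,
                          seed: int = 0,
                          n_estimators: int = 500) -> ClassifierReport:
    """Random-forest classification of samples from panel methylation.

    ``features`` is region x sample; ``labels`` maps sample -> class
    (two classes for ``mode='binary'``, the four stages for
    ``mode='multiclass'``).  Samples are split stratified by class into
    train (``split_fraction``) and test; missing feature values are imputed
    with train-set feature means; one-vs-rest AUC is reported per class on
    train and test, with the unweighted macro mean as the summary
    ("average AUC").  Deterministic given (data, seed).
    """
    if mode not in ("binary", "multiclass"):
        raise ValueError(f"unknown mode {mode!r}")
    X = features.T  # samples x regions
    y = labels.loc[X.index]
    counts = y.value_counts()
    if mode == "binary" and len(counts) != 2:
        raise ValueError("binary mode needs exactly two classes")
    if (counts < 4).any():
        raise ValueError("need >= 4 samples per class")
    tr_idx, te_idx = train_test_split(
        np.arange(len(X)), train_size=split_fraction, stratify=y,
        random_state=seed)
    y_tr, y_te = y.iloc[tr_idx], y.iloc[te_idx]
    if set(y_tr) != set(y) or set(y_te) != set(y):
        raise ValueError("a class is absent from train or test after split")
    X_tr = X.iloc[tr_idx].to_numpy(dtype=float)
    X_te = X.iloc[te_idx].to_numpy(dtype=float)
    col_mean = np.nanmean(X_tr, axis=0)
    col_mean = np.where(np.isfinite(col_mean), col_mean, 0.0)
    X_tr = np.where(np.isfinite(X_tr), X_tr, col_mean)
    X_te = np.where(np.isfinite(X_te), X_te, col_mean)

    model = RandomForestClassifier(n_estimators=n_estimators, random_state=seed)
    model.fit(X_tr, y_tr)
    classes = list(model.classes_)
    auc_tr, _ = _ovr_aucs(model, X_tr, y_tr, classes)
    auc_te, roc_te = _ovr_aucs(model, X_te, y_te, classes)
    return ClassifierReport(
        mode=mode, seed=seed,
        train_samples=list(X.index[tr_idx]), test_samples=list(X.index[te_idx]),
        auc_train=auc_tr, auc_test=auc_te,
        macro_auc_train=float(np.mean(list(auc_tr.values()))),
        macro_auc_test=float(np.mean(list(auc_te.values()))),
        roc_test=roc_te,
    )


@dataclass
class SampleClustering:
    samples: list[str]
    linkage: np.ndarray
    labels: pd.Series | None


def hierarchical_cluster_samples(panel_meth: pd.DataFrame,
                                 k: int | None = None) -> SampleClustering:
    """Ward clustering of samples over their region-methylation vectors.

    ``panel_meth`` is region x sample.  Samples with no defined metric at
    all are excluded with a warning; remaining missing values are imputed
    with the feature mean.  Sample order is canonicalized lexicographically
    so permuted input yields the same partition.
    """
    X = panel_meth.T
    all_nan = X.isna().all(axis=1)
    if all_nan.any():
        warnings.warn(f"excluding samples with no metrics: {list(X.index[all_nan])}")
        X = X.loc[~all_nan]
    if len(X) < 2:
        raise ValueError("need >= 2 samples with metrics")
    X = X.loc[sorted(X.index)]
    arr = X.to_numpy(dtype=float)
    col_mean = np.nanmean(arr, axis=0)
    col_mean = np.where(np.isfinite(col_mean), col_mean, 0.0)
    arr = np.where(np.isfinite(arr), arr, col_mean)
    Z = hierarchy.linkage(arr, method="ward")
    labels = None
    if k is not None:
        flat = hierarchy.fcluster(Z, t=k, criterion="maxclust")
        remap: dict[int, int] = {}
        out = []
        for lab in flat:
            if lab not in remap:
                remap[lab] = len(remap) + 1
            out.append(remap[lab])
        labels = pd.Series(out, index=X.index, name="cluster")
    return SampleClustering(list(X.index), Z, labels)


@dataclass
class SurvivalStratification:
    """Two-group survival comparison by panel methylation."""

    rule: str
    threshold: float
    groups: pd.Series              # sample -> "low" / "high"
    n_events: dict[str, int]
    chi_square: float
    p_value: float
    km_curves: dict[str, pd.DataFrame] = field(repr=False, default_factory=dict)


def _km_curve(time: np.ndarray, event: np.ndarray) -> pd.DataFrame:
    """Kaplan-Meier step curve: non-increasing, starts at 1."""
    order = np.argsort(time, kind="mergesort")
    time, event = time[order], event[order]
    rows = [(0.0, 1.0, len(time))]
    surv = 1.0
    for t in np.unique(time[event == 1]):
        at_risk = int((time >= t).sum())
        d = int(((time == t) & (event == 1)).sum())
        surv *= 1.0 - d / at_risk
        rows.append((float(t), surv, at_risk))
    return pd.DataFrame(rows, columns=["time", "survival", "at_risk"])


def logrank_statistic(time1, event1, time2, event2) -> tuple[float, float]:
    """Two-group log-rank chi-square (1 df) from observed-vs-expected sums
    over distinct event times, and its upper-tail p-value."""
    t1, e1 = np.asarray(time1, float), np.asarray(event1, int)
    t2, e2 = np.asarray(time2, float), np.asarray(event2, int)
    event_times = np.unique(np.concatenate([t1[e1 == 1], t2[e2 == 1]]))
    if event_times.size == 0:
        return (float("nan"), float("nan"))
    O1 = E1 = V = 0.0
    for t in event_times:
        n1 = int((t1 >= t).sum())
        n2 = int((t2 >= t).sum())
        d1 = int(((t1 == t) & (e1 == 1)).sum())
        d2 = int(((t2 == t) & (e2 == 1)).sum())
        n, d = n1 + n2, d1 + d2
        if n < 1 or n1 == 0 or n2 == 0:
            continue
        O1 += d1
        E1 += d * n1 / n
        if n > 1:
            V += d * (n1 / n) * (n2 / n) * (n - d) / (n - 1)
    if V == 0:
        return (0.0, 1.0)
    chi2 = (O1 - E1) ** 2 / V
    return float(chi2), float(stats.chi2.sf(chi2, df=1))


def km_split_logrank(score: pd.Series, sheet: pd.DataFrame,
                     quantile: float = 0.5) -> SurvivalStratification:
    """Stratify samples by a methylation score and compare survival.

    ``score`` maps sample -> mean panel methylation; ``sheet`` provides
    survival_time and event per sample_id.  Samples at or below the
    ``quantile`` threshold (default median split) form the low group.
    Emits Kaplan-Meier curves per group and the log-rank chi-square; when
    no events occur anywhere the statistic is flagged undefined (NaN).
    """
    sheet = sheet.set_index("sample_id") if "sample_id" in sheet.columns else sheet
    common = [s for s in score.index if s in sheet.index]
    sc = score.loc[common].astype(float)
    sub = sheet.loc[common]
    thr = float(np.quantile(sc, quantile))
    groups = pd.Series(np.where(sc <= thr, "low", "high"), index=sc.index,
                       name="group")
    if (groups == "low").sum() < 2 or (groups == "high").sum() < 2:
        raise ValueError("need >= 2 samples per survival group")
    tim = sub["survival_time"].to_numpy(dtype=float)
    evt = sub["event"].to_numpy(dtype=int)
    lo = groups.to_numpy() == "low"
    chi2, p = logrank_statistic(tim[lo], evt[lo], tim[~lo], evt[~lo])
    if evt.sum() == 0:
        warnings.warn("no events in either group; log-rank undefined")
    curves = {"low": _km_curve(tim[lo], evt[lo]),
              "high": _km_curve(tim[~lo], evt[~lo])}
    return SurvivalStratification(
        rule=f"quantile={quantile}", threshold=thr, groups=groups,
        n_events={"low": int(evt[lo].sum()), "high": int(evt[~lo].sum())},
        chi_square=chi2, p_value=p, km_curves=curves,
    )
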