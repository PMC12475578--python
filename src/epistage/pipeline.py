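"""End-to-end orchestration: from a cohort's raw matrices to stage-resolved
feature sets, the srDMR-srDAR panel, classifiers and survival stratification.

Thin glue over the per-module operations; every step is available (and
tested) individually.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .clinical import (ClassifierReport, SurvivalStratification,
                       km_split_logrank, train_eval_classifier)
from .cohort import Cohort
from .counts import call_dars, call_degs, nb_test
from .integrate import Panel, build_panel
from .methylation import call_dmcs
from .staging import CASE_STAGES, stage_dmrs, stage_partition, stage_vectors
from .tabular import CountMatrix, MethylationMatrix

__all__ = [
    "stage_resolved_dmcs",
    "stage_resolved_counts",
    "srdmr_table",
    "srdar_table",
    "PipelineResult",
    "run_pipeline",
]


def stage_resolved_dmcs(meth: MethylationMatrix, stages: Mapping[str, str],
                        min_credible_dif: float = 0.20
                        ) -> dict[str, pd.DataFrame]:
    """Call DMCs for each case stage vs control, assign earliest-onset
    categories, and return one coordinate-sorted DMC frame per category."""
    calls = {}
    for stage in CASE_STAGES:
        d = call_dmcs(meth, stages, stage, min_credible_dif=min_credible_dif)
        calls[stage] = {(r.chrom, r.start): r.direction for r in d.itertuples()}
    part = stage_partition(stage_vectors(calls))
    out = {}
    for cat, feats in part.items():
        if cat == "unassigned":
            continue
        rows = sorted(feats)
        out[cat] = pd.DataFrame(
            [(c, s, s + 1, cat.split("-")[0]) for c, s in rows],
            columns=["chrom", "start", "end", "direction"])
    return out


def stage_resolved_counts(counts: CountMatrix, sheet: pd.DataFrame,
                          kind: str) -> dict[str, set]:
    """Stage-onset partition of DARs (``kind='peaks'``) or DEGs
    (``kind='genes'``): NB test per stage vs control, threshold call,
    earliest-onset assignment."""
    caller = call_dars if kind == "peaks" else call_degs
    ctl = sheet.loc[sheet["stage"] == "CTL", "sample_id"].tolist()
    calls = {}
    for stage in CASE_STAGES:
        case = sheet.loc[sheet["stage"] == stage, "sample_id"].tolist()
        res = nb_test(counts, case, ctl)
        sig = caller(res)
        calls[stage] = {f: ("hyper" if l > 0 else "hypo")
                        for f, l in zip(sig.index, sig["log2fc"])}
    return stage_partition(stage_vectors(calls))


def srdmr_table(dmcs_by_category: Mapping[str, pd.DataFrame],
                min_dmcs: int = 3, max_gap: int = 200) -> pd.DataFrame:
    """Merge per-category DMCs into one srDMR table with a category column."""
    merged = stage_dmrs(dmcs_by_category, min_dmcs=min_dmcs, max_gap=max_gap)
    rows = []
    for cat in sorted(merged):
        for r in merged[cat].itertuples():
            rows.append((r.chrom, r.start, r.end, r.n_dmcs, cat))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "n_dmcs",
                                       "category"])


def srdar_table(partition: Mapping[str, set]) -> pd.DataFrame:
    """srDAR table from a peak partition whose feature ids are
    ``chrom:start-end`` strings."""
    rows = []
    for cat in sorted(partition):
        if cat == "unassigned":
            continue
        for fid in sorted(partition[cat]):
            chrom, rng = fid.split(":")
            start, end = rng.split("-")
            rows.append((chrom, int(start), int(end), cat, fid))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "category",
                                       "feature"])


@dataclass
class PipelineResult:
    dmcs_by_category: dict[str, pd.DataFrame]
    srdmrs: pd.DataFrame
    dar_partition: dict[str, set]
    srdars: pd.DataFrame
    deg_partition: dict[str, set]
    panel: Panel
    binary_report: ClassifierReport | None = None
    multiclass_report: ClassifierReport | None = None
    survival: SurvivalStratification | None = None
    extras: dict = field(default_factory=dict)


def run_pipeline(cohort: Cohort, seed: int = 0,
                 classify: bool = True) -> PipelineResult:
    """Run the full analysis on a simulated cohort.

    Stages: DMC calling and srDMR merging; NB differential accessibility
    and expression with earliest-onset partitions; srDMR-srDAR panel; then
    (optionally) binary and 4-class random-forest classification on the
    panel's srDAR methylation and a median-split survival stratification.
    """
    stages = cohort.stages()
    sheet = cohort.sample_sheet
    dmcs_by_cat = stage_resolved_dmcs(cohort.meth, stages)
    srdmrs = srdmr_table(dmcs_by_cat)
    dar_part = stage_resolved_counts(cohort.peaks, sheet, "peaks")
    srdars = srdar_table(dar_part)
    deg_part = stage_resolved_counts(cohort.genes, sheet, "genes")
    panel = build_panel(srdmrs, srdars, cohort.meth, cohort.peaks)

    binary_report = multiclass_report = survival = None
    if classify and len(panel) > 0:
        feats = panel.srdar_meth
        labels2 = pd.Series(
            np.where(sheet["stage"] == "CTL", "CTL", "cancer"),
            index=sheet["sample_id"])
        binary_report = train_eval_classifier(feats, labels2, "binary",
                                              seed=seed)
        labels4 = pd.Series(sheet["stage"].astype(str).to_numpy(),
                            index=sheet["sample_id"])
        multiclass_report = train_eval_classifier(feats, labels4,
                                                  "multiclass", seed=seed)
        score = feats.mean(axis=0)
        survival = km_split_logrank(score, sheet)
    return PipelineResult(dmcs_by_cat, srdmrs, dar_part, srdars, deg_part,
                          panel, binary_report, multiclass_report, survival)
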