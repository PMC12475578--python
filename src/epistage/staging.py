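"""Stage-onset category assignment (the srDMC / srDAR / srDEG procedure).

Each feature carries a per-stage call (hyper, hypo or ns) for the three
case stages AIS, MIA, IAC, each compared against control.  A feature is
assigned to the earliest stage with a significant call, taking the
direction observed there; its calls at later stages are not considered.
The six categories {hyper, hypo} x {AIS, MIA, IAC} therefore partition the
ever-significant features with no overlap; features never significant are
unassigned.  One generic engine serves methylation sites, accessibility
peaks and genes alike.
"""

from __future__ import annotations

from typing import Hashable, Mapping, Sequence

import pandas as pd

from .methylation import merge_dmcs_to_dmrs

__all__ = [
    "CASE_STAGES",
    "CATEGORIES",
    "assign_stage_category",
    "stage_partition",
    "stage_vectors",
    "stage_dmrs",
]

CASE_STAGES = ("AIS", "MIA", "IAC")
CATEGORIES = tuple(
    f"{d}-{s}" for s in CASE_STAGES for d in ("hyper", "hypo")
)

_ALIAS = {"up": "hyper", "down": "hypo", "hyper": "hyper", "hypo": "hypo", "ns": "ns"}


def _norm_call(call: str) -> str:
    try:
        return _ALIAS[call]
    except KeyError:
        raise ValueError(f"unknown call {call!r}") from None


def assign_stage_category(vector: Sequence[str]) -> str:
    """Category of one stage-result vector (calls for AIS, MIA, IAC in order).

    Returns e.g. ``hyper-MIA`` for the earliest significant call, or
    ``unassigned`` when all three are ``ns``.  Later calls are ignored even
    if they flip direction.
    """
    if len(vector) != len(CASE_STAGES):
        raise ValueError("expected one call per case stage (AIS, MIA, IAC)")
    for stage, call in zip(CASE_STAGES, vector):
        call = _norm_call(call)
        if call != "ns":
            return f"{call}-{stage}"
    return "unassigned"


def stage_partition(
    vectors: Mapping[Hashable, Sequence[str]]
) -> dict[str, set]:
    """Partition features into the six onset categories plus unassigned.

    ``vectors`` maps feature id -> (AIS, MIA, IAC) calls (a mapping or an
    iterable of (id, vector) pairs; duplicate ids are an error).  The six
    named sets are pairwise disjoint and their union is exactly the set of
    features with at least one significant call.
    """
    items = list(vectors.items()) if isinstance(vectors, Mapping) else list(vectors)
    ids = [fid for fid, _ in items]
    if len(ids) != len(set(ids)):
        raise ValueError("duplicate feature ids")
    out: dict[str, set] = {c: set() for c in CATEGORIES}
    out["unassigned"] = set()
    for fid, vec in items:
        out[assign_stage_category(vec)].add(fid)
    return out


def stage_vectors(
    calls_by_stage: Mapping[str, Mapping[Hashable, str]]
) -> dict[Hashable, tuple[str, str, str]]:
    """Assemble stage-result vectors from three per-stage call maps.

    ``calls_by_stage`` maps each of AIS, MIA, IAC to {feature id ->
    direction} for its significant features; absent features are ``ns``.
    """
    missing = [s for s in CASE_STAGES if s not in calls_by_stage]
    if missing:
        raise ValueError(f"missing stages {missing}")
    features: set = set()
    for s in CASE_STAGES:
        features |= set(calls_by_stage[s])
    return {
        fid: tuple(_norm_call(calls_by_stage[s].get(fid, "ns")) for s in CASE_STAGES)
        for fid in sorted(features, key=str)
    }


def stage_dmrs(
    dmcs_by_category: Mapping[str, pd.DataFrame],
    min_dmcs: int = 3,
    max_gap: int = 200,
) -> dict[str, pd.DataFrame]:
    """Merge stage-categorized DMCs into stage-related DMRs.

    The DMC-to-DMR merge runs within each of the six categories separately,
    so DMCs from different onset categories never co-occupy one srDMR even
    when interleaved on the chromosome.
    """
    out = {}
    for category, dmcs in dmcs_by_category.items():
        out[category] = merge_dmcs_to_dmrs(dmcs, min_dmcs=min_dmcs, max_gap=max_gap)
    return out
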