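"""Epigenetics-related TF analysis: motif-site enrichment in target region
sets, joint (srDMR and srDAR) epi-TF identification, ChIP-evidence site
filtering, pairwise co-localization matrices and their clustering.

Enrichment is count-based: a hypergeometric upper tail on the number of
target regions containing at least one motif site, against containment in a
background region universe.  Co-localization between two TFs is the Jaccard
index of the region sets they occupy within a stated context (e.g. srDARs
versus genome-wide), matching a symmetric co-localization heatmap; the
asymmetric conditional proportion is available as an option.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from scipy.stats import hypergeom

from .counts import bh_adjust
from .intervals import GenomicInterval, intersect_intervals, sort_intervals

__all__ = [
    "TFSiteSet",
    "site_enrichment",
    "identify_epi_tfs",
    "filter_sites_by_evidence",
    "coloc_matrix",
    "ratio_change",
    "cluster_tfs",
]


@dataclass
class TFSiteSet:
    """Motif-site occurrences of one transcription factor."""

    tf: str
    sites: list[GenomicInterval] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.sites = sort_intervals(self.sites)


def _occupied(sites: Sequence[GenomicInterval],
              regions: Sequence[GenomicInterval]) -> set[int]:
    """Indices of regions containing >= 1 site."""
    return {ri for _, ri, _ in intersect_intervals(list(sites), list(regions))}


def site_enrichment(tf: TFSiteSet,
                    targets: Sequence[GenomicInterval],
                    background: Sequence[GenomicInterval]) -> tuple[float, float]:
    """Hypergeometric enrichment of a TF's sites in target regions.

    ``targets`` must be a subset of the ``background`` region universe.
    Returns (fold, p): fold is the target hit rate over the background hit
    rate; p is the upper-tail probability of observing at least the target
    hit count when drawing ``len(targets)`` regions from the background.
    Zero background hits yield (inf, 1.0).
    """
    bg_keys = {(r.chrom, r.start, r.end) for r in background}
    for r in targets:
        if (r.chrom, r.start, r.end) not in bg_keys:
            raise ValueError(f"target {r} not in background universe")
    N = len(background)
    n = len(targets)
    if N == 0 or n == 0:
        raise ValueError("empty region set")
    K = len(_occupied(tf.sites, background))
    k = len(_occupied(tf.sites, targets))
    if K == 0:
        warnings.warn(f"{tf.tf}: no background hits; enrichment undefined")
        return (float("inf"), 1.0)
    fold = (k / n) / (K / N)
    p = float(hypergeom.sf(k - 1, N, K, n))
    return fold, p


def identify_epi_tfs(enrichments_in_srdmrs: pd.DataFrame,
                     enrichments_in_srdars: pd.DataFrame,
                     alpha: float = 0.05) -> set[str]:
    """TFs enriched in both srDMRs and srDARs.

    Each table has columns tf, category, p_value (one row per TF per stage
    category).  P-values are BH-adjusted within each table; a TF qualifies
    when it reaches q < ``alpha`` in at least one srDMR category AND at
    least one srDAR category.
    """
    hits = []
    for table in (enrichments_in_srdmrs, enrichments_in_srdars):
        if len(table) == 0:
            return set()
        q = bh_adjust(table["p_value"].to_numpy())
        hits.append(set(table.loc[q < alpha, "tf"]))
    return hits[0] & hits[1]


def filter_sites_by_evidence(
    sites: TFSiteSet,
    evidence: Sequence[Sequence[GenomicInterval]],
) -> TFSiteSet:
    """Keep sites supported by every evidence track.

    A site survives when it overlaps >= 1 interval in EVERY evidence list
    (intersection-of-evidence, e.g. JUN ChIP and FOS ChIP and H3K27ac).
    Adding a track can only remove sites.  An empty track removes all sites
    (with a warning).
    """
    kept = list(sites.sites)
    for track in evidence:
        track = list(track)
        if not track:
            warnings.warn(f"{sites.tf}: empty evidence track removes all sites")
            return TFSiteSet(sites.tf, [])
        hit = {ai for ai, _, _ in intersect_intervals(kept, track)}
        kept = [s for i, s in enumerate(kept) if i in hit]
        if not kept:
            break
    return TFSiteSet(sites.tf, kept)


def coloc_matrix(tfs: Sequence[TFSiteSet],
                 regions: Sequence[GenomicInterval],
                 method: str = "jaccard") -> pd.DataFrame:
    """Pairwise TF co-localization over a region context.

    Entry (i, j) is the Jaccard index of the sets of regions occupied
    (>= 1 site) by TF i and TF j (``method='conditional'`` gives the
    asymmetric |A∩B| / |A| instead).  Diagonal is 1 for every TF occupying
    at least one region; TFs with no sites in the context get NaN rows and
    columns.
    """
    if len(tfs) < 2:
        raise ValueError("need >= 2 TFs")
    if method not in ("jaccard", "conditional"):
        raise ValueError(f"unknown method {method!r}")
    names = [t.tf for t in tfs]
    occ = {t.tf: _occupied(t.sites, regions) for t in tfs}
    mat = np.full((len(tfs), len(tfs)), np.nan)
    for i, a in enumerate(names):
        if not occ[a]:
            continue
        for j, b in enumerate(names):
            if not occ[b]:
                continue
            inter = len(occ[a] & occ[b])
            if method == "jaccard":
                mat[i, j] = inter / len(occ[a] | occ[b])
            else:
                mat[i, j] = inter / len(occ[a])
    return pd.DataFrame(mat, index=names, columns=names)


def ratio_change(coloc_in_srdars: pd.DataFrame,
                 coloc_genomewide: pd.DataFrame) -> pd.DataFrame:
    """Elementwise ratio of srDAR co-localization to genome-wide
    co-localization; NaN where the genome-wide proportion is zero."""
    if list(coloc_in_srdars.index) != list(coloc_genomewide.index):
        raise ValueError("TF lists must match")
    denom = coloc_genomewide.to_numpy(dtype=float)
    num = coloc_in_srdars.to_numpy(dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where(denom > 0, num / np.where(denom > 0, denom, 1.0), np.nan)
    return pd.DataFrame(ratio, index=coloc_in_srdars.index,
                        columns=coloc_in_srdars.columns)


def cluster_tfs(coloc: pd.DataFrame, k: int = 6,
                linkage: str = "average") -> pd.Series:
    """Cut a hierarchical tree over 1 - co-localization into ``k`` groups.

    Average linkage by default.  Deterministic given the matrix content:
    TFs are processed in lexicographic name order and cluster ids are
    renumbered by first appearance in that order.
    """
    if k > len(coloc):
        raise ValueError("k exceeds number of TFs")
    if coloc.isna().any().any():
        raise ValueError("co-localization matrix has absent rows; drop them first")
    names = sorted(coloc.index)
    mat = coloc.loc[names, names].to_numpy(dtype=float)
    dist = 1.0 - mat
    np.fill_diagonal(dist, 0.0)
    dist = 0.5 * (dist + dist.T)  # guard symmetry against float noise
    Z = hierarchy.linkage(squareform(dist, checks=False), method=linkage)
    raw = hierarchy.fcluster(Z, t=k, criterion="maxclust")
    remap: dict[int, int] = {}
    labels = []
    for lab in raw:
        if lab not in remap:
            remap[lab] = len(remap) + 1
        labels.append(remap[lab])
    return pd.Series(labels, index=names, name="cluster")
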