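"""Synthetic four-stage multi-omic cohort with planted, recorded effects.

The generator emulates the study design the pipeline targets: a CTL / AIS /
MIA / IAC cohort with

* per-CpG bisulfite counts — coverage Poisson around a configurable mean
  (default 25.8 reads, floored at 1 so every CpG is observed) and
  methylated reads beta-binomial around a stage-dependent mean,
* peak and gene count matrices — negative binomial with log-normal
  per-sample size factors,
* per-TF motif-site sets with block co-localization structure inside
  planted differentially accessible regions,
* survival times exponentially linked to panel methylation (a positive
  link coefficient makes LOW methylation mean HIGH hazard).

Every planted effect switches on at its onset stage and persists through
IAC (matching earliest-onset categorization); the full registry of planted
truth is returned so downstream callers can be tested by parameter
recovery.  All output is bit-reproducible given (config, seed): each
modality draws from its own RNG stream derived from the master seed, so
e.g. enlarging the CpG set never perturbs the peak counts.

Genome layout is deliberately schematic (one chromosome, uniform spacing):
planted methylation regions are blocks of adjacently spaced CpGs, and the
i-th planted peak is centred on the i-th planted methylation block so that
an srDMR-srDAR intersection panel exists by construction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .intervals import GenomicInterval
from .methylation import region_methylation
from .tabular import CountMatrix, MethylationMatrix, MethylationTrack, STAGES
from .tfcoloc import TFSiteSet

__all__ = [
    "PlantedEffect",
    "CohortConfig",
    "CohortTruth",
    "Cohort",
    "standard_effects",
    "simulate_methylation",
    "simulate_counts",
    "simulate_sites",
    "simulate_survival",
    "simulate_cohort",
]

_ONSETS = ("AIS", "MIA", "IAC")
_CHROM = "chr1"


@dataclass(frozen=True)
class PlantedEffect:
    """One planted stage-onset effect.

    ``target`` is ``meth_region``, ``peak`` or ``gene``; ``effect_size`` is
    the methylation delta (level units) or the absolute log2 fold change.
    The effect persists from ``onset_stage`` through IAC.
    """

    target: str
    onset_stage: str
    direction: str
    effect_size: float

    def __post_init__(self) -> None:
        if self.target not in ("meth_region", "peak", "gene"):
            raise ValueError(f"unknown target {self.target!r}")
        if self.onset_stage not in _ONSETS:
            raise ValueError(f"unknown onset stage {self.onset_stage!r}")
        if self.direction not in ("hyper", "hypo", "up", "down"):
            raise ValueError(f"unknown direction {self.direction!r}")
        if self.effect_size <= 0:
            raise ValueError("effect_size must be positive")

    @property
    def signed(self) -> float:
        return self.effect_size if self.direction in ("hyper", "up") else -self.effect_size


def standard_effects(n_per_category: int = 10,
                     meth_delta: float = 0.4,
                     peak_lfc: float = 4.0,
                     gene_lfc: float = 1.16) -> list[PlantedEffect]:
    """A balanced grid of effects: every (onset, direction) category gets
    ``n_per_category`` methylation regions, peaks and genes.

    Default effect sizes sit at twice the calling thresholds (methylation
    delta 0.4 vs the 0.20 credible cut; peak |log2FC| 4 vs 2; gene
    |log2FC| 1.16 vs 0.58), the regime in which category recovery is
    expected to be near-complete.
    """
    out = []
    for onset in _ONSETS:
        for meth_dir, count_dir in (("hyper", "up"), ("hypo", "down")):
            for _ in range(n_per_category):
                out.append(PlantedEffect("meth_region", onset, meth_dir, meth_delta))
                out.append(PlantedEffect("peak", onset, meth_dir, peak_lfc))
                out.append(PlantedEffect("gene", onset, count_dir, gene_lfc))
    return out


@dataclass
class CohortConfig:
    """All knobs of the synthetic cohort (defaults are desk scale)."""

    n_per_stage: dict = field(
        default_factory=lambda: {"CTL": 10, "AIS": 10, "MIA": 10, "IAC": 10})
    n_cpgs: int = 5000
    n_peaks: int = 1000
    n_genes: int = 1000
    mean_coverage: float = 25.8
    baseline_meth: float = 0.5
    meth_precision: float = 30.0
    nb_mean: float = 100.0
    nb_mean_sigma: float = 0.5
    nb_dispersion: float = 0.1
    size_factor_sigma: float = 0.15
    planted_effects: list = field(default_factory=standard_effects)
    # genome layout
    cpgs_per_region: int = 5
    cpg_region_spacing: int = 50
    region_pitch: int = 3000
    cpg_background_spacing: int = 250
    peak_width: int = 500
    # TF motif-site structure
    n_tfs: int = 12
    n_tf_clusters: int = 3
    sites_per_tf_dar: int = 15
    sites_per_tf_background: int = 60
    within_cluster_jaccard_dar: float = 0.8
    within_cluster_jaccard_background: float = 0.2
    between_cluster_jaccard: float = 0.1
    # survival
    survival_hazard_link: float = 3.0
    baseline_hazard: float = 0.08
    censor_time_max: float = 60.0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(v <= 0 for v in self.n_per_stage.values()):
            raise ValueError("n_per_stage counts must be positive")
        if not 0.0 <= self.baseline_meth <= 1.0:
            raise ValueError("baseline_meth must lie in [0, 1]")
        if self.meth_precision <= 0 or self.nb_dispersion < 0:
            raise ValueError("dispersion parameters must be positive")

    def effects(self, target: str) -> list[PlantedEffect]:
        return [e for e in self.planted_effects if e.target == target]


@dataclass
class CohortTruth:
    """Registry of everything the generator planted."""

    effects: pd.DataFrame
    meth_sites: pd.DataFrame
    tf_clusters: pd.Series | None = None
    size_factors: dict = field(default_factory=dict)
    survival: dict = field(default_factory=dict)
    clip_warnings: list = field(default_factory=list)

    def merged(self, other: "CohortTruth") -> "CohortTruth":
        frames = [f for f in (self.effects, other.effects) if len(f)]
        eff = (pd.concat(frames, ignore_index=True) if frames
               else _EMPTY_EFFECTS.copy())
        if eff["feature_id"].duplicated().any():
            raise ValueError("planted feature ids collide across fragments")
        sframes = [f for f in (self.meth_sites, other.meth_sites) if len(f)]
        return CohortTruth(
            effects=eff,
            meth_sites=(pd.concat(sframes, ignore_index=True) if sframes
                        else _EMPTY_SITES.copy()),
            tf_clusters=other.tf_clusters if self.tf_clusters is None
            else self.tf_clusters,
            size_factors={**self.size_factors, **other.size_factors},
            survival={**self.survival, **other.survival},
            clip_warnings=self.clip_warnings + other.clip_warnings,
        )


_EMPTY_EFFECTS = pd.DataFrame(columns=[
    "feature_id", "target", "onset_stage", "direction", "effect_size",
    "chrom", "start", "end"])
_EMPTY_SITES = pd.DataFrame(columns=[
    "chrom", "start", "region_id", "onset_stage", "direction", "delta"])


def make_sample_sheet(config: CohortConfig) -> pd.DataFrame:
    rows = []
    for stage in STAGES:
        for i in range(config.n_per_stage[stage]):
            rows.append((f"{stage}_{i:02d}", stage))
    return pd.DataFrame(rows, columns=["sample_id", "stage"])


def _stage_onset_mask(sample_stages: Sequence[str], onset: str) -> np.ndarray:
    order = {s: i for i, s in enumerate(STAGES)}
    return np.array([order[s] >= order[onset] for s in sample_stages])


def meth_region_intervals(config: CohortConfig) -> list[GenomicInterval]:
    """Deterministic coordinates of the planted methylation regions."""
    width = (config.cpgs_per_region - 1) * config.cpg_region_spacing + 1
    return [
        GenomicInterval(_CHROM, i * config.region_pitch,
                        i * config.region_pitch + width)
        for i in range(len(config.effects("meth_region")))
    ]


def _cpg_positions(config: CohortConfig) -> tuple[np.ndarray, list[list[int]]]:
    """All CpG positions plus, per planted region, its member site indices."""
    region_members: list[list[int]] = []
    pos: list[int] = []
    for i, _ in enumerate(config.effects("meth_region")):
        base = i * config.region_pitch
        members = []
        for j in range(config.cpgs_per_region):
            members.append(len(pos))
            pos.append(base + j * config.cpg_region_spacing)
        region_members.append(members)
    n_bg = config.n_cpgs - len(pos)
    if n_bg < 0:
        raise ValueError("n_cpgs too small for the planted regions")
    bg_start = (len(region_members) * config.region_pitch) + 10_000
    pos.extend(bg_start + np.arange(n_bg) * config.cpg_background_spacing)
    return np.asarray(pos, dtype=int), region_members


def simulate_methylation(
    config: CohortConfig, rng: np.random.Generator
) -> tuple[list[MethylationTrack], CohortTruth]:
    """Simulate per-sample CpG tracks with planted stage-onset effects.

    Coverage per CpG is Poisson(mean_coverage) floored at 1; the methylated
    count is beta-binomial: a per-(site, sample) level drawn from
    Beta(mean * precision, (1-mean) * precision) feeds a binomial.  The
    stage-dependent mean is the baseline shifted by the planted delta for
    samples at or after the onset stage, clipped into [0.01, 0.99] (clips
    are recorded in the truth registry).
    """
    sheet = make_sample_sheet(config)
    stages = sheet["stage"].tolist()
    n_samples = len(sheet)
    positions, region_members = _cpg_positions(config)
    n_sites = len(positions)

    mean = np.full((n_sites, n_samples), float(config.baseline_meth))
    effects = config.effects("meth_region")
    eff_rows, site_rows = [], []
    clips: list[str] = []
    intervals = meth_region_intervals(config)
    for i, eff in enumerate(effects):
        fid = f"meth_region_{eff.direction}-{eff.onset_stage}_{i:03d}"
        onset = _stage_onset_mask(stages, eff.onset_stage)
        members = region_members[i]
        shifted = config.baseline_meth + eff.signed
        if not 0.01 <= shifted <= 0.99:
            clips.append(f"{fid}: mean {shifted:.3f} clipped into [0.01, 0.99]")
        for si in members:
            mean[si, onset] = shifted
            site_rows.append((_CHROM, positions[si], fid,
                              eff.onset_stage, eff.direction, eff.signed))
        iv = intervals[i]
        eff_rows.append((fid, "meth_region", eff.onset_stage, eff.direction,
                         eff.effect_size, iv.chrom, iv.start, iv.end))
    mean = np.clip(mean, 0.01, 0.99)

    total = np.maximum(rng.poisson(config.mean_coverage, size=(n_sites, n_samples)), 1)
    a = mean * config.meth_precision
    b = (1.0 - mean) * config.meth_precision
    level = rng.beta(a, b)
    meth = rng.binomial(total, level)

    tracks = []
    for j, sid in enumerate(sheet["sample_id"]):
        df = pd.DataFrame({
            "chrom": _CHROM, "start": positions, "end": positions + 1,
            "methylated": meth[:, j], "total": total[:, j]})
        tracks.append(MethylationTrack(sid, df))
    truth = CohortTruth(
        effects=pd.DataFrame(eff_rows, columns=_EMPTY_EFFECTS.columns)
        if eff_rows else _EMPTY_EFFECTS.copy(),
        meth_sites=pd.DataFrame(site_rows, columns=_EMPTY_SITES.columns)
        if site_rows else _EMPTY_SITES.copy(),
        clip_warnings=clips,
    )
    return tracks, truth


def peak_intervals(config: CohortConfig) -> list[GenomicInterval]:
    """Peak coordinates: planted peaks centred on the planted methylation
    regions, background peaks tiled over the background CpG run."""
    ivs = []
    meth_ivs = meth_region_intervals(config)
    planted = config.effects("peak")
    for i, _ in enumerate(planted):
        if i < len(meth_ivs):
            centre = (meth_ivs[i].start + meth_ivs[i].end) // 2
        else:  # extra peaks beyond the methylation blocks
            centre = (len(meth_ivs) + i) * config.region_pitch
        start = max(0, centre - config.peak_width // 2)
        ivs.append(GenomicInterval(_CHROM, start, start + config.peak_width))
    n_bg = config.n_peaks - len(planted)
    if n_bg < 0:
        raise ValueError("n_peaks too small for the planted peak effects")
    bg_cpg_start = len(meth_ivs) * config.region_pitch + 10_000
    for m in range(n_bg):
        start = bg_cpg_start + m * 1000
        ivs.append(GenomicInterval(_CHROM, start, start + config.peak_width))
    return ivs


def simulate_counts(
    config: CohortConfig, modality: str, rng: np.random.Generator
) -> tuple[CountMatrix, CohortTruth]:
    """Simulate a peak or gene count matrix with planted fold changes.

    counts ~ NB(mean = base_i * size_factor_j * 2^(signed lfc when the
    sample is at/after onset), dispersion ``nb_dispersion``); per-feature
    baselines are log-normal around ``nb_mean`` and per-sample size factors
    log-normal with sigma ``size_factor_sigma`` (recorded in the truth).
    Dispersion 0 falls back to Poisson.
    """
    if modality not in ("peaks", "genes"):
        raise ValueError(f"unknown modality {modality!r}")
    target = "peak" if modality == "peaks" else "gene"
    n_features = config.n_peaks if modality == "peaks" else config.n_genes
    sheet = make_sample_sheet(config)
    stages = sheet["stage"].tolist()
    n_samples = len(sheet)
    planted = config.effects(target)
    if len(planted) > n_features:
        raise ValueError("more planted effects than features")

    base = np.exp(rng.normal(np.log(config.nb_mean), config.nb_mean_sigma,
                             size=n_features))
    sf = np.exp(rng.normal(0.0, config.size_factor_sigma, size=n_samples))
    lfc = np.zeros((n_features, n_samples))
    ivs = peak_intervals(config) if modality == "peaks" else None
    if modality == "peaks":
        # peak features are keyed by their coordinates, planted rows first
        index = [f"{iv.chrom}:{iv.start}-{iv.end}" for iv in ivs]
    else:
        index = [f"gene_{e.direction}-{e.onset_stage}_{i:03d}"
                 for i, e in enumerate(planted)]
        index += [f"gene_bg_{m:04d}" for m in range(n_features - len(planted))]
    eff_rows = []
    for i, eff in enumerate(planted):
        lfc[i, _stage_onset_mask(stages, eff.onset_stage)] = eff.signed
        if ivs is not None:
            eff_rows.append((index[i], target, eff.onset_stage, eff.direction,
                             eff.effect_size, ivs[i].chrom, ivs[i].start,
                             ivs[i].end))
        else:
            eff_rows.append((index[i], target, eff.onset_stage, eff.direction,
                             eff.effect_size, None, np.nan, np.nan))
    mu = base[:, None] * sf[None, :] * np.exp2(lfc)
    if config.nb_dispersion < 1e-12:
        counts = rng.poisson(mu)
    else:
        r = 1.0 / config.nb_dispersion
        counts = rng.negative_binomial(r, r / (r + mu))
    df = pd.DataFrame(counts, index=index, columns=sheet["sample_id"].tolist())
    cm = CountMatrix(df, feature_intervals=ivs)
    truth = CohortTruth(
        effects=pd.DataFrame(eff_rows, columns=_EMPTY_EFFECTS.columns)
        if eff_rows else _EMPTY_EFFECTS.copy(),
        meth_sites=_EMPTY_SITES.copy(),
        size_factors={modality: pd.Series(sf, index=df.columns)},
    )
    return cm, truth


def _block_occupancy(pool: list[int], n_tfs: int, clusters: np.ndarray,
                     m: int, s_within: float, s_between: float,
                     rng: np.random.Generator) -> list[set[int]]:
    """Assign each TF a set of occupied regions from ``pool`` so that the
    pairwise region Jaccard is ``s_within`` inside a cluster and
    ``s_between`` across clusters (exact by construction)."""
    g = int(round(2 * m * s_between / (1 + s_between)))
    c = max(int(round(2 * m * s_within / (1 + s_within))), g)
    private = m - c
    n_clusters = len(np.unique(clusters))
    need = g + n_clusters * (c - g) + n_tfs * private
    if need > len(pool):
        raise ValueError(f"region pool too small: need {need}, have {len(pool)}")
    perm = list(rng.permutation(pool))
    global_core = set(perm[:g])
    cursor = g
    cluster_core = {}
    for cl in np.unique(clusters):
        cluster_core[cl] = set(perm[cursor:cursor + (c - g)])
        cursor += c - g
    occ = []
    for i in range(n_tfs):
        mine = set(perm[cursor:cursor + private])
        cursor += private
        occ.append(global_core | cluster_core[clusters[i]] | mine)
    return occ


def simulate_sites(
    config: CohortConfig, rng: np.random.Generator,
    dar_regions: Sequence[GenomicInterval] | None = None,
    background_regions: Sequence[GenomicInterval] | None = None,
) -> tuple[list[TFSiteSet], pd.Series]:
    """Simulate per-TF motif-site sets with planted co-binding clusters.

    TFs are split into ``n_tf_clusters`` contiguous blocks.  Within the
    planted-DAR region pool, same-cluster TFs share occupied regions at
    Jaccard ``within_cluster_jaccard_dar``; in the background pool at the
    lower ``within_cluster_jaccard_background``; pairs from different
    clusters share at ``between_cluster_jaccard`` in both pools.  Each
    occupied region holds one 10 bp site at its midpoint.  Returns the site
    sets and the planted cluster labels.
    """
    if config.n_tf_clusters < 2:
        raise ValueError("need >= 2 planted TF clusters")
    if dar_regions is None or background_regions is None:
        all_peaks = peak_intervals(config)
        n_planted = len(config.effects("peak"))
        dar_regions = all_peaks[:n_planted]
        background_regions = all_peaks[n_planted:]
    dar_regions = list(dar_regions)
    background_regions = list(background_regions)
    clusters = np.array([i * config.n_tf_clusters // config.n_tfs + 1
                         for i in range(config.n_tfs)])
    occ_dar = _block_occupancy(
        list(range(len(dar_regions))), config.n_tfs, clusters,
        config.sites_per_tf_dar, config.within_cluster_jaccard_dar,
        config.between_cluster_jaccard, rng)
    occ_bg = _block_occupancy(
        list(range(len(background_regions))), config.n_tfs, clusters,
        config.sites_per_tf_background,
        config.within_cluster_jaccard_background,
        config.between_cluster_jaccard, rng)

    def _site(region: GenomicInterval) -> GenomicInterval:
        mid = (region.start + region.end) // 2
        return GenomicInterval(region.chrom, mid - 5, mid + 5)

    tf_sets = []
    names = [f"TF{i:02d}" for i in range(config.n_tfs)]
    for i, name in enumerate(names):
        sites = [_site(dar_regions[r]) for r in sorted(occ_dar[i])]
        sites += [_site(background_regions[r]) for r in sorted(occ_bg[i])]
        tf_sets.append(TFSiteSet(name, sites))
    return tf_sets, pd.Series(clusters, index=names, name="cluster")


def simulate_survival(
    config: CohortConfig, panel_methylation: pd.Series,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Survival columns linked to per-sample panel methylation.

    Event times are exponential with hazard = baseline_hazard *
    exp(-survival_hazard_link * methylation); with a positive link, low
    methylation means high hazard (worse survival).  Censoring is
    independent uniform on (0, censor_time_max].
    """
    meth = panel_methylation.astype(float)
    hazard = config.baseline_hazard * np.exp(
        -config.survival_hazard_link * meth.to_numpy())
    t_event = rng.exponential(1.0 / hazard)
    t_censor = rng.uniform(0.0, config.censor_time_max, size=len(meth))
    time = np.minimum(t_event, t_censor)
    event = (t_event <= t_censor).astype(int)
    return pd.DataFrame({"sample_id": meth.index, "survival_time": time,
                         "event": event})


@dataclass
class Cohort:
    """A fully simulated cohort plus its planted-truth registry."""

    config: CohortConfig
    sample_sheet: pd.DataFrame
    tracks: list[MethylationTrack]
    meth: MethylationMatrix
    peaks: CountMatrix
    genes: CountMatrix
    tf_sites: list[TFSiteSet]
    truth: CohortTruth

    def stages(self) -> dict[str, str]:
        return dict(zip(self.sample_sheet["sample_id"],
                        self.sample_sheet["stage"].astype(str)))


def simulate_cohort(config: CohortConfig | None = None,
                    seed: int | None = None) -> Cohort:
    """Simulate the full multi-omic cohort.

    Each modality uses its own RNG stream spawned from the master seed
    (``seed`` overrides ``config.seed``), so outputs are bit-identical for
    identical (config, seed) and modalities do not perturb one another.
    Survival is linked to the mean methylation level over the planted
    methylation regions (the ground-truth panel).
    """
    config = config if config is not None else CohortConfig()
    if seed is not None:
        config = replace(config, seed=seed)
    streams = {name: np.random.default_rng([config.seed, k])
               for k, name in enumerate(
                   ["meth", "peaks", "genes", "sites", "survival"])}
    sheet = make_sample_sheet(config)
    tracks, truth = simulate_methylation(config, streams["meth"])
    meth = MethylationMatrix.from_tracks(tracks)
    peaks, t_peaks = simulate_counts(config, "peaks", streams["peaks"])
    genes, t_genes = simulate_counts(config, "genes", streams["genes"])
    truth = truth.merged(t_peaks).merged(t_genes)
    tf_sites, tf_clusters = simulate_sites(config, streams["sites"])
    truth.tf_clusters = tf_clusters

    # survival couples to the hypomethylated planted regions (the panel the
    # study design cares about: low methylation there means poor prognosis);
    # with no hypo regions planted, all planted regions are used
    all_regions = meth_region_intervals(config)
    meth_effects = config.effects("meth_region")
    regions = [iv for iv, e in zip(all_regions, meth_effects)
               if e.direction == "hypo"] or all_regions
    if regions:
        panel_meth = region_methylation(meth, regions).mean(axis=0)
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            panel_meth = pd.Series(
                np.full(len(sheet), config.baseline_meth),
                index=sheet["sample_id"])
    surv = simulate_survival(config, panel_meth, streams["survival"])
    sheet = sheet.merge(surv, on="sample_id")
    truth.survival = {
        "link": config.survival_hazard_link,
        "baseline_hazard": config.baseline_hazard,
        "panel_methylation": panel_meth,
    }
    return Cohort(config, sheet, tracks, meth, peaks, genes, tf_sites, truth)
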