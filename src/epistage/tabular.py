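"""Tabular containers and TSV I/O: methylation tracks, count matrices, sample sheets.

All writers emit a header row, tab separation, deterministic column order
and coordinate/row sort, so every read/write pair round-trips exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .intervals import GenomicInterval

__all__ = [
    "STAGES",
    "STAGE_DTYPE",
    "MethylationTrack",
    "MethylationMatrix",
    "CountMatrix",
    "read_methylation_track",
    "write_methylation_track",
    "read_count_matrix",
    "write_count_matrix",
    "read_sample_sheet",
    "write_sample_sheet",
    "validate_sample_sheet",
]

#: Ordered disease stages: non-cancer control, adenocarcinoma in situ,
#: minimally invasive and invasive adenocarcinoma.
STAGES = ("CTL", "AIS", "MIA", "IAC")
STAGE_DTYPE = pd.CategoricalDtype(STAGES, ordered=True)

_TRACK_COLS = ["chrom", "start", "end", "methylated", "total"]


@dataclass
class MethylationTrack:
    """Per-sample per-CpG bisulfite counts.

    ``records`` has columns chrom, start, end, methylated, total; one row per
    CpG, coordinate sorted, no duplicate positions, 0 <= methylated <= total.
    The methylation level is always derived as methylated/total, never stored.
    """

    sample_id: str
    records: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.records
        missing = [c for c in _TRACK_COLS if c not in df.columns]
        if missing:
            raise ValueError(f"track missing columns {missing}")
        if (df["methylated"] > df["total"]).any():
            raise ValueError("methylated exceeds total")
        if (df["methylated"] < 0).any() or (df["total"] < 0).any():
            raise ValueError("negative counts")
        key = df[["chrom", "start"]]
        if key.duplicated().any():
            raise ValueError("duplicate CpG positions")
        srt = df.sort_values(["chrom", "start"], kind="mergesort")
        if not (srt.index == df.index).all():
            raise ValueError("records not coordinate sorted")

    def levels(self) -> pd.Series:
        return self.records["methylated"] / self.records["total"]


def read_methylation_track(path, sample_id: str | None = None) -> MethylationTrack:
    """Read a bedGraph-like TSV (chrom, start, end, methylated, total).

    Malformed rows, methylated > total and unsorted input raise a parse
    error naming the line number.
    """
    rows = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:5] != _TRACK_COLS:
            raise ValueError(f"{path}: line 1: expected header {_TRACK_COLS}")
        prev = None
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            f = line.split("\t")
            if len(f) < 5:
                raise ValueError(f"{path}: line {lineno}: expected 5 columns")
            try:
                start, end, m, t = int(f[1]), int(f[2]), int(f[3]), int(f[4])
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: non-integer field") from exc
            if end <= start:
                raise ValueError(f"{path}: line {lineno}: end <= start")
            if m > t:
                raise ValueError(f"{path}: line {lineno}: methylated exceeds total")
            if m < 0:
                raise ValueError(f"{path}: line {lineno}: negative count")
            key = (f[0], start)
            if prev is not None and key <= prev:
                raise ValueError(f"{path}: line {lineno}: input not sorted")
            prev = key
            rows.append((f[0], start, end, m, t))
    df = pd.DataFrame(rows, columns=_TRACK_COLS)
    if sample_id is None:
        sample_id = str(path)
    return MethylationTrack(sample_id, df)


def write_methylation_track(path, track: MethylationTrack) -> None:
    track.records[_TRACK_COLS].to_csv(path, sep="\t", index=False)


class MethylationMatrix:
    """Aligned CpG x sample methylated/total count arrays.

    Sites are the union of positions over tracks; a sample without coverage
    at a site carries total 0 there (treated as missing downstream, never as
    level 0).
    """

    def __init__(self, sites: pd.DataFrame, meth: np.ndarray, total: np.ndarray,
                 samples: Sequence[str]):
        if meth.shape != total.shape or meth.shape != (len(sites), len(samples)):
            raise ValueError("inconsistent matrix dimensions")
        if (meth > total).any() or (meth < 0).any():
            raise ValueError("invalid counts")
        self.sites = sites.reset_index(drop=True)
        self.meth = np.asarray(meth)
        self.total = np.asarray(total)
        self.samples = list(samples)

    @classmethod
    def from_tracks(cls, tracks: Iterable[MethylationTrack]) -> "MethylationMatrix":
        tracks = list(tracks)
        frames = []
        for tr in tracks:
            df = tr.records.set_index(["chrom", "start", "end"])
            frames.append(df[["methylated", "total"]].add_suffix(f"|{tr.sample_id}"))
        wide = pd.concat(frames, axis=1).sort_index()
        samples = [tr.sample_id for tr in tracks]
        meth = wide[[f"methylated|{s}" for s in samples]].fillna(0).to_numpy(int)
        total = wide[[f"total|{s}" for s in samples]].fillna(0).to_numpy(int)
        sites = wide.index.to_frame(index=False)
        return cls(sites, meth, total, samples)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def site_intervals(self) -> list[GenomicInterval]:
        return [
            GenomicInterval(c, s, e)
            for c, s, e in zip(self.sites["chrom"], self.sites["start"], self.sites["end"])
        ]

    def sample_index(self, sample_ids: Sequence[str]) -> np.ndarray:
        pos = {s: i for i, s in enumerate(self.samples)}
        return np.array([pos[s] for s in sample_ids], dtype=int)


class CountMatrix:
    """Feature x sample non-negative integer counts (ATAC peaks or genes).

    ``feature_intervals`` carries peak coordinates when features are genomic
    regions; gene matrices leave it ``None``.
    """

    def __init__(self, counts: pd.DataFrame,
                 feature_intervals: Sequence[GenomicInterval] | None = None):
        arr = counts.to_numpy()
        if (arr < 0).any():
            raise ValueError("negative counts")
        if feature_intervals is not None and len(feature_intervals) != len(counts):
            raise ValueError("feature_intervals length mismatch")
        self.counts = counts
        self.feature_intervals = (
            list(feature_intervals) if feature_intervals is not None else None
        )

    @property
    def features(self) -> list:
        return list(self.counts.index)

    @property
    def samples(self) -> list:
        return list(self.counts.columns)


def read_count_matrix(path) -> CountMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    iv = None
    if df.index.size and all(":" in str(i) and "-" in str(i) for i in df.index):
        iv = []
        for name in df.index:
            chrom, rng = str(name).split(":")
            start, end = rng.split("-")
            iv.append(GenomicInterval(chrom, int(start), int(end)))
    return CountMatrix(df.astype(int), iv)


def write_count_matrix(path, cm: CountMatrix) -> None:
    df = cm.counts.copy()
    df.index.name = "feature"
    df.to_csv(path, sep="\t")


_SHEET_COLS = ["sample_id", "stage", "survival_time", "event"]


def validate_sample_sheet(sheet: pd.DataFrame,
                          samples: Sequence[str] | None = None) -> pd.DataFrame:
    """Validate and normalize a sample sheet.

    Requires unique sample ids, stages restricted to CTL/AIS/MIA/IAC,
    non-negative survival times, events in {0, 1}.  When ``samples`` is
    given, every one must appear exactly once in the sheet.
    """
    missing = [c for c in _SHEET_COLS if c not in sheet.columns]
    if missing:
        raise ValueError(f"sample sheet missing columns {missing}")
    if sheet["sample_id"].duplicated().any():
        raise ValueError("duplicate sample ids")
    bad = set(sheet["stage"]) - set(STAGES)
    if bad:
        raise ValueError(f"unknown stages {sorted(bad)}")
    if (sheet["survival_time"] < 0).any():
        raise ValueError("negative survival time")
    if not sheet["event"].isin([0, 1]).all():
        raise ValueError("event must be 0 or 1")
    if samples is not None:
        absent = set(samples) - set(sheet["sample_id"])
        if absent:
            raise ValueError(f"samples missing from sheet: {sorted(absent)}")
    out = sheet.copy()
    out["stage"] = out["stage"].astype(STAGE_DTYPE)
    return out


def read_sample_sheet(path) -> pd.DataFrame:
    return validate_sample_sheet(pd.read_csv(path, sep="\t"))


def write_sample_sheet(path, sheet: pd.DataFrame) -> None:
    cols = _SHEET_COLS + [c for c in sheet.columns if c not in _SHEET_COLS]
    sheet[cols].to_csv(path, sep="\t", index=False)
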