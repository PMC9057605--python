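"""Readers and writers for the plain-text genomic formats the pipeline touches.

All coordinates are 0-based half-open (BED / bedGraph convention) throughout
the package. Chromosome names are matched as exact strings ("chr1" != "1").
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "GenomicRegion",
    "SignalTrack",
    "CountsMatrix",
    "FormatError",
    "read_bedgraph",
    "write_bedgraph",
    "read_regions_bed",
    "write_regions_bed",
    "read_counts_matrix",
    "read_condition_map",
    "read_cpg_table",
    "write_cpg_table",
    "read_tss_table",
    "write_tss_table",
]


class FormatError(ValueError):
    """Malformed input file (wrong columns, bad coordinates, bad values)."""


@dataclass(frozen=True)
class GenomicRegion:
    """A 0-based half-open interval [start, end) on a named chromosome."""

    chrom: str
    start: int
    end: int
    name: str | None = None
    score: float | None = None

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"end must exceed start, got [{self.start}, {self.end})"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def center(self) -> int:
        return (self.start + self.end) // 2

    def key(self) -> tuple[str, int, int]:
        return (self.chrom, self.start, self.end)


class SignalTrack:
    """Piecewise-constant coverage with bedGraph semantics.

    Per chromosome the track stores sorted, non-overlapping intervals
    (starts, ends, values); any base not covered by an interval has
    implicit value 0.
    """

    def __init__(self, data: Mapping[str, tuple[np.ndarray, np.ndarray, np.ndarray]]):
        self._data: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        for chrom, (starts, ends, values) in data.items():
            starts = np.asarray(starts, dtype=np.int64)
            ends = np.asarray(ends, dtype=np.int64)
            values = np.asarray(values, dtype=float)
            order = np.argsort(starts, kind="stable")
            starts, ends, values = starts[order], ends[order], values[order]
            if np.any(ends <= starts):
                raise FormatError(f"empty or inverted interval on {chrom}")
            if np.any(starts[1:] < ends[:-1]):
                raise FormatError(f"overlapping intervals on {chrom}")
            self._data[chrom] = (starts, ends, values)
        # prefix sums of value*length for O(log n) window sums
        self._cum = {
            c: np.concatenate(([0.0], np.cumsum(v * (e - s))))
            for c, (s, e, v) in self._data.items()
        }

    @classmethod
    def from_intervals(
        cls, intervals: Iterable[tuple[str, int, int, float]]
    ) -> "SignalTrack":
        by_chrom: dict[str, list[tuple[int, int, float]]] = {}
        for chrom, start, end, value in intervals:
            by_chrom.setdefault(chrom, []).append((start, end, value))
        data = {}
        for chrom, recs in by_chrom.items():
            arr = np.array(recs, dtype=float)
            data[chrom] = (
                arr[:, 0].astype(np.int64),
                arr[:, 1].astype(np.int64),
                arr[:, 2],
            )
        return cls(data)

    @property
    def chroms(self) -> list[str]:
        return list(self._data)

    def intervals(self, chrom: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return self._data[chrom]

    def iter_records(self):
        for chrom in self._data:
            starts, ends, values = self._data[chrom]
            for s, e, v in zip(starts, ends, values):
                yield chrom, int(s), int(e), float(v)

    def total_mass(self) -> float:
        """Sum of value x length over every interval."""
        return float(sum(cum[-1] for cum in self._cum.values()))

    def window_sum(self, chrom: str, start: int, end: int) -> float:
        """Integral of the signal over [start, end); 0 where uncovered."""
        if chrom not in self._data:
            return 0.0
        starts, ends, values = self._data[chrom]
        cum = self._cum[chrom]
        lo = int(np.searchsorted(ends, start, side="right"))
        hi = int(np.searchsorted(starts, end, side="left"))
        if lo >= hi:
            return 0.0
        total = cum[hi] - cum[lo]
        # trim the partially covered edge intervals
        total -= values[lo] * max(0, start - starts[lo])
        total -= values[hi - 1] * max(0, ends[hi - 1] - end)
        return float(total)


def _data_lines(path: str | Path):
    """Yield (line_number, line) skipping headers/comments/blank lines."""
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped:
                continue
            if stripped.startswith(("#", "track", "browser")):
                continue
            yield i, stripped


def read_bedgraph(path: str | Path) -> SignalTrack:
    """Parse a 4-column bedGraph file into a :class:`SignalTrack`.

    Overlapping intervals, empty intervals, or malformed lines raise
    :class:`FormatError` naming the offending line.
    """
    records = []
    for lineno, line in _data_lines(path):
        fields = line.split()
        if len(fields) != 4:
            raise FormatError(
                f"{path}:{lineno}: expected 4 columns, got {len(fields)}"
            )
        chrom = fields[0]
        try:
            start, end = int(fields[1]), int(fields[2])
            value = float(fields[3])
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: non-numeric field: {exc}") from exc
        if end <= start or start < 0:
            raise FormatError(
                f"{path}:{lineno}: invalid interval [{start}, {end})"
            )
        records.append((chrom, start, end, value))
    try:
        return SignalTrack.from_intervals(records)
    except FormatError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def write_bedgraph(track: SignalTrack, path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, start, end, value in track.iter_records():
            fh.write(f"{chrom}\t{start}\t{end}\t{value:g}\n")


def read_regions_bed(path: str | Path) -> list[GenomicRegion]:
    """Read BED3/BED6(+) regions in file order; name/score kept if present."""
    regions = []
    for lineno, line in _data_lines(path):
        fields = line.split()
        if len(fields) < 3:
            raise FormatError(f"{path}:{lineno}: expected >=3 columns")
        try:
            start, end = int(fields[1]), int(fields[2])
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: non-integer coordinate") from exc
        name = fields[3] if len(fields) > 3 else None
        score = None
        if len(fields) > 4 and fields[4] != ".":
            try:
                score = float(fields[4])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-numeric score") from exc
        try:
            regions.append(GenomicRegion(fields[0], start, end, name, score))
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: {exc}") from exc
    return regions


def write_regions_bed(regions: Iterable[GenomicRegion], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in regions:
            cols = [r.chrom, str(r.start), str(r.end)]
            if r.name is not None or r.score is not None:
                cols.append(r.name if r.name is not None else ".")
            if r.score is not None:
                cols.append(f"{r.score:g}")
            fh.write("\t".join(cols) + "\n")


@dataclass
class CountsMatrix:
    """Integer RNA-seq counts (genes x samples) plus a sample->condition map."""

    counts: pd.DataFrame
    conditions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.counts.shape[1] < 2:
            raise ValueError("need at least 2 samples")
        if self.counts.index.has_duplicates:
            dupes = self.counts.index[self.counts.index.duplicated()][:3]
            raise ValueError(f"duplicate gene ids: {list(dupes)}")
        if self.counts.isna().any().any():
            raise ValueError("missing cells in counts matrix")
        missing = [s for s in self.counts.columns if s not in self.conditions]
        if self.conditions and missing:
            raise ValueError(f"samples without condition: {missing}")

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def genes(self) -> pd.Index:
        return self.counts.index

    def samples_of(self, condition: str) -> list[str]:
        return [s for s in self.samples if self.conditions.get(s) == condition]


def read_counts_matrix(
    path: str | Path, condition_map: Mapping[str, str]
) -> CountsMatrix:
    """Read a TSV counts table (first column gene ids, header = sample ids)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        raise FormatError(f"{path}: duplicate gene ids")
    for col in df.columns:
        vals = df[col]
        if not np.issubdtype(vals.dtype, np.integer):
            as_float = vals.astype(float)
            if not np.allclose(as_float, np.round(as_float)):
                bad = vals[as_float != np.round(as_float)].index[0]
                raise FormatError(
                    f"{path}: non-integer count for gene {bad!r}, sample {col!r}"
                )
            df[col] = as_float.astype(np.int64)
    if (df < 0).any().any():
        raise FormatError(f"{path}: negative counts")
    missing = [s for s in df.columns if s not in condition_map]
    if missing:
        raise FormatError(f"{path}: samples without condition: {missing}")
    return CountsMatrix(df, {s: condition_map[s] for s in df.columns})


def read_condition_map(path: str | Path) -> dict[str, str]:
    """Two-column TSV: sample id, condition name."""
    df = pd.read_csv(path, sep="\t", header=None, names=["sample", "condition"])
    return dict(zip(df["sample"].astype(str), df["condition"].astype(str)))


CPG_COLUMNS = ["chrom", "pos", "sample", "meth", "total"]


def read_cpg_table(path: str | Path) -> pd.DataFrame:
    """Per-CpG bisulfite counts: chrom, pos (0-based), sample, meth, total."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in CPG_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    df = df[CPG_COLUMNS].copy()
    if (df["meth"] > df["total"]).any():
        raise FormatError(f"{path}: methylated count exceeds coverage")
    if (df["meth"] < 0).any() or (df["total"] < 0).any():
        raise FormatError(f"{path}: negative counts")
    return df


def write_cpg_table(df: pd.DataFrame, path: str | Path) -> None:
    df[CPG_COLUMNS].to_csv(path, sep="\t", index=False)


def read_tss_table(path: str | Path) -> pd.DataFrame:
    """TSS table: gene, chrom, tss (0-based), strand."""
    df = pd.read_csv(path, sep="\t")
    for col in ("gene", "chrom", "tss", "strand"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    if df["gene"].duplicated().any():
        raise FormatError(f"{path}: duplicate gene ids")
    return df


def write_tss_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)
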