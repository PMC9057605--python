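"""Ranked-signal classification of regions by H3K27ac and set enrichment.

The core procedure mirrors super-enhancer style "hockey-stick" analysis:
regions are scored by the mean ChIP signal in a window around their
centers, sorted ascending, and the inflection point of the ranked curve is
found by the sliding-diagonal construction — the chord through the curve's
end points is translated until it is tangent to the curve, i.e. the knee
is the rank with the maximal vertical gap below the chord. Regions above
the knee are "High"; remaining regions under a fixed signal threshold are
"Low". Enrichment of a region subset inside a class is a Fisher exact
test on the 2x2 membership table.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .fisher import FisherResult, fisher_exact
from .io import GenomicRegion, SignalTrack

__all__ = [
    "RegionSignal",
    "RankedClassification",
    "EnrichmentResult",
    "region_signal",
    "aggregate_profile",
    "detect_knee",
    "classify_regions",
    "fisher_exact",
    "enrichment_test",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class RegionSignal:
    region: GenomicRegion
    mean_signal: float


@dataclass
class RankedClassification:
    """Regions sorted by ascending mean signal with High/Low/Mid labels.

    ``knee_index`` is a 1-based rank into the ascending order, or None when
    the ranked curve is indistinguishable from its chord; ranks above the
    knee are High, remaining regions below ``low_threshold`` are Low.
    """

    signals: list[RegionSignal]  # ascending by mean_signal
    knee_index: int | None
    labels: list[str]  # parallel to signals; "High" | "Low" | "Mid"
    low_threshold: float

    def label_of(self) -> dict[tuple[str, int, int], str]:
        return {rs.region.key(): lab for rs, lab in zip(self.signals, self.labels)}

    def regions_with_label(self, label: str) -> list[GenomicRegion]:
        return [rs.region for rs, lab in zip(self.signals, self.labels) if lab == label]


@dataclass
class EnrichmentResult:
    group_name: str
    class_label: str
    table: tuple[int, int, int, int]  # (group&class, group-class, others&class, others-class)
    fold_enrichment: float
    odds_ratio: float
    p: float
    significant: bool


def _window(region: GenomicRegion, half_window_bp: int,
            chrom_size: int | None) -> tuple[int, int]:
    center = region.center
    w0 = max(0, center - half_window_bp)
    w1 = center + half_window_bp
    if chrom_size is not None:
        w1 = min(w1, chrom_size)
    return w0, w1


def region_signal(
    track: SignalTrack,
    regions: Sequence[GenomicRegion],
    half_window_bp: int = 2500,
    chrom_sizes: Mapping[str, int] | None = None,
) -> list[RegionSignal]:
    """Coverage-weighted mean signal in [center-half, center+half) per region.

    Uncovered bases contribute 0; clipping at chromosome bounds shrinks the
    denominator to the in-bounds window length.
    """
    if half_window_bp < 1:
        raise ValueError("half_window_bp must be >= 1")
    out = []
    missing: set[str] = set()
    for region in regions:
        if region.chrom not in track.chroms:
            if region.chrom not in missing:
                missing.add(region.chrom)
                log.warning("chromosome %s absent from track; mean set to 0",
                            region.chrom)
            out.append(RegionSignal(region, 0.0))
            continue
        size = chrom_sizes.get(region.chrom) if chrom_sizes else None
        w0, w1 = _window(region, half_window_bp, size)
        mean = track.window_sum(region.chrom, w0, w1) / (w1 - w0)
        out.append(RegionSignal(region, float(mean)))
    return out


def aggregate_profile(
    track: SignalTrack,
    regions: Sequence[GenomicRegion],
    half_window_bp: int = 2500,
    bin_bp: int = 50,
) -> np.ndarray:
    """Mean signal per offset bin across region centers (aggregation plot).

    Returns an array of length 2*half_window_bp/bin_bp whose i-th entry is
    the across-region mean of the coverage-weighted signal in the bin at
    offset [-half + i*bin, -half + (i+1)*bin) from the center.
    """
    if (2 * half_window_bp) % bin_bp != 0:
        raise ValueError("bin_bp must divide the full window length")
    n_bins = 2 * half_window_bp // bin_bp
    sums = np.zeros(n_bins)
    denom = np.zeros(n_bins)
    for region in regions:
        center = region.center
        for i in range(n_bins):
            b0 = center - half_window_bp + i * bin_bp
            b1 = b0 + bin_bp
            lo = max(0, b0)
            if lo >= b1:
                continue
            if region.chrom in track.chroms:
                sums[i] += track.window_sum(region.chrom, lo, b1) / (b1 - lo)
            denom[i] += 1
    with np.errstate(invalid="ignore"):
        return np.where(denom > 0, sums / np.maximum(denom, 1), 0.0)


def detect_knee(signals: Sequence[float], tol: float = 1e-9) -> int | None:
    """Knee of the ranked-signal curve by the sliding-diagonal construction.

    Signals are sorted ascending to s_(1..n); the chord runs from
    (1, s_(1)) to (n, s_(n)); the knee is the 1-based rank maximizing the
    vertical gap chord - curve (ties resolved to the largest rank, giving
    the most conservative High set). Returns None when the maximal gap is
    <= tol, i.e. the curve is indistinguishable from its chord.
    """
    s = np.sort(np.asarray(signals, dtype=float))
    n = s.size
    if n < 3:
        raise ValueError(f"need at least 3 signals, got {n}")
    ranks = np.arange(1, n + 1)
    chord = s[0] + (s[-1] - s[0]) * (ranks - 1) / (n - 1)
    gaps = chord - s
    max_gap = gaps.max()
    if max_gap <= tol:
        return None
    # largest rank among ties
    k = int(n - 1 - np.argmax(gaps[::-1]))
    return k + 1


def classify_regions(
    region_signals: Sequence[RegionSignal],
    knee_index: int | None,
    low_threshold: float = 0.5,
) -> RankedClassification:
    """Label regions High (ranks above the knee), Low (below the signal
    threshold), or Mid. High takes precedence over Low."""
    ordered = sorted(region_signals, key=lambda rs: rs.mean_signal)
    n = len(ordered)
    labels = []
    for rank, rs in enumerate(ordered, start=1):
        if knee_index is not None and rank > knee_index:
            labels.append("High")
        elif rs.mean_signal < low_threshold:
            labels.append("Low")
        else:
            labels.append("Mid")
    return RankedClassification(ordered, knee_index, labels, low_threshold)


def enrichment_test(
    classification: RankedClassification,
    group: Sequence[GenomicRegion],
    class_label: str,
    group_name: str = "group",
    alpha: float = 0.05,
) -> EnrichmentResult:
    """Fisher enrichment of a region subset within a High/Low class."""
    labels = classification.label_of()
    group_keys = {r.key() for r in group}
    unknown = group_keys - set(labels)
    if unknown:
        raise ValueError(
            f"group regions absent from classification: {sorted(unknown)[:3]}"
        )
    n_total = len(labels)
    in_class = {k for k, lab in labels.items() if lab == class_label}
    a = len(group_keys & in_class)
    b = len(group_keys) - a
    c = len(in_class) - a
    d = n_total - a - b - c

    if not group_keys:
        log.warning("empty group %r", group_name)
        return EnrichmentResult(group_name, class_label, (0, 0, c, d),
                                math.nan, math.nan, 1.0, False)
    class_rate = len(in_class) / n_total if n_total else math.nan
    fold = (a / len(group_keys)) / class_rate if class_rate > 0 else math.nan
    res: FisherResult = fisher_exact([[a, b], [c, d]])
    return EnrichmentResult(
        group_name, class_label, (a, b, c, d), float(fold),
        res.odds_ratio, res.p, res.p < alpha,
    )
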