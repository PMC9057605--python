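"""Tile-based differential methylation calling and region-set overlap.

The genome is cut into fixed-width tiles (default 400 bp). Per tile and
condition, CpG counts passing a per-CpG coverage floor in every sample of
that condition are pooled, and tiles are tested for a methylation
difference with a two-sided Fisher exact test on the pooled 2x2 counts.
Calls require a minimum CpG number, a minimum absolute difference, a BH
FDR cut, and (optionally) direction-consistent replicates.
Hypermethylated regions (HMRs) are the calls with positive delta
(case above control).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .fisher import fisher_exact
from .io import GenomicRegion

__all__ = [
    "TileMethylation",
    "DmrCall",
    "VennCounts",
    "tile_genome",
    "pool_tile_counts",
    "test_tile",
    "call_dmrs",
    "overlap_sets",
    "dmr_calls_to_regions",
]

log = logging.getLogger(__name__)


@dataclass
class TileMethylation:
    """Pooled methylation counts for one tile.

    ``meth``/``total``/``n_cpg`` map condition -> pooled values over the
    eligible CpGs of that condition; ``replicate_fractions`` maps
    condition -> {sample: methylation fraction over the same CpGs}.
    """

    region: GenomicRegion
    meth: dict[str, int]
    total: dict[str, int]
    n_cpg: dict[str, int]
    replicate_fractions: dict[str, dict[str, float]]

    def fraction(self, condition: str) -> float:
        t = self.total.get(condition, 0)
        return self.meth.get(condition, 0) / t if t > 0 else np.nan


@dataclass
class DmrCall:
    tile: TileMethylation
    delta: float
    p: float
    q: float
    direction: str  # "hyper" | "hypo"

    @property
    def region(self) -> GenomicRegion:
        return self.tile.region


@dataclass(frozen=True)
class VennCounts:
    """Pairwise region-set overlap under the >= min_overlap_bp rule.

    ``a_and_b`` counts regions of A that overlap some region of B (and is
    therefore not symmetric in A and B when regions overlap unevenly).
    """

    a_only: int
    b_only: int
    a_and_b: int

    @property
    def overlap_fraction_a(self) -> float:
        n_a = self.a_only + self.a_and_b
        return self.a_and_b / n_a if n_a else np.nan


def tile_genome(
    chrom_sizes: Mapping[str, int], tile_bp: int = 400
) -> list[GenomicRegion]:
    """Adjacent non-overlapping tiles [k*tile_bp, (k+1)*tile_bp) per chromosome."""
    if tile_bp < 1:
        raise ValueError(f"tile_bp must be >= 1, got {tile_bp}")
    tiles = []
    for chrom, size in chrom_sizes.items():
        if size <= 0:
            raise ValueError(f"non-positive size for chromosome {chrom!r}")
        for start in range(0, size, tile_bp):
            tiles.append(GenomicRegion(chrom, start, min(start + tile_bp, size)))
    return tiles


def pool_tile_counts(
    cpgs: pd.DataFrame,
    tiles: Sequence[GenomicRegion],
    condition_map: Mapping[str, str],
    min_cov_per_cpg: int = 10,
) -> list[TileMethylation]:
    """Pool CpG counts into tiles, per condition.

    A CpG contributes to a condition only when its coverage reaches
    ``min_cov_per_cpg`` in *every* sample of that condition; a position
    missing from any sample of the condition fails the floor (coverage 0).
    """
    unknown = set(cpgs["sample"].unique()) - set(condition_map)
    if unknown:
        raise ValueError(f"samples absent from condition map: {sorted(unknown)}")
    conditions = sorted(set(condition_map.values()))
    samples_by_cond = {
        c: sorted(s for s, cc in condition_map.items() if cc == c) for c in conditions
    }

    # wide per-position layout: one row per (chrom, pos), columns per sample
    meth_w = cpgs.pivot_table(
        index=["chrom", "pos"], columns="sample", values="meth", aggfunc="sum"
    )
    tot_w = cpgs.pivot_table(
        index=["chrom", "pos"], columns="sample", values="total", aggfunc="sum"
    )

    out: list[TileMethylation] = []
    pos_by_chrom: dict[str, np.ndarray] = {}
    idx_by_chrom: dict[str, np.ndarray] = {}
    chrom_level = meth_w.index.get_level_values(0)
    positions = meth_w.index.get_level_values(1).to_numpy()
    for chrom in pd.unique(chrom_level):
        mask = (chrom_level == chrom).to_numpy() if hasattr(chrom_level == chrom, "to_numpy") else np.asarray(chrom_level == chrom)
        idx = np.nonzero(mask)[0]
        order = np.argsort(positions[idx], kind="stable")
        idx = idx[order]
        pos_by_chrom[chrom] = positions[idx]
        idx_by_chrom[chrom] = idx

    meth_arr = {s: meth_w[s].to_numpy() if s in meth_w else None for s in condition_map}
    tot_arr = {s: tot_w[s].to_numpy() if s in tot_w else None for s in condition_map}

    for tile in tiles:
        meth_c: dict[str, int] = {}
        tot_c: dict[str, int] = {}
        ncpg_c: dict[str, int] = {}
        reps: dict[str, dict[str, float]] = {}
        if tile.chrom in pos_by_chrom:
            pos = pos_by_chrom[tile.chrom]
            lo = int(np.searchsorted(pos, tile.start, side="left"))
            hi = int(np.searchsorted(pos, tile.end, side="left"))
            rows = idx_by_chrom[tile.chrom][lo:hi]
        else:
            rows = np.array([], dtype=int)
        for cond in conditions:
            samples = samples_by_cond[cond]
            if rows.size == 0 or not samples:
                meth_c[cond], tot_c[cond], ncpg_c[cond] = 0, 0, 0
                reps[cond] = {s: np.nan for s in samples}
                continue
            covs = np.vstack(
                [
                    np.nan_to_num(tot_arr[s][rows]) if tot_arr[s] is not None else np.zeros(rows.size)
                    for s in samples
                ]
            )
            eligible = (covs >= min_cov_per_cpg).all(axis=0)
            ncpg_c[cond] = int(eligible.sum())
            m_tot = t_tot = 0
            rep_frac: dict[str, float] = {}
            for k, s in enumerate(samples):
                m_s = (
                    np.nan_to_num(meth_arr[s][rows])[eligible].sum()
                    if meth_arr[s] is not None
                    else 0.0
                )
                t_s = covs[k][eligible].sum()
                m_tot += int(m_s)
                t_tot += int(t_s)
                rep_frac[s] = float(m_s / t_s) if t_s > 0 else np.nan
            meth_c[cond], tot_c[cond] = m_tot, t_tot
            reps[cond] = rep_frac
        out.append(TileMethylation(tile, meth_c, tot_c, ncpg_c, reps))
    return out


def test_tile(
    tile: TileMethylation, case: str, control: str
) -> tuple[float, float]:
    """Methylation difference (case - control) and two-sided Fisher p."""
    m1, t1 = tile.meth[case], tile.total[case]
    m0, t0 = tile.meth[control], tile.total[control]
    if t1 == 0 or t0 == 0:
        warnings.warn(
            f"tile {tile.region.key()} has zero coverage in a condition; skipped"
        )
        return np.nan, np.nan
    delta = m1 / t1 - m0 / t0
    res = fisher_exact([[m1, t1 - m1], [m0, t0 - m0]])
    return delta, res.p


def call_dmrs(
    tiles: Sequence[TileMethylation],
    case: str,
    control: str,
    min_cpg: int = 3,
    min_delta: float = 0.10,
    q_max: float = 0.01,
    require_replicate_consistency: bool = True,
) -> list[DmrCall]:
    """Call differentially methylated tiles for case vs control.

    BH adjustment runs over all eligible tiles (CpG floor met in both
    conditions, positive coverage); emitted calls additionally satisfy the
    delta, FDR, and replicate-sign filters. Hyper calls (delta > 0) form
    the HMR set of the case condition.
    """
    eligible: list[TileMethylation] = []
    stats: list[tuple[float, float]] = []
    for tile in tiles:
        if min(tile.n_cpg.get(case, 0), tile.n_cpg.get(control, 0)) < min_cpg:
            continue
        if tile.total.get(case, 0) == 0 or tile.total.get(control, 0) == 0:
            continue
        delta, p = test_tile(tile, case, control)
        if np.isnan(p):
            continue
        eligible.append(tile)
        stats.append((delta, p))
    if not eligible:
        log.warning("no eligible tiles for %s vs %s", case, control)
        return []

    pvals = np.array([p for _, p in stats])
    qvals = multipletests(pvals, method="fdr_bh")[1]

    calls: list[DmrCall] = []
    for tile, (delta, p), q in zip(eligible, stats, qvals):
        if abs(delta) < min_delta or q > q_max or delta == 0:
            continue
        if require_replicate_consistency:
            case_f = [f for f in tile.replicate_fractions[case].values() if not np.isnan(f)]
            ctrl_f = [f for f in tile.replicate_fractions[control].values() if not np.isnan(f)]
            pair_deltas = [cf - kf for cf in case_f for kf in ctrl_f]
            if not pair_deltas or not all(d * delta > 0 for d in pair_deltas):
                continue
        calls.append(
            DmrCall(tile, float(delta), float(p), float(q),
                    "hyper" if delta > 0 else "hypo")
        )
    return calls


def dmr_calls_to_regions(calls: Sequence[DmrCall], direction: str | None = None
                         ) -> list[GenomicRegion]:
    return [
        GenomicRegion(c.region.chrom, c.region.start, c.region.end,
                      name=c.direction, score=round(100 * abs(c.delta)))
        for c in calls
        if direction is None or c.direction == direction
    ]


def _max_single_overlap(region: GenomicRegion, others: Sequence[GenomicRegion]) -> int:
    best = 0
    for o in others:
        if o.chrom != region.chrom:
            continue
        best = max(best, min(region.end, o.end) - max(region.start, o.start))
    return best


def overlap_sets(
    a: Sequence[GenomicRegion],
    b: Sequence[GenomicRegion],
    min_overlap_bp: int = 1,
) -> VennCounts:
    """Venn counts: a region overlaps when >= min_overlap_bp bases intersect
    a single region of the other set."""
    by_chrom_b: dict[str, list[GenomicRegion]] = {}
    for r in b:
        by_chrom_b.setdefault(r.chrom, []).append(r)
    by_chrom_a: dict[str, list[GenomicRegion]] = {}
    for r in a:
        by_chrom_a.setdefault(r.chrom, []).append(r)

    def count_hits(queries, targets_by_chrom):
        hits = 0
        for r in queries:
            cands = targets_by_chrom.get(r.chrom, [])
            # restrict to candidates that could overlap
            near = [o for o in cands if o.start < r.end and o.end > r.start]
            if near and _max_single_overlap(r, near) >= min_overlap_bp:
                hits += 1
        return hits

    a_hits = count_hits(a, by_chrom_b)
    b_hits = count_hits(b, by_chrom_a)
    return VennCounts(a_only=len(a) - a_hits, b_only=len(b) - b_hits, a_and_b=a_hits)
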