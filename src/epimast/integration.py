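"""Crossing the methylation and expression layers.

Promoter methylation is the unweighted mean of methylation signals in a
TSS +/- 1 kb window (symmetric, strand-ignored), binned either into the
four quartile bins Low/MidLow/MidHigh/High of [0, 1] or into a
hyper/hypo/stable category by a 20-point absolute difference between
conditions; DE status is then cross-tabulated against either
categorization. Regions are associated to genes by nearest TSS within a
distance cutoff (a deliberately simple surrogate for regulatory-domain
association tools).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .expression import DETable
from .io import GenomicRegion

__all__ = [
    "PromoterMethylation",
    "GeneRegionAssociation",
    "promoter_methylation",
    "quartile_bin",
    "delta_category",
    "cross_tabulate",
    "associate_regions_to_genes",
]

log = logging.getLogger(__name__)

QUARTILE_BINS = ("Low", "MidLow", "MidHigh", "High")
DE_STATUSES = ("up", "down", "ns")
DELTA_CATEGORIES = ("hyper", "hypo", "stable")


@dataclass(frozen=True)
class PromoterMethylation:
    gene: str
    mean_by_condition: dict[str, float]  # fractions in [0, 1]


@dataclass(frozen=True)
class GeneRegionAssociation:
    region: GenomicRegion
    gene: str | None
    distance: int | None  # |region center - TSS|
    promoter: bool  # region overlaps TSS +/- 1 kb


def promoter_methylation(
    signals: pd.DataFrame,
    tss: pd.DataFrame,
    window_bp: int = 1000,
) -> list[PromoterMethylation]:
    """Mean methylation per gene promoter and condition.

    ``signals`` has columns chrom, pos, condition, value (fractions in
    [0, 1]; for binned input pass the bin center as pos). A signal counts
    when pos lies in [tss - window, tss + window). Genes with no signal in
    any condition are excluded (and counted in the log).
    """
    bad = signals[(signals["value"] < 0) | (signals["value"] > 1)]
    if len(bad):
        raise ValueError("methylation values must lie in [0, 1]")
    out = []
    excluded = 0
    by_chrom = {c: g.sort_values("pos") for c, g in signals.groupby("chrom")}
    for row in tss.itertuples(index=False):
        sub = by_chrom.get(row.chrom)
        means: dict[str, float] = {}
        if sub is not None:
            pos = sub["pos"].to_numpy()
            lo = np.searchsorted(pos, row.tss - window_bp, side="left")
            hi = np.searchsorted(pos, row.tss + window_bp, side="left")
            window = sub.iloc[lo:hi]
            means = window.groupby("condition")["value"].mean().to_dict()
        if means:
            out.append(PromoterMethylation(row.gene, means))
        else:
            excluded += 1
    if excluded:
        log.info("promoter_methylation: %d genes had no signal and were excluded",
                 excluded)
    return out


def quartile_bin(value: float) -> str:
    """Quartile bin of [0, 1]: left-closed right-open, last bin closed."""
    if not 0.0 <= value <= 1.0:
        raise ValueError(f"methylation value outside [0, 1]: {value}")
    if value < 0.25:
        return "Low"
    if value < 0.5:
        return "MidLow"
    if value < 0.75:
        return "MidHigh"
    return "High"


def delta_category(meth_case: float, meth_control: float,
                   threshold: float = 0.20) -> str:
    """hyper when case - control >= +threshold, hypo when <= -threshold."""
    for v in (meth_case, meth_control):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"methylation value outside [0, 1]: {v}")
    delta = meth_case - meth_control
    eps = 1e-9  # guards the boundary against float round-off (0.7 - 0.5)
    if delta >= threshold - eps:
        return "hyper"
    if delta <= -threshold + eps:
        return "hypo"
    return "stable"


def cross_tabulate(
    de: DETable,
    meth_categories: dict[str, str],
    categories: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Contingency table of DE status x methylation category.

    ``meth_categories`` maps gene -> category (quartile bin or delta
    category). Genes absent from either layer are discarded; the
    intersection size is logged. Rows are DE statuses, columns categories.
    """
    genes = [g for g in de.table.index if g in meth_categories]
    if not genes:
        raise ValueError("no genes shared between DE table and methylation")
    log.info("cross_tabulate: %d shared genes (%d DE, %d methylation)",
             len(genes), len(de.table), len(meth_categories))
    if categories is None:
        categories = sorted(set(meth_categories[g] for g in genes))
    table = pd.DataFrame(0, index=list(DE_STATUSES), columns=list(categories))
    for g in genes:
        cat = meth_categories[g]
        if cat in table.columns:
            table.loc[de.table.loc[g, "status"], cat] += 1
    return table


def associate_regions_to_genes(
    regions: Sequence[GenomicRegion],
    tss: pd.DataFrame,
    max_dist_bp: int = 50_000,
    promoter_bp: int = 1000,
) -> list[GeneRegionAssociation]:
    """Nearest-TSS association within max_dist_bp; ties go to the smaller
    gene id; the promoter flag marks overlap with TSS +/- promoter_bp."""
    if tss.empty:
        raise ValueError("TSS table is empty")
    by_chrom = {}
    for chrom, grp in tss.groupby("chrom"):
        grp = grp.sort_values(["tss", "gene"])
        by_chrom[chrom] = (grp["tss"].to_numpy(), grp["gene"].to_numpy())
    out = []
    for region in regions:
        if region.chrom not in by_chrom:
            out.append(GeneRegionAssociation(region, None, None, False))
            continue
        pos, genes = by_chrom[region.chrom]
        center = region.center
        dists = np.abs(pos - center)
        best = dists.min()
        if best > max_dist_bp:
            out.append(GeneRegionAssociation(region, None, None, False))
            continue
        tied = np.nonzero(dists == best)[0]
        pick = min(tied, key=lambda i: str(genes[i]))
        gene_tss = int(pos[pick])
        promoter = region.start < gene_tss + promoter_bp and region.end > gene_tss - promoter_bp
        out.append(
            GeneRegionAssociation(region, str(genes[pick]), int(best), bool(promoter))
        )
    return out
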