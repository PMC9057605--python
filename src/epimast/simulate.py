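"""Synthetic multi-omics data with the structure the pipeline assumes.

The generator emits, from one seed:

* beta-binomially dispersed CpG methylation counts for a control genotype
  and case genotypes carrying planted hypermethylated tile sets with a
  controlled pairwise overlap (shared tiles are chosen constructively,
  not by rejection);
* a piecewise-constant H3K27ac-like track whose heavy right tail
  ("super-enhancers") is co-localized with a chosen HMR set;
* an NB-distributed expression matrix with planted DE genes, a curated
  activation-gene list split into concordant and mutant-repressed groups,
  and a TSS table that couples a fraction of the repressed genes to
  promoter-spanning HMR blocks of the mutant genotype.

Ground truth (planted sets) always accompanies the data so tests can
score recovery; the pipeline itself never reads the truth.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import (
    CountsMatrix,
    GenomicRegion,
    SignalTrack,
    write_bedgraph,
    write_cpg_table,
    write_regions_bed,
    write_tss_table,
)
from .methylation import tile_genome

__all__ = [
    "SimulationDesign",
    "simulate_methylation",
    "simulate_chip_track",
    "simulate_expression",
    "simulate_all",
]

log = logging.getLogger(__name__)

PROMOTER_BLOCK_TILES = 5  # planted promoter HMRs span 5 tiles (~2 kb)


@dataclass
class SimulationDesign:
    """All knobs of the coupled simulation; one seed fixes every draw.

    The default genome is one chromosome of 2,900 x 400 bp tiles with
    planted hypermethylated sets of 139 (tet2ko) and 106 (tet2kit) tiles
    overlapping at 46% — the study's scale reduced twenty-fold.
    """

    seed: int = 1
    # genome / methylation
    chrom: str = "chr1"
    n_tiles: int = 2900
    tile_bp: int = 400
    n_cpg_per_tile: int = 20
    coverage_mean: float = 30.0
    baseline_meth: float = 0.30
    effect: float = 0.30
    bb_precision: float = 60.0
    n_replicates: int = 2
    control_condition: str = "wt"
    hmr_sizes: dict[str, int] = field(
        default_factory=lambda: {"kit": 0, "tet2ko": 139, "tet2kit": 106}
    )
    overlap_pair: tuple[str, str] = ("tet2ko", "tet2kit")
    overlap_target: float = 0.46
    # ChIP track
    chip_background_level: float = 0.2
    se_width_bp: int = 2000
    se_amplitude: float = 30.0
    se_amplitude_sigma: float = 0.1
    se_coupled_condition: str = "tet2ko"
    se_coupled_fraction: float = 0.8
    n_extra_se: int = 5
    # expression
    n_genes: int = 2000
    expr_conditions: tuple[str, ...] = ("wt", "kit", "tet2kit")
    mutant_condition: str = "tet2kit"
    n_reps_expr: int = 2
    expr_base_log_mean: float = float(np.log(100.0))
    expr_base_log_sd: float = 2.0  # heavy-tailed means: stable genes carry
    # most of the library mass, as in real transcriptomes
    library_log_sd: float = 0.1
    constant_dispersion: float | None = None
    dispersion_asymptote: float = 0.02
    dispersion_slope: float = 3.0
    n_de: int = 150
    de_log2fc: float = 2.0
    de_up_fraction: float = 0.5
    de_fixed_base_mean: float | None = None
    n_concordant: int = 31
    n_repressed: int = 17
    curated_mean: float = 1000.0
    curated_log2fc: float = 2.0
    promoter_coupling_fraction: float = 0.5

    @property
    def chrom_size(self) -> int:
        return self.n_tiles * self.tile_bp

    @property
    def meth_conditions(self) -> list[str]:
        return [self.control_condition] + list(self.hmr_sizes)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["overlap_pair"] = list(self.overlap_pair)
        d["expr_conditions"] = list(self.expr_conditions)
        return d


def _tile_region(design: SimulationDesign, index: int) -> GenomicRegion:
    start = index * design.tile_bp
    return GenomicRegion(design.chrom, start,
                         min(start + design.tile_bp, design.chrom_size))


def _plant_hmr_tiles(design: SimulationDesign, rng: np.random.Generator
                     ) -> tuple[dict[str, np.ndarray], np.ndarray]:
    """Choose planted tile indices per genotype; shared tiles first.

    Returns (genotype -> sorted tile indices, promoter block center tiles).
    Promoter blocks (PROMOTER_BLOCK_TILES adjacent tiles each) are carved
    out of the mutant genotype's exclusive budget so set sizes stay exact.
    """
    sizes = design.hmr_sizes
    g1, g2 = design.overlap_pair
    n1, n2 = sizes.get(g1, 0), sizes.get(g2, 0)
    n_shared = int(round(design.overlap_target * n1)) if n1 and n2 else 0
    n_shared = min(n_shared, n1, n2)

    n_blocks = 0
    if (design.promoter_coupling_fraction > 0 and design.n_repressed > 0
            and design.mutant_condition in sizes):
        n_blocks = int(round(design.promoter_coupling_fraction * design.n_repressed))
        exclusive_budget = sizes[design.mutant_condition] - (
            n_shared if design.mutant_condition == g2 else 0
        )
        if n_blocks * PROMOTER_BLOCK_TILES > exclusive_budget:
            raise ValueError(
                "promoter blocks exceed the mutant genotype's exclusive HMR budget"
            )

    occupied: set[int] = set()

    def draw(n: int) -> list[int]:
        picked: list[int] = []
        while len(picked) < n:
            cand = int(rng.integers(0, design.n_tiles))
            if cand not in occupied:
                occupied.add(cand)
                picked.append(cand)
        return picked

    # promoter blocks: runs of adjacent tiles for the mutant genotype
    block_centers: list[int] = []
    half = PROMOTER_BLOCK_TILES // 2
    while len(block_centers) < n_blocks:
        c = int(rng.integers(half, design.n_tiles - half))
        block = range(c - half, c + half + 1)
        if all(t not in occupied for t in block):
            occupied.update(block)
            block_centers.append(c)

    shared = draw(n_shared)
    planted: dict[str, list[int]] = {}
    for genotype, size in sizes.items():
        tiles = []
        if genotype in (g1, g2):
            tiles += shared
        if genotype == design.mutant_condition:
            for c in block_centers:
                tiles += list(range(c - half, c + half + 1))
        remaining = size - len(tiles)
        if remaining < 0:
            raise ValueError(f"HMR budget exceeded for {genotype}")
        tiles += draw(remaining)
        planted[genotype] = tiles
    return (
        {g: np.sort(np.array(t, dtype=int)) for g, t in planted.items()},
        np.array(sorted(block_centers), dtype=int),
    )


def simulate_methylation(
    design: SimulationDesign, rng: np.random.Generator
) -> tuple[pd.DataFrame, dict[str, list[GenomicRegion]], dict[str, str], np.ndarray]:
    """Beta-binomial CpG counts per sample plus planted-HMR ground truth.

    Per CpG and sample, methylated ~ Binomial(coverage, pi) with
    pi ~ Beta centered at the baseline (baseline + effect inside that
    genotype's planted tiles) at the design precision; replicates share
    centers. Returns (CpG table, truth regions per genotype,
    sample -> condition map, promoter block center tiles).
    """
    planted, block_centers = _plant_hmr_tiles(design, rng)

    n_pos = design.n_tiles * design.n_cpg_per_tile
    offsets = ((np.arange(design.n_cpg_per_tile) + 0.5)
               * design.tile_bp / design.n_cpg_per_tile).astype(int)
    positions = (np.repeat(np.arange(design.n_tiles), design.n_cpg_per_tile)
                 * design.tile_bp + np.tile(offsets, design.n_tiles))
    tile_of = np.repeat(np.arange(design.n_tiles), design.n_cpg_per_tile)

    lo, hi = 1e-3, 1 - 1e-3
    frames = []
    condition_map: dict[str, str] = {}
    for genotype in design.meth_conditions:
        centers = np.full(n_pos, design.baseline_meth)
        if genotype in planted and planted[genotype].size:
            in_set = np.isin(tile_of, planted[genotype])
            centers[in_set] += design.effect
        if centers.max() > hi or centers.min() < lo:
            log.warning("beta centers clipped to [%g, %g]", lo, hi)
            centers = np.clip(centers, lo, hi)
        a = centers * design.bb_precision
        b = (1 - centers) * design.bb_precision
        for rep in range(1, design.n_replicates + 1):
            sample = f"{genotype}_rep{rep}"
            condition_map[sample] = genotype
            pi = rng.beta(a, b)
            cov = rng.poisson(design.coverage_mean, size=n_pos)
            meth = rng.binomial(cov, pi)
            frames.append(pd.DataFrame({
                "chrom": design.chrom, "pos": positions,
                "sample": sample, "meth": meth, "total": cov,
            }))
    cpgs = pd.concat(frames, ignore_index=True)
    truth = {
        g: [_tile_region(design, int(t)) for t in tiles]
        for g, tiles in planted.items()
    }
    return cpgs, truth, condition_map, block_centers


def simulate_chip_track(
    design: SimulationDesign,
    hmr_truth: dict[str, list[GenomicRegion]],
    rng: np.random.Generator,
) -> tuple[SignalTrack, list[GenomicRegion]]:
    """Background track with super-enhancer intervals over a chosen HMR set.

    The designated fraction of the coupled HMR set is centered inside
    super-enhancers whose amplitudes follow a heavy-tailed (Pareto)
    distribution; overlapping super-enhancers are merged (max amplitude).
    Returns the track and the merged super-enhancer intervals.
    """
    values = np.full(design.chrom_size, design.chip_background_level)

    centers: list[int] = []
    coupled = hmr_truth.get(design.se_coupled_condition, [])
    if coupled:
        n_pick = int(round(design.se_coupled_fraction * len(coupled)))
        picked = rng.choice(len(coupled), size=n_pick, replace=False)
        centers += [coupled[int(i)].center for i in picked]
    for _ in range(design.n_extra_se):
        centers.append(int(rng.integers(0, design.chrom_size)))

    half = design.se_width_bp // 2
    raw = []
    for c in centers:
        amp = design.se_amplitude * rng.lognormal(0.0, design.se_amplitude_sigma)
        raw.append((max(0, c - half), min(design.chrom_size, c + half), amp))
    raw.sort()
    merged: list[list[float]] = []
    for s, e, amp in raw:
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
            merged[-1][2] = max(merged[-1][2], amp)
        else:
            merged.append([s, e, amp])
    for s, e, amp in merged:
        seg = slice(int(s), int(e))
        values[seg] = np.maximum(values[seg], amp)

    # compress per-base values into bedGraph runs
    change = np.nonzero(np.diff(values))[0] + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [design.chrom_size]))
    track = SignalTrack({design.chrom: (starts, ends, values[starts])})
    se_regions = [
        GenomicRegion(design.chrom, int(s), int(e), name="SE", score=float(amp))
        for s, e, amp in merged
    ]
    return track, se_regions


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, phi: np.ndarray
             ) -> np.ndarray:
    """NB2 draw with var = mean + phi * mean^2 (Poisson where phi ~ 0)."""
    out = np.empty(mean.shape, dtype=np.int64)
    poisson = phi < 1e-8
    if poisson.any():
        out[poisson] = rng.poisson(mean[poisson])
    if (~poisson).any():
        r = 1.0 / phi[~poisson]
        p = r / (r + mean[~poisson])
        out[~poisson] = rng.negative_binomial(r, p)
    return out


def simulate_expression(
    design: SimulationDesign, rng: np.random.Generator
) -> tuple[CountsMatrix, pd.DataFrame]:
    """NB counts with planted DE genes and the curated activation list.

    Returns the counts matrix and a per-gene truth table with columns:
    base_mean, dispersion, lfc_<condition> for every non-control
    condition, de (bool, shared planted program), curated_group
    ("Group1" / "Group2" / "").
    """
    n = design.n_genes
    genes = [f"g{i:05d}" for i in range(n)]
    conditions = list(design.expr_conditions)
    control = conditions[0]
    cases = conditions[1:]

    n_curated = design.n_concordant + design.n_repressed
    if n_curated + design.n_de > n:
        raise ValueError("more planted genes than genes in the design")

    base = rng.lognormal(design.expr_base_log_mean, design.expr_base_log_sd, n)
    curated_group = np.array([""] * n, dtype=object)
    curated_group[: design.n_concordant] = "Group1"
    curated_group[design.n_concordant: n_curated] = "Group2"
    base[:n_curated] = design.curated_mean * rng.lognormal(0.0, 0.2, n_curated)

    de = np.zeros(n, dtype=bool)
    de[n_curated: n_curated + design.n_de] = True
    if design.de_fixed_base_mean is not None:
        base[de] = design.de_fixed_base_mean
    sign = np.where(rng.random(n) < design.de_up_fraction, 1.0, -1.0)

    lfc = {c: np.zeros(n) for c in cases}
    for c in cases:
        lfc[c][de] = design.de_log2fc * sign[de]
        lfc[c][curated_group == "Group1"] = design.curated_log2fc
        if c == design.mutant_condition:
            lfc[c][curated_group == "Group2"] = -design.curated_log2fc
        else:
            lfc[c][curated_group == "Group2"] = design.curated_log2fc

    if design.constant_dispersion is not None:
        phi = np.full(n, design.constant_dispersion)
    else:
        phi = design.dispersion_asymptote + design.dispersion_slope / base

    counts = {}
    condition_map = {}
    for cond in conditions:
        mult = 2.0 ** lfc[cond] if cond in lfc else np.ones(n)
        for rep in range(1, design.n_reps_expr + 1):
            sample = f"{cond}_rep{rep}"
            condition_map[sample] = cond
            factor = rng.lognormal(0.0, design.library_log_sd)
            counts[sample] = _nb_draw(rng, base * mult * factor, phi)

    matrix = CountsMatrix(pd.DataFrame(counts, index=genes), condition_map)
    truth = pd.DataFrame({"base_mean": base, "dispersion": phi, "de": de,
                          "curated_group": curated_group}, index=genes)
    for c in cases:
        truth[f"lfc_{c}"] = lfc[c]
    return matrix, truth


def make_tss_table(
    design: SimulationDesign,
    expr_truth: pd.DataFrame,
    block_centers: np.ndarray,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """TSS per gene; coupled repressed genes sit on promoter HMR blocks."""
    genes = list(expr_truth.index)
    repressed = [g for g in genes if expr_truth.loc[g, "curated_group"] == "Group2"]
    tss_tile = {}
    used: set[int] = set(int(t) for t in block_centers)
    for g, center in zip(repressed, block_centers):
        tss_tile[g] = int(center)
    free = [t for t in range(design.n_tiles) if t not in used]
    order = rng.permutation(len(free))
    i = 0
    for g in genes:
        if g in tss_tile:
            continue
        # tiles are reused (round-robin) when genes outnumber free tiles
        tss_tile[g] = free[int(order[i % len(order)])]
        i += 1
    rows = []
    strands = rng.choice(["+", "-"], size=len(genes))
    for g, strand in zip(genes, strands):
        tile = tss_tile[g]
        rows.append((g, design.chrom, tile * design.tile_bp + design.tile_bp // 2,
                     strand))
    return pd.DataFrame(rows, columns=["gene", "chrom", "tss", "strand"])


def simulate_all(design: SimulationDesign, outdir: str | Path) -> dict:
    """Run the full coupled simulation and write every file.

    Emits the formats the pipeline consumes (CpG TSV, bedGraph, BED,
    counts TSV, condition maps, TSS TSV) plus truth files and a JSON
    manifest; returns the manifest dict.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(design.seed)

    cpgs, hmr_truth, meth_conditions, block_centers = simulate_methylation(design, rng)
    track, se_regions = simulate_chip_track(design, hmr_truth, rng)
    counts, expr_truth = simulate_expression(design, rng)
    tss = make_tss_table(design, expr_truth, block_centers, rng)

    write_cpg_table(cpgs, outdir / "cpg_counts.tsv")
    pd.Series(meth_conditions).rename_axis("sample").to_csv(
        outdir / "meth_conditions.tsv", sep="\t", header=False
    )
    write_bedgraph(track, outdir / "h3k27ac.bedgraph")
    counts.counts.rename_axis("gene").to_csv(outdir / "rna_counts.tsv", sep="\t")
    pd.Series(counts.conditions).rename_axis("sample").to_csv(
        outdir / "rna_conditions.tsv", sep="\t", header=False
    )
    write_tss_table(tss, outdir / "tss.tsv")
    for genotype, regions in hmr_truth.items():
        write_regions_bed(regions, outdir / f"truth_hmr_{genotype}.bed")
    write_regions_bed(se_regions, outdir / "truth_superenhancers.bed")
    expr_truth.rename_axis("gene").to_csv(outdir / "truth_expression.tsv", sep="\t")

    manifest = {
        "design": design.to_dict(),
        "files": sorted(p.name for p in outdir.iterdir()),
        "n_hmr_planted": {g: len(r) for g, r in hmr_truth.items()},
        "n_superenhancers": len(se_regions),
        "n_de_planted": int(expr_truth["de"].sum()),
        "curated": {
            "Group1": int((expr_truth["curated_group"] == "Group1").sum()),
            "Group2": int((expr_truth["curated_group"] == "Group2").sum()),
        },
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
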