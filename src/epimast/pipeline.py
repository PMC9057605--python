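"""End-to-end orchestration: simulate -> methylation -> ChIP -> expression
-> integration, with a YAML-configurable threshold set and a
machine-readable JSON report.

Every stage reads and writes plain-text files under the configured output
directory, so stages can also be run one at a time (see the CLI). The
report contains only seeds, thresholds, and computed counts — no paths or
timestamps — and is byte-identical across reruns with the same config.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import chip_signal, expression, integration, methylation
from .io import (
    read_bedgraph,
    read_condition_map,
    read_counts_matrix,
    read_cpg_table,
    read_regions_bed,
    read_tss_table,
    write_regions_bed,
)
from .simulate import SimulationDesign, simulate_all

__all__ = ["RunConfig", "ConfigError", "run_pipeline"]

log = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Invalid run configuration (unknown key, bad value)."""


@dataclass
class RunConfig:
    """All pipeline inputs, thresholds (paper defaults), and the seed."""

    seed: int = 1
    outdir: str = "results/pipeline"
    simulate: bool = True
    design: dict = field(default_factory=dict)  # SimulationDesign overrides
    inputs: dict = field(default_factory=dict)  # paths when simulate=False
    control_condition: str = "wt"
    mutant_condition: str = "tet2kit"
    other_condition: str = "kit"
    # methylation
    tile_bp: int = 400
    min_cov_per_cpg: int = 10
    min_cpg: int = 3
    min_delta: float = 0.10
    q_max: float = 0.01
    # ChIP
    half_window_bp: int = 2500
    low_threshold: float = 0.5
    alpha: float = 0.05
    # expression
    min_count: int = 10
    min_samples: int = 2
    q_max_de: float = 0.05
    min_abs_log2fc: float = 1.0
    n_top: int = 500
    # integration
    window_bp: int = 1000
    max_dist_bp: int = 50_000
    delta_threshold: float = 0.20

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @property
    def data_dir(self) -> Path:
        return Path(self.outdir) / "data"


def _load_data(config: RunConfig) -> dict:
    d = config.data_dir
    paths = {
        "cpg": d / "cpg_counts.tsv",
        "meth_conditions": d / "meth_conditions.tsv",
        "bedgraph": d / "h3k27ac.bedgraph",
        "rna_counts": d / "rna_counts.tsv",
        "rna_conditions": d / "rna_conditions.tsv",
        "tss": d / "tss.tsv",
        "curated": d / "curated_genes.txt",
    }
    paths.update({k: Path(v) for k, v in config.inputs.items()})
    missing = [str(p) for p in paths.values() if not p.exists()]
    if missing:
        raise FileNotFoundError(f"missing input file(s): {missing}")
    return paths


def stage_simulate(config: RunConfig) -> dict:
    design = SimulationDesign(**{"seed": config.seed, **config.design})
    manifest = simulate_all(design, config.data_dir)
    # curated gene list: ids only — a pipeline input, unlike the truth files
    truth = pd.read_csv(config.data_dir / "truth_expression.tsv", sep="\t",
                        index_col=0)
    curated = truth.index[truth["curated_group"].fillna("") != ""]
    (config.data_dir / "curated_genes.txt").write_text(
        "".join(f"{g}\n" for g in curated)
    )
    return {
        "n_hmr_planted": manifest["n_hmr_planted"],
        "n_superenhancers": manifest["n_superenhancers"],
        "n_de_planted": manifest["n_de_planted"],
    }


def stage_dmr(config: RunConfig) -> dict:
    paths = _load_data(config)
    outdir = Path(config.outdir)
    cpgs = read_cpg_table(paths["cpg"])
    condition_map = read_condition_map(paths["meth_conditions"])
    chrom_sizes = {
        chrom: (int(grp["pos"].max()) // config.tile_bp + 1) * config.tile_bp
        for chrom, grp in cpgs.groupby("chrom")
    }
    tiles = methylation.tile_genome(chrom_sizes, config.tile_bp)
    pooled = methylation.pool_tile_counts(
        cpgs, tiles, condition_map, config.min_cov_per_cpg
    )
    control = config.control_condition
    genotypes = sorted(set(condition_map.values()) - {control})
    report: dict = {"n_tiles": len(tiles), "hmr_counts": {}, "dmr_counts": {}}
    hmr_sets = {}
    for genotype in genotypes:
        calls = methylation.call_dmrs(
            pooled, genotype, control,
            min_cpg=config.min_cpg, min_delta=config.min_delta,
            q_max=config.q_max,
        )
        hmrs = methylation.dmr_calls_to_regions(calls, "hyper")
        hmr_sets[genotype] = hmrs
        report["dmr_counts"][genotype] = len(calls)
        report["hmr_counts"][genotype] = len(hmrs)
        write_regions_bed(hmrs, outdir / f"hmr_{genotype}.bed")
        pd.DataFrame(
            [
                {
                    "chrom": c.region.chrom, "start": c.region.start,
                    "end": c.region.end, "direction": c.direction,
                    "delta": c.delta, "p": c.p, "q": c.q,
                }
                for c in calls
            ]
        ).to_csv(outdir / f"dmr_{genotype}.tsv", sep="\t", index=False)

    # pairwise overlap of the two largest HMR sets (1 bp rule)
    ranked = sorted(hmr_sets, key=lambda g: -len(hmr_sets[g]))
    if len(ranked) >= 2:
        a, b = ranked[0], ranked[1]
        venn = methylation.overlap_sets(hmr_sets[a], hmr_sets[b])
        report["venn"] = {
            "set_a": a, "set_b": b,
            "a_only": venn.a_only, "b_only": venn.b_only,
            "a_and_b": venn.a_and_b,
            "overlap_fraction_a": round(venn.overlap_fraction_a, 4),
        }
        with open(outdir / "venn.json", "w") as fh:
            json.dump(report["venn"], fh, indent=2, sort_keys=True)
    return report


def stage_chip(config: RunConfig) -> dict:
    paths = _load_data(config)
    outdir = Path(config.outdir)
    track = read_bedgraph(paths["bedgraph"])
    condition_map = read_condition_map(paths["meth_conditions"])
    genotypes = sorted(set(condition_map.values()) - {config.control_condition})
    hmr_sets = {}
    for genotype in genotypes:
        bed = outdir / f"hmr_{genotype}.bed"
        if bed.exists():
            hmr_sets[genotype] = read_regions_bed(bed)
    universe_keys = {}
    for genotype, regions in sorted(hmr_sets.items()):
        for r in regions:
            universe_keys.setdefault(r.key(), r)
    universe = list(universe_keys.values())
    report: dict = {"n_ranked_regions": len(universe)}
    if len(universe) < 3:
        log.warning("fewer than 3 HMRs; skipping ranked classification")
        return report

    signals = chip_signal.region_signal(track, universe, config.half_window_bp)
    knee = chip_signal.detect_knee([s.mean_signal for s in signals])
    classified = chip_signal.classify_regions(signals, knee, config.low_threshold)
    report["knee_index"] = knee
    report["n_high"] = classified.labels.count("High")
    report["n_low"] = classified.labels.count("Low")
    report["n_mid"] = classified.labels.count("Mid")

    rows = []
    report["enrichment"] = {}
    for genotype in sorted(hmr_sets):
        group = [r for r in hmr_sets[genotype]]
        for label in ("High", "Low"):
            res = chip_signal.enrichment_test(
                classified, group, label, group_name=genotype, alpha=config.alpha
            )
            rows.append({
                "group": genotype, "class": label,
                "a": res.table[0], "b": res.table[1],
                "c": res.table[2], "d": res.table[3],
                "fold": res.fold_enrichment, "odds_ratio": res.odds_ratio,
                "p": res.p, "significant": res.significant,
            })
            fold = res.fold_enrichment
            report["enrichment"][f"{genotype}:{label}"] = {
                "fold": None if pd.isna(fold) else round(fold, 4),
                "p": float(f"{res.p:.6g}"),
                "significant": res.significant,
            }
    pd.DataFrame(rows).to_csv(outdir / "enrichment.tsv", sep="\t", index=False)

    bed = [
        dataclasses.replace(rs.region, name=label, score=round(rs.mean_signal, 4))
        for rs, label in zip(classified.signals, classified.labels)
    ]
    write_regions_bed(bed, outdir / "classification.bed")

    profile = chip_signal.aggregate_profile(
        track, universe, config.half_window_bp, bin_bp=50
    )
    pd.DataFrame({
        "offset": range(-config.half_window_bp, config.half_window_bp, 50),
        "mean_signal": profile,
    }).to_csv(outdir / "profile_hmr.tsv", sep="\t", index=False)
    return report


def stage_de(config: RunConfig) -> dict:
    paths = _load_data(config)
    outdir = Path(config.outdir)
    condition_map = read_condition_map(paths["rna_conditions"])
    counts = read_counts_matrix(paths["rna_counts"], condition_map)
    n_before = len(counts.genes)
    filtered = expression.filter_low_expression(
        counts, config.min_count, config.min_samples
    )
    report: dict = {
        "n_genes_total": n_before,
        "n_genes_kept": len(filtered.genes),
        "pct_genes_kept": round(100.0 * len(filtered.genes) / n_before, 2),
    }
    cpm = expression.normalize_library_size(filtered)
    disp = expression.estimate_dispersion(filtered)
    report["common_dispersion"] = round(disp.common, 4)

    control = config.control_condition
    conditions = sorted(set(condition_map.values()))
    contrasts = [(c, control) for c in conditions if c != control]
    if (config.mutant_condition in conditions
            and config.other_condition in conditions):
        contrasts.append((config.mutant_condition, config.other_condition))
    report["de_counts"] = {}
    for case, ctrl in contrasts:
        de = expression.test_de(
            filtered, case, ctrl, disp,
            q_max=config.q_max_de, min_abs_log2fc=config.min_abs_log2fc,
        )
        de.table.rename_axis("gene").to_csv(
            outdir / f"de_{case}_vs_{ctrl}.tsv", sep="\t"
        )
        report["de_counts"][f"{case}_vs_{ctrl}"] = {
            "up": de.n_status("up"), "down": de.n_status("down"),
        }

    z = expression.top_variance_zscore(cpm, config.n_top)
    z.rename_axis("gene").to_csv(outdir / "zscores_top_variance.tsv", sep="\t")
    report["n_zscore_genes"] = len(z)

    curated = [
        line.strip() for line in Path(paths["curated"]).read_text().splitlines()
        if line.strip()
    ]
    if curated:
        de_case = _read_de_table(outdir, config.mutant_condition, control, config)
        de_other = _read_de_table(outdir, config.other_condition, control, config)
        grouping = expression.group_activation_genes(de_case, de_other, curated)
        grouping.assignments.to_csv(
            outdir / "activation_groups.tsv", sep="\t", index=False
        )
        counts_by_group = grouping.counts()
        pct = grouping.percentages()
        report["activation_groups"] = {
            g: {"n": counts_by_group.get(g, 0), "pct": round(pct.get(g, 0.0), 1)}
            for g in ("Group1", "Group2", "unclassified")
        }
    return report


def _read_de_table(outdir: Path, case: str, control: str,
                   config: RunConfig) -> expression.DETable:
    df = pd.read_csv(outdir / f"de_{case}_vs_{control}.tsv", sep="\t",
                     index_col="gene")
    return expression.DETable(df, config.q_max_de, config.min_abs_log2fc,
                              case, control)


def stage_integrate(config: RunConfig) -> dict:
    paths = _load_data(config)
    outdir = Path(config.outdir)
    cpgs = read_cpg_table(paths["cpg"])
    condition_map = read_condition_map(paths["meth_conditions"])
    tss = read_tss_table(paths["tss"])

    case, other = config.mutant_condition, config.other_condition
    signals = integration_signals(cpgs, condition_map, [case, other])
    promoters = integration.promoter_methylation(signals, tss, config.window_bp)

    de = _read_de_table(outdir, case, other, config)
    quartiles = {}
    deltas = {}
    for pm in promoters:
        if case in pm.mean_by_condition:
            quartiles[pm.gene] = integration.quartile_bin(
                pm.mean_by_condition[case]
            )
        if case in pm.mean_by_condition and other in pm.mean_by_condition:
            deltas[pm.gene] = integration.delta_category(
                pm.mean_by_condition[case], pm.mean_by_condition[other],
                config.delta_threshold,
            )
    report: dict = {"n_promoters": len(promoters)}
    tab_q = integration.cross_tabulate(de, quartiles,
                                       integration.QUARTILE_BINS)
    tab_d = integration.cross_tabulate(de, deltas,
                                       integration.DELTA_CATEGORIES)
    tab_q.rename_axis("status").to_csv(outdir / "crosstab_quartile.tsv", sep="\t")
    tab_d.rename_axis("status").to_csv(outdir / "crosstab_delta.tsv", sep="\t")
    report["crosstab_quartile"] = {
        s: {c: int(tab_q.loc[s, c]) for c in tab_q.columns} for s in tab_q.index
    }
    report["crosstab_delta"] = {
        s: {c: int(tab_d.loc[s, c]) for c in tab_d.columns} for s in tab_d.index
    }

    hmr_bed = outdir / f"hmr_{case}.bed"
    if hmr_bed.exists():
        assoc = integration.associate_regions_to_genes(
            read_regions_bed(hmr_bed), tss, config.max_dist_bp
        )
        pd.DataFrame(
            [
                {
                    "chrom": a.region.chrom, "start": a.region.start,
                    "end": a.region.end, "gene": a.gene or "",
                    "distance": a.distance if a.distance is not None else "",
                    "promoter": a.promoter,
                }
                for a in assoc
            ]
        ).to_csv(outdir / "hmr_gene_associations.tsv", sep="\t", index=False)
        report["n_hmr_associated"] = sum(1 for a in assoc if a.gene)
        report["n_hmr_promoter"] = sum(1 for a in assoc if a.promoter)
    return report


def integration_signals(cpgs: pd.DataFrame, condition_map: dict,
                        conditions: list[str]) -> pd.DataFrame:
    """Pooled per-CpG methylation fraction per condition (long layout)."""
    df = cpgs.copy()
    df["condition"] = df["sample"].map(condition_map)
    df = df[df["condition"].isin(conditions)]
    grouped = df.groupby(["chrom", "pos", "condition"])[["meth", "total"]].sum()
    grouped = grouped[grouped["total"] > 0]
    out = (grouped["meth"] / grouped["total"]).rename("value").reset_index()
    return out


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage and write a deterministic JSON report."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "seed": config.seed,
        "thresholds": {
            k: getattr(config, k)
            for k in (
                "tile_bp", "min_cov_per_cpg", "min_cpg", "min_delta", "q_max",
                "half_window_bp", "low_threshold", "alpha", "min_count",
                "min_samples", "q_max_de", "min_abs_log2fc", "n_top",
                "window_bp", "max_dist_bp", "delta_threshold",
            )
        },
    }
    if config.simulate:
        report["simulate"] = stage_simulate(config)
    report["methylation"] = stage_dmr(config)
    report["chip"] = stage_chip(config)
    report["expression"] = stage_de(config)
    report["integration"] = stage_integrate(config)
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return report
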