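import numpy as np
import pandas as pd
import pytest
from scipy import stats

from epimast.expression import (
    DETable,
    DispersionEstimate,
    estimate_dispersion,
    filter_low_expression,
    group_activation_genes,
    normalize_library_size,
    test_de as nb_lrt_test,
    top_variance_zscore,
)
from epimast.io import CountsMatrix
from epimast.simulate import SimulationDesign, simulate_expression


def two_condition_design(**kwargs):
    base = dict(
        n_genes=2000, expr_conditions=("control", "case"),
        mutant_condition="case", n_reps_expr=4, constant_dispersion=0.1,
        n_de=0, n_concordant=0, n_repressed=0, promoter_coupling_fraction=0,
    )
    base.update(kwargs)
    return SimulationDesign(**base)


def simulate_counts(design):
    return simulate_expression(design, np.random.default_rng(design.seed))


class TestFilterLowExpression:
    def _cm(self, rows):
        df = pd.DataFrame(rows, columns=["s1", "s2", "s3", "s4"])
        df.index = [f"g{i}" for i in range(len(df))]
        return CountsMatrix(df, {s: "A" for s in df.columns})

    def test_threshold_rule(self):
        cm = self._cm([[10, 10, 0, 0], [9, 20, 0, 0]])
        kept = filter_low_expression(cm)
        assert list(kept.genes) == ["g0"]

    def test_idempotent(self):
        rng = np.random.default_rng(1)
        cm = self._cm(rng.poisson(8, size=(50, 4)))
        once = filter_low_expression(cm)
        twice = filter_low_expression(once)
        assert once.counts.equals(twice.counts)

    def test_printed_bookkeeping_fractions(self):
        """23,420 genes with 11,821 failing leaves 11,599 (about 49%)."""
        n_total, n_fail = 23_420, 11_821
        fail = np.zeros((n_fail, 4), dtype=int)
        fail[:, 0] = 100  # high in one sample only: still fails
        keep = np.full((n_total - n_fail, 4), 10, dtype=int)
        df = pd.DataFrame(np.vstack([fail, keep]),
                          columns=["s1", "s2", "s3", "s4"])
        df.index = [f"g{i}" for i in range(n_total)]
        cm = CountsMatrix(df, {s: "A" for s in df.columns})
        kept = filter_low_expression(cm)
        assert len(kept.genes) == 11_599
        assert round(100 * len(kept.genes) / n_total) == 50  # 49.52%


class TestNormalizeLibrarySize:
    def test_cpm_arithmetic(self, small_counts):
        cpm = normalize_library_size(small_counts)
        assert np.allclose(cpm.sum(axis=0), 1e6)

    def test_scale_invariance(self, small_counts):
        doubled = CountsMatrix(small_counts.counts * 2,
                               dict(small_counts.conditions))
        assert np.allclose(normalize_library_size(small_counts),
                           normalize_library_size(doubled))

    def test_zero_library_rejected(self):
        df = pd.DataFrame({"s1": [0, 0], "s2": [1, 2]}, index=["g0", "g1"])
        cm = CountsMatrix(df, {"s1": "A", "s2": "A"})
        with pytest.raises(ValueError, match="s1"):
            normalize_library_size(cm)


class TestEstimateDispersion:
    def test_poisson_counts_give_near_zero_common(self):
        counts, _ = simulate_counts(
            two_condition_design(seed=1, n_reps_expr=3, constant_dispersion=0.0)
        )
        est = estimate_dispersion(filter_low_expression(counts))
        assert est.common <= 0.05

    def test_nb_dispersion_recovered(self):
        counts, _ = simulate_counts(
            two_condition_design(seed=1, n_reps_expr=6, constant_dispersion=0.2)
        )
        est = estimate_dispersion(filter_low_expression(counts))
        assert 0.1 <= est.common <= 0.3

    def test_constant_gene_has_zero_dispersion(self):
        df = pd.DataFrame({s: [5, 100] for s in ["s1", "s2", "s3"]},
                          index=["flat", "alsoflat"])
        cm = CountsMatrix(df, {s: "A" for s in df.columns})
        est = estimate_dispersion(cm)
        assert (est.per_gene == 0).all()

    def test_single_replicate_condition_rejected(self):
        df = pd.DataFrame({"s1": [5], "s2": [9]}, index=["g"])
        cm = CountsMatrix(df, {"s1": "A", "s2": "B"})
        with pytest.raises(ValueError):
            estimate_dispersion(cm)

    def test_fixed_weight_shrink_lies_between(self):
        counts, _ = simulate_counts(two_condition_design(seed=2))
        est = estimate_dispersion(filter_low_expression(counts),
                                  shrink_weight=0.5)
        lo = np.minimum(est.per_gene, est.common)
        hi = np.maximum(est.per_gene, est.common)
        ok = np.isfinite(est.per_gene)
        assert ((est.shrunken[ok] >= lo[ok] - 1e-12)
                & (est.shrunken[ok] <= hi[ok] + 1e-12)).all()


class TestTestDe:
    def test_identical_conditions_are_ns(self):
        df = pd.DataFrame(
            {"a1": [100, 5], "a2": [80, 8], "b1": [100, 5], "b2": [80, 8]},
            index=["g0", "g1"],
        )
        cm = CountsMatrix(df, {"a1": "A", "a2": "A", "b1": "B", "b2": "B"})
        disp = DispersionEstimate(pd.Series(0.1, index=cm.genes), 0.1,
                                  pd.Series(0.1, index=cm.genes), 0.0)
        de = nb_lrt_test(cm, "A", "B", disp)
        assert de.table.loc["g0", "log2FC"] == pytest.approx(0.0)
        assert (de.table["status"] == "ns").all()

    def test_null_pvalues_uniform(self):
        counts, _ = simulate_counts(two_condition_design(seed=7))
        filt = filter_low_expression(counts)
        de = nb_lrt_test(filt, "case", "control", estimate_dispersion(filt))
        assert stats.kstest(de.table["p"], "uniform").pvalue > 0.01

    def test_planted_fourfold_recovery(self):
        counts, truth = simulate_counts(two_condition_design(
            seed=7, n_de=200, de_log2fc=2.0, de_up_fraction=1.0,
            de_fixed_base_mean=100.0,
        ))
        filt = filter_low_expression(counts)
        de = nb_lrt_test(filt, "case", "control", estimate_dispersion(filt))
        planted = set(truth.index[truth["de"]])
        up = set(de.table.index[de.table["status"] == "up"])
        assert len(up & planted) / len(planted) >= 0.9
        assert len(up - planted) / max(1, len(up)) <= 0.1

    def test_condition_swap_negates_log2fc(self):
        counts, _ = simulate_counts(two_condition_design(seed=5, n_genes=200,
                                                         n_de=20))
        filt = filter_low_expression(counts)
        disp = estimate_dispersion(filt)
        fwd = nb_lrt_test(filt, "case", "control", disp)
        rev = nb_lrt_test(filt, "control", "case", disp)
        assert np.allclose(fwd.table["log2FC"], -rev.table["log2FC"])
        assert np.allclose(fwd.table["p"], rev.table["p"], rtol=1e-6,
                           atol=1e-12)
        swapped = {"up": "down", "down": "up", "ns": "ns"}
        assert (rev.table["status"] == fwd.table["status"].map(swapped)).all()

    def test_matches_statsmodels_glm_oracle(self):
        import statsmodels.api as sm

        counts, _ = simulate_counts(two_condition_design(
            seed=3, n_genes=40, n_de=10, de_up_fraction=1.0,
            constant_dispersion=0.15,
        ))
        filt = filter_low_expression(counts)
        disp = estimate_dispersion(filt)
        de = nb_lrt_test(filt, "case", "control", disp)
        samples = filt.samples_of("case") + filt.samples_of("control")
        totals = filt.counts.sum(axis=0).astype(float)
        s = (totals / totals.mean())[samples].to_numpy()
        is_case = np.array([filt.conditions[x] == "case" for x in samples])
        x1 = np.column_stack([np.ones(len(samples)), is_case.astype(float)])
        offset = np.log(s)
        for gene in filt.genes[:25]:
            y = filt.counts.loc[gene, samples].to_numpy(float)
            phi = float(disp.shrunken.loc[gene])
            fam = (sm.families.NegativeBinomial(alpha=phi) if phi > 1e-8
                   else sm.families.Poisson())
            r1 = sm.GLM(y, x1, family=fam, offset=offset).fit()
            r0 = sm.GLM(y, x1[:, :1], family=fam, offset=offset).fit()
            p_ref = stats.chi2.sf(max(0.0, 2 * (r1.llf - r0.llf)), 1)
            # abs tolerance reflects the GLM's IRLS convergence threshold
            assert de.table.loc[gene, "p"] == pytest.approx(p_ref, abs=1e-6)


class TestTopVarianceZscore:
    def test_rows_standardized(self):
        rng = np.random.default_rng(0)
        cpm = pd.DataFrame(rng.uniform(1, 1000, size=(50, 6)),
                           index=[f"g{i}" for i in range(50)])
        z = top_variance_zscore(cpm, n_top=20)
        assert z.shape == (20, 6)
        assert np.allclose(z.mean(axis=1), 0, atol=1e-9)
        assert np.allclose(z.std(axis=1, ddof=1), 1, atol=1e-9)

    def test_planted_high_variance_genes_selected(self):
        rng = np.random.default_rng(1)
        low = rng.normal(100, 0.01, size=(1000, 5))
        high = np.tile([1.0, 1000.0, 1.0, 1000.0, 1.0], (10, 1))
        cpm = pd.DataFrame(np.vstack([low, high]),
                           index=[f"lo{i}" for i in range(1000)]
                           + [f"hi{i}" for i in range(10)])
        z = top_variance_zscore(cpm, n_top=10)
        assert set(z.index) == {f"hi{i}" for i in range(10)}

    def test_constant_gene_never_selected(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame(rng.uniform(1, 100, size=(30, 4)),
                          index=[f"g{i}" for i in range(30)])
        df.loc["flat"] = 50.0
        z = top_variance_zscore(df, n_top=30)
        assert "flat" not in z.index

    def test_fewer_genes_than_requested_warns_and_uses_all(self):
        df = pd.DataFrame(np.random.default_rng(3).uniform(1, 9, (5, 4)),
                          index=list("abcde"))
        z = top_variance_zscore(df, n_top=500)
        assert len(z) == 5


class TestGroupActivationGenes:
    def _tables(self, rows):
        idx = [r[0] for r in rows]
        case = pd.DataFrame({"log2FC": [r[1] for r in rows], "p": 0.001,
                             "q": 0.01, "status": "ns"}, index=idx)
        other = pd.DataFrame({"log2FC": [r[2] for r in rows], "p": 0.001,
                              "q": 0.01, "status": "ns"}, index=idx)
        return (DETable(case, 0.05, 1.0), DETable(other, 0.05, 1.0))

    def test_concordant_gene(self):
        de_case, de_other = self._tables([("g", 2.0, 2.1)])
        grouping = group_activation_genes(de_case, de_other, ["g"])
        assert grouping.assignments.loc[0, "group"] == "Group1"

    def test_repressed_gene(self):
        de_case, de_other = self._tables([("g", -1.0, 2.0)])
        grouping = group_activation_genes(de_case, de_other, ["g"])
        assert grouping.assignments.loc[0, "group"] == "Group2"

    def test_discordant_but_not_repressed_is_unclassified(self):
        de_case, de_other = self._tables([("g", 2.5, -1.0)])
        grouping = group_activation_genes(de_case, de_other, ["g"])
        assert grouping.assignments.loc[0, "group"] == "unclassified"

    def test_missing_genes_reported_not_fatal(self):
        de_case, de_other = self._tables([("g", 2.0, 2.0)])
        grouping = group_activation_genes(de_case, de_other, ["g", "absent"])
        assert grouping.missing == ["absent"]

    def test_closed_loop_fixture_yields_65_35_split(self):
        """31 concordant + 17 repressed planted genes recovered exactly."""
        design = SimulationDesign(seed=1)
        counts, truth = simulate_expression(design,
                                            np.random.default_rng(design.seed))
        filt = filter_low_expression(counts)
        disp = estimate_dispersion(filt)
        de_case = nb_lrt_test(filt, "tet2kit", "wt", disp)
        de_other = nb_lrt_test(filt, "kit", "wt", disp)
        curated = list(truth.index[truth["curated_group"] != ""])
        grouping = group_activation_genes(de_case, de_other, curated)
        counts_by = grouping.counts()
        assert counts_by == {"Group1": 31, "Group2": 17}
        pct = grouping.percentages()
        assert round(pct["Group1"]) == 65
        assert round(pct["Group2"]) == 35
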