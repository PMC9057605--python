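import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from epimast.io import GenomicRegion
from epimast.methylation import (
    TileMethylation,
    call_dmrs,
    overlap_sets,
    pool_tile_counts,
    test_tile as tile_test,
    tile_genome,
)
from epimast.simulate import SimulationDesign, simulate_methylation


def make_tile(m1, t1, m0, t0, reps=None):
    return TileMethylation(
        GenomicRegion("chr1", 0, 400),
        {"case": m1, "ctrl": m0},
        {"case": t1, "ctrl": t0},
        {"case": 5, "ctrl": 5},
        reps or {"case": {"c1": m1 / t1 if t1 else np.nan},
                 "ctrl": {"k1": m0 / t0 if t0 else np.nan}},
    )


class TestTileGenome:
    def test_truncated_last_tile(self):
        tiles = tile_genome({"chr1": 1000}, 400)
        assert [(t.start, t.end) for t in tiles] == [(0, 400), (400, 800),
                                                     (800, 1000)]

    def test_exact_single_tile(self):
        tiles = tile_genome({"chr1": 400}, 400)
        assert [(t.start, t.end) for t in tiles] == [(0, 400)]

    def test_bad_inputs_rejected(self):
        with pytest.raises(ValueError):
            tile_genome({"chr1": 1000}, 0)
        with pytest.raises(ValueError):
            tile_genome({"chr1": 0}, 400)


class TestPoolTileCounts:
    def _cpgs(self, rows):
        return pd.DataFrame(rows, columns=["chrom", "pos", "sample", "meth",
                                           "total"])

    def test_sums_within_tile(self):
        cpgs = self._cpgs([("chr1", 10, "s1", 5, 10), ("chr1", 20, "s1", 10, 10)])
        tiles = [GenomicRegion("chr1", 0, 400)]
        (tm,) = pool_tile_counts(cpgs, tiles, {"s1": "A"}, min_cov_per_cpg=10)
        assert tm.meth["A"] == 15 and tm.total["A"] == 20
        assert tm.fraction("A") == pytest.approx(0.75)
        assert tm.n_cpg["A"] == 2

    def test_coverage_floor_excludes_cpg(self):
        cpgs = self._cpgs([("chr1", 10, "s1", 2, 4), ("chr1", 20, "s1", 10, 10)])
        tiles = [GenomicRegion("chr1", 0, 400)]
        (tm,) = pool_tile_counts(cpgs, tiles, {"s1": "A"}, min_cov_per_cpg=10)
        assert tm.meth["A"] == 10 and tm.total["A"] == 10 and tm.n_cpg["A"] == 1

    def test_floor_applies_to_every_sample_of_condition(self):
        # position covered well in s1 but thinly in s2: fails for the condition
        cpgs = self._cpgs([("chr1", 10, "s1", 5, 30), ("chr1", 10, "s2", 1, 4)])
        tiles = [GenomicRegion("chr1", 0, 400)]
        (tm,) = pool_tile_counts(cpgs, tiles, {"s1": "A", "s2": "A"})
        assert tm.n_cpg["A"] == 0 and tm.total["A"] == 0

    def test_empty_tile_flagged(self):
        tiles = [GenomicRegion("chr1", 0, 400), GenomicRegion("chr1", 400, 800)]
        cpgs = self._cpgs([("chr1", 500, "s1", 5, 20)])
        tms = pool_tile_counts(cpgs, tiles, {"s1": "A"})
        assert tms[0].n_cpg["A"] == 0 and tms[1].n_cpg["A"] == 1

    def test_unknown_sample_rejected(self):
        cpgs = self._cpgs([("chr1", 10, "sX", 1, 20)])
        with pytest.raises(ValueError, match="condition map"):
            pool_tile_counts(cpgs, [GenomicRegion("chr1", 0, 400)], {"s1": "A"})


class TestTestTile:
    def test_identical_margins_null(self):
        delta, p = tile_test(make_tile(50, 100, 50, 100), "case", "ctrl")
        assert delta == 0 and p == 1.0

    def test_tea_tasting_counts(self):
        delta, p = tile_test(make_tile(3, 4, 1, 4), "case", "ctrl")
        assert delta == pytest.approx(0.5)
        assert p == pytest.approx(34 / 70, rel=1e-12)

    def test_large_difference(self):
        delta, p = tile_test(make_tile(90, 100, 50, 100), "case", "ctrl")
        assert delta == pytest.approx(0.40)
        # independent enumeration with exact integers
        w_obs = math.comb(100, 90) * math.comb(100, 50)
        num = sum(
            w for x in range(40, 101)
            if (w := math.comb(100, x) * math.comb(100, 140 - x)) <= w_obs
        )
        assert p == pytest.approx(num / math.comb(200, 140), rel=1e-9)

    @given(st.integers(0, 30), st.integers(0, 30), st.integers(1, 30),
           st.integers(1, 30))
    def test_matches_enumeration_small_margins(self, m1, m0, extra1, extra0):
        t1, t0 = m1 + extra1, m0 + extra0
        delta, p = tile_test(make_tile(m1, t1, m0, t0), "case", "ctrl")
        row1, row2 = t1, t0
        col1 = m1 + m0
        w_obs = math.comb(row1, m1) * math.comb(row2, m0)
        num = sum(
            w for x in range(max(0, col1 - row2), min(row1, col1) + 1)
            if (w := math.comb(row1, x) * math.comb(row2, col1 - x)) <= w_obs
        )
        assert p == pytest.approx(num / math.comb(row1 + row2, col1), rel=1e-9)

    def test_zero_coverage_skipped_with_warning(self):
        with pytest.warns(UserWarning):
            delta, p = tile_test(make_tile(0, 0, 5, 10), "case", "ctrl")
        assert np.isnan(p)


def _simulate_pooled(planted, seed=1, n_tiles=2000):
    design = SimulationDesign(
        seed=seed, n_tiles=n_tiles, hmr_sizes={"case": planted},
        overlap_pair=("case", "case"), promoter_coupling_fraction=0.0,
        n_repressed=0,
    )
    rng = np.random.default_rng(design.seed)
    cpgs, truth, cmap, _ = simulate_methylation(design, rng)
    tiles = tile_genome({design.chrom: design.chrom_size}, design.tile_bp)
    return pool_tile_counts(cpgs, tiles, cmap), truth


class TestCallDmrs:
    def test_null_simulation_type_one_control(self):
        pooled, _ = _simulate_pooled(planted=0)
        calls = call_dmrs(pooled, "case", "wt")
        assert len(calls) / 2000 <= 0.02

    def test_planted_effect_recovery(self):
        pooled, truth = _simulate_pooled(planted=100)
        calls = call_dmrs(pooled, "case", "wt")
        hyper = [c for c in calls if c.direction == "hyper"]
        true_keys = {r.key() for r in truth["case"]}
        tp = sum(1 for c in hyper if c.region.key() in true_keys)
        assert tp / 100 >= 0.9
        assert (len(hyper) - tp) / max(1, len(hyper)) <= 0.1

    def test_condition_swap_antisymmetry(self):
        pooled, _ = _simulate_pooled(planted=50, n_tiles=400)
        fwd = call_dmrs(pooled, "case", "wt")
        rev = call_dmrs(pooled, "wt", "case")
        key = lambda c: c.region.key()
        assert {key(c) for c in fwd} == {key(c) for c in rev}
        rev_by_key = {key(c): c for c in rev}
        for c in fwd:
            r = rev_by_key[key(c)]
            assert r.delta == pytest.approx(-c.delta)
            assert r.p == pytest.approx(c.p)
            assert {c.direction, r.direction} == {"hyper", "hypo"}

    def test_min_cpg_gates_eligibility(self):
        tile = make_tile(90, 100, 10, 100)
        tile.n_cpg = {"case": 2, "ctrl": 5}
        assert call_dmrs([tile], "case", "ctrl", min_cpg=3) == []


class TestOverlapSets:
    def test_one_bp_overlap_counts(self):
        a = [GenomicRegion("chr1", 100, 500)]
        b = [GenomicRegion("chr1", 499, 600)]
        v = overlap_sets(a, b)
        assert v.a_and_b == 1 and v.a_only == 0

    def test_half_open_boundary_does_not_count(self):
        a = [GenomicRegion("chr1", 100, 500)]
        b = [GenomicRegion("chr1", 500, 600)]
        v = overlap_sets(a, b)
        assert v.a_and_b == 0 and v.a_only == 1 and v.b_only == 1

    def test_shifted_fixture_half_overlap(self):
        a = [GenomicRegion("chr1", i * 1000, i * 1000 + 400) for i in range(10)]
        b = [GenomicRegion("chr1", i * 1000 + 200, i * 1000 + 600)
             for i in range(5)]
        v = overlap_sets(a, b)
        assert v.a_and_b == 5
        assert v.overlap_fraction_a == pytest.approx(0.5)

    def test_min_overlap_threshold(self):
        a = [GenomicRegion("chr1", 0, 100)]
        b = [GenomicRegion("chr1", 90, 200)]
        assert overlap_sets(a, b, min_overlap_bp=10).a_and_b == 1
        assert overlap_sets(a, b, min_overlap_bp=11).a_and_b == 0

    @given(st.lists(st.tuples(st.integers(0, 2000), st.integers(1, 300)),
                    max_size=15),
           st.lists(st.tuples(st.integers(0, 2000), st.integers(1, 300)),
                    max_size=15))
    def test_count_identity(self, raw_a, raw_b):
        a = [GenomicRegion("chr1", s, s + w) for s, w in raw_a]
        b = [GenomicRegion("chr1", s, s + w) for s, w in raw_b]
        v = overlap_sets(a, b)
        assert v.a_only + v.a_and_b == len(a)
        assert v.a_only >= 0 and v.b_only >= 0
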