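"""Window tiling, the two-group rank test, BH adjustment, DMR calling,
merging and gene-region annotation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from methdiff import dmr as dmrmod
from methdiff import profiles
from test_profiles import make_pair


class TestTileWindows:
    def test_sliding_starts_and_truncated_tail(self):
        w = dmrmod.tile_windows({"chr1": 150})
        assert list(w.start) == [0, 25, 50, 75, 100, 125]
        assert list(w.end)[-1] == 150

    def test_exact_length(self):
        w = dmrmod.tile_windows({"chr1": 100})
        assert list(w.start) == [0, 25, 50, 75]
        assert (w.end == 100).sum() == 4

    def test_degenerate_chromosome(self):
        w = dmrmod.tile_windows({"chr1": 10})
        assert len(w) == 1 and w.iloc[0].end == 10

    def test_bad_parameters_raise(self):
        with pytest.raises(ValueError):
            dmrmod.tile_windows({"chr1": 0})
        with pytest.raises(ValueError):
            dmrmod.tile_windows({"chr1": 100}, size=10, step=20)


def kw_rank_oracle(a, b):
    """Independent midrank-formula implementation of the two-group
    Kruskal-Wallis statistic with tie correction (test oracle)."""
    from scipy.stats import chi2

    a = np.asarray(a, float)
    b = np.asarray(b, float)
    pooled = np.concatenate([a, b])
    n = len(pooled)
    order = np.argsort(pooled, kind="mergesort")
    ranks = np.empty(n)
    sv = pooled[order]
    i = 0
    while i < n:
        j = i
        while j < n and sv[j] == sv[i]:
            j += 1
        ranks[order[i:j]] = 0.5 * (i + 1 + j)  # midrank of positions i+1..j
        i = j
    ra, rb = ranks[: len(a)].sum(), ranks[len(a):].sum()
    h = 12.0 / (n * (n + 1)) * (ra ** 2 / len(a) + rb ** 2 / len(b)) - 3 * (n + 1)
    _, counts = np.unique(pooled, return_counts=True)
    denom = 1.0 - (counts ** 3 - counts).sum() / float(n ** 3 - n)
    if denom == 0.0:
        return 0.0, 1.0
    h /= denom
    if h <= 0.0:
        return 0.0, 1.0
    return float(h), float(chi2.sf(h, 1))


class TestKruskalWallis:
    def test_complete_ties(self):
        assert dmrmod.kruskal_wallis_2group([0.5] * 3, [0.5] * 3) == (0.0, 1.0)

    def test_separated_groups_reference_values(self):
        # H and p computed by hand from the rank formula:
        # ranks 1..6, H = 12/42*(36/3 + 225/3) - 21 = 27/7
        h, p = dmrmod.kruskal_wallis_2group([0.1, 0.2, 0.3], [0.4, 0.5, 0.6])
        assert h == pytest.approx(27 / 7, abs=1e-12)
        assert p == pytest.approx(0.049535, abs=1e-5)

    def test_empty_group_raises(self):
        with pytest.raises(ValueError):
            dmrmod.kruskal_wallis_2group([], [0.5])

    @given(st.data())
    def test_matches_rank_oracle_on_small_inputs(self, data):
        levels = st.sampled_from([0.0, 0.25, 0.5, 0.75, 1.0])
        na = data.draw(st.integers(1, 5))
        nb = data.draw(st.integers(1, 5))
        a = data.draw(st.lists(levels, min_size=na, max_size=na))
        b = data.draw(st.lists(levels, min_size=nb, max_size=nb))
        h, p = dmrmod.kruskal_wallis_2group(a, b)
        h2, p2 = kw_rank_oracle(a, b)
        assert h == pytest.approx(h2, abs=1e-12)
        assert p == pytest.approx(p2, abs=1e-12)


class TestBhAdjust:
    def test_step_up_worked_example(self):
        # hand application of the step-up formula
        q = dmrmod.bh_adjust([0.01, 0.02, 0.04, 0.05])
        assert np.allclose(q, [0.04, 0.04, 0.05, 0.05])

    def test_equal_ps_unchanged(self):
        assert np.allclose(dmrmod.bh_adjust([0.3] * 5), 0.3)

    def test_single_p(self):
        assert dmrmod.bh_adjust([0.123])[0] == 0.123

    def test_out_of_range_raises(self):
        with pytest.raises(ValueError):
            dmrmod.bh_adjust([0.5, 1.5])

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=60))
    def test_monotone_and_permutation_invariant(self, ps):
        ps = np.asarray(ps)
        q = dmrmod.bh_adjust(ps)
        order = np.argsort(ps, kind="mergesort")
        assert (np.diff(q[order]) >= -1e-15).all()
        assert (q <= 1.0).all() and (q >= ps - 1e-15).all()
        perm = np.random.default_rng(0).permutation(len(ps))
        assert np.allclose(dmrmod.bh_adjust(ps[perm]), q[perm])

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(5)
        for _ in range(20):
            ps = rng.random(rng.integers(1, 200))
            q = dmrmod.bh_adjust(ps)
            q_sm = multipletests(ps, method="fdr_bh")[1]
            assert np.allclose(q, q_sm, atol=1e-12)


class TestTestWindows:
    def test_sparse_windows_excluded_from_family(self):
        pair = make_pair([(0.5, 0.9)] * 3)  # 3 sites at pos 0,3,6
        w = dmrmod.test_windows(pair, {"chr1": 100}, "CHH", min_sites=4)
        assert w.empty

    def test_identical_levels_never_significant(self):
        pair = make_pair([(0.5, 0.5), (0.2, 0.2), (0.8, 0.8), (0.4, 0.4)])
        w = dmrmod.test_windows(pair, {"chr1": 100}, "CHH")
        assert (w.p_value == 1.0).all()

    def test_unknown_context_raises(self, small_pair):
        with pytest.raises(ValueError, match="context"):
            dmrmod.test_windows(small_pair, {"chr1": 100}, "CNN")


class TestCallDmrs:
    def windows(self, q, mean_a, mean_b):
        return pd.DataFrame(
            {
                "chrom": ["chr1"], "start": [0], "end": [100], "context": ["CHH"],
                "n_sites": [10], "mean_a": [mean_a], "mean_b": [mean_b],
                "h_stat": [5.0], "p_value": [0.01], "q_value": [q],
            }
        )

    def test_significant_window_becomes_dmr(self):
        dmrs = dmrmod.call_dmrs(self.windows(0.04, 0.2, 0.5))
        assert len(dmrs) == 1
        assert dmrs.iloc[0].fold_change == pytest.approx(2.5)
        assert dmrs.iloc[0].trend == "hyper"

    def test_non_significant_window_is_not(self):
        assert dmrmod.call_dmrs(self.windows(0.06, 0.2, 0.5)).empty

    def test_fold_change_filter(self):
        # significant rank shift but equal means: excluded when filter active
        assert dmrmod.call_dmrs(self.windows(0.01, 0.4, 0.4)).empty
        kept = dmrmod.call_dmrs(self.windows(0.01, 0.4, 0.4), fc_threshold=None)
        assert len(kept) == 1

    def test_zero_mean_a_flagged_infinite_hyper(self):
        dmrs = dmrmod.call_dmrs(self.windows(0.01, 0.0, 0.3))
        assert np.isinf(dmrs.iloc[0].fold_change)
        assert dmrs.iloc[0].trend == "hyper"

    def test_missing_q_raises(self):
        w = self.windows(0.01, 0.2, 0.5).drop(columns="q_value")
        with pytest.raises(ValueError, match="q-value"):
            dmrmod.call_dmrs(w)


def dmr_frame(rows):
    """rows: (start, end, trend[, q])"""
    out = []
    for r in rows:
        start, end, trend = r[:3]
        q = r[3] if len(r) > 3 else 0.01
        out.append(("chr1", start, end, "CHH", trend, 1.5, q, 1, 0.2, 0.5))
    return pd.DataFrame(out, columns=dmrmod.DMR_COLUMNS)


class TestMergeAdjacent:
    PAIR = make_pair([(0.2, 0.5)] * 100)  # sites at 0,3,...,297

    def test_same_trend_overlap_merges(self):
        merged = dmrmod.merge_adjacent(
            dmr_frame([(100, 200, "hyper"), (125, 225, "hyper")]), self.PAIR
        )
        assert len(merged) == 1
        assert (merged.iloc[0].start, merged.iloc[0].end) == (100, 225)
        assert merged.iloc[0].n_windows == 2

    def test_opposite_trend_never_merges(self):
        merged = dmrmod.merge_adjacent(
            dmr_frame([(100, 200, "hyper"), (125, 225, "hypo")]), self.PAIR
        )
        assert len(merged) == 2

    def test_chain_of_sliding_windows(self):
        k = 6
        rows = [(100 + 25 * i, 200 + 25 * i, "hypo") for i in range(k)]
        merged = dmrmod.merge_adjacent(dmr_frame(rows), self.PAIR)
        assert len(merged) == 1
        assert merged.iloc[0].end - merged.iloc[0].start == 100 + 25 * (k - 1)

    def test_merge_is_idempotent(self, small_dmrs, small_pair):
        again = dmrmod.merge_adjacent(small_dmrs, small_pair)
        pd.testing.assert_frame_equal(again, small_dmrs)

    def test_q_is_minimum_and_fc_recomputed(self):
        merged = dmrmod.merge_adjacent(
            dmr_frame([(0, 100, "hyper", 0.04), (75, 175, "hyper", 0.001)]), self.PAIR
        )
        assert merged.iloc[0].q_value == 0.001
        assert merged.iloc[0].fold_change == pytest.approx(2.5)  # 0.5 / 0.2

    def test_unsorted_raises(self):
        with pytest.raises(ValueError, match="sorted"):
            dmrmod.merge_adjacent(
                dmr_frame([(200, 300, "hyper"), (0, 100, "hyper")]), self.PAIR
            )


class TestAnnotateDmrs:
    GENES = pd.DataFrame(
        {
            "gene_id": ["gp", "gm"],
            "chrom": ["chr1", "chr2"],
            "start": [5000, 5000],
            "end": [8000, 8000],
            "strand": ["+", "-"],
        }
    )

    def annotate(self, rows):
        dmrs = pd.DataFrame(
            [(c, s, e, "CHH", "hyper", 2.0, 0.01, 1, 0.1, 0.2) for c, s, e in rows],
            columns=dmrmod.DMR_COLUMNS,
        )
        ann, summary = dmrmod.annotate_dmrs(dmrs, self.GENES)
        return ann, summary

    def test_plus_strand_flanks(self):
        ann, _ = self.annotate([("chr1", 4500, 4600), ("chr1", 8100, 8200)])
        by_region = ann.set_index("region")
        assert by_region.loc["upstream"].start == 4500
        assert by_region.loc["downstream"].start == 8100

    def test_minus_strand_flips_flanks(self):
        ann, _ = self.annotate([("chr2", 8100, 8200)])
        assert ann.iloc[0].region == "upstream"

    def test_boundary_dmr_gets_both_regions(self):
        ann, _ = self.annotate([("chr1", 4950, 5050)])
        assert set(ann.region) == {"upstream", "gene_body"}

    def test_intergenic_dmr_and_summary(self):
        _, summary = self.annotate([("chr1", 100_000, 100_100), ("chr1", 6000, 6100)])
        genic = summary.set_index("region").loc["any_gene_region"]
        assert genic.pct == pytest.approx(50.0)

    def test_negative_flank_raises(self):
        dmrs = dmr_frame([(0, 100, "hyper")])
        with pytest.raises(ValueError, match="flank"):
            dmrmod.annotate_dmrs(dmrs, self.GENES, flank=-1)


class TestLengthDistribution:
    def test_uniform_windows(self):
        dmrs = dmr_frame([(0, 100, "hyper"), (200, 300, "hyper")])
        hist = dmrmod.length_distribution(dmrs, [100, 200])
        assert hist.set_index("length_class").loc["[100, 200)"].pct == 100.0

    def test_single_break(self):
        dmrs = dmr_frame([(0, 100, "hyper"), (0, 125, "hyper"), (0, 250, "hyper")])
        hist = dmrmod.length_distribution(dmrs, [200])
        assert hist.iloc[0].pct == pytest.approx(200 / 3)

    def test_matches_brute_force_tally(self, small_dmrs):
        breaks = [200, 400]
        hist = dmrmod.length_distribution(small_dmrs, breaks)
        lengths = (small_dmrs.end - small_dmrs.start).tolist()
        expected = [
            sum(1 for L in lengths if L < 200),
            sum(1 for L in lengths if 200 <= L < 400),
            sum(1 for L in lengths if L >= 400),
        ]
        assert hist["count"].tolist() == expected

    def test_non_increasing_breaks_raise(self):
        with pytest.raises(ValueError):
            dmrmod.length_distribution(dmr_frame([(0, 100, "hyper")]), [200, 200])
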