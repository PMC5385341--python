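import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import _oracles
from selrep import disallowance
from selrep.disallowance import GeneList, PiTable


def make_pi_table(lfc_rows, adjp_rows, genes=None, comps=None) -> PiTable:
    lfc = np.atleast_2d(np.asarray(lfc_rows, dtype=float))
    adj = np.atleast_2d(np.asarray(adjp_rows, dtype=float))
    genes = genes or [f"g{i}" for i in range(lfc.shape[0])]
    comps = comps or [f"c{i}" for i in range(lfc.shape[1])]
    lfc_df = pd.DataFrame(lfc, index=genes, columns=comps)
    adj_df = pd.DataFrame(adj, index=genes, columns=comps)
    pi_df = pd.DataFrame(disallowance.pi_value(lfc, adj), index=genes, columns=comps)
    return PiTable(lfc_df, adj_df, pi_df)


class TestPiValue:
    def test_adj_p_one_gives_zero(self):
        assert disallowance.pi_value(-3.7, 1.0) == 0.0

    def test_zero_lfc_gives_zero(self):
        assert disallowance.pi_value(0.0, 0.2) == 0.0

    def test_hand_value(self):
        assert disallowance.pi_value(-2.0, 0.01) == pytest.approx(-4.0)

    def test_zero_p_floored_with_warning(self):
        with pytest.warns(UserWarning, match="floored"):
            pi = disallowance.pi_value(-1.0, 0.0)
        assert pi == pytest.approx(300.0 * -1.0)

    def test_out_of_range_p_rejected(self):
        with pytest.raises(ValueError):
            disallowance.pi_value(1.0, 1.5)
        with pytest.raises(ValueError):
            disallowance.pi_value(1.0, -0.1)

    def test_sign_follows_lfc(self):
        rng = np.random.default_rng(0)
        lfc = rng.normal(size=100)
        p = rng.uniform(0.001, 1.0, size=100)
        pi = disallowance.pi_value(lfc, p)
        assert np.all(np.sign(pi) == np.where(p == 1.0, 0, np.sign(lfc)))


class TestBuildPiTable:
    def test_per_cell_formula(self):
        de = {
            "c0": pd.DataFrame({"log2fc": [-1.0], "adj_p": [0.1], "flagged": [False]}, index=["g"]),
            "c1": pd.DataFrame({"log2fc": [-2.0], "adj_p": [0.01], "flagged": [False]}, index=["g"]),
            "c2": pd.DataFrame({"log2fc": [-3.0], "adj_p": [0.001], "flagged": [False]}, index=["g"]),
        }
        table = disallowance.build_pi_table(de)
        assert np.allclose(table.pi.loc["g"], [-1.0, -4.0, -9.0])

    def test_flagged_cell_missing_others_intact(self):
        de = {
            "c0": pd.DataFrame({"log2fc": [-1.0], "adj_p": [0.1], "flagged": [True]}, index=["g"]),
            "c1": pd.DataFrame({"log2fc": [-2.0], "adj_p": [0.01], "flagged": [False]}, index=["g"]),
        }
        table = disallowance.build_pi_table(de)
        assert np.isnan(table.pi.loc["g", "c0"])
        assert table.pi.loc["g", "c1"] == pytest.approx(-4.0)

    def test_empty_universe_gives_empty_table(self):
        de = {"c0": pd.DataFrame(columns=["log2fc", "adj_p", "flagged"])}
        table = disallowance.build_pi_table(de)
        assert len(table.genes) == 0

    def test_zero_comparisons_is_error(self):
        with pytest.raises(ValueError, match="at least one comparison"):
            disallowance.build_pi_table({})

    def test_long_format_round_trip(self):
        table = make_pi_table([[-1, 2], [3, -4]], [[0.1, 0.2], [0.3, 0.4]])
        back = PiTable.from_frame(table.to_frame())
        pd.testing.assert_frame_equal(back.pi, table.pi)


class TestCombine:
    def test_min_abs_of_consistent_gene(self):
        table = make_pi_table([[-2.0, -1.0, -2.0]], [[0.01, 0.03162278, 0.001]])
        out = disallowance.combine(table)
        assert out.loc["g0", "combined_pi"] == pytest.approx(-1.5, abs=1e-6)
        assert out.loc["g0", "direction"] == "down"

    def test_sign_discordance_excluded(self):
        table = make_pi_table([[-2.0, 0.5]], [[0.01, 0.1]])
        assert disallowance.combine(table).empty

    def test_zero_lfc_breaks_consistency(self):
        table = make_pi_table([[-2.0, 0.0]], [[0.01, 0.1]])
        assert disallowance.combine(table).empty

    def test_singleton_comparison_passes_through(self):
        table = make_pi_table([[-2.0]], [[0.01]])
        out = disallowance.combine(table)
        assert out.loc["g0", "combined_pi"] == pytest.approx(-4.0)

    def test_missing_cell_excluded_by_default_included_when_relaxed(self):
        table = make_pi_table([[-2.0, np.nan]], [[0.01, np.nan]])
        assert disallowance.combine(table).empty
        out = disallowance.combine(table, require_all_present=False)
        assert out.loc["g0", "combined_pi"] == pytest.approx(-4.0)

    def test_min_signed_variant_picks_strongest_down(self):
        table = make_pi_table([[-2.0, -1.0]], [[0.01, 0.1]])
        out = disallowance.combine(table, method="min_signed")
        assert out.loc["g0", "combined_pi"] == pytest.approx(-4.0)

    def test_monotonicity_adding_comparison(self):
        """An extra consistent comparison can only shrink or preserve the
        combined |pi|."""
        rng = np.random.default_rng(1)
        for _ in range(200):
            k = rng.integers(1, 6)
            lfc = -rng.uniform(0.1, 5, size=k + 1)
            adj = rng.uniform(1e-6, 1, size=k + 1)
            small = disallowance.combine(make_pi_table([lfc[:k]], [adj[:k]]))
            big = disallowance.combine(make_pi_table([lfc], [adj]))
            assert abs(big.loc["g0", "combined_pi"]) <= abs(small.loc["g0", "combined_pi"]) + 1e-12

    @settings(max_examples=200, deadline=None)
    @given(st.data())
    def test_matches_brute_force_oracle(self, data):
        n_comp = data.draw(st.integers(1, 5))
        n_genes = data.draw(st.integers(1, 8))
        finite = st.floats(-6, 6, allow_nan=False)
        lfc = np.array([[data.draw(finite) for _ in range(n_comp)] for _ in range(n_genes)])
        adj = np.array([[data.draw(st.floats(1e-12, 1.0)) for _ in range(n_comp)]
                        for _ in range(n_genes)])
        # sprinkle missing cells
        mask = np.array([[data.draw(st.booleans()) for _ in range(n_comp)]
                         for _ in range(n_genes)])
        lfc[mask] = np.nan
        adj[mask] = np.nan
        table = make_pi_table(lfc, adj)
        out = disallowance.combine(table)
        for i, gene in enumerate(table.genes):
            expect = _oracles.combine_pi(lfc[i], adj[i])
            if expect is None:
                assert gene not in out.index
            else:
                val, direction = expect
                assert out.loc[gene, "combined_pi"] == pytest.approx(val, abs=1e-12)
                assert out.loc[gene, "direction"] == direction


class TestRankAndTopN:
    def _ranking(self, scores):
        combined = pd.DataFrame(
            {
                "combined_pi": list(scores.values()),
                "direction": ["down" if v < 0 else "up" for v in scores.values()],
                "n_comparisons": 3,
                "min_comparison": "c0",
            },
            index=list(scores),
        )
        return disallowance.rank(combined)

    def test_ordering_both_ends(self):
        ranking = self._ranking({"A": -5.0, "B": -1.0, "C": 3.0})
        assert list(ranking.index) == ["A", "B", "C"]
        down = disallowance.top_n(ranking, 2, "down")
        up = disallowance.top_n(ranking, 1, "up")
        assert down.genes == ["A", "B"]
        assert up.genes == ["C"]

    def test_ties_broken_by_gene_id(self):
        ranking = self._ranking({"b": -2.0, "a": -2.0})
        assert list(ranking.index) == ["a", "b"]

    def test_matches_sort_oracle(self):
        rng = np.random.default_rng(4)
        scores = {f"g{i:04d}": v for i, v in enumerate(rng.normal(size=1000))}
        ranking = self._ranking(scores)
        expect = sorted(scores, key=lambda g: (scores[g], g))
        assert list(ranking.index) == expect
        assert list(ranking["rank"]) == list(range(1, 1001))

    def test_exhausted_direction_warns(self):
        ranking = self._ranking({"A": -1.0, "B": 2.0})
        with pytest.warns(UserWarning, match="only 1"):
            out = disallowance.top_n(ranking, 20, "down")
        assert out.genes == ["A"]

    def test_unknown_direction_is_error(self):
        ranking = self._ranking({"A": -1.0})
        with pytest.raises(ValueError, match="direction"):
            disallowance.top_n(ranking, 1, "sideways")

    def test_empty_ranking_warns(self):
        empty = pd.DataFrame(columns=["combined_pi", "direction", "n_comparisons",
                                      "min_comparison"])
        with pytest.warns(UserWarning, match="no scored genes"):
            out = disallowance.rank(empty)
        assert out.empty


class TestOverlap:
    def _list(self, genes, label):
        return GeneList(genes=list(genes), scores=[0.0] * len(genes),
                        direction="down", label=label)

    def test_two_list_enumeration(self):
        regions = disallowance.overlap([self._list("abc", "x"), self._list("cd", "y")])
        counts = {(bool(r["x"]), bool(r["y"])): r["count"] for _, r in regions.iterrows()}
        assert counts[(True, True)] == 1
        assert counts[(True, False)] == 2
        assert counts[(False, True)] == 1

    def test_identical_lists_concentrate_in_triple_intersection(self):
        genes = [f"g{i}" for i in range(50)]
        lists = [self._list(genes, lab) for lab in "xyz"]
        regions = disallowance.overlap(lists)
        assert len(regions) == 1
        assert regions["count"].iloc[0] == 50

    def test_duplicate_within_list_rejected(self):
        with pytest.raises(ValueError, match="duplicates"):
            self._list("aab", "x")

    def test_counts_sum_to_union_and_match_set_algebra(self):
        rng = np.random.default_rng(9)
        pool = [f"g{i}" for i in range(40)]
        lists = [
            self._list(rng.choice(pool, size=15, replace=False), lab)
            for lab in ("x", "y", "z")
        ]
        regions = disallowance.overlap(lists)
        union = set().union(*(set(gl.genes) for gl in lists))
        assert regions["count"].sum() == len(union)
        for _, row in regions.iterrows():
            expect = set(union)
            for gl in lists:
                members = set(gl.genes)
                expect &= members if row[gl.label] else (union - members)
            assert row["count"] == len(expect)
            assert set(row["genes"].split(",")) == expect or (row["count"] == 0)
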