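"""Quadrant assignment and the exact Fisher enrichment statistics.

Oracles: exact rational tail sums, a dense log-grid likelihood search for
the conditional-MLE odds ratio, and values frozen from R's fisher.test
(the analysis environment whose conventions these statistics reproduce).
R's printed estimates carry its root-finder's ~1e-4 tolerance, so they are
compared loosely; the grid/closed-form oracles are the tight checks.
"""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oracles import exact_p_greater, exact_p_less, grid_cmle_or
from senquad import (
    assign_quadrants,
    contingency,
    enrichment_scan,
    fisher_exact_one_sided,
    or_bar_export,
    scatter_export,
)
from senquad.quadrant import (
    ContingencyTable2x2,
    EnrichmentError,
    _tail_prob,
)

# fisher.test oracle values (R 4.3.3): (a,b,c,d) -> p greater, OR, CI lower
R_FISHER = [
    ((2, 0, 0, 2), 1 / 6, math.inf, 0.3576749805),
    ((3, 1, 1, 3), 17 / 70, 6.408308867, 0.3135692641),
    ((5, 5, 5, 5), 0.671859100652, 1.0, 0.1668305062),
    ((8, 2, 3, 7), 0.0348892593475, 8.153062604, 1.155326628),
    ((10, 1, 2, 9), 0.000952607763753, 33.97623136, 3.513220981),
]


def random_tables(rng, n_tables, n_max=40):
    for _ in range(n_tables):
        n = int(rng.integers(4, n_max + 1))
        row1 = int(rng.integers(1, n))
        col1 = int(rng.integers(1, n))
        lo, hi = max(0, row1 + col1 - n), min(row1, col1)
        a = int(rng.integers(lo, hi + 1))
        yield a, row1 - a, col1 - a, n - row1 - col1 + a


class TestAssignQuadrants:
    def test_sign_pattern_with_fixed_splits(self):
        res = assign_quadrants(
            [1, 1, -1, -1], [1, -1, 1, -1],
            split_method="fixed", x_split=0, y_split=0,
        )
        assert list(res.table["quadrant"]) == ["Q1", "Q4", "Q2", "Q3"]

    def test_all_identical_points_fall_in_q3(self):
        res = assign_quadrants([2.0] * 5, [3.0] * 5)
        assert set(res.table["quadrant"]) == {"Q3"}

    def test_median_splits_hand_example(self):
        # medians (2.5, 2.5): (1,4)->Q2 (2,3)->Q2 (3,2)->Q4 (4,1)->Q4
        res = assign_quadrants([1, 2, 3, 4], [4, 3, 2, 1])
        assert res.x_split == 2.5 and res.y_split == 2.5
        assert res.counts == {"Q1": 0, "Q2": 2, "Q3": 0, "Q4": 2}

    def test_absent_scores_excluded_with_warning(self):
        x = pd.Series([1.0, 2.0, 3.0, 4.0, np.nan])
        y = pd.Series([4.0, 3.0, 2.0, 1.0, 1.0])
        with pytest.warns(UserWarning, match="absent"):
            res = assign_quadrants(x, y)
        assert res.n == 4

    def test_too_few_samples_error(self):
        with pytest.raises(EnrichmentError, match="≥4"):
            assign_quadrants([1, 2, 3], [1, 2, 3])

    @given(st.integers(0, 2**31 - 1), st.integers(3, 30))
    @settings(max_examples=50, deadline=None)
    def test_median_split_balances_even_tie_free_scores(self, seed, half_n):
        """With continuous tie-free scores and even n, each axis puts
        exactly n/2 samples on each side of its median."""
        rng = np.random.default_rng(seed)
        x = rng.permutation(np.arange(2 * half_n, dtype=float))
        y = rng.permutation(np.arange(2 * half_n, dtype=float) + 0.5)
        res = assign_quadrants(x, y)
        counts = res.counts
        assert counts["Q1"] + counts["Q4"] == half_n  # high-x side
        assert counts["Q1"] + counts["Q2"] == half_n  # high-y side
        assert sum(counts.values()) == 2 * half_n


class TestContingency:
    def _assignment(self, quadrants):
        x = [1.0 if q in ("Q1", "Q4") else -1.0 for q in quadrants]
        y = [1.0 if q in ("Q1", "Q2") else -1.0 for q in quadrants]
        return assign_quadrants(x, y, split_method="fixed", x_split=0, y_split=0)

    def test_perfect_separation_counts(self):
        a = self._assignment(["Q3", "Q3", "Q1", "Q1"])
        tbl = contingency(a, ["sen", "sen", "non", "non"], "Q3", "sen")
        assert tbl.as_tuple() == (2, 0, 0, 2)

    def test_empty_target_quadrant(self):
        a = self._assignment(["Q1", "Q1", "Q2", "Q2"])
        tbl = contingency(a, ["sen", "non", "sen", "non"], "Q3", "sen")
        assert tbl.a == 0 and tbl.c == 0

    def test_all_samples_in_target_quadrant(self):
        a = self._assignment(["Q1"] * 8)
        tbl = contingency(a, ["s"] * 3 + ["n"] * 5, "Q1", "s")
        assert tbl.as_tuple() == (3, 0, 5, 0)

    def test_absent_target_group_error(self):
        a = self._assignment(["Q1", "Q2", "Q3", "Q4"])
        with pytest.raises(EnrichmentError, match="absent"):
            contingency(a, ["x", "x", "y", "y"], "Q3", "z")

    def test_third_group_excluded_with_warning(self):
        a = self._assignment(["Q3", "Q3", "Q1", "Q1"])
        with pytest.warns(UserWarning, match="excluding 1"):
            tbl = contingency(
                a, ["sen", "sen", "non", "other"], "Q3", "sen", other_group="non"
            )
        assert tbl.n == 3


class TestFisherExact:
    def test_worked_p_values(self):
        assert fisher_exact_one_sided((2, 0, 0, 2)).p == pytest.approx(
            1 / 6, abs=1e-12
        )
        assert fisher_exact_one_sided((3, 1, 1, 3)).p == pytest.approx(
            17 / 70, abs=1e-12
        )

    def test_balanced_table_p_closed_form(self):
        # (5,5,5,5): p = (1 + P(X=5))/2 with P(X=5) = C(10,5)^2 / C(20,10)
        p5 = math.comb(10, 5) ** 2 / math.comb(20, 10)
        res = fisher_exact_one_sided((5, 5, 5, 5))
        assert res.p == pytest.approx((1 + p5) / 2, abs=1e-12)
        assert res.or_cmle == pytest.approx(1.0, abs=1e-9)  # symmetry

    def test_cmle_exact_quartic_root(self):
        # For (3,1,1,3) the score equation reduces to
        # psi^4 - 36 psi^2 - 32 psi - 3 = 0; positive root:
        root = max(np.roots([1, 0, -36, -32, -3]).real)
        assert fisher_exact_one_sided((3, 1, 1, 3)).or_cmle == pytest.approx(
            root, rel=1e-9
        )

    def test_boundary_cell_gives_infinite_or(self):
        res = fisher_exact_one_sided((2, 0, 0, 2))
        assert math.isinf(res.or_cmle)
        res0 = fisher_exact_one_sided((0, 2, 2, 0))
        assert res0.or_cmle == 0.0

    @pytest.mark.parametrize("table,p_r,or_r,ci_r", R_FISHER)
    def test_matches_r_fisher_test(self, table, p_r, or_r, ci_r):
        res = fisher_exact_one_sided(table)
        assert res.p == pytest.approx(p_r, rel=1e-9)
        if math.isinf(or_r):
            assert math.isinf(res.or_cmle)
        else:
            assert res.or_cmle == pytest.approx(or_r, rel=2e-4)
        assert res.ci_lower == pytest.approx(ci_r, rel=2e-4)
        assert math.isinf(res.ci_upper)

    def test_two_sided_matches_r(self):
        res = fisher_exact_one_sided((3, 1, 1, 3), alternative="two-sided")
        assert res.p == pytest.approx(0.485714285714, rel=1e-9)
        assert res.ci_lower == pytest.approx(0.2117329153, rel=2e-4)
        assert res.ci_upper == pytest.approx(621.9337505, rel=1e-2)

    def test_less_alternative(self):
        res = fisher_exact_one_sided((3, 1, 1, 3), alternative="less")
        assert res.p == pytest.approx(0.985714285714, rel=1e-9)
        assert res.ci_lower == 0.0
        assert res.ci_upper == pytest.approx(306.2468625, rel=1e-2)

    def test_p_matches_exact_enumeration_on_random_tables(self):
        rng = np.random.default_rng(2024)
        for a, b, c, d in random_tables(rng, 200, n_max=30):
            res_g = fisher_exact_one_sided((a, b, c, d))
            assert res_g.p == pytest.approx(
                float(exact_p_greater(a, b, c, d)), abs=1e-12
            )
            res_l = fisher_exact_one_sided((a, b, c, d), alternative="less")
            assert res_l.p == pytest.approx(
                float(exact_p_less(a, b, c, d)), abs=1e-12
            )

    def test_cmle_matches_grid_search_on_random_tables(self):
        rng = np.random.default_rng(7)
        for a, b, c, d in random_tables(rng, 60, n_max=40):
            res = fisher_exact_one_sided((a, b, c, d))
            oracle = grid_cmle_or(a, b, c, d)
            if math.isinf(oracle) or oracle == 0.0:
                assert res.or_cmle == oracle
            else:
                assert res.or_cmle == pytest.approx(oracle, rel=1e-4)

    def test_ci_lower_residual_and_ordering(self):
        """The exact bound satisfies P_psi(X >= a) = alpha to 1e-10 and sits
        below the conditional MLE for non-degenerate tables."""
        rng = np.random.default_rng(99)
        checked = 0
        for a, b, c, d in random_tables(rng, 100, n_max=30):
            res = fisher_exact_one_sided((a, b, c, d))
            if not (0 < res.ci_lower < math.inf) or not math.isfinite(res.or_cmle):
                continue
            resid = _tail_prob(res.table, math.log(res.ci_lower), "ge")
            assert resid == pytest.approx(res.alpha, abs=1e-10)
            assert res.ci_lower < res.or_cmle
            checked += 1
        assert checked > 20

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=60, deadline=None)
    def test_p_greater_monotone_in_diagonal_shift(self, seed):
        """Shifting mass onto the diagonal (a+1, b-1, c-1, d+1), margins
        fixed, never increases the one-sided 'greater' p-value."""
        rng = np.random.default_rng(seed)
        a, b, c, d = next(iter(random_tables(rng, 1, n_max=30)))
        if b < 1 or c < 1:
            return
        p1 = fisher_exact_one_sided((a, b, c, d)).p
        p2 = fisher_exact_one_sided((a + 1, b - 1, c - 1, d + 1)).p
        assert p2 <= p1 + 1e-12

    def test_empty_margin_returns_p_one_with_warning(self):
        with pytest.warns(UserWarning, match="empty margin"):
            res = fisher_exact_one_sided((0, 0, 3, 4))
        assert res.p == 1.0
        assert math.isnan(res.or_cmle)

    @pytest.mark.parametrize("bad", [(-1, 2, 3, 4), (1.5, 2, 3, 4)])
    def test_invalid_cells_rejected(self, bad):
        with pytest.raises(EnrichmentError):
            fisher_exact_one_sided(bad)

    def test_invalid_alpha_rejected(self):
        with pytest.raises(EnrichmentError, match="alpha"):
            fisher_exact_one_sided((1, 1, 1, 1), alpha=1.5)


class TestEnrichmentScan:
    def _score_table(self):
        # senescent strictly lower on both axes: complete separation
        n = 10
        return pd.DataFrame(
            {
                "TREXes": np.r_[-np.arange(1, n + 1), np.arange(1, n + 1)] / 10,
                "NCTFs": np.r_[-np.arange(1, n + 1), np.arange(1, n + 1)] / 10,
                "group": ["senescent"] * n + ["nonsenescent"] * n,
            },
            index=[f"s{i}" for i in range(2 * n)],
        )

    def test_complete_separation_gives_boundary_ors(self):
        _, results = enrichment_scan(
            self._score_table(), "TREXes", "NCTFs", "group", "senescent"
        )
        by = {(r.target_group, r.target_quadrant): r for r in results}
        assert math.isinf(by[("senescent", "Q3")].or_cmle)
        assert by[("senescent", "Q1")].or_cmle == 0.0
        # complementary group reported for paired bar plots
        assert ("nonsenescent", "Q3") in by
        assert by[("nonsenescent", "Q3")].or_cmle == 0.0

    def test_single_quadrant_without_complement(self):
        _, results = enrichment_scan(
            self._score_table(), "TREXes", "NCTFs", "group", "senescent",
            quadrants=["Q3"], include_complement=False,
        )
        assert len(results) == 1
        assert results[0].target_quadrant == "Q3"

    def test_missing_column_error(self):
        with pytest.raises(EnrichmentError, match="not in score table"):
            enrichment_scan(
                self._score_table(), "TREXes", "NOPE", "group", "senescent"
            )


class TestExports:
    def test_scatter_rows_match_samples(self):
        res = assign_quadrants([1, 2, 3, 4], [4, 3, 2, 1])
        out = scatter_export(res, ["a", "a", "b", "b"])
        assert len(out) == 4
        assert list(out.columns) == ["sample", "x", "y", "quadrant", "group"]

    def test_empty_results_give_empty_table_with_header(self):
        out = or_bar_export([])
        assert out.empty
        assert "odds_ratio" in out.columns

    def test_infinite_or_serializes_as_Inf(self, tmp_path):
        from senquad.io import write_enrichment_tsv

        res = fisher_exact_one_sided((2, 0, 0, 2), target_quadrant="Q3",
                                     target_group="sen", comparison="x~y")
        path = tmp_path / "enr.tsv"
        write_enrichment_tsv([res], path)
        text = path.read_text()
        assert "\tInf\t" in text
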