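"""Counts, cross-tabs, quantile summaries, percent rendering and the rank-sum test."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from srcensus.census import (
    count_by,
    crosstab_interventions,
    grouped_quantiles,
    per_review_summary,
    quantile,
    render_percent,
    wilcoxon_rank_sum,
)
from srcensus.curation import select_eligible_meta_analyses
from srcensus.model import Comparison, SRDatabase
from srcensus.synthetic import default_config, generate_database

from conftest import plot, review


class TestQuantileConvention:
    def test_interpolation_at_position_np1(self):
        # position (n-1)p + 1 = 1.75 -> 1 + 0.75 * (2 - 1)
        assert quantile([1, 2, 3, 4], 0.25) == pytest.approx(1.75)

    def test_odd_length_median_is_order_statistic(self):
        assert quantile([2, 2, 3, 6, 10], 0.5) == 3

    def test_monotone_and_bounded(self):
        rng = np.random.default_rng(0)
        vals = rng.integers(2, 300, size=57)
        ps = [0.1, 0.25, 0.5, 0.75, 0.9, 0.99]
        qs = [quantile(vals, p) for p in ps]
        assert all(b >= a for a, b in zip(qs, qs[1:]))
        assert vals.min() <= qs[0] and qs[-1] <= vals.max()


class TestRenderPercent:
    @pytest.mark.parametrize("count,total,style,expected", [
        (186, 22453, "integer-floor-label", "<1%"),
        (0, 22453, "integer-floor-label", "0%"),
        (4027, 22453, "integer-floor-label", "18%"),
        (4321, 22453, "integer-floor-label", "19%"),
        (5571, 22453, "integer-floor-label", "25%"),
        (14105, 22453, "integer-floor-label", "63%"),
        (1204, 22453, "integer-floor-label", "5%"),
        (94, 22453, "one-decimal-small", "0.4%"),
        (29, 22453, "one-decimal-small", "0.1%"),
        (3639, 22453, "one-decimal-small", "16%"),
        (2368, 22453, "one-decimal-small", "11%"),
    ])
    def test_dialects(self, count, total, style, expected):
        assert render_percent(count, total, style) == expected

    def test_total_zero_rejected(self):
        with pytest.raises(ValueError):
            render_percent(0, 0)


class TestCountBy:
    def test_counts_with_zero_categories(self, tiny_db):
        table = count_by(tiny_db, "specialty")
        assert table.loc["Cancer", "count"] == 2
        assert table.loc["Urogenital", "count"] == 1
        assert table["count"].sum() == tiny_db.n_plots
        assert table.loc["Respiratory diseases", "count"] == 0

    def test_missing_label_names_plot(self):
        db = SRDatabase(reviews=[review(specialty=None)])
        with pytest.raises(ValueError, match="R1"):
            count_by(db, "specialty")

    def test_empty_database_renders_em_dash(self):
        table = count_by(SRDatabase(), "outcome_category")
        assert (table["count"] == 0).all()
        assert (table["percent"] == "—").all()

    def test_data_type_group_dimension(self, tiny_db):
        table = count_by(tiny_db, "data_type_group")
        assert table.loc["Dichotomous", "count"] == 3
        assert table.loc["Mixed", "count"] == 0


class TestCrossTab:
    def test_small_example_margins(self):
        db = SRDatabase(reviews=[
            review("R1", active="Pharmacological", comparator="Placebo"),
            review("R2", active="Pharmacological", comparator="Placebo"),
            review("R3", active="Surgical", comparator="Surgical"),
        ])
        xt = crosstab_interventions(db)
        assert xt.table.loc["Pharmacological", "Placebo"] == 2
        assert xt.table.loc["Surgical", "same-category non-pharm"] == 1
        assert xt.grand_total == 3
        xt.check_margins()
        assert xt.rendered().loc["Pharmacological", "same-category non-pharm"] == "n/a"

    def test_unclassified_comparison_rejected(self):
        db = SRDatabase(reviews=[review()])
        db.reviews[0].comparisons[0].active_intervention_label = None
        with pytest.raises(ValueError, match="not classified"):
            crosstab_interventions(db)

    def test_margins_conserved_on_synthetic_data(self):
        db, _ = generate_database(default_config(n_reviews=60, seed=2))
        curated = select_eligible_meta_analyses(db).curated
        xt = crosstab_interventions(curated)
        xt.check_margins()
        assert xt.grand_total == curated.n_plots


class TestPerReviewSummary:
    def test_median_comparisons_per_review(self):
        db = SRDatabase(reviews=[
            review("R1", comparisons=[
                Comparison(comparison_id=f"C{i}", outcomes=[plot()])
                for i in range(1, 2)]),
            review("R2", comparisons=[
                Comparison(comparison_id=f"C{i}", outcomes=[plot()])
                for i in range(1, 4)]),
        ])
        s = per_review_summary(db)
        assert s["comparisons_per_review"].quantiles[0.5] == 2

    def test_meta_analyses_per_review_sums_plots(self):
        db = SRDatabase(reviews=[review("R1", comparisons=[
            Comparison(comparison_id="C1", outcomes=[plot(f"O{i}") for i in range(2)]),
            Comparison(comparison_id="C2", outcomes=[plot(f"O{i}") for i in range(4)]),
        ])])
        s = per_review_summary(db)
        assert s["meta_analyses_per_review"].quantiles[0.5] == 6
        assert s["meta_analyses_per_review"].maximum == 6

    def test_single_comparison_five_outcomes(self):
        db = SRDatabase(reviews=[review("R1", comparisons=[
            Comparison(comparison_id="C1", outcomes=[plot(f"O{i}") for i in range(5)]),
        ])])
        s = per_review_summary(db)
        oc = s["outcomes_per_comparison"]
        assert oc.minimum == oc.quantiles[0.5] == oc.maximum == 5


@pytest.fixture(scope="module")
def curated():
    db, _ = generate_database(default_config(n_reviews=80, seed=7))
    return select_eligible_meta_analyses(db).curated


class TestGroupedQuantiles:
    @pytest.mark.parametrize("grouping", ["data_type_group", "specialty",
                                          "collapsed5", "outcome_group11"])
    def test_groups_partition_meta_analyses(self, curated, grouping):
        groups = grouped_quantiles(curated, "studies_per_meta_analysis", grouping)
        assert sum(g.n for g in groups) == curated.n_plots

    def test_sample_size_missing_counted(self, curated):
        groups = grouped_quantiles(curated, "study_sample_size", "none",
                                   probs=(0.25, 0.5, 0.75))
        total, = groups
        assert total.n + total.n_missing == curated.n_studies
        assert total.n_missing > 0  # some generic/O-E entries omit totals

    def test_quantiles_monotone_within_each_group(self, curated):
        for g in grouped_quantiles(curated, "study_sample_size", "specialty",
                                   probs=(0.25, 0.5, 0.75)):
            if g.n:
                vals = [g.quantiles[p] for p in sorted(g.quantiles)]
                assert vals == sorted(vals)
                assert g.maximum >= vals[-1]

    def test_unknown_grouping_rejected(self, curated):
        with pytest.raises(ValueError, match="grouping"):
            grouped_quantiles(curated, "studies_per_meta_analysis", "by-moon-phase")


def oracle_p(x, y):
    """Brute-force two-sided rank-sum p-value by enumerating assignments."""
    pooled = np.concatenate([x, y])
    n, n1 = len(pooled), len(x)
    order = np.argsort(pooled, kind="mergesort")
    ranks = np.empty(n)
    i = 0
    while i < n:  # mid-ranks computed from scratch
        j = i
        while j < n and pooled[order[j]] == pooled[order[i]]:
            j += 1
        ranks[order[i:j]] = (i + j + 1) / 2.0
        i = j
    mean_u = n1 * (n - n1) / 2.0
    offset = n1 * (n1 + 1) / 2.0
    dev = abs(ranks[:n1].sum() - offset - mean_u)
    hits = total = 0
    for combo in itertools.combinations(ranks, n1):
        total += 1
        if abs(sum(combo) - offset - mean_u) >= dev - 1e-12:
            hits += 1
    return hits / total


class TestWilcoxonRankSum:
    def test_complete_separation_small_sample(self):
        res = wilcoxon_rank_sum([1, 2, 3], [4, 5, 6])
        assert res.u == 0
        assert res.method == "exact"
        assert res.p_two_sided == pytest.approx(0.1)

    def test_identical_multisets_give_p_one(self):
        res = wilcoxon_rank_sum([1, 2, 2, 5], [1, 2, 2, 5])
        assert res.u == pytest.approx(8.0)  # n1 n2 / 2
        assert res.p_two_sided == pytest.approx(1.0)

    def test_u_within_range_and_p_valid(self):
        rng = np.random.default_rng(4)
        x, y = rng.normal(size=9), rng.normal(1.0, 1, size=12)
        res = wilcoxon_rank_sum(x, y)
        assert 0 <= res.u <= 9 * 12
        assert 0 <= res.p_two_sided <= 1

    def test_exact_matches_scipy_without_ties(self):
        rng = np.random.default_rng(8)
        x, y = rng.normal(size=6), rng.normal(0.8, 1, size=7)
        ours = wilcoxon_rank_sum(x, y)
        ref = sps.mannwhitneyu(x, y, alternative="two-sided", method="exact")
        assert ours.p_two_sided == pytest.approx(ref.pvalue, abs=1e-12)

    def test_normal_approximation_close_to_exact_oracle(self):
        """Fixed balanced 8+8 data: |p_normal - p_exact| < 0.01 (tie-free)."""
        rng = np.random.default_rng(0)
        x = rng.normal(0, 1, size=8)
        y = rng.normal(0.5, 1, size=8)
        approx = wilcoxon_rank_sum(x, y, exact_limit=0)
        assert approx.method == "normal-approximation"
        assert abs(approx.p_two_sided - oracle_p(x, y)) < 0.01

    @settings(max_examples=15, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 1000))
    def test_normal_approximation_matches_scipy_asymptotic(self, seed):
        """The tie-corrected, continuity-corrected approximation reproduces
        the reference asymptotic implementation on arbitrary samples."""
        rng = np.random.default_rng(seed)
        x = rng.integers(0, 12, size=9).astype(float)  # ties likely
        y = rng.integers(0, 12, size=13).astype(float)
        ours = wilcoxon_rank_sum(x, y, exact_limit=0)
        ref = sps.mannwhitneyu(x, y, alternative="two-sided",
                               method="asymptotic", use_continuity=True)
        assert ours.p_two_sided == pytest.approx(ref.pvalue, abs=1e-9)

    def test_tied_data_agrees_with_oracle(self):
        x = [1, 2, 2, 3, 5, 5]
        y = [2, 3, 3, 5, 6, 7]
        exact = wilcoxon_rank_sum(x, y)
        assert exact.method == "exact"
        assert exact.p_two_sided == pytest.approx(oracle_p(x, y))

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_rank_sum([], [1.0])
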