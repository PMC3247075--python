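"""Eligibility rules, phantom patterns, deduplication and ledger accounting."""

import pytest
from hypothesis import given, settings, strategies as st

from srcensus.curation import (
    CurationConfig,
    deduplicate_plot,
    detect_structural_anomalies,
    filter_reviews,
    is_phantom_study,
    select_eligible_meta_analyses,
)
from srcensus.model import (
    ContinuousData,
    DichotomousData,
    GenericData,
    OEData,
    OutcomePlot,
    SRDatabase,
    StudyEntry,
    Subgroup,
)
from srcensus.synthetic import default_config, generate_database

from conftest import dich, entry, plot, review


def centry(study_id, n1, n2, m1=0.0, m2=0.0, s1=0.0, s2=0.0):
    return StudyEntry(study_id=study_id, payload=ContinuousData(
        n_1=n1, n_2=n2, mean_1=m1, mean_2=m2, sd_1=s1, sd_2=s2))


class TestFilterReviews:
    def test_mixed_statuses(self):
        db = SRDatabase(reviews=[
            review("R1", status="protocol"),
            review("R2", status="withdrawn"),
            review("R3"), review("R4"), review("R5"),
        ])
        kept, ledger = filter_reviews(db)
        assert [r.review_id for r in kept.reviews] == ["R3", "R4", "R5"]
        excluded = {reason: ex for _, _, ex, reason in ledger.stages}
        assert excluded == {"protocol": 1, "withdrawn": 1,
                            "methodology review group": 0}

    def test_identity_on_clean_database(self, tiny_db):
        kept, ledger = filter_reviews(tiny_db)
        assert kept == tiny_db
        assert ledger.total_excluded == 0

    def test_empty_database(self):
        kept, ledger = filter_reviews(SRDatabase())
        assert kept.reviews == []
        assert ledger.records_out == 0
        assert all(ex == 0 for _, _, ex, _ in ledger.stages)

    def test_methodology_group_excluded(self):
        db = SRDatabase(reviews=[review("R1", methodology=True), review("R2")])
        kept, _ = filter_reviews(db)
        assert [r.review_id for r in kept.reviews] == ["R2"]


class TestPhantomPatterns:
    @pytest.mark.parametrize("payload,expected", [
        # the stored zero-pattern: apparent sample size 2, no data
        (DichotomousData(events_1=0, total_1=1, events_2=0, total_2=1), True),
        # sample size 2 with a *different* pattern is genuine
        (DichotomousData(events_1=1, total_1=1, events_2=0, total_2=1), False),
        (DichotomousData(events_1=0, total_1=2, events_2=0, total_2=2), False),
        (ContinuousData(n_1=1, n_2=1, mean_1=0, mean_2=0, sd_1=0, sd_2=0), True),
        (ContinuousData(n_1=1, n_2=1, mean_1=0.5, mean_2=0, sd_1=0, sd_2=0), False),
        (ContinuousData(n_1=2, n_2=2, mean_1=0, mean_2=0, sd_1=0, sd_2=0), False),
        (OEData(o_minus_e=0.0, variance=0.0), True),
        (OEData(o_minus_e=0.0, variance=1.0), False),
        (GenericData(estimate=0.0, standard_error=0.0), True),
        (GenericData(estimate=0.0, standard_error=0.2), False),
    ])
    def test_patterns(self, payload, expected):
        assert is_phantom_study(StudyEntry(study_id="S", payload=payload)) is expected

    def test_generic_rule_can_be_switched_off(self):
        e = StudyEntry(study_id="S",
                       payload=GenericData(estimate=0.0, standard_error=0.0))
        assert not is_phantom_study(e, CurationConfig(generic_phantom_rule=False))

    def test_continuous_any_split_reading(self):
        e = centry("S", 2, 0)
        assert not is_phantom_study(e)
        assert is_phantom_study(e, CurationConfig(continuous_any_split=True))


class TestDeduplication:
    def test_first_occurrence_across_subgroups(self):
        p = plot(subgroups=[
            Subgroup(name="s1", studies=[entry("A"), entry("B")]),
            Subgroup(name="s2", studies=[entry("A"), entry("C")]),
        ])
        out, removed = deduplicate_plot(p)
        assert removed == 1
        assert [e.study_id for e in out.subgroups[0].studies] == ["A", "B"]
        assert [e.study_id for e in out.subgroups[1].studies] == ["C"]

    def test_distinct_ids_identity(self):
        p = plot(ids=("A", "B", "C"))
        out, removed = deduplicate_plot(p)
        assert removed == 0 and out is p

    def test_slightly_different_labels_both_kept(self):
        p = plot(ids=("Smith 2001a", "Smith 2001b"))
        _, removed = deduplicate_plot(p)
        assert removed == 0

    def test_idempotent(self):
        p = plot(subgroups=[
            Subgroup(name="s1", studies=[entry("A"), entry("A"), entry("B")]),
            Subgroup(name="s2", studies=[entry("B")]),
        ])
        once, removed1 = deduplicate_plot(p)
        twice, removed2 = deduplicate_plot(once)
        assert removed1 == 2 and removed2 == 0 and twice == once
        ids = [e.study_id for _, _, e in once.iter_entries()]
        assert len(ids) == len(set(ids))


PHANTOM_DICH = DichotomousData(events_1=0, total_1=1, events_2=0, total_2=1)


class TestSelectEligible:
    def test_single_study_plot_excluded(self):
        db = SRDatabase(reviews=[review(plots=[plot(ids=("A",))])])
        report = select_eligible_meta_analyses(db)
        assert report.curated.n_plots == 0
        assert report.curated.reviews == []

    def test_phantom_reduces_plot_below_threshold(self):
        p = plot(subgroups=[Subgroup(studies=[
            entry("A"), StudyEntry(study_id="Ph", payload=PHANTOM_DICH)])])
        report = select_eligible_meta_analyses(SRDatabase(reviews=[review(plots=[p])]))
        assert report.curated.n_plots == 0

    def test_duplicate_leaves_two_distinct_studies(self):
        p = plot(subgroups=[
            Subgroup(name="s1", studies=[entry("A"), entry("B")]),
            Subgroup(name="s2", studies=[entry("A")]),
        ])
        report = select_eligible_meta_analyses(SRDatabase(reviews=[review(plots=[p])]))
        assert report.curated.n_plots == 1
        assert report.curated.n_studies == 2

    def test_idempotent_on_own_output(self):
        db, _ = generate_database(default_config(n_reviews=30, seed=11))
        first = select_eligible_meta_analyses(db)
        second = select_eligible_meta_analyses(first.curated)
        assert second.curated == first.curated
        assert second.study_ledger.total_excluded == 0
        assert second.meta_analysis_ledger.total_excluded == 0

    @settings(max_examples=10, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_ledger_conservation_on_random_databases(self, seed):
        db, _ = generate_database(default_config(n_reviews=12, seed=seed))
        report = select_eligible_meta_analyses(db)
        for ledger in (report.review_ledger, report.meta_analysis_ledger,
                       report.study_ledger):
            for (s0, in0, ex0, _), (s1, in1, _, _) in zip(ledger.stages,
                                                          ledger.stages[1:]):
                assert in1 == in0 - ex0, f"{s0} -> {s1}"
        assert (report.curated.n_studies + report.study_ledger.total_excluded
                == db.n_studies)
        assert (report.curated.n_plots + report.meta_analysis_ledger.total_excluded
                == db.n_plots)

    def test_curated_database_satisfies_report_invariants(self):
        db, _ = generate_database(default_config(n_reviews=40, seed=5))
        curated = select_eligible_meta_analyses(db).curated
        for r in curated.reviews:
            assert r.status == "full" and not r.is_methodology_group
            assert r.comparisons
        for _, _, p in curated.iter_plots():
            ids = [e.study_id for _, _, e in p.iter_entries()]
            assert len(ids) == len(set(ids)) and len(ids) >= 2
            for _, _, e in p.iter_entries():
                assert not is_phantom_study(e)


class TestAnomalies:
    def test_duplicate_sibling_outcome_names(self):
        db = SRDatabase(reviews=[review(plots=[
            plot("O1", name="Pain at 6 weeks"), plot("O2", name="Pain at 6 weeks")])])
        warnings = detect_structural_anomalies(db)
        assert len(warnings) == 1
        assert warnings[0].kind == "duplicate-outcome-name"

    def test_clean_database_is_quiet(self, tiny_db):
        assert detect_structural_anomalies(tiny_db) == []

    def test_missing_outcome_name_flagged(self):
        db = SRDatabase(reviews=[review(plots=[plot("O1", name=None)])])
        warnings = detect_structural_anomalies(db)
        assert [w.kind for w in warnings] == ["missing-name"]
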