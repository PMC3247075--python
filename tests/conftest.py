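import pytest

from srcensus.model import (
    Comparison,
    DichotomousData,
    OutcomePlot,
    Review,
    SRDatabase,
    StudyEntry,
    Subgroup,
)


def dich(e1=1, t1=10, e2=2, t2=10) -> DichotomousData:
    return DichotomousData(events_1=e1, total_1=t1, events_2=e2, total_2=t2)


def entry(study_id: str, payload=None) -> StudyEntry:
    return StudyEntry(study_id=study_id, payload=payload or dich())


_AUTO_NAME = object()


def plot(outcome_id="O1", ids=("A", "B"), name=_AUTO_NAME, category="Pain",
         data_type="dichotomous", subgroups=None) -> OutcomePlot:
    if name is _AUTO_NAME:
        name = f"Outcome {outcome_id}"
    if subgroups is None:
        subgroups = [Subgroup(name="", studies=[entry(i) for i in ids])]
    return OutcomePlot(
        outcome_id=outcome_id, name=name, data_type=data_type,
        outcome_category_label=category, subgroups=subgroups,
    )


def review(review_id="R1", status="full", methodology=False,
           specialty="Cancer", plots=None, comparisons=None,
           active="Pharmacological", comparator="Placebo") -> Review:
    if comparisons is None:
        comparisons = [Comparison(
            comparison_id="C1", name="test",
            active_intervention_label=active, comparator_label=comparator,
            outcomes=plots if plots is not None else [plot()],
        )]
    return Review(
        review_id=review_id, title=f"Review {review_id}", review_group="G",
        status=status, is_methodology_group=methodology,
        specialty_label=specialty, comparisons=comparisons,
    )


@pytest.fixture
def tiny_db() -> SRDatabase:
    """Two fully labelled reviews, three plots, all eligible."""
    return SRDatabase(issue_label="test", reviews=[
        review("R1", plots=[plot("O1", ("A", "B")), plot("O2", ("A", "C", "D"))]),
        review("R2", specialty="Urogenital", active="Surgical",
               comparator="Surgical", plots=[plot("O1", ("X", "Y"))]),
    ])
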