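"""Controlled vocabularies and collapse maps for the census classifications.

Three vocabularies: 11 medical specialties, 17 intervention categories
(15 "active" plus the two control kinds Control and Placebo), and 23
outcome categories with a priority order for multi-category outcomes.
Collapse maps produce the coarser groupings used in stratified summaries:
the five-way intervention-comparison grouping ("collapsed5"), the 11-group
outcome collapse, and the three-way data-type grouping (generic and O-E
data pooled as "mixed").

Vocabularies ship as an editable YAML file; see :func:`load_vocabularies`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import yaml

from .model import SRDatabase

__all__ = [
    "Vocabularies",
    "ComparisonClass",
    "LabelViolation",
    "load_vocabularies",
    "resolve_outcome_category",
    "classify_comparison",
    "collapse_outcome_group",
    "collapse_data_type",
    "validate_labels",
    "COLLAPSED5_GROUPS",
    "COMPARATOR_KINDS",
    "DATA_TYPE_GROUPS",
]

#: the five-way intervention-comparison grouping, in display order
COLLAPSED5_GROUPS = (
    "Pharm vs Control/Placebo",
    "Pharm vs Pharm",
    "Pharm vs Non-Pharm",
    "Non-Pharm vs Control/Placebo",
    "Non-Pharm vs Non-Pharm",
)

#: comparator kinds (the five "second intervention" columns), in display order
COMPARATOR_KINDS = (
    "Control",
    "Placebo",
    "Pharmacological",
    "same-category non-pharm",
    "different-category non-pharm",
)

#: data-type collapse: generic and O-E results are pooled as mixed outcome data
DATA_TYPE_GROUPS: Mapping[str, str] = {
    "dichotomous": "Dichotomous",
    "continuous": "Continuous",
    "generic": "Mixed",
    "oe_variance": "Mixed",
}

_PHARM = "Pharmacological"


@dataclass(frozen=True)
class Vocabularies:
    """The three controlled vocabularies plus collapse maps."""

    specialties: tuple[str, ...]
    active_interventions: tuple[str, ...]
    control_interventions: tuple[str, ...]
    outcomes: tuple[str, ...]
    outcome_priority: tuple[str, ...]
    outcome_group11: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.specialties) != 11:
            raise ValueError(f"expected 11 specialties, got {len(self.specialties)}")
        if len(self.active_interventions) != 15 or len(self.control_interventions) != 2:
            raise ValueError("expected 15 active + 2 control intervention categories")
        if len(self.outcomes) != 23:
            raise ValueError(f"expected 23 outcome categories, got {len(self.outcomes)}")
        for name, seq in (("specialties", self.specialties),
                          ("interventions", self.interventions),
                          ("outcomes", self.outcomes)):
            if len(set(seq)) != len(seq):
                raise ValueError(f"duplicate names in {name}")
        if sorted(self.outcome_priority) != sorted(self.outcomes):
            raise ValueError("outcome_priority must be a permutation of the outcome categories")
        if set(self.outcome_group11) != set(self.outcomes):
            raise ValueError("outcome_group11 must cover every outcome category")
        if len(set(self.outcome_group11.values())) != 11:
            raise ValueError("outcome_group11 must map onto exactly 11 groups")

    @property
    def interventions(self) -> tuple[str, ...]:
        """All 17 intervention categories (active + control)."""
        return self.active_interventions + self.control_interventions

    @property
    def outcome_groups(self) -> tuple[str, ...]:
        """The 11 collapsed outcome groups, in first-appearance order."""
        seen: dict[str, None] = {}
        for cat in self.outcomes:
            seen.setdefault(self.outcome_group11[cat], None)
        return tuple(seen)


def load_vocabularies(path: str | Path | None = None) -> Vocabularies:
    """Load vocabularies from a YAML file (the packaged defaults when *path* is None)."""
    if path is None:
        text = resources.files("srcensus.data").joinpath("vocabularies.yaml").read_text("utf-8")
    else:
        text = Path(path).read_text("utf-8")
    raw = yaml.safe_load(text)
    return Vocabularies(
        specialties=tuple(raw["specialties"]),
        active_interventions=tuple(raw["active_interventions"]),
        control_interventions=tuple(raw["control_interventions"]),
        outcomes=tuple(raw["outcomes"]),
        outcome_priority=tuple(raw["outcome_priority"]),
        outcome_group11=dict(raw["outcome_group11"]),
    )


_DEFAULT: Optional[Vocabularies] = None


def default_vocabularies() -> Vocabularies:
    """The packaged default vocabularies (cached)."""
    global _DEFAULT
    if _DEFAULT is None:
        _DEFAULT = load_vocabularies()
    return _DEFAULT


def resolve_outcome_category(candidates: Iterable[str], vocab: Vocabularies | None = None) -> str:
    """Pick the single category for an outcome that could fall under several.

    Returns the candidate highest on the vocabulary's priority list.
    """
    vocab = vocab or default_vocabularies()
    cands = set(candidates)
    if not cands:
        raise ValueError("empty candidate set")
    unknown = cands - set(vocab.outcomes)
    if unknown:
        raise KeyError(f"unknown outcome categories: {sorted(unknown)}")
    rank = {name: i for i, name in enumerate(vocab.outcome_priority)}
    return min(cands, key=rank.__getitem__)


@dataclass(frozen=True)
class ComparisonClass:
    """Classification of one pair-wise intervention comparison.

    ``comparator_kind`` is the fine five-way column (Control, Placebo,
    Pharmacological, same-/different-category non-pharm); ``collapsed5``
    is the coarse five-way grouping used in stratified summaries.
    """

    active_category: str
    comparator_kind: str
    collapsed5: str


def classify_comparison(
    active: str, comparator: str, vocab: Vocabularies | None = None
) -> ComparisonClass:
    """Assign a comparison to its comparator-kind cell and collapsed5 group.

    *active* must be one of the 15 active categories; *comparator* may be an
    active category or one of the control kinds.  A pharmacological active
    intervention has no "same-category non-pharm" cell.
    """
    vocab = vocab or default_vocabularies()
    if active not in vocab.active_interventions:
        raise KeyError(f"unknown active intervention {active!r}")
    if comparator not in vocab.interventions:
        raise KeyError(f"unknown comparator {comparator!r}")

    if comparator in vocab.control_interventions:
        kind = comparator  # "Control" or "Placebo"
    elif comparator == _PHARM:
        kind = _PHARM
    elif comparator == active:
        kind = "same-category non-pharm"
    else:
        kind = "different-category non-pharm"

    active_pharm = active == _PHARM
    if active_pharm and kind == "same-category non-pharm":  # unreachable by construction
        raise ValueError("pharmacological active intervention has no same-category non-pharm cell")

    if comparator in vocab.control_interventions:
        collapsed = "Pharm vs Control/Placebo" if active_pharm else "Non-Pharm vs Control/Placebo"
    else:
        comp_pharm = comparator == _PHARM
        if active_pharm and comp_pharm:
            collapsed = "Pharm vs Pharm"
        elif active_pharm or comp_pharm:
            collapsed = "Pharm vs Non-Pharm"
        else:
            collapsed = "Non-Pharm vs Non-Pharm"

    return ComparisonClass(active_category=active, comparator_kind=kind, collapsed5=collapsed)


def collapse_outcome_group(category: str, vocab: Vocabularies | None = None) -> str:
    """Map one of the 23 outcome categories onto its 11-group row."""
    vocab = vocab or default_vocabularies()
    try:
        return vocab.outcome_group11[category]
    except KeyError:
        raise KeyError(f"unknown outcome category {category!r}") from None


def collapse_data_type(data_type: str) -> str:
    """Map a plot data type onto the Dichotomous/Continuous/Mixed grouping."""
    try:
        return DATA_TYPE_GROUPS[data_type]
    except KeyError:
        raise KeyError(f"unknown data type {data_type!r}") from None


@dataclass(frozen=True)
class LabelViolation:
    path: str
    message: str

    def __str__(self) -> str:
        return f"{self.path}: {self.message}"


def validate_labels(db: SRDatabase, vocab: Vocabularies | None = None) -> list[LabelViolation]:
    """Check every specialty/intervention/outcome label against the vocabularies.

    Returns one violation per offending label, with the path into the
    hierarchy; an empty list means the database is fully classified.
    """
    vocab = vocab or default_vocabularies()
    out: list[LabelViolation] = []
    specialties = set(vocab.specialties)
    actives = set(vocab.active_interventions)
    all_interventions = set(vocab.interventions)
    outcomes = set(vocab.outcomes)

    for review in db.reviews:
        rpath = f"review {review.review_id}"
        if review.specialty_label is not None and review.specialty_label not in specialties:
            out.append(LabelViolation(rpath, f"unknown specialty {review.specialty_label!r}"))
        for comparison in review.comparisons:
            cpath = f"{rpath} / comparison {comparison.comparison_id}"
            a = comparison.active_intervention_label
            b = comparison.comparator_label
            if a is not None and a not in actives:
                out.append(LabelViolation(cpath, f"unknown active intervention {a!r}"))
            if b is not None and b not in all_interventions:
                out.append(LabelViolation(cpath, f"unknown comparator {b!r}"))
            for plot in comparison.outcomes:
                opath = f"{cpath} / outcome {plot.outcome_id}"
                lab = plot.outcome_category_label
                if lab is None:
                    out.append(LabelViolation(opath, "missing outcome category label"))
                elif lab not in outcomes:
                    out.append(LabelViolation(opath, f"unknown outcome category {lab!r}"))
    return out
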