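"""Eligibility and cleaning pipeline with a stage-by-stage audit ledger.

Review-level exclusions (protocols, withdrawn reviews, methodology-group
reviews), removal of phantom study records, within-plot deduplication of
overlapping subgroups, the at-least-two-studies rule for forest plots, and
finally removal of reviews left with no eligible meta-analysis.  Every
stage is recorded in a :class:`FlowLedger` so that counts can be audited
end to end.

Phantom study records are an artefact of legacy forest-plot software,
which stored a fixed zero-pattern row (apparent sample size 2) for studies
listed in a plot without contributing data to that particular
meta-analysis.  Genuine sample-size-2 studies with a different data
pattern are never removed.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd

from .model import (
    ContinuousData,
    DichotomousData,
    GenericData,
    OEData,
    OutcomePlot,
    Review,
    SRDatabase,
    StudyEntry,
    Subgroup,
)

__all__ = [
    "CurationConfig",
    "FlowLedger",
    "CurationReport",
    "filter_reviews",
    "is_phantom_study",
    "deduplicate_plot",
    "select_eligible_meta_analyses",
    "detect_structural_anomalies",
]


@dataclass(frozen=True)
class CurationConfig:
    """Switches for the data-pattern rules where the canonical rule is ambiguous.

    ``generic_phantom_rule``: treat estimate=0 with standard error 0 as the
    phantom pattern for generic payloads (by analogy with the other three
    data types, which have documented patterns).
    ``continuous_any_split``: accept any arm allocation summing to two
    (2+0 as well as 1+1) as the continuous phantom sample-size pattern.
    """

    generic_phantom_rule: bool = True
    continuous_any_split: bool = False


@dataclass
class FlowLedger:
    """Ordered record of (stage, records in, excluded, reason) rows.

    Conservation invariant: the records entering stage k+1 equal the
    records entering stage k minus the records excluded at stage k.
    """

    stages: list[tuple[str, int, int, str]] = field(default_factory=list)

    def add(self, stage: str, records_in: int, excluded: int, reason: str) -> None:
        if records_in < 0 or excluded < 0 or excluded > records_in:
            raise ValueError(f"bad ledger row: {stage!r} in={records_in} excluded={excluded}")
        if self.stages:
            prev_in, prev_ex = self.stages[-1][1], self.stages[-1][2]
            if records_in != prev_in - prev_ex:
                raise ValueError(
                    f"ledger conservation violated at {stage!r}: "
                    f"{records_in} != {prev_in} - {prev_ex}"
                )
        self.stages.append((stage, records_in, excluded, reason))

    @property
    def records_out(self) -> int:
        if not self.stages:
            return 0
        _, records_in, excluded, _ = self.stages[-1]
        return records_in - excluded

    @property
    def total_excluded(self) -> int:
        return sum(ex for _, _, ex, _ in self.stages)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.stages, columns=["stage", "records_in", "excluded", "reason"])


@dataclass
class CurationReport:
    """Full audit of one curation run: three ledgers plus the curated database."""

    review_ledger: FlowLedger
    meta_analysis_ledger: FlowLedger
    study_ledger: FlowLedger
    curated: SRDatabase
    removed_phantoms: list[tuple[str, str, str, int, int]] = field(default_factory=list)
    removed_duplicates: list[tuple[str, str, str, int, int]] = field(default_factory=list)

    def to_csv(self, path: str | Path) -> None:
        """Machine-readable ledger: one CSV with a `ledger` column."""
        frames = []
        for name, ledger in [("reviews", self.review_ledger),
                             ("meta_analyses", self.meta_analysis_ledger),
                             ("studies", self.study_ledger)]:
            frame = ledger.to_frame()
            frame.insert(0, "ledger", name)
            frames.append(frame)
        pd.concat(frames, ignore_index=True).to_csv(path, index=False)

    def summary_text(self) -> str:
        """Human-readable flow summary mirroring the eligibility diagram."""
        buf = io.StringIO()
        for name, ledger in [("Reviews", self.review_ledger),
                             ("Meta-analyses", self.meta_analysis_ledger),
                             ("Studies", self.study_ledger)]:
            buf.write(f"{name}\n")
            for stage, records_in, excluded, reason in ledger.stages:
                buf.write(f"  {stage}: {records_in} in, {excluded} excluded ({reason})\n")
            buf.write(f"  -> {ledger.records_out} retained\n")
        return buf.getvalue()


def filter_reviews(db: SRDatabase) -> tuple[SRDatabase, FlowLedger]:
    """Drop protocols, withdrawn reviews and methodology-group reviews.

    Each exclusion reason is a separate ledger stage so the counts can be
    reconciled individually.
    """
    ledger = FlowLedger()
    current = list(db.reviews)

    for reason, keep in [
        ("protocol", lambda r: r.status != "protocol"),
        ("withdrawn", lambda r: r.status != "withdrawn"),
        ("methodology review group", lambda r: not r.is_methodology_group),
    ]:
        kept = [r for r in current if keep(r)]
        ledger.add(f"exclude {reason}", len(current), len(current) - len(kept), reason)
        current = kept

    return SRDatabase(issue_label=db.issue_label, reviews=current), ledger


def is_phantom_study(entry: StudyEntry, config: CurationConfig | None = None) -> bool:
    """True when the entry matches the data-type-specific phantom zero-pattern.

    Dichotomous: 0/1 events in each group.  Continuous: sample size 2 with
    means and standard deviations of 0 in each group.  O-E: observed-minus-
    expected and variance both 0.  Generic (configurable, on by default):
    estimate and standard error both 0.  Anything else — including other
    sample-size-2 patterns — is genuine.
    """
    config = config or CurationConfig()
    p = entry.payload
    if isinstance(p, DichotomousData):
        return p.total_1 == 1 and p.total_2 == 1 and p.events_1 == 0 and p.events_2 == 0
    if isinstance(p, ContinuousData):
        if config.continuous_any_split:
            size_ok = p.n_1 + p.n_2 == 2
        else:
            size_ok = p.n_1 == 1 and p.n_2 == 1
        return size_ok and p.mean_1 == 0 and p.mean_2 == 0 and p.sd_1 == 0 and p.sd_2 == 0
    if isinstance(p, OEData):
        return p.o_minus_e == 0 and p.variance == 0
    if isinstance(p, GenericData):
        return config.generic_phantom_rule and p.estimate == 0 and p.standard_error == 0
    return False


def deduplicate_plot(plot: OutcomePlot) -> tuple[OutcomePlot, int]:
    """Keep only the first occurrence of each study identifier in the plot.

    Subgroups within a plot need not be mutually exclusive, so the same
    study may appear several times; document order across subgroups decides
    which occurrence survives.  Matching is exact string identity on the
    (trimmed) identifier — "Smith 2001a" and "Smith 2001b" are distinct.
    """
    seen: set[str] = set()
    new_subgroups: list[Subgroup] = []
    removed = 0
    for sg in plot.subgroups:
        kept = []
        for entry in sg.studies:
            if entry.study_id in seen:
                removed += 1
            else:
                seen.add(entry.study_id)
                kept.append(entry)
        new_subgroups.append(Subgroup(name=sg.name, studies=kept))
    if removed == 0:
        return plot, 0
    return plot.model_copy(update={"subgroups": new_subgroups}), removed


def select_eligible_meta_analyses(
    db: SRDatabase, config: CurationConfig | None = None
) -> CurationReport:
    """Run the full eligibility pipeline and return a complete audit.

    Stages, in order: review-level exclusions; phantom-record removal;
    within-plot deduplication; removal of forest plots left with fewer than
    two studies; removal of reviews left with no eligible plot.  Phantoms
    are removed before deduplication so a duplicated phantom cannot mask a
    second phantom occurrence; the final at-least-two-distinct-studies test
    is invariant to that order.
    """
    config = config or CurationConfig()

    filtered, review_ledger = filter_reviews(db)

    total_studies = db.n_studies
    studies_in_dropped_reviews = total_studies - filtered.n_studies
    total_plots = db.n_plots
    plots_in_dropped_reviews = total_plots - filtered.n_plots

    study_ledger = FlowLedger()
    study_ledger.add("in excluded reviews", total_studies, studies_in_dropped_reviews,
                     "review excluded")

    ma_ledger = FlowLedger()
    ma_ledger.add("in excluded reviews", total_plots, plots_in_dropped_reviews,
                  "review excluded")

    removed_phantoms: list[tuple[str, str, str, int, int]] = []
    removed_duplicates: list[tuple[str, str, str, int, int]] = []

    # pass 1: phantom removal
    n_phantoms = 0
    reviews_p1: list[Review] = []
    for review in filtered.reviews:
        comparisons = []
        for comparison in review.comparisons:
            outcomes = []
            for plot in comparison.outcomes:
                subgroups = []
                changed = False
                for i, sg in enumerate(plot.subgroups):
                    kept = []
                    for j, entry in enumerate(sg.studies):
                        if is_phantom_study(entry, config):
                            n_phantoms += 1
                            changed = True
                            removed_phantoms.append(
                                (review.review_id, comparison.comparison_id,
                                 plot.outcome_id, i, j)
                            )
                        else:
                            kept.append(entry)
                    subgroups.append(Subgroup(name=sg.name, studies=kept))
                outcomes.append(plot.model_copy(update={"subgroups": subgroups})
                                if changed else plot)
            comparisons.append(comparison.model_copy(update={"outcomes": outcomes}))
        reviews_p1.append(review.model_copy(update={"comparisons": comparisons}))
    study_ledger.add("phantom records", total_studies - studies_in_dropped_reviews,
                     n_phantoms, "zero-pattern phantom record")

    # pass 2: deduplication (positions recorded against the post-phantom plot)
    n_dups = 0
    reviews_p2: list[Review] = []
    for review in reviews_p1:
        comparisons = []
        for comparison in review.comparisons:
            outcomes = []
            for plot in comparison.outcomes:
                seen: set[str] = set()
                subgroups = []
                changed = False
                for i, sg in enumerate(plot.subgroups):
                    kept = []
                    for j, entry in enumerate(sg.studies):
                        if entry.study_id in seen:
                            n_dups += 1
                            changed = True
                            removed_duplicates.append(
                                (review.review_id, comparison.comparison_id,
                                 plot.outcome_id, i, j)
                            )
                        else:
                            seen.add(entry.study_id)
                            kept.append(entry)
                    subgroups.append(Subgroup(name=sg.name, studies=kept))
                outcomes.append(plot.model_copy(update={"subgroups": subgroups})
                                if changed else plot)
            comparisons.append(comparison.model_copy(update={"outcomes": outcomes}))
        reviews_p2.append(review.model_copy(update={"comparisons": comparisons}))
    study_ledger.add("within-plot duplicates",
                     study_ledger.records_out, n_dups, "duplicate study identifier")

    # pass 3: drop plots with fewer than two studies, then empty reviews
    plots_after_reviews = total_plots - plots_in_dropped_reviews
    n_small_plots = 0
    studies_in_small_plots = 0
    reviews_p3: list[Review] = []
    for review in reviews_p2:
        comparisons = []
        for comparison in review.comparisons:
            outcomes = []
            for plot in comparison.outcomes:
                if plot.n_studies >= 2:
                    outcomes.append(plot)
                else:
                    n_small_plots += 1
                    studies_in_small_plots += plot.n_studies
            comparisons.append(comparison.model_copy(update={"outcomes": outcomes}))
        # comparisons with no surviving plots are retained only if non-empty
        comparisons = [c for c in comparisons if c.outcomes]
        reviews_p3.append(review.model_copy(update={"comparisons": comparisons}))
    ma_ledger.add("fewer than two studies", plots_after_reviews, n_small_plots,
                  "fewer than two studies after cleaning")
    study_ledger.add("in ineligible plots", study_ledger.records_out,
                     studies_in_small_plots, "plot had fewer than two studies")

    surviving = [r for r in reviews_p3 if r.comparisons]
    review_ledger.add("no eligible meta-analysis", review_ledger.records_out,
                      len(reviews_p3) - len(surviving), "no eligible meta-analysis")

    curated = SRDatabase(issue_label=db.issue_label, reviews=surviving)
    return CurationReport(
        review_ledger=review_ledger,
        meta_analysis_ledger=ma_ledger,
        study_ledger=study_ledger,
        curated=curated,
        removed_phantoms=removed_phantoms,
        removed_duplicates=removed_duplicates,
    )


@dataclass(frozen=True)
class Anomaly:
    path: str
    kind: str
    message: str

    def __str__(self) -> str:
        return f"{self.path}: [{self.kind}] {self.message}"


def detect_structural_anomalies(db: SRDatabase) -> list[Anomaly]:
    """Flag likely data-entry mistakes without modifying anything.

    Checks: sibling outcomes under one comparison sharing a name (a common
    entry mistake is subgroups listed as if they were separate outcomes);
    plots with no outcome name; and study payloads whose type conflicts
    with the plot's declared data type.
    """
    warnings: list[Anomaly] = []
    for review in db.reviews:
        for comparison in review.comparisons:
            cpath = f"review {review.review_id} / comparison {comparison.comparison_id}"
            by_name: dict[str, list[str]] = {}
            for plot in comparison.outcomes:
                opath = f"{cpath} / outcome {plot.outcome_id}"
                if plot.name is None or not plot.name.strip():
                    warnings.append(Anomaly(opath, "missing-name", "plot has no outcome name"))
                else:
                    by_name.setdefault(plot.name.strip(), []).append(plot.outcome_id)
                for _, _, entry in plot.iter_entries():
                    if entry.payload.kind != plot.data_type:
                        warnings.append(Anomaly(
                            opath, "payload-type-conflict",
                            f"study {entry.study_id!r} has {entry.payload.kind} payload "
                            f"under {plot.data_type} plot",
                        ))
            for name, ids in by_name.items():
                if len(ids) > 1:
                    warnings.append(Anomaly(
                        cpath, "duplicate-outcome-name",
                        f"outcomes {ids} share the name {name!r} "
                        "(possible subgroups entered as outcomes)",
                    ))
    return warnings
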