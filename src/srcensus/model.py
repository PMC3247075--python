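"""Domain model for a hierarchical systematic-review database.

A database holds reviews; each review holds pair-wise intervention
comparisons; each comparison holds outcomes, where one outcome is one
forest plot (the unit treated as a candidate meta-analysis); each plot
holds one or more subgroups of study-level entries.  Study results come
in four shapes: dichotomous event counts, continuous summaries, generic
estimate/standard-error pairs, and observed-minus-expected ("O-E") event
counts with variance.

Two interchange formats are supported: a canonical JSON hierarchy and a
flat CSV with one row per study entry.  See :func:`load_database` and
:func:`save_database`.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Annotated, Iterator, Literal, Optional, Union

import pandas as pd
import pydantic
from pydantic import BaseModel, ConfigDict, Field, model_validator

__all__ = [
    "DataType",
    "DichotomousData",
    "ContinuousData",
    "GenericData",
    "OEData",
    "StudyEntry",
    "Subgroup",
    "OutcomePlot",
    "Comparison",
    "Review",
    "SRDatabase",
    "DatabaseFormatError",
    "sample_size",
    "load_database",
    "save_database",
]

DataType = Literal["dichotomous", "continuous", "generic", "oe_variance"]

NonNegInt = Annotated[int, Field(ge=0)]
NonNegFloat = Annotated[float, Field(ge=0)]


class DatabaseFormatError(ValueError):
    """Raised when an interchange file is malformed or violates an invariant.

    The message names the offending record and, for hierarchy violations,
    the path into the hierarchy.
    """


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid", validate_assignment=True)


class DichotomousData(_Strict):
    """Event counts and arm totals for a binary outcome."""

    kind: Literal["dichotomous"] = "dichotomous"
    events_1: NonNegInt
    total_1: NonNegInt
    events_2: NonNegInt
    total_2: NonNegInt

    @model_validator(mode="after")
    def _events_within_totals(self) -> "DichotomousData":
        if self.events_1 > self.total_1 or self.events_2 > self.total_2:
            raise ValueError("events exceed arm total")
        return self


class ContinuousData(_Strict):
    """Per-arm mean, standard deviation and sample size for a continuous outcome."""

    kind: Literal["continuous"] = "continuous"
    n_1: NonNegInt
    n_2: NonNegInt
    mean_1: float
    mean_2: float
    sd_1: NonNegFloat
    sd_2: NonNegFloat


class GenericData(_Strict):
    """An effect estimate with its standard error (time-to-event, ordinal, complex designs)."""

    kind: Literal["generic"] = "generic"
    estimate: float
    standard_error: NonNegFloat
    total_n: Optional[NonNegInt] = None


class OEData(_Strict):
    """Observed-minus-expected events and variance, typically from time-to-event analyses."""

    kind: Literal["oe_variance"] = "oe_variance"
    o_minus_e: float
    variance: NonNegFloat
    total_n: Optional[NonNegInt] = None


Payload = Annotated[
    Union[DichotomousData, ContinuousData, GenericData, OEData],
    Field(discriminator="kind"),
]

#: payload kind expected under each plot-level data type
PAYLOAD_KIND: dict[str, str] = {
    "dichotomous": "dichotomous",
    "continuous": "continuous",
    "generic": "generic",
    "oe_variance": "oe_variance",
}


class StudyEntry(_Strict):
    """One study's row in one forest plot."""

    study_id: str
    payload: Payload

    @model_validator(mode="after")
    def _trim_and_check_id(self) -> "StudyEntry":
        trimmed = self.study_id.strip()
        if not trimmed:
            raise ValueError("study_id empty after whitespace trimming")
        if trimmed != self.study_id:
            object.__setattr__(self, "__dict__", {**self.__dict__, "study_id": trimmed})
        return self


class Subgroup(_Strict):
    """A (possibly overlapping) partition of studies within a forest plot."""

    name: str = ""
    studies: list[StudyEntry] = Field(default_factory=list)


class OutcomePlot(_Strict):
    """One forest plot: one outcome under one comparison; a candidate meta-analysis.

    ``totals_displayed`` records whether review authors elected to display
    the pooled result; eligibility is independent of it.
    """

    outcome_id: str
    name: Optional[str] = None
    data_type: DataType
    totals_displayed: bool = True
    outcome_category_label: Optional[str] = None
    subgroups: list[Subgroup] = Field(default_factory=list)

    @model_validator(mode="after")
    def _payloads_match_type(self) -> "OutcomePlot":
        want = PAYLOAD_KIND[self.data_type]
        for sg in self.subgroups:
            for entry in sg.studies:
                if entry.payload.kind != want:
                    raise ValueError(
                        f"study {entry.study_id!r} carries {entry.payload.kind} "
                        f"payload under a {self.data_type} plot"
                    )
        return self

    def iter_entries(self) -> Iterator[tuple[int, int, StudyEntry]]:
        """Yield (subgroup_index, entry_index, entry) in document order."""
        for i, sg in enumerate(self.subgroups):
            for j, entry in enumerate(sg.studies):
                yield i, j, entry

    @property
    def n_studies(self) -> int:
        return sum(len(sg.studies) for sg in self.subgroups)


class Comparison(_Strict):
    """A pair-wise contrast of two interventions within a review."""

    comparison_id: str
    name: str = ""
    active_intervention_label: Optional[str] = None
    comparator_label: Optional[str] = None
    outcomes: list[OutcomePlot] = Field(default_factory=list)

    @model_validator(mode="after")
    def _unique_outcome_ids(self) -> "Comparison":
        _check_unique((o.outcome_id for o in self.outcomes), "outcome_id")
        return self


ReviewStatus = Literal["full", "protocol", "withdrawn"]


class Review(_Strict):
    review_id: str
    title: str = ""
    review_group: str = ""
    status: ReviewStatus = "full"
    is_methodology_group: bool = False
    specialty_label: Optional[str] = None
    comparisons: list[Comparison] = Field(default_factory=list)

    @model_validator(mode="after")
    def _unique_comparison_ids(self) -> "Review":
        _check_unique((c.comparison_id for c in self.comparisons), "comparison_id")
        return self


class SRDatabase(_Strict):
    """A full issue of a systematic-review database."""

    issue_label: str = ""
    reviews: list[Review] = Field(default_factory=list)

    @model_validator(mode="after")
    def _unique_review_ids(self) -> "SRDatabase":
        _check_unique((r.review_id for r in self.reviews), "review_id")
        return self

    def iter_plots(self) -> Iterator[tuple[Review, Comparison, OutcomePlot]]:
        for review in self.reviews:
            for comparison in review.comparisons:
                for plot in comparison.outcomes:
                    yield review, comparison, plot

    @property
    def n_plots(self) -> int:
        return sum(1 for _ in self.iter_plots())

    @property
    def n_studies(self) -> int:
        return sum(plot.n_studies for _, _, plot in self.iter_plots())


def _check_unique(ids, what: str) -> None:
    seen: set[str] = set()
    for ident in ids:
        if ident in seen:
            raise ValueError(f"duplicate {what} {ident!r}")
        seen.add(ident)


def sample_size(entry: StudyEntry) -> Optional[int]:
    """Total number of participants in a study entry, when determinable.

    Dichotomous and continuous payloads carry explicit arm totals; generic
    and O-E payloads report a total only when one was recorded.
    """
    p = entry.payload
    if isinstance(p, DichotomousData):
        return p.total_1 + p.total_2
    if isinstance(p, ContinuousData):
        return p.n_1 + p.n_2
    return p.total_n


# ---------------------------------------------------------------------------
# interchange formats

_CSV_PAYLOAD_COLS = [
    "events_1", "total_1", "events_2", "total_2",
    "n_1", "n_2", "mean_1", "mean_2", "sd_1", "sd_2",
    "estimate", "standard_error", "o_minus_e", "variance", "total_n",
]
_CSV_COLS = [
    "review_id", "review_title", "review_group", "status", "is_methodology_group",
    "specialty_label", "comparison_id", "comparison_name",
    "active_intervention_label", "comparator_label",
    "outcome_id", "outcome_name", "data_type", "totals_displayed",
    "outcome_category_label", "subgroup", "study_id",
] + _CSV_PAYLOAD_COLS


def load_database(path: str | Path, format: str | None = None) -> SRDatabase:
    """Load a database from canonical JSON or flat CSV.

    ``format`` is inferred from the suffix when omitted.  Malformed input
    raises :class:`DatabaseFormatError` naming the offending record.
    """
    path = Path(path)
    fmt = format or ("csv" if path.suffix.lower() == ".csv" else "json")
    if fmt == "json":
        try:
            raw = json.loads(path.read_text(encoding="utf-8"))
        except json.JSONDecodeError as exc:
            raise DatabaseFormatError(f"{path}: invalid JSON: {exc}") from exc
        try:
            return SRDatabase.model_validate(raw)
        except pydantic.ValidationError as exc:
            raise DatabaseFormatError(_format_validation_error(path, exc)) from exc
    if fmt == "csv":
        return _load_csv(path)
    raise ValueError(f"unknown format {fmt!r}")


def save_database(db: SRDatabase, path: str | Path, format: str | None = None) -> None:
    """Write a database in canonical form (stable key order, record order preserved)."""
    path = Path(path)
    fmt = format or ("csv" if path.suffix.lower() == ".csv" else "json")
    if fmt == "json":
        payload = db.model_dump(mode="json")
        path.write_text(
            json.dumps(payload, indent=2, sort_keys=True, ensure_ascii=False) + "\n",
            encoding="utf-8",
        )
    elif fmt == "csv":
        _save_csv(db, path)
    else:
        raise ValueError(f"unknown format {fmt!r}")


def _format_validation_error(path: Path, exc: pydantic.ValidationError) -> str:
    lines = [f"{path}: invalid database"]
    for err in exc.errors():
        loc = " -> ".join(str(part) for part in err["loc"])
        lines.append(f"  at {loc}: {err['msg']}")
    return "\n".join(lines)


def _save_csv(db: SRDatabase, path: Path) -> None:
    rows = []
    for review, comparison, plot in db.iter_plots():
        for sg in plot.subgroups:
            for entry in sg.studies:
                row = {
                    "review_id": review.review_id,
                    "review_title": review.title,
                    "review_group": review.review_group,
                    "status": review.status,
                    "is_methodology_group": review.is_methodology_group,
                    "specialty_label": review.specialty_label,
                    "comparison_id": comparison.comparison_id,
                    "comparison_name": comparison.name,
                    "active_intervention_label": comparison.active_intervention_label,
                    "comparator_label": comparison.comparator_label,
                    "outcome_id": plot.outcome_id,
                    "outcome_name": plot.name,
                    "data_type": plot.data_type,
                    "totals_displayed": plot.totals_displayed,
                    "outcome_category_label": plot.outcome_category_label,
                    "subgroup": sg.name,
                    "study_id": entry.study_id,
                }
                row.update(entry.payload.model_dump(exclude={"kind"}))
                rows.append(row)
    frame = pd.DataFrame(rows, columns=_CSV_COLS)
    frame.to_csv(path, index=False)


def _cell(row, key):
    val = row.get(key)
    if val is None or (isinstance(val, float) and pd.isna(val)) or val == "":
        return None
    return val


def _payload_from_row(row: dict, data_type: str, where: str):
    try:
        if data_type == "dichotomous":
            return DichotomousData(
                events_1=int(row["events_1"]), total_1=int(row["total_1"]),
                events_2=int(row["events_2"]), total_2=int(row["total_2"]),
            )
        if data_type == "continuous":
            return ContinuousData(
                n_1=int(row["n_1"]), n_2=int(row["n_2"]),
                mean_1=float(row["mean_1"]), mean_2=float(row["mean_2"]),
                sd_1=float(row["sd_1"]), sd_2=float(row["sd_2"]),
            )
        if data_type == "generic":
            tn = _cell(row, "total_n")
            return GenericData(
                estimate=float(row["estimate"]),
                standard_error=float(row["standard_error"]),
                total_n=None if tn is None else int(tn),
            )
        if data_type == "oe_variance":
            tn = _cell(row, "total_n")
            return OEData(
                o_minus_e=float(row["o_minus_e"]), variance=float(row["variance"]),
                total_n=None if tn is None else int(tn),
            )
    except (KeyError, TypeError, ValueError, pydantic.ValidationError) as exc:
        raise DatabaseFormatError(f"{where}: bad {data_type} payload: {exc}") from exc
    raise DatabaseFormatError(f"{where}: unknown data_type {data_type!r}")


def _load_csv(path: Path) -> SRDatabase:
    try:
        frame = pd.read_csv(path, dtype={"review_id": str, "comparison_id": str,
                                         "outcome_id": str, "study_id": str})
    except (pd.errors.ParserError, OSError) as exc:
        raise DatabaseFormatError(f"{path}: unreadable CSV: {exc}") from exc
    missing = {"review_id", "comparison_id", "outcome_id", "study_id", "data_type"} - set(frame.columns)
    if missing:
        raise DatabaseFormatError(f"{path}: missing columns {sorted(missing)}")

    reviews: dict[str, dict] = {}
    for idx, rec in enumerate(frame.to_dict(orient="records")):
        where = f"{path} row {idx + 2}"  # 1-based plus header
        rid = rec["review_id"]
        review = reviews.setdefault(rid, {
            "review_id": rid,
            "title": _cell(rec, "review_title") or "",
            "review_group": _cell(rec, "review_group") or "",
            "status": _cell(rec, "status") or "full",
            "is_methodology_group": bool(rec.get("is_methodology_group", False)),
            "specialty_label": _cell(rec, "specialty_label"),
            "comparisons": {},
        })
        cid = rec["comparison_id"]
        comparison = review["comparisons"].setdefault(cid, {
            "comparison_id": cid,
            "name": _cell(rec, "comparison_name") or "",
            "active_intervention_label": _cell(rec, "active_intervention_label"),
            "comparator_label": _cell(rec, "comparator_label"),
            "outcomes": {},
        })
        oid = rec["outcome_id"]
        data_type = rec["data_type"]
        plot = comparison["outcomes"].setdefault(oid, {
            "outcome_id": oid,
            "name": _cell(rec, "outcome_name"),
            "data_type": data_type,
            "totals_displayed": bool(rec.get("totals_displayed", True)),
            "outcome_category_label": _cell(rec, "outcome_category_label"),
            "subgroups": {},
        })
        sg_name = _cell(rec, "subgroup") or ""
        sg = plot["subgroups"].setdefault(sg_name, {"name": sg_name, "studies": []})
        sg["studies"].append(
            {"study_id": rec["study_id"], "payload": _payload_from_row(rec, data_type, where)}
        )

    def _ordered(d: dict) -> list:
        return list(d.values())

    try:
        return SRDatabase(
            issue_label=path.stem,
            reviews=[
                Review(**{**r, "comparisons": [
                    Comparison(**{**c, "outcomes": [
                        OutcomePlot(**{**p, "subgroups": [
                            Subgroup(**sg) for sg in _ordered(p["subgroups"])
                        ]}) for p in _ordered(c["outcomes"])
                    ]}) for c in _ordered(r["comparisons"])
                ]}) for r in reviews.values()
            ],
        )
    except pydantic.ValidationError as exc:
        raise DatabaseFormatError(_format_validation_error(path, exc)) from exc
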