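"""Descriptive census engine: counts, cross-tabulations, quantile summaries
and the rank-sum comparison, computed from a curated, classified database.

Quantile convention
-------------------
All quantiles use linear interpolation between order statistics at position
``(n - 1) p + 1`` (the common "type 7" definition, numpy's default), which
yields integer medians and quartiles on integer count data.

Percent rendering
-----------------
Two dialects are supported.  ``integer-floor-label``: zero counts render as
"0%", nonzero counts below one percent as "<1%", and everything else as the
nearest-integer percent (half away from zero).  ``one-decimal-small``:
values below one percent are shown with one decimal place instead of the
"<1%" label.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _sps

from . import taxonomy
from .model import SRDatabase, sample_size
from .taxonomy import (
    COLLAPSED5_GROUPS,
    COMPARATOR_KINDS,
    Vocabularies,
    classify_comparison,
    collapse_data_type,
    collapse_outcome_group,
)

__all__ = [
    "CrossTab",
    "QuantileSummary",
    "RankSumResult",
    "quantile",
    "count_by",
    "crosstab_interventions",
    "per_review_summary",
    "grouped_quantiles",
    "wilcoxon_rank_sum",
    "compare_study_counts",
    "render_percent",
]

EM_DASH = "—"


def quantile(values: Sequence[float], p: float | Sequence[float]):
    """Quantile(s) by linear interpolation at position (n-1)p + 1."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("quantile of empty sequence")
    return np.quantile(arr, p, method="linear")


def render_percent(count: int, total: int, style: str = "integer-floor-label") -> str:
    """Render `count / total` as a table percentage in one of two dialects."""
    if total <= 0:
        raise ValueError("total must be positive")
    if count < 0 or count > total:
        raise ValueError("count must lie in [0, total]")
    pct = 100.0 * count / total
    nearest = int(math.floor(pct + 0.5))  # half away from zero; pct >= 0 here
    if style == "integer-floor-label":
        if count == 0:
            return "0%"
        if pct < 1.0:
            return "<1%"
        return f"{nearest}%"
    if style == "one-decimal-small":
        if pct < 1.0 and count > 0:
            return f"{pct:.1f}%"
        return f"{nearest}%"
    raise ValueError(f"unknown percent style {style!r}")


# ---------------------------------------------------------------------------
# one-way counts


def count_by(
    db: SRDatabase,
    dimension: str,
    vocab: Vocabularies | None = None,
    percent_style: str = "integer-floor-label",
) -> pd.DataFrame:
    """One-way frequency table of eligible meta-analyses.

    *dimension* is one of ``specialty``, ``outcome_category``,
    ``data_type_group``.  Every vocabulary category appears, including
    zero-count ones; counts sum to the number of plots in *db*.  A plot
    lacking the needed label raises ``ValueError`` naming the plot.
    """
    vocab = vocab or taxonomy.default_vocabularies()
    if dimension == "specialty":
        categories = list(vocab.specialties)
    elif dimension == "outcome_category":
        categories = list(vocab.outcomes)
    elif dimension == "data_type_group":
        categories = ["Dichotomous", "Continuous", "Mixed"]
    else:
        raise ValueError(f"unknown dimension {dimension!r}")

    counts = {c: 0 for c in categories}
    for review, comparison, plot in db.iter_plots():
        if dimension == "specialty":
            label = review.specialty_label
        elif dimension == "outcome_category":
            label = plot.outcome_category_label
        else:
            label = collapse_data_type(plot.data_type)
        if label is None:
            raise ValueError(
                f"plot {plot.outcome_id!r} in review {review.review_id!r} "
                f"lacks a {dimension} label"
            )
        if label not in counts:
            raise ValueError(
                f"plot {plot.outcome_id!r} in review {review.review_id!r} "
                f"has unknown {dimension} label {label!r}"
            )
        counts[label] += 1

    total = sum(counts.values())
    frame = pd.DataFrame({"count": [counts[c] for c in categories]}, index=categories)
    frame.index.name = dimension
    if total > 0:
        frame["percent"] = [render_percent(c, total, percent_style) for c in frame["count"]]
    else:
        frame["percent"] = EM_DASH
    return frame


# ---------------------------------------------------------------------------
# intervention cross-tab


@dataclass
class CrossTab:
    """A two-way count table with margins.

    Structurally excluded cells (pairs that cannot occur by construction)
    are listed in ``na_cells`` and rendered "n/a"; they count as zero in
    marginal totals.
    """

    table: pd.DataFrame  # rows x columns, integer counts
    na_cells: set[tuple[str, str]] = field(default_factory=set)

    @property
    def row_totals(self) -> pd.Series:
        return self.table.sum(axis=1)

    @property
    def column_totals(self) -> pd.Series:
        return self.table.sum(axis=0)

    @property
    def grand_total(self) -> int:
        return int(self.table.to_numpy().sum())

    def check_margins(self) -> None:
        assert self.grand_total == int(self.row_totals.sum()) == int(self.column_totals.sum())

    def rendered(self, style: str = "integer-floor-label") -> pd.DataFrame:
        """Counts with percentages of the grand total, margins appended."""
        total = self.grand_total
        out = pd.DataFrame(index=self.table.index, columns=self.table.columns, dtype=object)
        for r, c in itertools.product(self.table.index, self.table.columns):
            if (r, c) in self.na_cells:
                out.loc[r, c] = "n/a"
            else:
                n = int(self.table.loc[r, c])
                out.loc[r, c] = f"{n} ({render_percent(n, total, style)})" if total else str(n)
        out["Total"] = [
            f"{int(v)} ({render_percent(int(v), total, style)})" if total else str(int(v))
            for v in self.row_totals
        ]
        bottom = [
            f"{int(v)} ({render_percent(int(v), total, style)})" if total else str(int(v))
            for v in self.column_totals
        ] + [str(total)]
        out.loc["Total"] = bottom
        return out


def crosstab_interventions(db: SRDatabase, vocab: Vocabularies | None = None) -> CrossTab:
    """15 active-intervention rows x 5 comparator-kind columns, one cell per plot.

    Every plot must carry active/comparator labels classifiable by
    :func:`srcensus.taxonomy.classify_comparison`; the pharmacological x
    same-category cell is structurally excluded.
    """
    vocab = vocab or taxonomy.default_vocabularies()
    table = pd.DataFrame(
        0, index=list(vocab.active_interventions), columns=list(COMPARATOR_KINDS), dtype=int
    )
    for review, comparison, plot in db.iter_plots():
        a, b = comparison.active_intervention_label, comparison.comparator_label
        if a is None or b is None:
            raise ValueError(
                f"comparison {comparison.comparison_id!r} in review "
                f"{review.review_id!r} is not classified"
            )
        cls = classify_comparison(a, b, vocab)
        table.loc[cls.active_category, cls.comparator_kind] += 1
    return CrossTab(table=table, na_cells={("Pharmacological", "same-category non-pharm")})


# ---------------------------------------------------------------------------
# quantile summaries


@dataclass(frozen=True)
class QuantileSummary:
    """Quantiles of one group of values, plus group size and extremes."""

    label: str
    n: int
    quantiles: Mapping[float, float]
    minimum: Optional[float] = None
    maximum: Optional[float] = None
    n_missing: int = 0

    def __post_init__(self) -> None:
        probs = sorted(self.quantiles)
        vals = [self.quantiles[p] for p in probs]
        if any(b < a for a, b in zip(vals, vals[1:])):
            raise ValueError("quantiles must be non-decreasing in probability")
        if self.maximum is not None and vals and self.maximum < vals[-1]:
            raise ValueError("max must dominate every quantile")


def _summarise(label: str, values: Sequence[float], probs: Sequence[float],
               n_missing: int = 0) -> QuantileSummary:
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        return QuantileSummary(label=label, n=0, quantiles={}, n_missing=n_missing)
    qs = quantile(arr, list(probs))
    return QuantileSummary(
        label=label,
        n=int(arr.size),
        quantiles={p: float(v) for p, v in zip(probs, np.atleast_1d(qs))},
        minimum=float(arr.min()),
        maximum=float(arr.max()),
        n_missing=n_missing,
    )


def per_review_summary(
    db: SRDatabase, probs: Sequence[float] = (0.25, 0.5, 0.75)
) -> dict[str, QuantileSummary]:
    """Min/quartile/max summaries of review and comparison composition.

    Returns summaries of comparisons per review, outcomes per comparison
    and meta-analyses (plots) per review.
    """
    comparisons_per_review = [len(r.comparisons) for r in db.reviews]
    outcomes_per_comparison = [
        len(c.outcomes) for r in db.reviews for c in r.comparisons
    ]
    plots_per_review = [
        sum(len(c.outcomes) for c in r.comparisons) for r in db.reviews
    ]
    return {
        "comparisons_per_review": _summarise(
            "Number of comparisons per review", comparisons_per_review, probs),
        "outcomes_per_comparison": _summarise(
            "Number of outcomes per comparison", outcomes_per_comparison, probs),
        "meta_analyses_per_review": _summarise(
            "Number of meta-analyses per review", plots_per_review, probs),
    }


_GROUPINGS = ("none", "data_type_group", "specialty", "collapsed5", "outcome_group11")


def grouped_quantiles(
    db: SRDatabase,
    unit: str,
    grouping: str = "none",
    probs: Sequence[float] = (0.5, 0.75, 0.9, 0.99),
    vocab: Vocabularies | None = None,
) -> list[QuantileSummary]:
    """Quantiles of study counts or study sample sizes, optionally stratified.

    *unit* is ``studies_per_meta_analysis`` (one value per plot) or
    ``study_sample_size`` (one value per study entry; entries whose sample
    size cannot be determined are excluded and counted in ``n_missing``).
    *grouping* is one of ``none``, ``data_type_group``, ``specialty``,
    ``collapsed5``, ``outcome_group11``; each unit falls in exactly one
    group, so group sizes sum to the overall count.
    """
    vocab = vocab or taxonomy.default_vocabularies()
    if grouping not in _GROUPINGS:
        raise ValueError(f"unknown grouping {grouping!r}; expected one of {_GROUPINGS}")
    if unit not in ("studies_per_meta_analysis", "study_sample_size"):
        raise ValueError(f"unknown unit {unit!r}")

    def group_of(review, comparison, plot) -> str:
        if grouping == "none":
            return "Total"
        if grouping == "data_type_group":
            return collapse_data_type(plot.data_type)
        if grouping == "specialty":
            if review.specialty_label is None:
                raise ValueError(f"review {review.review_id!r} lacks a specialty label")
            return review.specialty_label
        if grouping == "collapsed5":
            a, b = comparison.active_intervention_label, comparison.comparator_label
            if a is None or b is None:
                raise ValueError(
                    f"comparison {comparison.comparison_id!r} is not classified")
            return classify_comparison(a, b, vocab).collapsed5
        if plot.outcome_category_label is None:
            raise ValueError(f"plot {plot.outcome_id!r} lacks an outcome category label")
        return collapse_outcome_group(plot.outcome_category_label, vocab)

    if grouping == "none":
        order: list[str] = ["Total"]
    elif grouping == "data_type_group":
        order = ["Dichotomous", "Continuous", "Mixed"]
    elif grouping == "specialty":
        order = list(vocab.specialties)
    elif grouping == "collapsed5":
        order = list(COLLAPSED5_GROUPS)
    else:
        order = list(vocab.outcome_groups)

    values: dict[str, list[float]] = {g: [] for g in order}
    missing: dict[str, int] = {g: 0 for g in order}
    for review, comparison, plot in db.iter_plots():
        g = group_of(review, comparison, plot)
        if g not in values:
            raise ValueError(f"label {g!r} outside the configured vocabulary")
        if unit == "studies_per_meta_analysis":
            values[g].append(plot.n_studies)
        else:
            for _, _, entry in plot.iter_entries():
                size = sample_size(entry)
                if size is None:
                    missing[g] += 1
                else:
                    values[g].append(size)

    return [_summarise(g, values[g], probs, n_missing=missing[g]) for g in order]


# ---------------------------------------------------------------------------
# rank-sum test


@dataclass(frozen=True)
class RankSumResult:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test result.

    ``u`` is the Mann-Whitney U statistic of the first sample (number of
    (x, y) pairs with x > y, counting ties as half).
    """

    u: float
    method: str  # "exact" or "normal-approximation"
    z: Optional[float]
    p_two_sided: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_two_sided <= 1.0:
            raise ValueError("p-value outside [0, 1]")


def _u_statistic(ranks: np.ndarray, idx: np.ndarray, n1: int) -> float:
    return float(ranks[idx].sum() - n1 * (n1 + 1) / 2.0)


def wilcoxon_rank_sum(
    x: Sequence[float], y: Sequence[float], exact_limit: int = 20
) -> RankSumResult:
    """Two-sided test of stochastic equality of two independent samples.

    Uses mid-ranks for ties.  When ``n1 + n2 <= exact_limit`` the null
    distribution of U is enumerated exactly over all ways of assigning the
    pooled mid-ranks to the first sample (tie-aware); otherwise a normal
    approximation with tie-corrected variance and a 0.5 continuity
    correction is used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = x.size, y.size
    if n1 == 0 or n2 == 0:
        raise ValueError("both samples must be non-empty")
    n = n1 + n2
    pooled = np.concatenate([x, y])
    ranks = _sps.rankdata(pooled)  # mid-ranks
    u_obs = _u_statistic(ranks, np.arange(n1), n1)
    mean_u = n1 * n2 / 2.0

    if n <= exact_limit:
        dev = abs(u_obs - mean_u)
        offset = n1 * (n1 + 1) / 2.0
        hits = 0
        count = 0
        for combo in itertools.combinations(ranks.tolist(), n1):
            count += 1
            if abs(sum(combo) - offset - mean_u) >= dev - 1e-12:
                hits += 1
        return RankSumResult(u=u_obs, method="exact", z=None,
                             p_two_sided=hits / count)

    # tie-corrected variance of U under the null
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(((tie_counts ** 3 - tie_counts).sum()) / (n * (n - 1)))
    var_u = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var_u <= 0:  # all values identical
        return RankSumResult(u=u_obs, method="normal-approximation", z=0.0, p_two_sided=1.0)
    dev = abs(u_obs - mean_u)
    z = max(dev - 0.5, 0.0) / math.sqrt(var_u)
    p = 2.0 * float(_sps.norm.sf(z))
    return RankSumResult(u=u_obs, method="normal-approximation", z=z,
                         p_two_sided=min(p, 1.0))


def compare_study_counts(
    db: SRDatabase,
    outcome_group: str = "All-cause mortality",
    vocab: Vocabularies | None = None,
) -> RankSumResult:
    """Rank-sum comparison of studies-per-meta-analysis for one outcome group
    against all other outcome groups combined."""
    vocab = vocab or taxonomy.default_vocabularies()
    in_group: list[int] = []
    rest: list[int] = []
    for _, _, plot in db.iter_plots():
        if plot.outcome_category_label is None:
            raise ValueError(f"plot {plot.outcome_id!r} lacks an outcome category label")
        g = collapse_outcome_group(plot.outcome_category_label, vocab)
        (in_group if g == outcome_group else rest).append(plot.n_studies)
    return wilcoxon_rank_sum(in_group, rest)
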