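"""Calibrated synthetic systematic-review databases with recorded ground truth.

The generator emits the full review -> comparison -> outcome (forest
plot) -> subgroup -> study hierarchy with the statistical structure the
census engine assumes: heavy-tailed counts of comparisons, outcomes and
studies; log-normal study sample sizes; category labels drawn from the
published census margins.  Controlled contamination — phantom study
records and within-plot duplicates, plus protocol/withdrawn/methodology
reviews — exercises the curation rules, and every injected artefact is
recorded in a :class:`GroundTruth` so tests can verify that curation
removes exactly what was injected.

Randomness uses one root seed with an independent substream per review,
so extending ``n_reviews`` never perturbs earlier reviews.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Optional

import numpy as np
import yaml

from . import calibration
from .model import (
    Comparison,
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
    "CountDistribution",
    "TruncatedZipf",
    "ShiftedNegBinomial",
    "LogNormalCount",
    "GeneratorConfig",
    "GroundTruth",
    "default_config",
    "generate_database",
    "distribution_from_spec",
]


# ---------------------------------------------------------------------------
# distribution specs


class CountDistribution:
    """A named integer distribution; subclasses are swappable via config."""

    def sample(self, rng: np.random.Generator) -> int:
        raise NotImplementedError

    def spec(self) -> dict:
        d = asdict(self)  # type: ignore[call-overload]
        d["family"] = type(self).FAMILY  # type: ignore[attr-defined]
        return d


@dataclass(frozen=True)
class TruncatedZipf(CountDistribution):
    """P(k) proportional to k^-a on {minimum, ..., cap}."""

    FAMILY = "truncated_zipf"
    a: float = 2.0
    minimum: int = 1
    cap: int = 23

    def _pmf(self) -> tuple[np.ndarray, np.ndarray]:
        k = np.arange(self.minimum, self.cap + 1)
        w = k.astype(float) ** (-self.a)
        return k, w / w.sum()

    def sample(self, rng: np.random.Generator) -> int:
        k, p = self._pmf()
        return int(rng.choice(k, p=p))


@dataclass(frozen=True)
class ShiftedNegBinomial(CountDistribution):
    """shift + NegativeBinomial(r, p) with p = r / (r + mean), capped."""

    FAMILY = "shifted_negbin"
    r: float = 0.37
    mean: float = 2.85
    shift: int = 2
    cap: int = 300

    def sample(self, rng: np.random.Generator) -> int:
        p = self.r / (self.r + self.mean)
        return min(self.shift + int(rng.negative_binomial(self.r, p)), self.cap)


@dataclass(frozen=True)
class LogNormalCount(CountDistribution):
    """round(LogNormal(location, scale)) clipped to [minimum, cap]."""

    FAMILY = "lognormal"
    location: float = calibration.SAMPLE_SIZE_LOG_LOCATION
    scale: float = calibration.SAMPLE_SIZE_LOG_SCALE
    minimum: int = 2
    cap: int = 1_000_000

    def sample(self, rng: np.random.Generator) -> int:
        v = int(round(float(rng.lognormal(self.location, self.scale))))
        return max(self.minimum, min(v, self.cap))


_FAMILIES = {
    TruncatedZipf.FAMILY: TruncatedZipf,
    ShiftedNegBinomial.FAMILY: ShiftedNegBinomial,
    LogNormalCount.FAMILY: LogNormalCount,
}


def distribution_from_spec(spec: Mapping) -> CountDistribution:
    """Build a distribution from a plain mapping with a ``family`` key."""
    spec = dict(spec)
    family = spec.pop("family")
    try:
        cls = _FAMILIES[family]
    except KeyError:
        raise ValueError(f"unknown distribution family {family!r}") from None
    return cls(**spec)


# ---------------------------------------------------------------------------
# configuration


def _normalise(counts: Mapping[str, float]) -> dict[str, float]:
    total = float(sum(counts.values()))
    return {k: v / total for k, v in counts.items()}


@dataclass
class GeneratorConfig:
    """Everything the generator needs; defaults are the calibrated study conditions."""

    n_reviews: int = 500
    seed: int = 0
    comparisons_per_review: CountDistribution = field(default_factory=TruncatedZipf)
    outcomes_per_comparison: CountDistribution = field(
        default_factory=lambda: ShiftedNegBinomial(r=0.45, mean=4.1, shift=1, cap=68))
    studies_per_plot: CountDistribution = field(
        default_factory=lambda: ShiftedNegBinomial(r=0.37, mean=2.85, shift=2, cap=300))
    sample_size: CountDistribution = field(default_factory=LogNormalCount)
    #: probabilities over the four payload data types
    data_type_mixture: dict[str, float] = field(default_factory=dict)
    specialty_marginals: dict[str, float] = field(default_factory=dict)
    #: probabilities over (active category, comparator kind) cells
    intervention_cell_marginals: dict[tuple[str, str], float] = field(default_factory=dict)
    outcome_marginals: dict[str, float] = field(default_factory=dict)
    phantom_rate: float = 0.1
    duplicate_rate: float = 0.05
    protocol_rate: float = 0.3
    withdrawn_rate: float = 0.02
    methodology_rate: float = 0.01
    #: probability that a plot is split into two subgroups
    subgroup_rate: float = 0.2
    #: probability that a generic / O-E payload records a participant total
    total_n_present_rate: float = 0.9

    def __post_init__(self) -> None:
        if not self.data_type_mixture:
            # mixed data (generic + O-E pooled) split 70:30 between the two shapes
            mixed = calibration.DATA_TYPE_GROUP_COUNTS["Mixed"]
            self.data_type_mixture = _normalise({
                "dichotomous": calibration.DATA_TYPE_GROUP_COUNTS["Dichotomous"],
                "continuous": calibration.DATA_TYPE_GROUP_COUNTS["Continuous"],
                "generic": 0.7 * mixed,
                "oe_variance": 0.3 * mixed,
            })
        if not self.specialty_marginals:
            self.specialty_marginals = _normalise(calibration.SPECIALTY_COUNTS)
        if not self.intervention_cell_marginals:
            self.intervention_cell_marginals = _normalise(
                calibration.INTERVENTION_CELL_COUNTS)
        if not self.outcome_marginals:
            self.outcome_marginals = _normalise(calibration.OUTCOME_COUNTS)
        self.validate()

    def validate(self) -> None:
        for name in ("phantom_rate", "duplicate_rate", "protocol_rate",
                     "withdrawn_rate", "methodology_rate", "subgroup_rate",
                     "total_n_present_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a probability, got {v}")
        if self.protocol_rate + self.withdrawn_rate > 1.0:
            raise ValueError("protocol_rate + withdrawn_rate exceeds 1")
        if self.n_reviews < 0:
            raise ValueError("n_reviews must be non-negative")
        for name in ("data_type_mixture", "specialty_marginals",
                     "intervention_cell_marginals", "outcome_marginals"):
            probs = getattr(self, name)
            if any(p < 0 for p in probs.values()):
                raise ValueError(f"{name} has negative entries")
            if abs(sum(probs.values()) - 1.0) > 1e-9:
                raise ValueError(f"{name} must sum to 1")
        if set(self.data_type_mixture) != {"dichotomous", "continuous",
                                           "generic", "oe_variance"}:
            raise ValueError("data_type_mixture must cover the four data types")

    # -- plain-text round trip -------------------------------------------
    def to_yaml(self, path: str | Path) -> None:
        doc = {
            "n_reviews": self.n_reviews,
            "seed": self.seed,
            "comparisons_per_review": self.comparisons_per_review.spec(),
            "outcomes_per_comparison": self.outcomes_per_comparison.spec(),
            "studies_per_plot": self.studies_per_plot.spec(),
            "sample_size": self.sample_size.spec(),
            "data_type_mixture": self.data_type_mixture,
            "specialty_marginals": self.specialty_marginals,
            "intervention_cell_marginals": {
                f"{a}|{k}": v for (a, k), v in self.intervention_cell_marginals.items()
            },
            "outcome_marginals": self.outcome_marginals,
            "phantom_rate": self.phantom_rate,
            "duplicate_rate": self.duplicate_rate,
            "protocol_rate": self.protocol_rate,
            "withdrawn_rate": self.withdrawn_rate,
            "methodology_rate": self.methodology_rate,
            "subgroup_rate": self.subgroup_rate,
            "total_n_present_rate": self.total_n_present_rate,
        }
        Path(path).write_text(yaml.safe_dump(doc, sort_keys=False), encoding="utf-8")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "GeneratorConfig":
        doc = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
        for key in ("comparisons_per_review", "outcomes_per_comparison",
                    "studies_per_plot", "sample_size"):
            if key in doc:
                doc[key] = distribution_from_spec(doc[key])
        if "intervention_cell_marginals" in doc:
            doc["intervention_cell_marginals"] = {
                tuple(k.split("|", 1)): v
                for k, v in doc["intervention_cell_marginals"].items()
            }
        return cls(**doc)


def default_config(n_reviews: int = 500, seed: int = 0, **overrides) -> GeneratorConfig:
    """The documented calibration: census-margin categories, quartile-matched sizes."""
    return GeneratorConfig(n_reviews=n_reviews, seed=seed, **overrides)


# ---------------------------------------------------------------------------
# ground truth


@dataclass
class GroundTruth:
    """Positions of injected contamination plus pre-contamination counts."""

    phantoms: list[tuple[str, str, str, int, int]] = field(default_factory=list)
    duplicates: list[tuple[str, str, str, int, int]] = field(default_factory=list)
    pre_counts: dict[str, int] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# generation

def _comparator_label(active: str, kind: str, actives: list[str],
                      rng: np.random.Generator) -> str:
    if kind in ("Control", "Placebo", "Pharmacological"):
        return kind
    if kind == "same-category non-pharm":
        return active
    others = [a for a in actives if a not in (active, "Pharmacological")]
    return str(rng.choice(others))


def _dichotomous(rng: np.random.Generator, n_total: int) -> DichotomousData:
    n1 = max(1, n_total // 2)
    n2 = max(1, n_total - n1)
    p = float(rng.uniform(0.05, 0.5))
    e1 = int(rng.binomial(n1, p))
    e2 = int(rng.binomial(n2, p))
    if n1 == 1 and n2 == 1 and e1 == 0 and e2 == 0:
        e1 = 1  # avoid the phantom zero-pattern for genuine draws
    return DichotomousData(events_1=e1, total_1=n1, events_2=e2, total_2=n2)


def _continuous(rng: np.random.Generator, n_total: int) -> ContinuousData:
    n1 = max(1, n_total // 2)
    n2 = max(1, n_total - n1)
    return ContinuousData(
        n_1=n1, n_2=n2,
        mean_1=float(rng.normal(0, 1)), mean_2=float(rng.normal(0, 1)),
        sd_1=float(rng.lognormal(0, 0.5)), sd_2=float(rng.lognormal(0, 0.5)),
    )


def _generic(rng: np.random.Generator, n_total: int, present: bool) -> GenericData:
    se = 2.0 / math.sqrt(n_total) * float(rng.lognormal(0, 0.2))
    return GenericData(
        estimate=float(rng.normal(0, 0.3)),
        standard_error=se,
        total_n=n_total if present else None,
    )


def _oe(rng: np.random.Generator, n_total: int, present: bool) -> OEData:
    variance = n_total / 8.0 * float(rng.lognormal(0, 0.3))
    return OEData(
        o_minus_e=float(rng.normal(0, math.sqrt(variance))),
        variance=variance,
        total_n=n_total if present else None,
    )


def _phantom_payload(data_type: str):
    if data_type == "dichotomous":
        return DichotomousData(events_1=0, total_1=1, events_2=0, total_2=1)
    if data_type == "continuous":
        return ContinuousData(n_1=1, n_2=1, mean_1=0.0, mean_2=0.0, sd_1=0.0, sd_2=0.0)
    if data_type == "generic":
        return GenericData(estimate=0.0, standard_error=0.0, total_n=None)
    return OEData(o_minus_e=0.0, variance=0.0, total_n=None)


def generate_database(config: GeneratorConfig) -> tuple[SRDatabase, GroundTruth]:
    """Generate a database plus ground truth; deterministic given the config seed.

    Contamination is applied last: duplicates re-insert an existing study
    identifier into a sibling subgroup, then phantom records (matching the
    curation rules' zero-patterns exactly) are appended to the final
    subgroup.  Only reviews that pass the review-level exclusions receive
    contamination, so ground truth maps one-to-one onto curation removals.
    """
    config.validate()

    specs = list(config.specialty_marginals)
    spec_p = np.array([config.specialty_marginals[s] for s in specs])
    cells = list(config.intervention_cell_marginals)
    cell_p = np.array([config.intervention_cell_marginals[c] for c in cells])
    actives = sorted({a for a, _ in cells})
    outcomes = list(config.outcome_marginals)
    outcome_p = np.array([config.outcome_marginals[o] for o in outcomes])
    dtypes = list(config.data_type_mixture)
    dtype_p = np.array([config.data_type_mixture[d] for d in dtypes])

    truth = GroundTruth()
    n_comparisons = n_plots = n_studies = 0
    reviews: list[Review] = []

    for i in range(config.n_reviews):
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, i]))
        review_id = f"R{i:05d}"

        u = rng.uniform()
        if u < config.protocol_rate:
            status = "protocol"
        elif u < config.protocol_rate + config.withdrawn_rate:
            status = "withdrawn"
        else:
            status = "full"
        is_methodology = bool(rng.uniform() < config.methodology_rate)
        eligible_review = status == "full" and not is_methodology
        specialty = str(rng.choice(specs, p=spec_p))

        comparisons: list[Comparison] = []
        for c in range(config.comparisons_per_review.sample(rng)):
            cid = f"C{c + 1}"
            cell_idx = int(rng.choice(len(cells), p=cell_p))
            active, kind = cells[cell_idx]
            comparator = _comparator_label(active, kind, actives, rng)

            plots: list[OutcomePlot] = []
            for o in range(config.outcomes_per_comparison.sample(rng)):
                data_type = str(rng.choice(dtypes, p=dtype_p))
                category = str(rng.choice(outcomes, p=outcome_p))
                m = config.studies_per_plot.sample(rng)

                entries: list[StudyEntry] = []
                for k in range(m):
                    n_total = config.sample_size.sample(rng)
                    present = bool(rng.uniform() < config.total_n_present_rate)
                    if data_type == "dichotomous":
                        payload = _dichotomous(rng, n_total)
                    elif data_type == "continuous":
                        payload = _continuous(rng, n_total)
                    elif data_type == "generic":
                        payload = _generic(rng, n_total, present)
                    else:
                        payload = _oe(rng, n_total, present)
                    entries.append(StudyEntry(study_id=f"Study {i}-{c}-{o}-{k}",
                                              payload=payload))

                if len(entries) >= 2 and rng.uniform() < config.subgroup_rate:
                    split = int(rng.integers(1, len(entries)))
                    subgroups = [
                        Subgroup(name="Subgroup 1", studies=entries[:split]),
                        Subgroup(name="Subgroup 2", studies=entries[split:]),
                    ]
                else:
                    subgroups = [Subgroup(name="", studies=entries)]

                n_plots += 1
                n_studies += len(entries)

                oid = f"O{o + 1}"

                # contamination: duplicates first, then phantoms, both appended
                # at subgroup ends so ground-truth positions survive curation
                if eligible_review and rng.uniform() < config.duplicate_rate:
                    # re-insert a first-subgroup study into a *later* sibling
                    # subgroup, so the injected copy is the occurrence that
                    # first-occurrence deduplication removes
                    src_entry = subgroups[0].studies[
                        int(rng.integers(len(subgroups[0].studies)))]
                    if len(subgroups) == 1:
                        subgroups.append(Subgroup(name="Subgroup 2", studies=[]))
                    target = len(subgroups) - 1
                    subgroups[target] = Subgroup(
                        name=subgroups[target].name,
                        studies=subgroups[target].studies + [src_entry.model_copy()],
                    )
                    truth.duplicates.append(
                        (review_id, cid, oid, target, len(subgroups[target].studies) - 1))

                if eligible_review and rng.uniform() < config.phantom_rate:
                    last = len(subgroups) - 1
                    subgroups[last] = Subgroup(
                        name=subgroups[last].name,
                        studies=subgroups[last].studies + [StudyEntry(
                            study_id=f"Study {i}-{c}-{o}-x",
                            payload=_phantom_payload(data_type),
                        )],
                    )
                    truth.phantoms.append(
                        (review_id, cid, oid, last, len(subgroups[last].studies) - 1))

                plots.append(OutcomePlot(
                    outcome_id=oid,
                    name=f"Outcome {o + 1}",
                    data_type=data_type,
                    totals_displayed=bool(rng.uniform() < 0.9),
                    outcome_category_label=category,
                    subgroups=subgroups,
                ))
            n_comparisons += 1
            comparisons.append(Comparison(
                comparison_id=cid,
                name=f"{active} vs {comparator}",
                active_intervention_label=active,
                comparator_label=comparator,
                outcomes=plots,
            ))

        reviews.append(Review(
            review_id=review_id,
            title=f"Synthetic review {i}",
            review_group=f"{specialty} Group",
            status=status,
            is_methodology_group=is_methodology,
            specialty_label=specialty,
            comparisons=comparisons,
        ))

    truth.pre_counts = {
        "reviews": len(reviews),
        "comparisons": n_comparisons,
        "plots": n_plots,
        "studies": n_studies,
    }
    return SRDatabase(issue_label=f"synthetic seed={config.seed}", reviews=reviews), truth
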