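"""Published census margins used to calibrate the synthetic generator.

These are the category frequencies and quantile targets from a census of
the January 2008 issue of a large database of systematic reviews of
healthcare interventions (2321 reviews, 22,453 meta-analyses, 112,600
study records).  The synthetic generator draws its default category
marginals and distribution parameters from them; the numbers also serve
as worked-example inputs for the cross-tabulation algebra.
"""

from __future__ import annotations

import math

#: meta-analyses per medical specialty (one-way margin)
SPECIALTY_COUNTS: dict[str, int] = {
    "Cancer": 905,
    "Cardiovascular": 1693,
    "Central nervous system/musculoskeletal": 1965,
    "Digestive/endocrine, nutritional and metabolic": 2704,
    "Gynaecology, pregnancy and birth": 4656,
    "Infectious diseases": 965,
    "Mental health and behavioural conditions": 2918,
    "Pathological conditions, symptoms and signs": 701,
    "Respiratory diseases": 3021,
    "Urogenital": 1289,
    "Other": 1637,
}

#: meta-analyses per (active intervention, comparator kind) cell.
#: Columns: Control, Placebo, Pharmacological, same-category non-pharm,
#: different-category non-pharm.  The pharmacological/same-category cell
#: is structurally excluded.
INTERVENTION_CELL_COUNTS: dict[tuple[str, str], int] = {}
_CELL_ROWS: dict[str, tuple[int, ...]] = {
    # Control, Placebo, Pharm, same-cat, diff-cat
    "Pharmacological": (4027, 4321, 5571, -1, 186),
    "Vaccines": (95, 113, 0, 49, 0),
    "Surgical": (241, 2, 29, 1204, 86),
    "Medical devices": (706, 50, 82, 941, 159),
    "Cellular and gene": (29, 6, 0, 57, 7),
    "Radiotherapy": (124, 65, 3, 56, 63),
    "Physical": (318, 10, 8, 72, 39),
    "Educational": (303, 4, 1, 34, 27),
    "Behavioural": (380, 7, 3, 165, 14),
    "Screening": (17, 0, 0, 0, 0),
    "Complementary": (216, 104, 41, 8, 19),
    "Psychological": (379, 1, 6, 116, 44),
    "Resources and infrastructure": (506, 0, 14, 52, 33),
    "Complex": (505, 36, 43, 200, 154),
    "Other": (188, 44, 8, 51, 11),
}
_KINDS = ("Control", "Placebo", "Pharmacological",
          "same-category non-pharm", "different-category non-pharm")
for _active, _cells in _CELL_ROWS.items():
    for _kind, _count in zip(_KINDS, _cells):
        if _count >= 0:  # -1 marks the structurally excluded cell
            INTERVENTION_CELL_COUNTS[(_active, _kind)] = _count

#: meta-analyses per outcome category (one-way margin)
OUTCOME_COUNTS: dict[str, int] = {
    "Signs/symptoms reflecting continuation/end of condition": 3639,
    "Adverse events": 2368,
    "Infection/onset of new acute/chronic disease": 2215,
    "Biological markers": 2071,
    "General physical health": 1921,
    "Obstetric outcomes": 1477,
    "All-cause mortality": 1278,
    "Hospital stay/process measures": 1158,
    "Quality of life/functioning": 958,
    "Pain": 802,
    "Mental health outcomes": 743,
    "Surgical/device related success/failure": 737,
    "Withdrawals/dropouts": 643,
    "Internal structure": 504,
    "Major morbidity event": 502,
    "Composite (at least 1 non-mortality/morbidity)": 460,
    "Composite (mortality/morbidity only)": 224,
    "Cause-specific mortality": 194,
    "Consumption": 190,
    "External structure": 160,
    "Other": 94,
    "Satisfaction with care": 86,
    "Resource use": 29,
}

#: meta-analyses per outcome data-type group
DATA_TYPE_GROUP_COUNTS: dict[str, int] = {
    "Dichotomous": 14886,
    "Continuous": 6672,
    "Mixed": 895,
}

#: total eligible meta-analyses
TOTAL_META_ANALYSES = 22453

#: quantile targets for studies per meta-analysis (p -> value) and its support minimum
STUDIES_PER_MA_QUANTILES: dict[float, int] = {0.5: 3, 0.75: 6, 0.9: 10, 0.99: 28}

#: quartile targets for individual-study sample size
SAMPLE_SIZE_QUANTILES: dict[float, int] = {0.25: 44, 0.5: 91, 0.75: 210}

#: log-normal parameters matched to the sample-size quartiles:
#: location = ln(median); scale = (ln q75 - ln q25) / (2 * z_0.75)
SAMPLE_SIZE_LOG_LOCATION = math.log(SAMPLE_SIZE_QUANTILES[0.5])
SAMPLE_SIZE_LOG_SCALE = (
    math.log(SAMPLE_SIZE_QUANTILES[0.75]) - math.log(SAMPLE_SIZE_QUANTILES[0.25])
) / (2 * 0.6744897501960817)
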