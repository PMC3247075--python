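# Controlled vocabularies for the census classifications.
#
# Users may copy this file, edit it (e.g. re-order `outcome_priority`), and
# pass the copy to `srcensus.taxonomy.load_vocabularies`.

specialties:
  - Cancer
  - Cardiovascular
  - Central nervous system/musculoskeletal
  - Digestive/endocrine, nutritional and metabolic
  - Gynaecology, pregnancy and birth
  - Infectious diseases
  - Mental health and behavioural conditions
  - Pathological conditions, symptoms and signs
  - Respiratory diseases
  - Urogenital
  - Other

active_interventions:
  - Pharmacological
  - Vaccines
  - Surgical
  - Medical devices
  - Cellular and gene
  - Radiotherapy
  - Physical
  - Educational
  - Behavioural
  - Screening
  - Complementary
  - Psychological
  - Resources and infrastructure
  - Complex
  - Other

control_interventions:
  - Control
  - Placebo

outcomes:
  - Signs/symptoms reflecting continuation/end of condition
  - Adverse events
  - Infection/onset of new acute/chronic disease
  - Biological markers
  - General physical health
  - Obstetric outcomes
  - All-cause mortality
  - Hospital stay/process measures
  - Quality of life/functioning
  - Pain
  - Mental health outcomes
  - Surgical/device related success/failure
  - Withdrawals/dropouts
  - Internal structure
  - Major morbidity event
  - Composite (at least 1 non-mortality/morbidity)
  - Composite (mortality/morbidity only)
  - Cause-specific mortality
  - Consumption
  - External structure
  - Other
  - Satisfaction with care
  - Resource use

# Priority used when an outcome could fall under several categories: the
# category highest on this list wins.  The default places mortality and
# morbidity categories first and the broad sign/symptom categories last;
# reproduction work should supply its own order explicitly.
outcome_priority:
  - All-cause mortality
  - Cause-specific mortality
  - Major morbidity event
  - Composite (mortality/morbidity only)
  - Composite (at least 1 non-mortality/morbidity)
  - Obstetric outcomes
  - Surgical/device related success/failure
  - Infection/onset of new acute/chronic disease
  - Internal structure
  - External structure
  - Biological markers
  - General physical health
  - Consumption
  - Hospital stay/process measures
  - Resource use
  - Withdrawals/dropouts
  - Adverse events
  - Pain
  - Mental health outcomes
  - Quality of life/functioning
  - Satisfaction with care
  - Signs/symptoms reflecting continuation/end of condition
  - Other

# Collapse of the 23 outcome categories onto the 11 row groups used by the
# stratified summaries.  Membership of the two residual groups is uniquely
# determined by requiring the collapsed group sizes to reproduce the census
# cross-tabulations; "Other" is assigned to the subjective residual by
# convention (it sits in no natural group).
outcome_group11:
  Signs/symptoms reflecting continuation/end of condition: Signs/symptoms reflecting continuation/end of condition
  Adverse events: Adverse events
  Infection/onset of new acute/chronic disease: Infection/onset of new acute/chronic disease
  Biological markers: Biological markers
  General physical health: General physical health
  Obstetric outcomes: Obstetric outcomes
  All-cause mortality: All-cause mortality
  Resource use: Resource use/hospital stay/process
  Hospital stay/process measures: Resource use/hospital stay/process
  Cause-specific mortality: Cause-specific mortality/major morbidity event/composite (mortality or morbidity)
  Major morbidity event: Cause-specific mortality/major morbidity event/composite (mortality or morbidity)
  Composite (mortality/morbidity only): Cause-specific mortality/major morbidity event/composite (mortality or morbidity)
  Surgical/device related success/failure: Other outcomes (semi-objective)
  Withdrawals/dropouts: Other outcomes (semi-objective)
  Internal structure: Other outcomes (semi-objective)
  External structure: Other outcomes (semi-objective)
  Quality of life/functioning: Other outcomes (subjective)
  Pain: Other outcomes (subjective)
  Mental health outcomes: Other outcomes (subjective)
  Composite (at least 1 non-mortality/morbidity): Other outcomes (subjective)
  Consumption: Other outcomes (subjective)
  Satisfaction with care: Other outcomes (subjective)
  Other: Other outcomes (subjective)
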