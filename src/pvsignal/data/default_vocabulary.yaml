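# Synthetic vocabulary fixture for the hypertension case/non-case analysis.
#
# The smq_terms section is a flat, editable stand-in for a licensed
# "Hypertension (broad)" standardized-query term list (licensed MedDRA
# content is NOT shipped); the hypertensive_inducer_codes section is an
# editable placeholder for a published hypertension-inducing-drug list.
# All code sections are ATC prefixes: "C02" matches any C02* substance code.
smq_terms:
  - Hypertension
  - Blood pressure increased
  - Blood pressure systolic increased
  - Blood pressure diastolic increased
  - Hypertensive crisis
  - Hypertensive emergency
  - Essential hypertension
  - Labile hypertension
  - Secondary hypertension

target_drugs:
  alaproclate: [N06AB07]
  citalopram: [N06AB04]
  escitalopram: [N06AB10]
  etoperidone: [N06AB09]
  fluoxetine: [N06AB03]
  fluvoxamine: [N06AB08]
  paroxetine: [N06AB05]
  sertraline: [N06AB06]
  zimeldine: [N06AB02]

antihypertensive_codes:
  - C02

# Editable placeholder list of drug classes with known pressor potential
# (systemic corticosteroids, NSAIDs, ciclosporin/tacrolimus, sympathomimetic
# cardiac stimulants, triptans, estrogens).
hypertensive_inducer_codes:
  - H02AB
  - M01A
  - L04AD
  - C01CA
  - N02CC
  - G03C

comparator_population_codes:
  - N06A

stroke_terms:
  - Cerebrovascular accident
  - Ischaemic stroke
  - Haemorrhagic stroke

mi_terms:
  - Myocardial infarction
  - Acute myocardial infarction
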