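# Default semantic-type routing policy for condition concepts, plus the fixed
# target-ontology sets for drug ingredients and measurements.
#
# Condition concepts are routed by their UMLS-style semantic types: phenotype-
# like types go to the Human Phenotype Ontology (hp), disease-like types go to
# the Mondo disease ontology (mondo), and types without a clear pathological
# or biological origin (accidents, injuries, external complications,
# uninterpretable findings) are excluded from mapping with a recorded reason.
# The lists are editable defaults, not a claim of completeness.
phenotype_types:
  - Finding
  - Sign or Symptom
  - Laboratory or Test Result
  - Clinical Attribute
  - Organism Function
  - Mental Process
disease_types:
  - Disease or Syndrome
  - Neoplastic Process
  - Mental or Behavioral Dysfunction
  - Congenital Abnormality
  - Anatomical Abnormality
  - Acquired Abnormality
  - Cell or Molecular Dysfunction
  - Pathologic Function
excluded_types:
  - Injury or Poisoning
  - Accident
  - External Complication
  - Daily or Recreational Activity
  - Health Care Activity
  - Therapeutic or Preventive Procedure
  - Diagnostic Procedure
  - Social Behavior
  - Environmental Effect of Humans
drug_targets: [chebi, ncbitaxon, pr, vo]
measurement_targets: [hp, uberon, ncbitaxon, pr, chebi, cl]
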