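"""Type laboratory measurements and expand them into per-result mappings.

A quantitative plasma corticotropin test becomes three result slots
(low / normal / high), with the normal slot logically negated: a normal
result asserts the *absence* of the ACTH abnormality.  An ordinal urine
drug screen becomes two slots sharing one phenotype term, negated for the
negative result.
"""

from termbridge.clinical import ClinicalConcept
from termbridge.measurements import (MeasurementConcept, expand_result_slots,
                                     flag_unspecified_sample, infer_result_type)


def show(slots):
    for s in slots:
        for curie, label in s.terms:
            neg = "NOT " if s.negated else ""
            print(f"  {s.result_value:>8}: {neg}{curie}  ({label})")


acth = MeasurementConcept(
    base=ClinicalConcept(1, "loinc", "loinc:12460-2",
                         "Corticotropin [Mass/volume] in Plasma",
                         "measurement", usage_count=12),
    scale="quantitative", reference_range_kind="numeric")
rtype = infer_result_type(acth)
print(f"plasma corticotropin -> result type {rtype}")
show(expand_result_slots(acth, rtype, {
    "low": ([("hp:0002920", "Decreased Circulating ACTH Level")], False),
    "normal": ([("hp:0011043",
                 "Abnormality of Circulating Adrenocorticotropin Level")], True),
    "high": ([("hp:0003154", "Increased Circulating ACTH Level")], False)}))

amp = MeasurementConcept(
    base=ClinicalConcept(2, "loinc", "loinc:19343-3",
                         "Amphetamine [Presence] in Urine by Screen Method",
                         "measurement",
                         synonyms=["amphetamine presence urine screen"]),
    scale="ordinal")
rtype = infer_result_type(amp)
print(f"\nurine amphetamine screen -> result type {rtype}")
show(expand_result_slots(amp, rtype, {
    "positive": ([("hp:0500112", "Positive Urine Amphetamine Test")], False)}))

vague = MeasurementConcept(
    base=ClinicalConcept(3, "loinc", "loinc:3456-7",
                         "Analyte in Unspecified specimen", "measurement"),
    specimen_specified=False)
record = flag_unspecified_sample(vague)
print(f"\nnon-specific specimen -> unmapped, evidence {record.evidence!r}")
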