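"""Measurement scale and result-type semantics.

Laboratory measurement concepts are not mapped as a whole: each concept is
typed by how its results are interpreted and then expanded into per-result
mapping slots, following the LOINC-to-phenotype annotation style.

* **Normal/Low/High (NLH)** concepts (numeric reference ranges or a
  quantitative scale) expand into three slots — *low* and *high* map to the
  decreased/increased phenotype terms, and *normal* maps to the abnormality
  term **logically negated** (a normal result asserts the absence of the
  abnormality).
* **Positive/Negative (PN)** concepts (ordinal scale, "presence"/"screen"
  wording, or a positive/negative reference range) expand into two slots
  sharing one term: *positive* plain and *negative* negated.
* Everything else is an **unknown result type** and yields no slots.

Concepts whose specimen is unspecified (non-specific body substances) are
marked unmapped with the literal evidence string ``"Unspecified Sample"``.
Externally supplied annotation tables can replace or supplement slot terms;
every modification is recorded in the slot's evidence.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace

from .clinical import ClinicalConcept

__all__ = [
    "MeasurementConcept", "ResultSlot", "SlotTemplate", "UnmappedRecord",
    "ExpansionError", "MergeError", "SCALES", "infer_scale",
    "infer_result_type", "expand_result_slots", "flag_unspecified_sample",
    "merge_external_annotations",
]

SCALES = ("ordinal", "nominal", "quantitative", "qualitative", "narrative",
          "doc", "panel", "unknown")
NLH_VALUES = ("low", "normal", "high")
PN_VALUES = ("positive", "negative")

_KEYWORDS = ("presence", "screen")


class ExpansionError(ValueError):
    pass


class MergeError(ValueError):
    pass


@dataclass
class MeasurementConcept:
    base: ClinicalConcept
    scale: str = "unknown"
    reference_range_kind: str = "none"   # numeric | pos_neg | none
    specimen_specified: bool = True

    def __post_init__(self):
        if self.scale not in SCALES:
            raise ValueError(f"unknown scale {self.scale!r}")
        if self.reference_range_kind not in ("numeric", "pos_neg", "none"):
            raise ValueError(f"unknown range kind {self.reference_range_kind!r}")


@dataclass
class ResultSlot:
    concept_id: int
    result_value: str                    # low | normal | high | positive | negative
    terms: list[tuple[str, str]]         # (curie, label)
    negated: bool
    evidence_items: list[str] = field(default_factory=list)


@dataclass
class UnmappedRecord:
    concept_id: int
    evidence: str


# a slot template supplies, per result value, the terms and negation flag
# (e.g. derived from external LOINC-to-HPO style annotation files)
SlotTemplate = dict[str, tuple[list[tuple[str, str]], bool]]


def infer_scale(concept: ClinicalConcept, cdm_scale: str | None = None) -> str:
    """CDM-provided scale wins; otherwise parse synonyms/label for scale
    tokens; otherwise unknown."""
    if cdm_scale:
        scale = cdm_scale.strip().lower()
        if scale not in SCALES:
            raise ValueError(f"unknown CDM scale {cdm_scale!r}")
        return scale
    text = " ".join(concept.strings()).lower()
    for scale in ("ordinal", "nominal", "quantitative", "qualitative",
                  "narrative", "panel", "doc"):
        if re.search(rf"\b{scale}\b", text):
            return scale
    return "unknown"


def _has_keyword(m: MeasurementConcept) -> bool:
    text = " ".join(m.base.strings()).lower()
    return any(re.search(rf"\b{kw}\b", text) for kw in _KEYWORDS)


def infer_result_type(m: MeasurementConcept, wave: str | None = None) -> str:
    """Classify a measurement as ``"NLH"``, ``"PN"`` or ``"UNKNOWN"``.

    Rule order (first match wins):

    1. used wave, numeric reference range        → NLH
    2. used wave, positive/negative range        → PN
    3. ordinal scale                             → PN
    4. "presence"/"screen" in label or synonyms  → PN
    5. quantitative scale                        → NLH
    6. otherwise                                 → UNKNOWN

    Reference-range evidence (observed only for concepts used in practice)
    outranks scale rules; the keyword rule outranks the quantitative-scale
    fallback.
    """
    wave = wave or m.base.wave
    if wave == "used":
        if m.reference_range_kind == "numeric":
            return "NLH"
        if m.reference_range_kind == "pos_neg":
            return "PN"
    if m.scale == "ordinal":
        return "PN"
    if _has_keyword(m):
        return "PN"
    if m.scale == "quantitative":
        return "NLH"
    return "UNKNOWN"


def expand_result_slots(m: MeasurementConcept, rtype: str,
                        template: SlotTemplate) -> list[ResultSlot]:
    """Expand a typed measurement into its per-result mapping slots.

    NLH yields exactly three slots (low, normal, high); PN yields exactly
    two (positive, plus negative as the positive terms negated).  The
    template must carry every required result value; a present-but-empty
    term list yields an empty slot (categorized unmapped downstream) rather
    than dropping the slot.
    """
    cid = m.base.concept_id
    if rtype == "NLH":
        missing = [v for v in NLH_VALUES if v not in template]
        if missing:
            raise ExpansionError(f"template missing result value(s) {missing}")
        slots = []
        for value in NLH_VALUES:
            terms, negated = template[value]
            slots.append(ResultSlot(cid, value, list(terms), negated,
                                    [f"result_type:NLH:{value}"]))
        return slots
    if rtype == "PN":
        if "positive" not in template:
            raise ExpansionError("template missing result value(s) ['positive']")
        terms, negated = template["positive"]
        return [
            ResultSlot(cid, "positive", list(terms), negated,
                       ["result_type:PN:positive"]),
            ResultSlot(cid, "negative", list(terms), not negated,
                       ["result_type:PN:negative"]),
        ]
    raise ExpansionError(f"cannot expand result type {rtype!r}")


def flag_unspecified_sample(m: MeasurementConcept) -> UnmappedRecord | None:
    """Unmapped record (evidence exactly "Unspecified Sample") when the
    measurement's specimen is a non-specific body substance; else None."""
    if not m.specimen_specified:
        return UnmappedRecord(m.base.concept_id, "Unspecified Sample")
    return None


def merge_external_annotations(slots: list[ResultSlot],
                               external: list[dict],
                               code_of: dict[int, str]) -> list[ResultSlot]:
    """Merge external per-result annotations into expanded slots.

    ``external`` rows are dicts with keys (code, result_value, curie, label,
    negated, source), keyed by (code, result_value); ``code_of`` maps
    concept_id to its measurement code.  An external row identical to the
    slot adds only a source marker; a differing row replaces the slot terms
    and records that the original annotation was updated.  Conflicting
    duplicate external rows for one key are a merge error.
    """
    by_key: dict[tuple[str, str], dict] = {}
    for row in external:
        key = (row["code"], row["result_value"])
        if key in by_key:
            prev = by_key[key]
            if (prev["curie"], prev["negated"]) != (row["curie"], row["negated"]):
                raise MergeError(f"conflicting external rows for {key}")
            continue
        by_key[key] = row
    merged: list[ResultSlot] = []
    for slot in slots:
        code = code_of.get(slot.concept_id)
        row = by_key.get((code, slot.result_value)) if code else None
        if row is None:
            merged.append(slot)
            continue
        ext_terms = [(row["curie"], row.get("label", ""))]
        ext_negated = bool(row["negated"])
        source = row.get("source", "external")
        if [c for c, _ in slot.terms] == [row["curie"]] and slot.negated == ext_negated:
            new = replace(slot, evidence_items=slot.evidence_items
                          + [f"source:{source}"])
        else:
            new = replace(slot, terms=ext_terms, negated=ext_negated,
                          evidence_items=slot.evidence_items
                          + [f"source:{source}",
                             f"updated:{source}:original annotation replaced"])
        merged.append(new)
    return merged
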