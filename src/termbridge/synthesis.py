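"""Mapping synthesis: candidates + overrides → final categorized mappings.

Every routed (concept, ontology) pair yields exactly one mapping block.
Candidate tiers are resolved by a fixed precedence:

    manual override > automatic concept-level (exact/xref) >
    selected cosine pair > automatic ancestor-level > unmapped

The resulting block carries: the term set with AND/OR/NOT logic, one of
the eight closed mapping-category labels, and a pipe-delimited evidence
string listing every resource supporting the mapping.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

from .align import CandidateMatch, EXACT_METHODS, XREF_METHODS
from .clinical import ClinicalConcept

__all__ = [
    "MappingCategory", "Mapping", "MappingSet", "ManualOverride",
    "SynthesisError", "CATEGORY_LABELS",
    "assemble", "compose_logic", "build_evidence",
    "serialize", "parse_mappings",
]


class SynthesisError(ValueError):
    pass


@dataclass(frozen=True)
class MappingCategory:
    approach: str = "automatic"      # automatic | cosine | manual
    cardinality: str = "one_to_one"  # one_to_one | one_to_many
    level: str = "concept"           # concept | ancestor
    special: str = "none"            # none | unmapped

    _APPROACH = {"automatic": "Automatic", "cosine": "Cosine Similarity",
                 "manual": "Manual"}
    _CARD = {"one_to_one": "One-to-One", "one_to_many": "One-to-Many"}
    _LEVEL = {"concept": "Concept", "ancestor": "Ancestor"}

    @property
    def label(self) -> str:
        if self.special == "unmapped":
            return "Unmapped"
        return (f"{self._APPROACH[self.approach]} "
                f"{self._CARD[self.cardinality]} {self._LEVEL[self.level]}")


#: the closed set of rendered category labels
CATEGORY_LABELS = frozenset({
    "Automatic One-to-One Concept", "Automatic One-to-One Ancestor",
    "Automatic One-to-Many Concept", "Automatic One-to-Many Ancestor",
    "Cosine Similarity One-to-One Concept", "Manual One-to-One Concept",
    "Manual One-to-Many Concept", "Unmapped",
})


@dataclass
class Mapping:
    """One synthesized mapping block: a concept (or measurement result)
    against one target ontology."""

    concept_id: int
    concept_label: str
    domain: str
    ontology: str
    terms: list[tuple[str, str, bool]]   # (curie, label, negated)
    category: MappingCategory
    evidence: str
    logic: str = ""
    score: float | None = None
    result_value: str | None = None      # measurements only

    def __post_init__(self):
        if not self.logic and self.terms:
            self.logic = compose_logic([(c, n) for c, _, n in self.terms])


@dataclass
class MappingSet:
    mappings: list[Mapping] = field(default_factory=list)

    def __iter__(self):
        return iter(self.mappings)

    def __len__(self):
        return len(self.mappings)


@dataclass(frozen=True)
class ManualOverride:
    concept_id: int
    ontology: str
    curie: str
    label: str = ""
    negated: bool = False
    evidence: str = "manual:curated"


def compose_logic(terms: list[tuple[str, bool]], operator: str = "and") -> str:
    """Render a term set as a logic expression.

    A single non-negated term renders as the bare curie; a single negated
    term as ``NOT curie``; multiple terms as ``AND(...)`` / ``OR(...)``
    with ``NOT`` prefixing each negated member.  Rendering is
    deterministic: positives first, sorted by curie within polarity.
    """
    if not terms:
        raise SynthesisError("cannot compose logic over an empty term list")
    if operator not in ("and", "or"):
        raise SynthesisError(f"unknown operator {operator!r}")
    positives = sorted(c for c, neg in terms if not neg)
    negatives = sorted(c for c, neg in terms if neg)
    rendered = positives + [f"NOT {c}" for c in negatives]
    if len(rendered) == 1:
        return rendered[0]
    return f"{operator.upper()}({', '.join(rendered)})"


def build_evidence(items) -> str:
    """Deduplicate, sort and pipe-join evidence items."""
    return "|".join(sorted(set(items)))


def _term_tuple(curie: str, label: str, negated: bool = False):
    return (curie, label, negated)


def assemble(concept: ClinicalConcept,
             candidates: list[CandidateMatch],
             overrides: list[ManualOverride] | None = None,
             *,
             targets: frozenset[str] | set[str],
             exclusion_reason: str | None = None,
             term_labels: dict[str, str] | None = None,
             operator: str = "and") -> list[Mapping]:
    """Assemble one mapping per target ontology for ``concept``.

    ``candidates`` are this concept's aligner outputs (any ontology);
    ``overrides`` are manual mapping rows keyed by (concept_id, ontology).
    When routing excluded the concept (empty ``targets`` plus a reason) a
    single Unmapped block carrying the reason is emitted.  ``operator``
    sets the default multi-term logic connective for this concept's domain.
    """
    overrides = [o for o in (overrides or []) if o.concept_id == concept.concept_id]
    term_labels = term_labels or {}
    out: list[Mapping] = []
    if not targets:
        reason = exclusion_reason or "NOT YET MAPPED"
        return [Mapping(concept.concept_id, concept.label, concept.domain,
                        ontology="none", terms=[], logic="",
                        category=MappingCategory(special="unmapped"),
                        evidence=reason)]
    for ontology in sorted(targets):
        mine = [c for c in candidates
                if c.concept_id == concept.concept_id and c.ontology_id == ontology]
        out.append(_assemble_block(concept, ontology, mine,
                                   [o for o in overrides if o.ontology == ontology],
                                   term_labels, operator))
    return out


def _label_of(curie: str, cands: list[CandidateMatch],
              term_labels: dict[str, str]) -> str:
    return term_labels.get(curie, "")


def _assemble_block(concept, ontology, cands, overrides, term_labels,
                    operator) -> Mapping:
    cid, label, domain = concept.concept_id, concept.label, concept.domain

    def _make(terms, category, evidence_items, score=None):
        if terms:
            card = "one_to_one" if len(terms) == 1 else "one_to_many"
            category = MappingCategory(category.approach, card, category.level,
                                       category.special)
        op = operator if len(terms) > 1 else "and"
        logic = compose_logic([(c, n) for c, _, n in terms], op) if terms else ""
        return Mapping(cid, label, domain, ontology, terms, category,
                       build_evidence(evidence_items), logic=logic, score=score)

    # 1. manual override
    if overrides:
        for o in overrides:
            if term_labels and o.curie not in term_labels and not o.label:
                raise SynthesisError(
                    f"override for concept {cid} names unknown curie {o.curie}")
        terms = sorted({(o.curie, o.label or term_labels.get(o.curie, ""),
                         o.negated) for o in overrides})
        return _make(terms, MappingCategory("manual"),
                     [o.evidence for o in overrides])

    # 2. automatic concept-level exact/xref
    auto = [c for c in cands if c.level == "concept"
            and c.method in EXACT_METHODS + XREF_METHODS]
    if auto:
        terms = sorted({(c.curie, _label_of(c.curie, auto, term_labels), False)
                        for c in auto})
        return _make(terms, MappingCategory("automatic"),
                     [e for c in auto for e in c.evidence_items])

    # 3. selected cosine pair
    cosine = [c for c in cands if c.method == "cosine" and c.selected]
    if cosine:
        best = cosine[0]
        terms = [(best.curie, _label_of(best.curie, cosine, term_labels), False)]
        return _make(terms, MappingCategory("cosine"),
                     list(best.evidence_items), score=best.score)

    # 4. automatic ancestor-level
    anc = [c for c in cands if c.level == "ancestor"]
    if anc:
        terms = sorted({(c.curie, _label_of(c.curie, anc, term_labels), False)
                        for c in anc})
        return _make(terms, MappingCategory("automatic", level="ancestor"),
                     [e for c in anc for e in c.evidence_items])

    # 5. unmapped
    evidence = "NOT YET MAPPED" if concept.wave == "unused" else "UNABLE TO MAP"
    return Mapping(cid, label, domain, ontology, [], logic="",
                   category=MappingCategory(special="unmapped"),
                   evidence=evidence)


# ---------------------------------------------------------------------------
# serialization

_COLUMNS = ["concept_id", "concept_label", "domain", "result_value", "ontology",
            "logic_expression", "term_curies", "term_labels", "term_negated",
            "category", "score", "evidence"]


def _mapping_row(m: Mapping) -> list[str]:
    return [str(m.concept_id), m.concept_label, m.domain,
            m.result_value or "", m.ontology, m.logic,
            ";".join(c for c, _, _ in m.terms),
            ";".join(l for _, l, _ in m.terms),
            ";".join(str(int(n)) for _, _, n in m.terms),
            m.category.label,
            "" if m.score is None else repr(m.score), m.evidence]


def _row_mapping(values: dict[str, str]) -> Mapping:
    curies = values["term_curies"].split(";") if values["term_curies"] else []
    labels = values["term_labels"].split(";") if values["term_labels"] else [""] * len(curies)
    negs = values["term_negated"].split(";") if values["term_negated"] else ["0"] * len(curies)
    terms = [(c, l, bool(int(n))) for c, l, n in zip(curies, labels, negs)]
    cat_label = values["category"]
    if cat_label == "Unmapped":
        category = MappingCategory(special="unmapped")
    else:
        approach_word, card_word, level_word = cat_label.rsplit(" ", 2)
        inv_a = {v: k for k, v in MappingCategory._APPROACH.items()}
        inv_c = {v: k for k, v in MappingCategory._CARD.items()}
        inv_l = {v: k for k, v in MappingCategory._LEVEL.items()}
        category = MappingCategory(inv_a[approach_word], inv_c[card_word],
                                   inv_l[level_word])
    return Mapping(concept_id=int(values["concept_id"]),
                   concept_label=values["concept_label"],
                   domain=values["domain"],
                   result_value=values["result_value"] or None,
                   ontology=values["ontology"], terms=terms,
                   logic=values["logic_expression"], category=category,
                   score=float(values["score"]) if values["score"] else None,
                   evidence=values["evidence"])


def serialize(mappings: MappingSet, path, format: str = "tsv") -> Path:
    """Write ``mappings`` to ``path`` as tsv, jsonl or sssom_tsv.

    tsv and jsonl round-trip losslessly through :func:`parse_mappings`;
    sssom_tsv expands each mapping to one row per (concept, term) pair with
    an exact-match predicate for exact/xref/manual blocks and a
    close-match predicate otherwise — logic nesting is lost (documented
    lossy, for interchange only).
    """
    path = Path(path)
    if format == "tsv":
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            fh.write("\t".join(_COLUMNS) + "\n")
            for m in mappings:
                fh.write("\t".join(_mapping_row(m)) + "\n")
    elif format == "jsonl":
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            for m in mappings:
                fh.write(json.dumps(dict(zip(_COLUMNS, _mapping_row(m))),
                                    sort_keys=True) + "\n")
    elif format == "sssom_tsv":
        cols = ["subject_id", "subject_label", "predicate_id", "object_id",
                "object_label", "mapping_justification", "confidence"]
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            fh.write("\t".join(cols) + "\n")
            for m in mappings:
                pred = ("skos:exactMatch"
                        if m.category.approach in ("automatic", "manual")
                        and m.category.special == "none" else "skos:closeMatch")
                just = ("semapv:LexicalMatching"
                        if m.category.approach != "manual"
                        else "semapv:ManualMappingCuration")
                for curie, tlabel, negated in m.terms:
                    fh.write("\t".join([
                        f"omop:{m.concept_id}", m.concept_label,
                        pred if not negated else "skos:relatedMatch",
                        curie, tlabel, just,
                        "" if m.score is None else repr(m.score)]) + "\n")
    else:
        raise SynthesisError(f"unknown serialization format {format!r}")
    return path


def parse_mappings(path, format: str = "tsv") -> MappingSet:
    path = Path(path)
    out = MappingSet()
    if format == "tsv":
        lines = path.read_text(encoding="utf-8").splitlines()
        header = lines[0].split("\t")
        if header != _COLUMNS:
            raise SynthesisError(f"unexpected header in {path}")
        for line in lines[1:]:
            values = dict(zip(_COLUMNS, line.split("\t")))
            out.mappings.append(_row_mapping(values))
    elif format == "jsonl":
        for line in path.read_text(encoding="utf-8").splitlines():
            out.mappings.append(_row_mapping(json.loads(line)))
    else:
        raise SynthesisError(f"cannot parse format {format!r}")
    return out
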