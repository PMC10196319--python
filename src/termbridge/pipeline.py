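"""End-to-end mapping run: ingest → annotate → route → align → synthesize.

Thin orchestration over the library modules; every step is independently
usable.  A run produces exactly one mapping block per routed (concept,
ontology) pair, plus one Unmapped block for concepts excluded by routing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .align import (ancestor_fallback, cosine_candidates, exact_string_match,
                    fit_tfidf, xref_match)
from .clinical import (ConceptSet, RoutingPolicy, UmlsTables, annotate_cui,
                       route_targets)
from .ontology import OntologyIndex
from .synthesis import ManualOverride, MappingSet, assemble
from .text import Preprocessor

__all__ = ["AlignerConfig", "run_mapping"]


@dataclass(frozen=True)
class AlignerConfig:
    """Tunable alignment parameters (all cut-offs customizable)."""

    fields: tuple[str, ...] = ("label", "synonym")
    min_score: float = 0.25
    keep_fraction: float = 0.75
    aggregation: str = "max"
    use_cosine: bool = True
    use_ancestor_fallback: bool = True
    operator_by_domain: dict = field(default_factory=lambda: {
        "condition": "and", "measurement": "and", "drug": "or"})


def run_mapping(concepts: ConceptSet, index: OntologyIndex,
                umls: UmlsTables | None = None,
                overrides: list[ManualOverride] | None = None,
                policy: RoutingPolicy | None = None,
                config: AlignerConfig | None = None) -> MappingSet:
    """Map every concept in ``concepts`` against ``index``.

    The cosine stage fits one TF-IDF model over the union of all concept
    and term label/synonym strings and is only consulted for concepts
    without a concept-level exact or cross-reference candidate (precedence
    makes higher tiers final).
    """
    config = config or AlignerConfig()
    policy = policy or RoutingPolicy.default()
    umls = umls or UmlsTables.empty()
    overrides = overrides or []
    annotations = annotate_cui(concepts, umls)
    term_labels = {t.curie: t.label for t in index.terms.values()}

    routed: dict[int, tuple[frozenset, str | None]] = {}
    for c in concepts:
        routed[c.concept_id] = route_targets(c, annotations[c.concept_id], policy)

    candidates: dict[int, list] = {}
    need_cosine: list = []
    for c in concepts:
        targets, _ = routed[c.concept_id]
        found = exact_string_match(c, index, config.fields)
        found += xref_match(c, index, annotations[c.concept_id], umls)
        matched_onts = {m.ontology_id for m in found if m.level == "concept"}
        if targets - matched_onts:
            need_cosine.append(c)
        candidates[c.concept_id] = found

    if config.use_cosine and need_cosine:
        corpus, cmap, tmap = [], {}, {}
        seen: set[str] = set()

        def _add(text):
            if text not in seen:
                seen.add(text)
                corpus.append((text, text))
            return text

        for c in need_cosine:
            cmap[c.concept_id] = [_add(s.lower()) for s in c.strings()]
        for t in index.terms.values():
            tmap[t.curie] = [_add(s.lower()) for s in t.strings()]
        model = fit_tfidf(corpus, Preprocessor())
        cos = cosine_candidates(model, cmap, tmap, config.min_score,
                                config.keep_fraction, config.aggregation)
        for m in cos:
            candidates[m.concept_id].append(m)

    if config.use_ancestor_fallback:
        for c in concepts:
            targets, _ = routed[c.concept_id]
            concept_level = {m.ontology_id for m in candidates[c.concept_id]
                             if m.level == "concept"}
            if c.ancestors and targets - concept_level:
                fb = ancestor_fallback(c, index, config.fields,
                                       annotations[c.concept_id], umls)
                candidates[c.concept_id].extend(
                    m for m in fb if m.ontology_id not in concept_level)

    out = MappingSet()
    for c in concepts:
        targets, reason = routed[c.concept_id]
        operator = config.operator_by_domain.get(c.domain, "and")
        out.mappings.extend(assemble(
            c, candidates[c.concept_id], overrides, targets=targets,
            exclusion_reason=reason, term_labels=term_labels,
            operator=operator))
    out.mappings.sort(key=lambda m: (m.concept_id, m.ontology))
    return out
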