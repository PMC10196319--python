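"""Candidate concept↔term alignment.

Four strategies, in descending order of confidence:

* **exact string matching** — case-folded equality between a clinical
  concept's label/synonyms and an ontology term's label, synonyms or
  (optionally) definition;
* **cross-reference bridging** — equality between the concept's standard or
  source codes and a term's database cross-references, either directly
  (``xref_code``) or through a shared UMLS-style CUI (``xref_cui``);
* **TF-IDF cosine embedding** — a bag-of-words vector space model with
  smoothed inverse document frequency and L2 normalization over the union
  of all concept and term strings; a concept–term pair is scored by the
  best cosine over its constituent string pairs, thresholded and trimmed to
  the top fraction, with the single best term per concept flagged as the
  selected mapping candidate;
* **ancestor fallback** — exact/xref matching rerun against the concept's
  hierarchy ancestors when nothing matched at the concept level.

All outputs are :class:`CandidateMatch` records with deterministic ordering
so identical inputs yield byte-identical candidate lists.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from sklearn.feature_extraction.text import TfidfVectorizer

from .clinical import ClinicalConcept, CuiAnnotation, UmlsTables
from .ontology import OntologyIndex
from .text import Preprocessor

__all__ = ["CandidateMatch", "EmbeddingModel", "AlignerError",
           "exact_string_match", "xref_match", "fit_tfidf",
           "cosine_candidates", "ancestor_fallback"]

EXACT_METHODS = ("label_exact", "synonym_exact", "definition_exact")
XREF_METHODS = ("xref_code", "xref_cui")


class AlignerError(ValueError):
    pass


@dataclass(frozen=True)
class CandidateMatch:
    concept_id: int
    curie: str
    ontology_id: str
    method: str          # label_exact | synonym_exact | definition_exact | xref_code | xref_cui | cosine
    level: str = "concept"          # concept | ancestor
    score: float | None = None      # present iff method == "cosine"
    selected: bool = False          # best cosine pair for this concept
    evidence_items: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self):
        if (self.score is not None) != (self.method == "cosine"):
            raise AlignerError("score present iff method is cosine")
        if not self.evidence_items:
            raise AlignerError("evidence_items must be nonempty")


def _sort_key(m: CandidateMatch):
    return (m.concept_id, m.curie, m.method, m.level, m.evidence_items)


def exact_string_match(c: ClinicalConcept, idx: OntologyIndex,
                       fields: tuple[str, ...] = ("label", "synonym"),
                       *, _strings: list[str] | None = None,
                       _level: str = "concept",
                       _extra_evidence: tuple[str, ...] = ()) -> list[CandidateMatch]:
    """Exact (case-folded) matches between concept strings and term fields.

    ``fields`` selects the ontology-side fields compared; definition
    matching is off by default.  One candidate per (matched string, term).
    """
    maps = {"label": (idx.by_label, "label_exact"),
            "synonym": (idx.by_synonym, "synonym_exact"),
            "definition": (idx.by_definition, "definition_exact")}
    out: list[CandidateMatch] = []
    strings = _strings if _strings is not None else c.strings()
    for text in strings:
        key = text.lower()
        for fname in fields:
            lookup, method = maps[fname]
            for curie in lookup.get(key, ()):
                term = idx.terms[curie]
                out.append(CandidateMatch(
                    concept_id=c.concept_id, curie=curie,
                    ontology_id=term.ontology_id, method=method, level=_level,
                    evidence_items=_extra_evidence + (f"{method}:{key}",)))
    return sorted(set(out), key=_sort_key)


def xref_match(c: ClinicalConcept, idx: OntologyIndex,
               ann: CuiAnnotation | None = None,
               umls: UmlsTables | None = None,
               *, _codes: list[str] | None = None,
               _level: str = "concept",
               _extra_evidence: tuple[str, ...] = ()) -> list[CandidateMatch]:
    """Cross-reference matches, direct (code↔xref) and CUI-bridged.

    The CUI bridge follows concept code → CUI → sibling codes under the
    same CUI → term xref; it requires both ``ann`` and ``umls``.
    """
    out: list[CandidateMatch] = []
    codes = _codes if _codes is not None else c.codes()
    for code in codes:
        for curie in idx.by_xref.get(code, ()):
            term = idx.terms[curie]
            out.append(CandidateMatch(
                concept_id=c.concept_id, curie=curie,
                ontology_id=term.ontology_id, method="xref_code", level=_level,
                evidence_items=_extra_evidence + (f"xref_code:{code}",)))
    if ann is not None and umls is not None and ann.cuis and not umls.conso.empty:
        bridged = umls.conso[umls.conso["cui"].isin(ann.cuis)]
        own = set(codes)
        for cui, sab, code in zip(bridged["cui"], bridged["sab"], bridged["code"]):
            bridge_code = f"{sab}:{code}"
            if bridge_code in own:
                continue  # direct joins already handled above
            for curie in idx.by_xref.get(bridge_code, ()):
                term = idx.terms[curie]
                out.append(CandidateMatch(
                    concept_id=c.concept_id, curie=curie,
                    ontology_id=term.ontology_id, method="xref_cui",
                    level=_level,
                    evidence_items=_extra_evidence
                    + (f"xref_cui:{cui}:{bridge_code}",)))
    return sorted(set(out), key=_sort_key)


# ---------------------------------------------------------------------------
# TF-IDF embedding


@dataclass
class EmbeddingModel:
    """A fitted document-term model: one unit-L2-norm row per input string.

    ``idf`` follows the smoothed variant ln((1+N)/(1+df)) + 1; strings whose
    tokens are all removed in preprocessing keep a zero vector.
    """

    vocabulary: list[str]
    idf: np.ndarray
    matrix: "np.ndarray"            # dense (N, M), rows unit-norm or zero
    row_ids: list[str]
    _row_index: dict[str, int] = field(default_factory=dict, repr=False)

    def __post_init__(self):
        if not self._row_index:
            self._row_index = {rid: i for i, rid in enumerate(self.row_ids)}

    def vector(self, string_id: str) -> np.ndarray:
        return self.matrix[self._row_index[string_id]]

    def cosine(self, a: str, b: str) -> float:
        return float(self.vector(a) @ self.vector(b))


def fit_tfidf(corpus: list[tuple[str, str]],
              preprocessor: Preprocessor | None = None) -> EmbeddingModel:
    """Fit the TF-IDF model over ``corpus`` rows of (string_id, text)."""
    if not corpus:
        raise AlignerError("empty corpus")
    ids = [sid for sid, _ in corpus]
    if len(set(ids)) != len(ids):
        raise AlignerError("duplicate string ids in corpus")
    pre = preprocessor or Preprocessor()
    texts = [text for _, text in corpus]
    try:
        vec = TfidfVectorizer(analyzer=pre, norm="l2", smooth_idf=True,
                              sublinear_tf=False)
        X = vec.fit_transform(texts).toarray()
    except ValueError as exc:  # every string empty after preprocessing
        raise AlignerError(f"no tokens survive preprocessing: {exc}") from exc
    order = np.argsort(vec.get_feature_names_out())
    vocab = list(vec.get_feature_names_out()[order])
    return EmbeddingModel(vocabulary=vocab, idf=vec.idf_[order],
                          matrix=X[:, order], row_ids=ids)


def _top_fraction(pairs: list[tuple], keep_fraction: float) -> list[tuple]:
    """Keep the top ``keep_fraction`` of (score-sorted) pairs, ties at the
    cut retained."""
    if not pairs:
        return pairs
    ranked = sorted(pairs, key=lambda p: (-p[2], p[0], p[1]))
    k = math.ceil(keep_fraction * len(ranked))
    cutoff = ranked[k - 1][2]
    return [p for p in ranked if p[2] >= cutoff]


def cosine_candidates(model: EmbeddingModel,
                      concepts: dict[int, list[str]],
                      terms: dict[str, list[str]],
                      min_score: float = 0.25,
                      keep_fraction: float = 0.75,
                      aggregation: str = "max") -> list[CandidateMatch]:
    """Score all concept×term pairs and emit thresholded cosine candidates.

    ``concepts`` / ``terms`` map concept_id / term curie to the string_ids
    of their label and synonyms within ``model`` (fitted on the union
    corpus).  Pair score is the maximum cosine over constituent string
    pairs (``aggregation="mean"`` scores the mean vectors instead).  Pairs
    below ``min_score`` are dropped, the survivors trimmed to the top
    ``keep_fraction`` globally, and for each concept the single
    highest-scoring surviving term is flagged ``selected``.
    """
    if not (0.0 <= min_score <= 1.0):
        raise AlignerError(f"min_score {min_score} outside [0, 1]")
    if not (0.0 < keep_fraction <= 1.0):
        raise AlignerError(f"keep_fraction {keep_fraction} outside (0, 1]")
    if aggregation not in ("max", "mean"):
        raise AlignerError(f"unknown aggregation {aggregation!r}")

    def _vectors(string_ids: list[str]) -> np.ndarray:
        return np.vstack([model.vector(s) for s in string_ids])

    def _agg(v: np.ndarray) -> np.ndarray:
        m = v.mean(axis=0)
        n = np.linalg.norm(m)
        return m / n if n > 0 else m

    scored: list[tuple[int, str, float, str]] = []
    cvecs = {cid: _vectors(s) for cid, s in concepts.items() if s}
    tvecs = {cu: _vectors(s) for cu, s in terms.items() if s}
    for cid in sorted(cvecs):
        for curie in sorted(tvecs):
            if aggregation == "max":
                sims = cvecs[cid] @ tvecs[curie].T
                i, j = np.unravel_index(int(np.argmax(sims)), sims.shape)
                score = float(sims[i, j])
                pair = f"{concepts[cid][int(i)]}~{terms[curie][int(j)]}"
            else:
                score = float(_agg(cvecs[cid]) @ _agg(tvecs[curie]))
                pair = "mean-vector"
            if score >= min_score:
                scored.append((cid, curie, score, pair))
    kept = _top_fraction(scored, keep_fraction)
    best: dict[int, tuple[str, float]] = {}
    for cid, curie, score, _ in kept:
        if cid not in best or score > best[cid][1] \
                or (score == best[cid][1] and curie < best[cid][0]):
            best[cid] = (curie, score)
    out = [CandidateMatch(
        concept_id=cid, curie=curie, ontology_id=curie.split(":", 1)[0],
        method="cosine", score=round(score, 12),
        selected=(best.get(cid, (None,))[0] == curie),
        evidence_items=(f"cosine:{score:.6f}:{pair}",))
        for cid, curie, score, pair in kept]
    return sorted(out, key=_sort_key)


def ancestor_fallback(c: ClinicalConcept, idx: OntologyIndex,
                      fields: tuple[str, ...] = ("label", "synonym"),
                      ann: CuiAnnotation | None = None,
                      umls: UmlsTables | None = None) -> list[CandidateMatch]:
    """Exact/xref matching rerun per concept ancestor (level="ancestor").

    Only meaningful when the concept itself produced no concept-level
    candidate for the target ontology; every hit names its ancestor in the
    evidence.
    """
    out: list[CandidateMatch] = []
    for anc_id, anc_code, anc_label in c.ancestors:
        tag = (f"ancestor:{anc_id}:{anc_code}",)
        out.extend(exact_string_match(c, idx, fields, _strings=[anc_label],
                                      _level="ancestor", _extra_evidence=tag))
        out.extend(xref_match(c, idx, ann=ann, umls=umls, _codes=[anc_code],
                              _level="ancestor", _extra_evidence=tag))
    return sorted(set(out), key=_sort_key)
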