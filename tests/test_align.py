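"""Aligner: exact/xref strategies, the TF-IDF embedding and its thresholds."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from termbridge.align import (AlignerError, ancestor_fallback,
                              cosine_candidates, exact_string_match,
                              fit_tfidf, xref_match)
from termbridge.clinical import ClinicalConcept, CuiAnnotation, UmlsTables
from termbridge.ontology import OntologyIndex, OntologyTerm


def _concept(cid=1, label="asthma", synonyms=(), code="snomedct:1",
             source_codes=(), ancestors=()):
    return ClinicalConcept(concept_id=cid, vocabulary="snomedct", code=code,
                           label=label, domain="condition",
                           synonyms=list(synonyms),
                           source_codes=list(source_codes),
                           ancestors=list(ancestors))


def _index(*terms):
    return OntologyIndex.build(terms)


class TestExactMatch:
    def test_case_folded_label_match(self):
        idx = _index(OntologyTerm("hp:1", "Asthma"))
        (m,) = exact_string_match(_concept(label="asthma"), idx)
        assert (m.curie, m.method, m.level) == ("hp:1", "label_exact", "concept")

    def test_synonym_only_match_routes_to_synonym_exact(self):
        idx = _index(OntologyTerm("hp:1", "Asthma attack",
                                  synonyms=[("asthma", "exact")]))
        (m,) = exact_string_match(_concept(label="Asthma"), idx)
        assert m.method == "synonym_exact"

    def test_definition_matching_off_by_default(self):
        idx = _index(OntologyTerm("hp:1", "Other", definition="asthma"))
        assert exact_string_match(_concept(label="asthma"), idx) == []
        (m,) = exact_string_match(_concept(label="asthma"), idx,
                                  fields=("label", "synonym", "definition"))
        assert m.method == "definition_exact"

    def test_planted_collisions_match_nested_loop_oracle(self, loaded_mapping):
        """Candidates over the fixture equal a brute-force nested-loop
        lowercase string comparison."""
        concepts, idx, _, _ = loaded_mapping
        got = set()
        for c in concepts:
            for m in exact_string_match(c, idx):
                got.add((m.concept_id, m.curie, m.method))
        expected = set()
        for c in concepts:
            for s in c.strings():
                for t in idx.terms.values():
                    if s.lower() == t.label.lower():
                        expected.add((c.concept_id, t.curie, "label_exact"))
                    for syn, _ in t.synonyms:
                        if s.lower() == syn.lower():
                            expected.add((c.concept_id, t.curie, "synonym_exact"))
        assert got == expected and len(got) > 0


class TestXrefMatch:
    def test_direct_code_join(self):
        idx = _index(OntologyTerm("hp:1", "t", xrefs=["snomedct:111111"]))
        (m,) = xref_match(_concept(code="snomedct:111111"), idx)
        assert m.method == "xref_code"
        assert "xref_code:snomedct:111111" in m.evidence_items

    def test_three_hop_cui_bridge(self):
        """code -> CUI -> sibling code in another vocabulary -> term xref."""
        idx = _index(OntologyTerm("mondo:1", "t", xrefs=["icd10cm:E11.9"]))
        umls = UmlsTables(
            conso=pd.DataFrame([("C1", "snomedct", "44054006", "x"),
                                ("C1", "icd10cm", "E11.9", "x")],
                               columns=["cui", "sab", "code", "string"]),
            sty=pd.DataFrame(columns=["cui", "semantic_type"]))
        ann = CuiAnnotation(1, cuis={"C1"}, semantic_types=set())
        (m,) = xref_match(_concept(code="snomedct:44054006"), idx, ann, umls)
        assert m.method == "xref_cui"
        assert "xref_cui:C1:icd10cm:E11.9" in m.evidence_items

    def test_no_shared_codes_yields_empty(self):
        idx = _index(OntologyTerm("hp:1", "t", xrefs=["loinc:9-9"]))
        assert xref_match(_concept(), idx) == []


class TestTfidf:
    def test_single_string_self_cosine_one(self):
        model = fit_tfidf([("a", "chronic kidney failure")])
        assert model.cosine("a", "a") == pytest.approx(1.0, abs=1e-12)
        assert np.linalg.norm(model.vector("a")) == pytest.approx(1.0)

    def test_disjoint_token_sets_cosine_zero(self):
        model = fit_tfidf([("a", "kidney failure"), ("b", "serum glucose")])
        assert model.cosine("a", "b") == 0.0

    def test_empty_corpus_raises(self):
        with pytest.raises(AlignerError):
            fit_tfidf([])

    def test_pairwise_cosines_match_formula_oracle(self, tfidf_oracle):
        """All 45 pairwise cosines of a 10-string corpus equal the
        independent implementation of the pinned definition within 1e-9."""
        texts = ["increased blood glucose level", "decreased blood glucose level",
                 "acute asthma attack", "chronic kidney failure",
                 "acute kidney failure", "elevated blood pressure",
                 "decreased serum sodium", "impaired glucose tolerance",
                 "asthma", "elevated serum glucose"]
        model = fit_tfidf([(f"s{i}", t) for i, t in enumerate(texts)])
        expected = tfidf_oracle(texts)
        for i in range(len(texts)):
            for j in range(i + 1, len(texts)):
                assert model.cosine(f"s{i}", f"s{j}") == pytest.approx(
                    expected[i, j], abs=1e-9)


def _fit_pairs(concept_texts, term_texts):
    corpus = [(t, t) for t in dict.fromkeys(
        [s for ss in concept_texts.values() for s in ss]
        + [s for ss in term_texts.values() for s in ss])]
    return fit_tfidf(corpus)


class TestCosineCandidates:
    def test_identical_synonym_scores_one_and_selected(self):
        concepts = {1: ["peptic ulcer"]}
        terms = {"hp:1": ["peptic ulcer"], "hp:2": ["kidney stone"]}
        model = _fit_pairs(concepts, terms)
        out = cosine_candidates(model, concepts, terms)
        assert [(m.curie, m.selected) for m in out] == [("hp:1", True)]
        assert out[0].score == pytest.approx(1.0)

    def test_all_below_threshold_empty(self):
        concepts = {1: ["alpha beta"]}
        terms = {"hp:1": ["gamma delta"]}
        model = _fit_pairs(concepts, terms)
        assert cosine_candidates(model, concepts, terms, min_score=0.25) == []

    @pytest.mark.parametrize("bad", [dict(min_score=-0.1), dict(min_score=1.5),
                                     dict(keep_fraction=0.0),
                                     dict(keep_fraction=1.2)])
    def test_parameter_validation(self, bad):
        concepts = {1: ["a b"]}
        model = _fit_pairs(concepts, {"hp:1": ["a c"]})
        with pytest.raises(AlignerError):
            cosine_candidates(model, concepts, {"hp:1": ["a c"]}, **bad)

    def _grid(self):
        rng = np.random.default_rng(5)
        words = ["vala", "belo", "coda", "dima", "enos", "fipo", "gilo",
                 "hato", "ivon", "jepa", "kelo", "lima", "mopo", "nilo"]
        concepts = {i: [" ".join(rng.choice(words, 3, replace=False))]
                    for i in range(8)}
        terms = {f"hp:{j}": [" ".join(rng.choice(words, 3, replace=False))]
                 for j in range(12)}
        return concepts, terms

    def test_retained_set_matches_brute_force(self, tfidf_oracle):
        """8×12 grid: output equals brute-force filter(score >= 0.25) then
        keep-top-75% (ceiling, ties kept)."""
        concepts, terms = self._grid()
        model = _fit_pairs(concepts, terms)
        out = cosine_candidates(model, concepts, terms, 0.25, 0.75)
        # the document universe is the set of distinct strings, matching the
        # one-row-per-input-string model
        texts = list(dict.fromkeys([s[0] for s in concepts.values()]
                                   + [s[0] for s in terms.values()]))
        pos = {t: i for i, t in enumerate(texts)}
        sims = tfidf_oracle(texts)
        survivors = []
        for cid, cstrs in concepts.items():
            for curie, tstrs in terms.items():
                score = sims[pos[cstrs[0]], pos[tstrs[0]]]
                if score >= 0.25:
                    survivors.append((cid, curie, score))
        survivors.sort(key=lambda p: -p[2])
        k = math.ceil(0.75 * len(survivors))
        cutoff = survivors[k - 1][2]
        expected = {(cid, curie) for cid, curie, s in survivors if s >= cutoff}
        assert {(m.concept_id, m.curie) for m in out} == expected
        for m in out:
            match = [s for cid, cu, s in survivors
                     if (cid, cu) == (m.concept_id, m.curie)]
            assert m.score == pytest.approx(match[0], abs=1e-9)

    @given(lo=st.floats(0.05, 0.9), hi=st.floats(0.05, 0.9))
    @settings(max_examples=20, deadline=None)
    def test_threshold_monotonicity(self, lo, hi):
        lo, hi = min(lo, hi), max(lo, hi)
        concepts, terms = self._grid()
        model = _fit_pairs(concepts, terms)
        at_lo = {(m.concept_id, m.curie)
                 for m in cosine_candidates(model, concepts, terms, lo, 1.0)}
        at_hi = {(m.concept_id, m.curie)
                 for m in cosine_candidates(model, concepts, terms, hi, 1.0)}
        assert at_hi <= at_lo

    def test_keep_fraction_nesting(self):
        concepts, terms = self._grid()
        model = _fit_pairs(concepts, terms)
        small = {(m.concept_id, m.curie)
                 for m in cosine_candidates(model, concepts, terms, 0.1, 0.4)}
        large = {(m.concept_id, m.curie)
                 for m in cosine_candidates(model, concepts, terms, 0.1, 0.9)}
        assert small <= large

    def test_deterministic_output(self):
        concepts, terms = self._grid()
        model = _fit_pairs(concepts, terms)
        a = cosine_candidates(model, concepts, terms)
        b = cosine_candidates(model, concepts, terms)
        assert a == b


class TestAncestorFallback:
    def test_ancestor_label_hit(self):
        idx = _index(OntologyTerm("hp:1", "Broad finding"))
        c = _concept(ancestors=[(9, "snomedct:9", "Broad finding")])
        (m,) = ancestor_fallback(c, idx)
        assert m.level == "ancestor"
        assert "ancestor:9:snomedct:9" in m.evidence_items

    def test_three_matching_ancestors_match_per_ancestor_oracle(self):
        terms = [OntologyTerm(f"hp:{k}", f"ancestor label {k}") for k in range(3)]
        idx = _index(*terms)
        ancestors = [(k, f"snomedct:{k}", f"ancestor label {k}") for k in range(3)]
        c = _concept(ancestors=ancestors)
        got = {(m.curie, m.level) for m in ancestor_fallback(c, idx)}
        expected = set()
        for _, _, anc_label in ancestors:
            for m in exact_string_match(_concept(label=anc_label), idx):
                expected.add((m.curie, "ancestor"))
        assert got == expected and len(got) == 3

    def test_no_ancestors_yields_empty(self):
        idx = _index(OntologyTerm("hp:1", "x"))
        assert ancestor_fallback(_concept(), idx) == []
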