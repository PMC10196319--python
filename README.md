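# termbridge

Structured data in electronic health records is coded in clinical
vocabularies (SNOMED-CT for conditions, RxNorm for drug ingredients, LOINC
for laboratory measurements) that were never designed to interoperate with
the biomedical ontologies — HPO, Mondo, ChEBI, Uberon, NCBITaxon, PRO, CL,
VO — that make deep phenotyping and cross-domain data integration possible.
`termbridge` is a toolkit for building those bridges at health-system
scale: it aligns clinical vocabulary concepts to ontology terms with a
stack of strategies ordered by confidence, synthesizes the results into
categorized, evidence-backed mappings with explicit AND/OR/NOT semantics,
and ships the two evaluation layers such a mapping set needs — a multi-site
coverage analysis and a phenotype-risk-score clinical utility test.

It is written for informaticians and computational biologists who have
exported concept tables from a common-data-model warehouse and want
ontology mappings they can audit: every mapping records *how* it was made
and *what evidence* supports it.

## The method

For each clinical concept `c` and candidate ontology term `t`, candidates
are generated by, in descending precedence:

1. **Manual overrides** — curated rows that always win.
2. **Exact lexical matching** — case-folded equality between the concept's
   label/synonyms and the term's label, synonyms or definition.
3. **Cross-reference bridging** — the concept's standard or source codes
   equal a term's database cross-reference (xref), either directly or via a
   shared UMLS-style CUI (code → CUI → sibling code → xref). All codes pass
   through one prefix-normalization table, so `SNOMED-CT:1234567` and
   `sctid:1234567` join.
4. **TF-IDF cosine embedding** — strings are lowercased, tokenized,
   stop-word-filtered and lemmatized, embedded in a bag-of-words space with
   smoothed inverse document frequency `idf(w) = ln((1+N)/(1+df_w)) + 1`
   and L2 normalization; a pair is scored by the best cosine over its
   constituent strings, pairs below 0.25 are dropped, the survivors trimmed
   to the top 75%, and each concept's best surviving term is its cosine
   candidate. All cut-offs are configurable.
5. **Ancestor fallback** — strategies 2–3 rerun against the concept's
   hierarchy ancestors when nothing matched at the concept level.

The winning tier fixes one of eight closed category labels (Automatic /
Cosine Similarity / Manual × One-to-One / One-to-Many × Concept /
Ancestor, plus Unmapped); multi-term mappings render as logic expressions
such as `AND(hp:0004398, hp:0004796, NOT hp:0002239, NOT hp:0031368)`.
Measurement concepts additionally expand into per-result slots
(low/normal/high or positive/negative) with negation semantics, so a
*normal* lab result maps to the *negated* abnormality term.

Coverage of a prevalence data set is `|overlap| / (|overlap| +
|prevalence-only|)` (raw) and the overlapped concepts' share of floored,
site-aggregated occurrence counts (weighted); between-site differences use
Yates-corrected chi-square tests with Bonferroni post hocs.  The phenotype
risk score of patient *i* for disease *d* is
`Σ_p −log10(prevalence_p)` over the profile phenotypes `p ∈ P_d` the
patient exhibits, standardized by covariate-residual z-scoring, with a
one-sided Wilcoxon rank-sum test comparing cases and controls.

## Worked example

All inputs a real deployment needs (concept exports, ontology metadata,
UMLS tables) are licensed, so the package ships generators for synthetic
stand-ins with planted ground truth:

```bash
python examples/01_map_concepts.py
```

prints

```
40 concepts x 60 ontology terms -> 64 mapping blocks

mapping blocks by category (one block per routed concept-ontology pair):
   34  Unmapped
   20  Automatic One-to-One Concept
    8  Cosine Similarity One-to-One Concept
    2  Automatic One-to-One Ancestor
```

The 12 planted exact-string collisions and 8 planted code→CUI→xref chains
all surface as Automatic One-to-One Concept blocks; the 8 planted
near-duplicate labels come back as Cosine Similarity blocks with their
scores in the evidence; concepts with no lexical or code bridge stay
Unmapped (`NOT YET MAPPED` for concepts never used in practice).  The other
examples show measurement result typing (`02`), the coverage evaluation —
planted raw 80.0% / weighted 95.0% recovered exactly (`03`) — and the
risk-score case/control test (`04`).

The same capabilities are scriptable from a shell:

```bash
termbridge fixtures --kind mapping --seed 7 --out fx
termbridge run --concepts fx --ontology fx/ontology \
    --umls-conso fx/umls_conso.psv --umls-sty fx/umls_sty.psv --out out
termbridge eval-coverage --prevalence pv/prevalence.tsv \
    --mapper-concepts pv/mapper_concepts.txt --out coverage.json
```

## Layout

- `src/termbridge/` — the library: `identifiers`, `ontology`, `clinical`,
  `measurements`, `align`, `synthesis`, `coverage`, `phers`, `fixtures`,
  `pipeline`, `cli`.
- `examples/` — one narrative script per capability.
- `docs/methods.md` — model assumptions, parameter defaults, numerical
  choices and known limitations.
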