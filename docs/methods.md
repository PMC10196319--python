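# Methods

## Problem setting

Clinical data warehouses store conditions, drug exposures and laboratory
measurements as standard vocabulary concepts (SNOMED-CT, RxNorm, LOINC
style), each with a label, synonyms, source codes mapped onto it, and a
hierarchy of ancestor concepts. Biomedical ontologies expose labels,
definitions, typed synonyms, database cross-references (xrefs) and an
ancestor closure per term. `termbridge` aligns the former to the latter
and packages the alignment as auditable mapping records.

The package deliberately works on *pre-extracted metadata tables*, not
live databases or OWL axioms: clinical exports are the norm (patient data
cannot leave the warehouse), and the ontology side needs no reasoning —
ancestor closures are either supplied or computed from `is_a` edges alone.

## Identifier normalization

Every code is canonicalized to `prefix:local` with a lowercase canonical
prefix; the prefix-synonym table (`data/normalization.tsv`) folds the
common alias spellings (`SNOMED-CT`, `sctid`, `SNOMEDCT_US` → `snomedct`;
`ICD-10-CM` variants → `icd10cm`; …) and is user-overridable. Unknown
prefixes pass through lowercased with a warning rather than failing, which
keeps normalization total and idempotent — the property every join in the
package relies on. Bare codes without a prefix are rejected: a code is
only joinable once its vocabulary is explicit.

## Concept annotation and routing

When UMLS-style MRCONSO/MRSTY tables are available, each concept is
annotated with every CUI whose (vocabulary, code) row matches one of the
concept's codes, and with the union of semantic types over those CUIs.
Semantic types route condition concepts: phenotype-like types (Finding,
Sign or Symptom, …) to the phenotype ontology `hp`, disease-like types
(Disease or Syndrome, Neoplastic Process, …) to the disease ontology
`mondo`, both lists editable in `data/routing.yaml`. Types without a clear
pathological or biological origin (injuries, accidents, procedures, …)
exclude the concept with the reason recorded in its evidence field. Drug
and measurement concepts have fixed target sets (chebi/ncbitaxon/pr/vo and
hp/uberon/ncbitaxon/pr/chebi/cl respectively).

Design choices where the routing was genuinely open:

- A concept with both phenotype- and disease-like types routes to **both**
  ontologies (the union is the safe reading).
- A condition with **no** semantic-type annotation routes to both rather
  than being excluded: absence of annotation is not evidence of a
  non-biological concept.
- The shipped type lists are sensible defaults, not a complete partition
  of the UMLS semantic network; deployments should edit the YAML.
- Without UMLS tables the aligner falls back to direct code↔xref joins.

## Alignment strategies and precedence

Per concept and target ontology, candidates are taken from the highest
non-empty tier:

    manual override > exact/xref at concept level > selected cosine pair >
    exact/xref at ancestor level > unmapped

Exact matching compares case-folded strings only — no fuzzy or
edit-distance matching, so a hit is exactly reproducible. Definition-field
equality is implemented but off by default (long definitions rarely equal
concept labels; enabling it mostly adds noise). Cross-reference bridging
is either direct (a concept code equals a term xref) or CUI-mediated
(concept code → CUI → sibling code under that CUI → term xref), with the
bridging code recorded in the evidence.

### The embedding

Text preprocessing: lowercase, word tokenization (`[a-z0-9]+`), stop-word
removal against a packaged common-English list, and a packaged
dictionary-plus-suffix-rule English lemmatizer (irregular plurals first,
then regular inflectional endings, with a guard list for clinical words a
naive stripper would mangle). Both are deliberately shipped inside the
package and overridable, so the embedding is bit-reproducible across
environments. The document-term model has one row per distinct input
string; cell values are term frequency × smoothed inverse document
frequency, `idf(w) = ln((1+N)/(1+df_w)) + 1`, rows L2-normalized (strings
whose tokens are all removed keep a zero vector). This variant is pinned
so an independent reimplementation of the formula reproduces every cosine
to machine precision, which the test suite verifies.

A concept–term pair is scored by the **maximum** cosine over all pairs of
their label/synonym strings; mean-vector aggregation is available behind a
switch but the max preserves the single-best-string-pair selection rule.
Pairs below `min_score = 0.25` are dropped; survivors are trimmed globally
(per run) to the top `keep_fraction = 0.75` by score, computed with a
ceiling and with ties at the cut retained so the retained set is a
deterministic function of the scores. The filter runs before per-concept
best selection (selecting first and filtering after is the other
defensible order; filter-then-select is the default because the trim is
defined over the pair population). Each concept's best surviving term is
flagged as its selected cosine candidate. Both thresholds are exposed in
`AlignerConfig`.

### Ancestor fallback

Only consulted when a concept has no concept-level candidate for a target
ontology; exact and xref matching rerun against each ancestor's label and
code, every hit carries `level=ancestor` and names the ancestor in its
evidence. No prioritization among ancestors is attempted — all hits are
reported, and the mapping category's cardinality counts distinct *matched
terms*, not distinct ancestors.

## Synthesis

The winning tier determines the category: approach (automatic / cosine
similarity / manual) × cardinality (one-to-one / one-to-many) × level
(concept / ancestor), rendered into a closed set of eight labels. Ties at
the automatic tier (several distinct terms with equal standing) become
one-to-many mappings joined by AND for conditions and measurements and OR
for drugs (multi-ingredient xrefs enumerate alternatives); the operator is
configurable per domain. Logic rendering is deterministic: positives
first, sorted by CURIE within polarity, `NOT` prefixing negated terms.
Evidence strings are deduplicated, sorted, pipe-joined items of the form
`kind:value` (`label_exact:asthma`, `xref_cui:C0004096:icd10cm:J45`,
`cosine:0.715:a~b`, `manual:curated`).

Unmapped blocks carry, in priority order: the routing exclusion reason;
`NOT YET MAPPED` for concepts never used in clinical practice (candidates
were attempted automatically but nothing was curated); or `UNABLE TO MAP`
for used concepts with neither candidates nor overrides. The manual
override table doubles as the channel for curated measurement
specimen/entity/organism annotations — the package models the *output* of
curation, not curator workflow.

Serialization: TSV and JSONL round-trip losslessly (verified byte-exactly
in tests); an SSSOM-style TSV export emits one row per (concept, term)
pair with an exact-match predicate for automatic/manual mappings and a
close-match predicate otherwise. SSSOM cannot carry the AND/OR/NOT
nesting, so that export is documented as lossy interchange.

## Measurement result semantics

Scale inference prefers a warehouse-provided scale and falls back to
parsing scale tokens out of synonyms, then `unknown`. Result typing, first
match wins:

1. used in practice + numeric reference range → Normal/Low/High (NLH)
2. used in practice + positive/negative range → Positive/Negative (PN)
3. ordinal scale → PN
4. "presence"/"screen" in label or synonyms (case-insensitive,
   whole-word — substring matching would catch screening-adjacent terms)
   → PN
5. quantitative scale → NLH
6. otherwise → unknown result type (no slots; the concept is unmapped)

Reference-range evidence is only consulted for concepts used in practice —
ranges are observed from use — and outranks scale rules; the keyword rule
outranks the quantitative fallback. NLH expands to exactly three slots
with the *normal* slot negated against the abnormality term; PN to exactly
two slots sharing one term, negated for *negative*. A template key that is
present but empty yields an empty slot categorized unmapped (keeping slot
cardinality invariant); an absent key is an error. Measurements whose
specimen is a non-specific body substance are unmapped with evidence
exactly `Unspecified Sample`. External per-result annotation tables merge
in with full provenance: identical rows add a source marker, differing
rows replace the terms and add an `updated:` marker, conflicting
duplicates are an error.

## Coverage evaluation

Counts below 100 are floored to 100 before weighting (the
de-identification convention of concept-prevalence releases). Raw coverage
is the percentage of prevalence concepts present in the (valid-mapping
filtered) mapper set; weighted coverage is the overlapped concepts' share
of total floored counts aggregated across sites — frequency weighting is
the only construction under which weighted coverage can exceed raw
coverage when commonly used concepts are preferentially covered, which is
the quantity of interest. Per-site coverage uses each site's own concept
set as denominator. Missing concepts are triaged in strict priority:
recovered in a newer data-model release, else purposefully excluded, else
truly missing — exhaustive and mutually exclusive by construction. The
omnibus between-site test treats the sites × (covered, uncovered) r×2
table with the chi-square test of independence; Yates' continuity
correction applies at one degree of freedom (all 2×2 pairwise post hocs),
larger tables use the uncorrected statistic. Post hoc p values are
Bonferroni-multiplied by the number of pairs and clipped at 1.

## Phenotype risk score

A disease profile is the union of phenotype annotations over the disease's
genes. The raw score is `Σ −log10(prevalence_p)` over profile phenotypes
the patient exhibits at least once — the inverse-log-prevalence weighting
of the phenotype-risk-score literature, so rare phenotypes dominate.
Standardization regresses raw scores on intercept + age + sex + record
length by ordinary least squares and z-scores the residuals (mean 0, sd 1
with the sample ddof=1 convention); it is location-invariant and reduces
covariate-driven baseline differences before group comparison. Cases
require ≥ 2 occurrences of a disease diagnosis code, controls 0;
single-occurrence patients are excluded as ambiguous. Matching is greedy
without replacement on exact sex and binned age (5-year bins) and record
length (1-year bins), with unmatched cases reported rather than silently
dropped.

The one-sided Wilcoxon rank-sum test (alternative: cases score higher)
uses midranks; for combined samples of ≤ 12 the p value is exact by
enumeration of all rank assignments (ties handled by enumerating observed
values), otherwise the normal approximation with tie-corrected variance
and a 0.5 continuity correction. The two routes agree within 0.02 at
n₁ = n₂ = 6 and the approximation matches the standard asymptotic
Mann-Whitney test to 1e-9, both verified in the suite. All-identical
scores are a degenerate-test error, not a p value.

## Synthetic fixtures: what they do and do not show

The generators emulate the *structure* of the real inputs with planted,
machine-readable ground truth:

- **Mapping fixture** (default 40 concepts × 60 terms): 30% of concepts
  get an exact-string collision (alternating label↔label and
  label↔synonym), 20% a code→CUI→code→xref chain, 20% a near-duplicate
  cosine partner sharing 3 of 4 tokens, two decoys an ancestor-level hit;
  all other labels draw from disjoint synthetic token pools, so exact and
  xref recovery is exactly 100% recall and precision by construction.
  Labels are built from consonant-vowel pseudo-words that are stable under
  the packaged lemmatizer and never stop words.
- **Prevalence fixture** (default 4 sites, 100 prevalence concepts):
  uniform per-site counts solve the planted raw (80%) and weighted (95%)
  coverage exactly in rational arithmetic; a handful of records carry
  sub-floor raw counts that floor back onto the planted value, so flooring
  is exercised without moving the totals.
- **Cohort fixture**: cases draw each profile phenotype independently with
  `p_case = 0.3`, controls with `p_control = 0.05` (defaults; the power
  simulation uses 200 cases / 2000 controls and the null calibration
  100/100 at equal rates of 0.2 — a deliberately modest cohort for the
  type-I check); ages uniform on 0–21 years (a pediatric population),
  record lengths uniform on 30–7300 days, phenotype prevalences fixed on a
  0.001–0.1 grid.

Every generator draws from its own stream derived from the master seed by
a fixed label, so regeneration is byte-identical and adding a generator
never perturbs existing fixtures.

What passing tests on these fixtures shows: the algorithmic contracts —
recall of planted structure, threshold semantics, precedence, category
closure, exact coverage arithmetic, test calibration — hold. What they do
**not** show: performance on real vocabularies (real synonym noise,
near-miss labels, inconsistent xref curation, skewed frequency
distributions), the quality of manual curation, or coverage numbers for
any real site. Real-data claims require real data and expert review.

## Numerical choices and degenerate inputs

- Cosine scores are compared with exact `>=` thresholds; candidate lists
  are sorted by (concept, curie, method, level, evidence) so equal inputs
  give byte-identical outputs; no randomness anywhere in the mapper.
- Zero vectors (strings with no surviving tokens) score 0 against
  everything and can never pass the 0.25 floor.
- Empty prevalence records, zero contingency marginals, zero residual
  variance, empty score groups and all-tied rank tests raise typed errors
  rather than returning NaN.
- Problem sizes in the test suite and acceptance script (40×60 mapping
  grid, 4-site prevalence set, 100 power and 1000 null replicates) were
  chosen as the smallest sizes at which each property is non-trivially
  exercised.

## Known limitations

- No fuzzy lexical matching or contextual (neural) embeddings; the
  embedding is bag-of-words by design, and the cosine tier's precision on
  real data depends on the curated thresholds.
- Xrefs are treated as exact correspondences; source ontologies' broad/
  narrow xref annotations are not modeled.
- Ancestor fallback maps all matching ancestors without ranking them.
- SSSOM export loses logic nesting.
- The risk-score layer models phenotype presence as a binary at ≥ 1
  occurrence and does not use occurrence counts or dates.
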