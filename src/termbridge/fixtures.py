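"""Synthetic fixtures with planted, machine-readable ground truth.

Real inputs to the mapper — clinical concept exports, ontology metadata,
UMLS tables, multi-site concept prevalence, patient cohorts — are licensed
or restricted.  This module generates small synthetic stand-ins for all of
them, with every recoverable fact *planted by construction* and recorded in
a manifest: exact-string collisions, code→CUI→code cross-reference chains,
near-duplicate string pairs for the cosine aligner, exact coverage
fractions, and case/control phenotype enrichment.  Generators are
deterministic: a given seed always regenerates byte-identical files, and
each generator draws from its own seed-derived stream so adding one never
perturbs another.

These fixtures emulate the *structure* of clinical and ontology data (ids,
codes, synonyms, hierarchies, per-site counts), not its statistical realism.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from fractions import Fraction
from math import ceil
from pathlib import Path

import numpy as np

from .clinical import UmlsTables
from .phers import Cohort, DiseaseProfile, Patient

__all__ = ["FixtureManifest", "make_mapping_fixture",
           "make_prevalence_fixture", "make_cohort_fixture",
           "simulate_group_scores"]

# fixed per-generator stream labels: adding a generator never perturbs others
_STREAMS = {"mapping": 101, "prevalence": 202, "cohort": 303}

_CONSONANTS = "bdfgklmnprtvz"
_VOWELS = "aeiou"


class FixtureError(ValueError):
    pass


@dataclass
class FixtureManifest:
    seed: int
    kind: str
    planted: dict = field(default_factory=dict)
    files: list[str] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps({"seed": self.seed, "kind": self.kind,
                           "planted": self.planted, "files": self.files},
                          indent=2, sort_keys=True)

    def write(self, path: Path) -> None:
        path.write_text(self.to_json() + "\n", encoding="utf-8")


def _rng(seed: int, kind: str) -> np.random.Generator:
    return np.random.default_rng([int(seed), _STREAMS[kind]])


def _word(rng: np.random.Generator, syllables: int = 3) -> str:
    # CV syllables ending in a non-s consonant: stable under the packaged
    # lemmatizer and never a stop word
    parts = []
    for _ in range(syllables):
        parts.append(_CONSONANTS[rng.integers(len(_CONSONANTS))])
        parts.append(_VOWELS[rng.integers(len(_VOWELS))])
    parts.append(_CONSONANTS[rng.integers(len(_CONSONANTS))])
    return "".join(parts)


def _word_pool(rng: np.random.Generator, n: int) -> list[str]:
    pool: list[str] = []
    seen: set[str] = set()
    while len(pool) < n:
        w = _word(rng)
        if w not in seen:
            seen.add(w)
            pool.append(w)
    return pool


def _write(path: Path, header: str, rows: list[str],
           relative_to: Path | None = None) -> str:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(header + "\n")
        for row in rows:
            fh.write(row + "\n")
    return str(path.relative_to(relative_to)) if relative_to else str(path)


# ---------------------------------------------------------------------------
# mapping fixture


def make_mapping_fixture(out_dir, seed: int = 7, n_concepts: int = 40,
                         n_terms: int = 60,
                         rates: tuple[float, float, float] = (0.3, 0.2, 0.2),
                         n_unused: int | None = None) -> FixtureManifest:
    """Emit clinical tables, ontology TSVs, mini UMLS tables and a manifest.

    ``rates`` are the fractions of concepts given a planted exact-string
    collision, a planted code→CUI→xref chain, and a planted near-duplicate
    (cosine) partner, respectively.  Exact pairs alternate between
    label↔label and label↔synonym collisions.  Two extra decoy concepts
    carry an ancestor whose label matches a term, to exercise the
    ancestor-level fallback.  All remaining concepts and terms draw labels
    from disjoint token pools, so planted recall and precision are exactly
    100% for the exact and cross-reference strategies.
    """
    if sum(rates) > 1.0 + 1e-9:
        raise FixtureError(f"rates {rates} sum above 1")
    n_exact = round(rates[0] * n_concepts)
    n_xref = round(rates[1] * n_concepts)
    n_cos = round(rates[2] * n_concepts)
    n_planted = n_exact + n_xref + n_cos
    n_anc = 2 if n_planted > 0 and n_concepts - n_planted >= 4 else 0
    if n_exact + n_xref + n_cos > min(n_concepts, n_terms):
        raise FixtureError("infeasible rates for the requested sizes")
    if n_unused is None:
        n_unused = max(1, n_concepts // 4)
    rng = _rng(seed, "mapping")
    out_dir = Path(out_dir)
    (out_dir / "ontology").mkdir(parents=True, exist_ok=True)

    # disjoint token pools per planting class
    pool_exact = _word_pool(rng, 2 * n_exact)
    pool_cos = _word_pool(rng, 5 * max(n_cos, 1))
    pool_cdecoy = _word_pool(rng, 2 * n_concepts)
    pool_tdecoy = _word_pool(rng, 2 * n_terms)
    pool_anc = _word_pool(rng, 2 * max(n_anc, 1))
    used = set(pool_exact) | set(pool_cos) | set(pool_cdecoy) | set(pool_anc)
    pool_tdecoy = [w for w in pool_tdecoy if w not in used][: 2 * n_terms]
    while len(pool_tdecoy) < 2 * n_terms:
        w = _word(rng)
        if w not in used:
            pool_tdecoy.append(w)
            used.add(w)

    concepts: list[dict] = []
    terms: list[dict] = []
    conso_rows: list[str] = []
    sty_rows: list[str] = []
    planted_exact, planted_xref, planted_cos = [], [], []
    planted_anc = []

    def new_concept(i, label, code, domain="condition", synonyms=(),
                    ancestors=(), sty="Disease or Syndrome"):
        cid = 1000 + i
        concepts.append(dict(concept_id=cid, vocabulary=code.split(":")[0],
                             code=code, label=label, domain=domain,
                             synonyms=list(synonyms), ancestors=list(ancestors)))
        if sty:
            cui = f"C{900000 + i}"
            conso_rows.append(f"{cui}|{code.split(':')[0]}|{code.split(':')[1]}|{label}")
            sty_rows.append(f"{cui}|{sty}")
        return cid

    def new_term(j, label, curie=None, synonyms=(), xrefs=(), ancestors=()):
        curie = curie or f"mondo:{7000000 + j:07d}"
        terms.append(dict(curie=curie, label=label, synonyms=list(synonyms),
                          xrefs=list(xrefs), ancestors=list(ancestors)))
        return curie

    i = j = 0
    # planted exact-string collisions (label↔label / label↔synonym alternating)
    for k in range(n_exact):
        phrase = f"{pool_exact[2 * k]} {pool_exact[2 * k + 1]}"
        cid = new_concept(i, phrase.capitalize(), f"snomedct:{100000 + i}")
        if k % 2 == 0:
            curie = new_term(j, phrase.capitalize())
        else:
            curie = new_term(j, f"{pool_tdecoy[j]} finding", synonyms=[phrase])
        planted_exact.append([cid, curie, "label" if k % 2 == 0 else "synonym"])
        i += 1
        j += 1
    # planted code→CUI→code→xref chains
    for k in range(n_xref):
        label = f"{pool_cdecoy[i]} disorder"
        code = f"snomedct:{100000 + i}"
        cid = new_concept(i, label, code, sty="Disease or Syndrome")
        cui = f"C{900000 + i}"
        bridge = f"icd10cm:Z{500 + k}.{k % 10}"
        conso_rows.append(f"{cui}|icd10cm|Z{500 + k}.{k % 10}|{label}")
        curie = new_term(j, f"{pool_tdecoy[j]} disease",
                         xrefs=[f"ICD-10-CM:Z{500 + k}.{k % 10}"])
        planted_xref.append([cid, curie, bridge])
        i += 1
        j += 1
    # planted near-duplicate (cosine) pairs: share 3 of 4 tokens
    for k in range(n_cos):
        toks = pool_cos[4 * k: 4 * k + 4]
        extra = pool_cos[4 * n_cos + k] if 4 * n_cos + k < len(pool_cos) \
            else _word(rng)
        c_label = " ".join(toks)
        t_label = " ".join(toks[:3] + [extra])
        cid = new_concept(i, c_label, f"snomedct:{100000 + i}")
        curie = new_term(j, t_label)
        planted_cos.append([cid, curie, 0.5])  # similarity band floor
        i += 1
        j += 1
    # planted ancestor-fallback concepts: no own match, ancestor label matches
    for k in range(n_anc):
        anc_phrase = f"{pool_anc[2 * k]} {pool_anc[2 * k + 1]}"
        curie = new_term(j, anc_phrase)
        anc = (5000 + k, f"snomedct:{300000 + k}", anc_phrase)
        cid = new_concept(i, f"{pool_cdecoy[i]} specific variant",
                          f"snomedct:{100000 + i}", ancestors=[anc])
        planted_anc.append([cid, curie])
        i += 1
        j += 1
    # decoy concepts (some drugs/measurements, one excluded semantic type)
    while i < n_concepts:
        k = i
        domain = ("condition", "drug", "measurement")[k % 3]
        sty = {"condition": "Disease or Syndrome", "drug": "Pharmacologic Substance",
               "measurement": "Laboratory Procedure"}[domain]
        if k == n_concepts - 1:
            domain, sty = "condition", "Injury or Poisoning"
        code = {"condition": f"snomedct:{100000 + i}",
                "drug": f"rxnorm:{200000 + i}",
                "measurement": f"loinc:{3000 + i}-1"}[domain]
        new_concept(i, f"{pool_cdecoy[i]} {pool_cdecoy[n_concepts + i]}",
                    code, domain=domain, sty=sty)
        i += 1
    while j < n_terms:
        prefix = ("mondo", "hp", "chebi")[j % 3]
        new_term(j, f"{pool_tdecoy[j]} {pool_tdecoy[n_terms + j]}",
                 curie=f"{prefix}:{7000000 + j:07d}")
        j += 1

    # usage: the last n_unused concepts lack usage rows entirely
    usage_rows = []
    for k, c in enumerate(concepts[: n_concepts - n_unused]):
        usage_rows.append(f"{c['concept_id']}\t{int(rng.integers(1, 5000))}")

    files = []
    files.append(_write(out_dir / "concepts.tsv",
                        "concept_id\tvocabulary\tcode\tlabel\tdomain\tsource_codes",
                        [f"{c['concept_id']}\t{c['vocabulary']}\t{c['code']}\t"
                         f"{c['label']}\t{c['domain']}\t" for c in concepts]))
    files.append(_write(out_dir / "concept_synonyms.tsv", "concept_id\tsynonym",
                        [f"{c['concept_id']}\t{s}" for c in concepts
                         for s in c["synonyms"]]))
    files.append(_write(out_dir / "concept_ancestors.tsv",
                        "concept_id\tancestor_id\tancestor_code\tancestor_label",
                        [f"{c['concept_id']}\t{a[0]}\t{a[1]}\t{a[2]}"
                         for c in concepts for a in c["ancestors"]]))
    files.append(_write(out_dir / "concept_usage.tsv", "concept_id\tusage_count",
                        usage_rows))
    files.append(_write(out_dir / "ontology" / "terms.tsv",
                        "curie\tlabel\tdefinition",
                        [f"{t['curie']}\t{t['label']}\t" for t in terms]))
    files.append(_write(out_dir / "ontology" / "synonyms.tsv",
                        "curie\tsynonym\ttype",
                        [f"{t['curie']}\t{s}\texact" for t in terms
                         for s in t["synonyms"]]))
    files.append(_write(out_dir / "ontology" / "xrefs.tsv", "curie\txref",
                        [f"{t['curie']}\t{x}" for t in terms
                         for x in t["xrefs"]]))
    files.append(_write(out_dir / "ontology" / "ancestors.tsv",
                        "curie\tancestor_curie", []))
    # RRF-style pipe files are headerless
    (out_dir / "umls_conso.psv").write_text(
        "".join(r + "\n" for r in conso_rows), encoding="utf-8")
    files.append(str(out_dir / "umls_conso.psv"))
    (out_dir / "umls_sty.psv").write_text(
        "".join(r + "\n" for r in sty_rows), encoding="utf-8")
    files.append(str(out_dir / "umls_sty.psv"))

    manifest = FixtureManifest(
        seed=seed, kind="mapping",
        planted={
            "n_concepts": n_concepts, "n_terms": n_terms,
            "n_unused": n_unused,
            "exact_pairs": planted_exact, "xref_chains": planted_xref,
            "cosine_pairs": planted_cos, "ancestor_pairs": planted_anc,
        },
        files=sorted(str(Path(f).relative_to(out_dir)) for f in files))
    manifest.write(out_dir / "manifest.json")
    return manifest


def load_mapping_fixture(out_dir):
    """Reload the emitted fixture through the package's own loaders.

    Returns (ConceptSet, OntologyIndex, UmlsTables, manifest dict).
    """
    from .clinical import load_concepts
    from .ontology import load_ontology

    out_dir = Path(out_dir)
    concepts = load_concepts(out_dir / "concepts.tsv",
                             out_dir / "concept_synonyms.tsv",
                             out_dir / "concept_ancestors.tsv",
                             out_dir / "concept_usage.tsv")
    index = load_ontology(out_dir / "ontology", format="tsv")
    umls = UmlsTables.from_rrf(out_dir / "umls_conso.psv",
                               out_dir / "umls_sty.psv",
                               conso_cols=(0, 1, 2, 3), sty_cols=(0, 1))
    manifest = json.loads((out_dir / "manifest.json").read_text(encoding="utf-8"))
    return concepts, index, umls, manifest


# ---------------------------------------------------------------------------
# prevalence fixture


def make_prevalence_fixture(out_dir, seed: int = 7, n_sites: int = 4,
                            overlap_fraction: float = 0.8,
                            weight_skew: float = 0.95,
                            n_prevalence: int = 100,
                            n_mapper_only: int = 10,
                            floor: int = 100) -> FixtureManifest:
    """Emit per-site prevalence records with exactly planted coverage.

    Raw coverage equals ``overlap_fraction`` (as a percentage) and weighted
    coverage equals ``weight_skew`` by assigning uniform per-site counts
    whose mass ratio solves the skew exactly (rational arithmetic).  When
    the prevalence-only per-site count lands exactly on the floor, a few of
    those records are written with sub-floor raw counts so flooring is
    exercised without moving the planted totals.
    """
    if not (0.0 <= overlap_fraction <= 1.0):
        raise FixtureError("overlap_fraction outside [0, 1]")
    n_overlap = round(overlap_fraction * n_prevalence)
    n_only = n_prevalence - n_overlap
    rng = _rng(seed, "prevalence")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    overlap_ids = [20000 + k for k in range(n_overlap)]
    only_ids = [30000 + k for k in range(n_only)]
    mapper_ids = overlap_ids + [40000 + k for k in range(n_mapper_only)]

    # per-site per-concept counts a (overlap) and b (prevalence-only) with
    # n_overlap*a : n_only*b == skew : 1-skew, all counts >= floor
    if n_overlap and n_only:
        skew = Fraction(str(weight_skew))
        ratio = (skew * n_only) / ((1 - skew) * n_overlap)  # a/b
        a_unit, b_unit = ratio.numerator, ratio.denominator
        k = ceil(Fraction(floor, min(a_unit, b_unit)))
        a, b = a_unit * k, b_unit * k
    else:
        a = b = max(floor, 500)

    records: list[tuple[str, int, int]] = []
    sub_floor_records = 0
    for s in range(n_sites):
        site = f"site_{s:02d}"
        for cid in overlap_ids:
            records.append((site, cid, a))
        for idx, cid in enumerate(only_ids):
            raw = b
            if b == floor and s == 0 and idx < min(5, n_only):
                raw = int(rng.integers(1, floor))  # floors back to b exactly
                sub_floor_records += 1
            records.append((site, cid, raw))

    expected_weighted = (100.0 * n_overlap * a / (n_overlap * a + n_only * b)
                         if (n_overlap or n_only) and n_overlap else 0.0)
    files = [
        _write(out_dir / "prevalence.tsv", "site_id\tconcept_id\tcount",
               [f"{s}\t{c}\t{n}" for s, c, n in records]),
        _write(out_dir / "mapper_concepts.txt", "concept_id",
               [str(c) for c in mapper_ids]),
    ]
    manifest = FixtureManifest(
        seed=seed, kind="prevalence",
        planted={
            "n_sites": n_sites, "floor": floor,
            "raw_coverage": 100.0 * n_overlap / n_prevalence if n_prevalence else 0.0,
            "weighted_coverage": expected_weighted,
            "overlap_ids": overlap_ids, "prevalence_only_ids": only_ids,
            "mapper_only_ids": mapper_ids[n_overlap:],
            "sub_floor_records": sub_floor_records,
        },
        files=sorted(str(Path(f).relative_to(out_dir)) for f in files))
    manifest.write(out_dir / "manifest.json")
    return manifest


# ---------------------------------------------------------------------------
# cohort fixture


_DEFAULT_PHENOTYPE_PREVALENCE = [0.001, 0.002, 0.004, 0.005, 0.008, 0.01,
                                 0.02, 0.03, 0.04, 0.05, 0.08, 0.1]


def default_profile() -> tuple[DiseaseProfile, dict[str, float]]:
    """A synthetic single-disease profile with fixed phenotype prevalences."""
    phenotypes = [f"hp:{9000000 + k:07d}"
                  for k in range(len(_DEFAULT_PHENOTYPE_PREVALENCE))]
    profile = DiseaseProfile("synthetic_disease", ("GENE1", "GENE2"),
                             frozenset(phenotypes))
    prevalence = dict(zip(phenotypes, _DEFAULT_PHENOTYPE_PREVALENCE))
    return profile, prevalence


def make_cohort_fixture(seed: int = 7, n_cases: int = 200,
                        n_controls: int = 2000, p_case: float = 0.3,
                        p_control: float = 0.05,
                        profile: DiseaseProfile | None = None,
                        prevalence: dict[str, float] | None = None
                        ) -> tuple[Cohort, DiseaseProfile, dict[str, float],
                                   FixtureManifest]:
    """Build a synthetic patient cohort with planted phenotype enrichment.

    Case patients carry each profile phenotype independently with
    probability ``p_case`` and at least two disease diagnosis codes;
    controls use ``p_control`` and zero codes, so the planted labels are
    recovered exactly by case/control definition.  Ages (0–21 years,
    pediatric), sex and record lengths are drawn from simple uniform
    distributions recorded in the manifest.
    """
    for p in (p_case, p_control):
        if not (0.0 <= p <= 1.0):
            raise FixtureError(f"probability {p} outside [0, 1]")
    if profile is None or prevalence is None:
        profile, prevalence = default_profile()
    rng = _rng(seed, "cohort")
    phenotypes = sorted(profile.phenotypes)
    patients: list[Patient] = []
    for group, n, p_hit, dx in (("case", n_cases, p_case, 2),
                                ("control", n_controls, p_control, 0)):
        hits = rng.random((n, len(phenotypes))) < p_hit
        ages = rng.uniform(0.0, 21.0, n)
        sexes = rng.integers(0, 2, n)
        lengths = rng.uniform(30.0, 7300.0, n)
        for k in range(n):
            counts = {ph: int(1 + rng.integers(0, 3))
                      for ph, hit in zip(phenotypes, hits[k]) if hit}
            patients.append(Patient(
                patient_id=f"{group}_{k:05d}", age=float(ages[k]),
                sex="F" if sexes[k] == 0 else "M",
                record_length_days=float(lengths[k]),
                phenotype_counts=counts,
                diagnosis_counts={profile.disease: dx} if dx else {}))
    manifest = FixtureManifest(
        seed=seed, kind="cohort",
        planted={"n_cases": n_cases, "n_controls": n_controls,
                 "p_case": p_case, "p_control": p_control,
                 "age_distribution": "uniform(0, 21) years",
                 "record_length_distribution": "uniform(30, 7300) days",
                 "phenotype_prevalence": prevalence})
    return Cohort(patients), profile, prevalence, manifest


def simulate_group_scores(rng: np.random.Generator, n_case: int,
                          n_control: int, p_case: float, p_control: float,
                          weights: np.ndarray
                          ) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized raw risk scores for one simulation replicate.

    Each patient draws independent Bernoulli presence per profile
    phenotype; the score is the weight sum over present phenotypes — the
    same quantity :func:`termbridge.phers.phers_score` computes patient by
    patient, generated in bulk for simulation studies.
    """
    case = (rng.random((n_case, weights.size)) < p_case) @ weights
    control = (rng.random((n_control, weights.size)) < p_control) @ weights
    return case, control
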