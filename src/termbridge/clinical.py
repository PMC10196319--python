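"""Clinical concept tables, CUI annotation and ontology routing.

Input is a set of exported delimited tables describing standard clinical
vocabulary concepts (conditions from SNOMED-CT-like vocabularies, drug
ingredients from RxNorm-like vocabularies, measurements from LOINC-like
vocabularies): one row per concept plus companion synonym, ancestor and
usage tables.  Concepts are partitioned into two waves by whether they were
used at least once in clinical practice; optional UMLS-style MRCONSO/MRSTY
tables provide concept-unique-identifier (CUI) bridges and semantic types,
which drive routing of condition concepts to a disease ontology (mondo), a
phenotype ontology (hp), both, or exclusion.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd
import yaml

from .identifiers import NormalizationTable, normalize_identifier

logger = logging.getLogger(__name__)

__all__ = [
    "ClinicalConcept", "ConceptSet", "ConceptLoadError", "CuiAnnotation",
    "UmlsTables", "RoutingPolicy", "RoutingError",
    "load_concepts", "assign_waves", "annotate_cui", "route_targets",
]

DOMAINS = ("condition", "drug", "measurement")


class ConceptLoadError(ValueError):
    pass


class RoutingError(ValueError):
    pass


@dataclass
class ClinicalConcept:
    concept_id: int
    vocabulary: str
    code: str                       # canonical CURIE
    label: str
    domain: str                     # condition | drug | measurement
    synonyms: list[str] = field(default_factory=list)
    source_codes: list[str] = field(default_factory=list)
    ancestors: list[tuple[int, str, str]] = field(default_factory=list)  # (id, code, label)
    usage_count: int = 0

    @property
    def wave(self) -> str:
        """"used" iff the concept occurred at least once in practice."""
        return "used" if self.usage_count >= 1 else "unused"

    def strings(self) -> list[str]:
        return [self.label] + list(self.synonyms)

    def codes(self) -> list[str]:
        return [self.code] + list(self.source_codes)


@dataclass
class ConceptSet:
    concepts: dict[int, ClinicalConcept] = field(default_factory=dict)

    def __iter__(self):
        return iter(self.concepts.values())

    def __len__(self) -> int:
        return len(self.concepts)

    def __getitem__(self, concept_id: int) -> ClinicalConcept:
        return self.concepts[concept_id]


@dataclass
class CuiAnnotation:
    concept_id: int
    cuis: set[str] = field(default_factory=set)
    semantic_types: set[str] = field(default_factory=set)


@dataclass
class UmlsTables:
    """MRCONSO-like (cui, sab, code, string) and MRSTY-like (cui, semantic_type)
    tables with sab/code values already normalized."""

    conso: pd.DataFrame
    sty: pd.DataFrame

    @classmethod
    def empty(cls) -> "UmlsTables":
        return cls(conso=pd.DataFrame(columns=["cui", "sab", "code", "string"]),
                   sty=pd.DataFrame(columns=["cui", "semantic_type"]))

    @classmethod
    def from_rrf(cls, conso_path, sty_path,
                 table: NormalizationTable | None = None,
                 conso_cols: tuple[int, int, int, int] = (0, 11, 13, 14),
                 sty_cols: tuple[int, int] = (0, 3)) -> "UmlsTables":
        """Read pipe-delimited RRF-style files.

        Column positions default to the standard MRCONSO (CUI, SAB, CODE,
        STR) and MRSTY (CUI, STY) layouts and are configurable for trimmed
        exports.
        """
        if table is None:
            table = NormalizationTable.default()
        conso_raw = pd.read_csv(conso_path, sep="|", header=None, dtype=str,
                                keep_default_na=False, engine="python")
        ci = list(conso_cols)
        # compact 4-column exports (cui, sab, code, string)
        if max(ci) >= conso_raw.shape[1] and conso_raw.shape[1] == 4:
            ci = [0, 1, 2, 3]
        conso = pd.DataFrame({
            "cui": conso_raw.iloc[:, ci[0]],
            "sab": [table.canonical_prefix(s) for s in conso_raw.iloc[:, ci[1]]],
            "code": conso_raw.iloc[:, ci[2]].astype(str),
            "string": conso_raw.iloc[:, ci[3]],
        })
        sty_raw = pd.read_csv(sty_path, sep="|", header=None, dtype=str,
                              keep_default_na=False, engine="python")
        si = list(sty_cols)
        if max(si) >= sty_raw.shape[1] and sty_raw.shape[1] == 2:
            si = [0, 1]
        sty = pd.DataFrame({"cui": sty_raw.iloc[:, si[0]],
                            "semantic_type": sty_raw.iloc[:, si[1]]})
        return cls(conso=conso, sty=sty)

    def curies(self) -> pd.Series:
        """conso rows rendered as canonical CURIEs (sab:code)."""
        if self.conso.empty:
            return pd.Series([], dtype=str)
        return self.conso["sab"].str.cat(self.conso["code"], sep=":")


def load_concepts(concepts, synonyms=None, ancestors=None, usage=None,
                  table: NormalizationTable | None = None) -> ConceptSet:
    """Load a :class:`ConceptSet` from delimited tables.

    ``concepts`` requires columns (concept_id, vocabulary, code, label,
    domain); an optional ``source_codes`` column holds comma-separated
    non-standard codes.  Synonym/ancestor rows referencing unknown
    concept_ids are a load error; concepts absent from ``usage`` default to
    a count of 0 (the "unused" wave).
    """
    if table is None:
        table = NormalizationTable.default()
    cdf = pd.read_csv(concepts, sep="\t", dtype=str, keep_default_na=False)
    required = {"concept_id", "vocabulary", "code", "label", "domain"}
    if missing := required - set(cdf.columns):
        raise ConceptLoadError(f"concept table missing columns {sorted(missing)}")
    out: dict[int, ClinicalConcept] = {}
    for row in cdf.itertuples(index=False):
        cid = int(row.concept_id)
        if cid in out:
            raise ConceptLoadError(f"duplicate concept_id {cid}")
        if row.domain not in DOMAINS:
            raise ConceptLoadError(f"concept {cid} has unknown domain {row.domain!r}")
        source_codes = []
        raw_sources = getattr(row, "source_codes", "")
        if raw_sources:
            source_codes = [normalize_identifier(c, table)
                            for c in str(raw_sources).split(",") if c.strip()]
        out[cid] = ClinicalConcept(
            concept_id=cid, vocabulary=row.vocabulary.lower(),
            code=normalize_identifier(row.code, table),
            label=row.label, domain=row.domain, source_codes=source_codes)

    def _rows(path, cols):
        if path is None:
            return []
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
        if missing := set(cols) - set(df.columns):
            raise ConceptLoadError(f"{path} missing columns {sorted(missing)}")
        return list(df.itertuples(index=False))

    dangling = []
    for row in _rows(synonyms, ["concept_id", "synonym"]):
        cid = int(row.concept_id)
        if cid not in out:
            dangling.append(("synonym", cid))
        else:
            out[cid].synonyms.append(row.synonym)
    for row in _rows(ancestors, ["concept_id", "ancestor_id", "ancestor_code",
                                 "ancestor_label"]):
        cid = int(row.concept_id)
        if cid not in out:
            dangling.append(("ancestor", cid))
        else:
            out[cid].ancestors.append((int(row.ancestor_id),
                                       normalize_identifier(row.ancestor_code, table),
                                       row.ancestor_label))
    if dangling:
        raise ConceptLoadError(f"rows reference unknown concept_ids: {dangling}")
    for row in _rows(usage, ["concept_id", "usage_count"]):
        cid = int(row.concept_id)
        if cid in out:
            out[cid].usage_count = int(row.usage_count)
    return ConceptSet(concepts=out)


def assign_waves(concepts: ConceptSet) -> dict[str, set[int]]:
    """Exhaustive, disjoint partition of concept_ids into usage waves."""
    waves = {"used": set(), "unused": set()}
    for c in concepts:
        waves[c.wave].add(c.concept_id)
    return waves


def annotate_cui(concepts: ConceptSet, umls: UmlsTables) -> dict[int, CuiAnnotation]:
    """Annotate each concept with the CUIs bridging any of its codes.

    A concept's CUIs are all CUIs whose (sab, code) row matches the
    concept's standard code or any of its source codes; semantic types are
    the union over matched CUIs.  No match yields an empty annotation.
    """
    code_to_cuis: dict[str, set[str]] = {}
    if not umls.conso.empty:
        for curie, cui in zip(umls.curies(), umls.conso["cui"]):
            code_to_cuis.setdefault(curie, set()).add(cui)
    cui_to_types: dict[str, set[str]] = {}
    if not umls.sty.empty:
        for cui, stype in zip(umls.sty["cui"], umls.sty["semantic_type"]):
            cui_to_types.setdefault(cui, set()).add(stype)
    annotations: dict[int, CuiAnnotation] = {}
    for c in concepts:
        cuis: set[str] = set()
        for code in c.codes():
            cuis |= code_to_cuis.get(code, set())
        types: set[str] = set()
        for cui in cuis:
            types |= cui_to_types.get(cui, set())
        annotations[c.concept_id] = CuiAnnotation(c.concept_id, cuis, types)
    return annotations


@dataclass(frozen=True)
class RoutingPolicy:
    """Semantic-type routing policy (editable; the default is a packaged
    YAML file, not a claim of fidelity to any specific partition)."""

    phenotype_types: frozenset[str]
    disease_types: frozenset[str]
    excluded_types: frozenset[str]
    drug_targets: frozenset[str]
    measurement_targets: frozenset[str]

    @classmethod
    def from_yaml(cls, path) -> "RoutingPolicy":
        text = path.read_text(encoding="utf-8") if hasattr(path, "read_text") \
            else Path(path).read_text(encoding="utf-8")
        doc = yaml.safe_load(text)
        return cls(phenotype_types=frozenset(doc["phenotype_types"]),
                   disease_types=frozenset(doc["disease_types"]),
                   excluded_types=frozenset(doc["excluded_types"]),
                   drug_targets=frozenset(doc["drug_targets"]),
                   measurement_targets=frozenset(doc["measurement_targets"]))

    @classmethod
    def default(cls) -> "RoutingPolicy":
        return cls.from_yaml(resources.files("termbridge.data").joinpath("routing.yaml"))


def route_targets(concept: ClinicalConcept, ann: CuiAnnotation | None,
                  policy: RoutingPolicy | None = None
                  ) -> tuple[frozenset[str], str | None]:
    """Route a concept to its target ontologies.

    Drugs and measurements have fixed target sets.  Conditions route by
    semantic type: phenotype-like types to hp, disease-like types to mondo
    (both when both kinds are present); types on the exclusion list — or
    annotated types matching no routing list — yield an empty target set
    with a recorded exclusion reason.  Conditions without any semantic-type
    annotation route to both hp and mondo, since there is no evidence on
    which to exclude or discriminate.
    """
    if policy is None:
        policy = RoutingPolicy.default()
    if concept.domain == "drug":
        return policy.drug_targets, None
    if concept.domain == "measurement":
        return policy.measurement_targets, None
    if concept.domain != "condition":
        raise RoutingError(f"unknown domain {concept.domain!r}")
    types = ann.semantic_types if ann is not None else set()
    if not types:
        return frozenset({"hp", "mondo"}), None
    excluded = sorted(types & policy.excluded_types)
    targets = set()
    if types & policy.phenotype_types:
        targets.add("hp")
    if types & policy.disease_types:
        targets.add("mondo")
    if excluded and not targets:
        return frozenset(), ("excluded semantic type(s): " + "; ".join(excluded))
    if not targets:
        return frozenset(), ("semantic type(s) outside the pathological/biological "
                             "allow-list: " + "; ".join(sorted(types)))
    return frozenset(targets), None
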