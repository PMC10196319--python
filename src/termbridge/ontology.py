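"""Ontology metadata ingestion and lookup indexes.

The aligner never reasons over ontology axioms; it consumes pre-extracted
per-term metadata — label, definition, typed synonyms, database
cross-references (xrefs) and the transitive ancestor closure.  Two input
dialects are supported:

* an OBO-Graphs-style JSON document (``nodes``/``edges``, ``is_a`` edges),
  from which the ancestor closure is computed by graph traversal; and
* a plain TSV dialect (``terms.tsv``, ``synonyms.tsv``, ``xrefs.tsv``,
  ``ancestors.tsv`` and optionally ``deprecated.tsv``) where the closure is
  taken as given.

Deprecated terms are dropped at load time so they can never enter an
alignment candidate pool.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import pandas as pd

from .identifiers import IdentifierError, NormalizationTable, normalize_identifier

logger = logging.getLogger(__name__)

__all__ = ["OntologyTerm", "OntologyIndex", "OntologyLoadError",
           "load_ontology", "save_ontology_tsv", "ancestor_closure"]


class OntologyLoadError(ValueError):
    pass


@dataclass
class OntologyTerm:
    curie: str
    label: str
    definition: str | None = None
    synonyms: list[tuple[str, str]] = field(default_factory=list)  # (text, type)
    xrefs: list[str] = field(default_factory=list)  # canonical CURIEs
    ancestors: set[str] = field(default_factory=set)
    deprecated: bool = False
    ontology_id: str = ""

    def __post_init__(self) -> None:
        self.ancestors.discard(self.curie)
        if not self.ontology_id:
            self.ontology_id = self.curie.split(":", 1)[0]

    def strings(self) -> list[str]:
        """Label plus synonym texts, the aligner's text fields for this term."""
        return [self.label] + [s for s, _ in self.synonyms]


@dataclass
class OntologyIndex:
    """Lookup maps over a set of :class:`OntologyTerm`.

    All string keys are lowercase; all xref keys are canonical CURIEs.  The
    maps are rebuilt deterministically from ``terms`` and never contain
    deprecated terms.
    """

    terms: dict[str, OntologyTerm] = field(default_factory=dict)
    by_label: dict[str, set[str]] = field(default_factory=dict)
    by_synonym: dict[str, set[str]] = field(default_factory=dict)
    by_definition: dict[str, set[str]] = field(default_factory=dict)
    by_xref: dict[str, set[str]] = field(default_factory=dict)

    @classmethod
    def build(cls, terms) -> "OntologyIndex":
        idx = cls()
        for term in terms:
            if term.curie in idx.terms:
                raise OntologyLoadError(f"duplicate curie {term.curie}")
            if term.deprecated:
                continue
            idx.terms[term.curie] = term
        idx.rebuild()
        return idx

    def rebuild(self) -> None:
        self.by_label, self.by_synonym = {}, {}
        self.by_definition, self.by_xref = {}, {}
        for curie, term in self.terms.items():
            self.by_label.setdefault(term.label.lower(), set()).add(curie)
            for syn, _type in term.synonyms:
                self.by_synonym.setdefault(syn.lower(), set()).add(curie)
            if term.definition:
                self.by_definition.setdefault(term.definition.lower(), set()).add(curie)
            for xref in term.xrefs:
                self.by_xref.setdefault(xref, set()).add(curie)

    def __len__(self) -> int:
        return len(self.terms)


def ancestor_closure(curie: str, index: OntologyIndex) -> set[str]:
    """The stored transitive ancestor set of ``curie`` (empty for roots)."""
    if curie not in index.terms:
        raise KeyError(f"unknown curie {curie}")
    return set(index.terms[curie].ancestors)


# ---------------------------------------------------------------------------
# loading


def _curie_from_graph_id(node_id: str, table: NormalizationTable) -> str:
    # OBO-Graphs ids are IRIs like .../obo/HP_0004398 or already CURIEs
    tail = node_id.rstrip("/").rsplit("/", 1)[-1].rsplit("#", 1)[-1]
    return normalize_identifier(tail, table)


def _load_graph_json(path: Path, table: NormalizationTable) -> list[OntologyTerm]:
    doc = json.loads(path.read_text(encoding="utf-8"))
    graphs = doc.get("graphs", [doc])
    terms: dict[str, OntologyTerm] = {}
    is_a = nx.DiGraph()
    for graph in graphs:
        for node in graph.get("nodes", []):
            if node.get("type") not in (None, "CLASS"):
                continue
            try:
                curie = _curie_from_graph_id(node["id"], table)
            except IdentifierError:
                continue
            meta = node.get("meta", {}) or {}
            if "lbl" not in node or node["lbl"] is None:
                logger.warning("term %s has no label; skipped", curie)
                continue
            xrefs = []
            for xref in meta.get("xrefs", []):
                try:
                    xrefs.append(normalize_identifier(xref["val"], table))
                except IdentifierError:
                    logger.warning("unparsable xref %r on %s", xref.get("val"), curie)
            term = OntologyTerm(
                curie=curie,
                label=node["lbl"],
                definition=(meta.get("definition") or {}).get("val"),
                synonyms=[(s["val"], s.get("pred", "hasExactSynonym"))
                          for s in meta.get("synonyms", [])],
                xrefs=xrefs,
                deprecated=bool(meta.get("deprecated", False)),
            )
            if curie in terms:
                raise OntologyLoadError(f"duplicate curie {curie}")
            terms[curie] = term
        for edge in graph.get("edges", []):
            if edge.get("pred") in ("is_a", "subClassOf", "rdfs:subClassOf"):
                try:
                    sub = _curie_from_graph_id(edge["sub"], table)
                    obj = _curie_from_graph_id(edge["obj"], table)
                except IdentifierError:
                    continue
                is_a.add_edge(sub, obj)
    # closure from is_a edges only (no OWL reasoning)
    for curie, term in terms.items():
        if curie in is_a:
            term.ancestors = set(nx.descendants(is_a, curie))
            term.ancestors.discard(curie)
    return list(terms.values())


def _read_tsv(path: Path, required: list[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise OntologyLoadError(f"{path} missing columns {missing}")
    return df


def _load_tsv_dir(path: Path, table: NormalizationTable) -> list[OntologyTerm]:
    terms_df = _read_tsv(path / "terms.tsv", ["curie", "label"])
    deprecated: set[str] = set()
    dep_path = path / "deprecated.tsv"
    if dep_path.exists():
        deprecated = {normalize_identifier(c, table)
                      for c in _read_tsv(dep_path, ["curie"])["curie"]}
    terms: dict[str, OntologyTerm] = {}
    for row in terms_df.itertuples(index=False):
        curie = normalize_identifier(row.curie, table)
        if curie in terms:
            raise OntologyLoadError(f"duplicate curie {curie}")
        if not row.label:
            logger.warning("term %s has no label; skipped", curie)
            continue
        definition = getattr(row, "definition", "") or None
        terms[curie] = OntologyTerm(curie=curie, label=row.label,
                                    definition=definition,
                                    deprecated=curie in deprecated)
    syn_path = path / "synonyms.tsv"
    if syn_path.exists():
        for row in _read_tsv(syn_path, ["curie", "synonym"]).itertuples(index=False):
            curie = normalize_identifier(row.curie, table)
            if curie in terms:
                terms[curie].synonyms.append(
                    (row.synonym, getattr(row, "type", "") or "exact"))
    xref_path = path / "xrefs.tsv"
    if xref_path.exists():
        for row in _read_tsv(xref_path, ["curie", "xref"]).itertuples(index=False):
            curie = normalize_identifier(row.curie, table)
            if curie in terms:
                terms[curie].xrefs.append(normalize_identifier(row.xref, table))
    anc_path = path / "ancestors.tsv"
    if anc_path.exists():
        for row in _read_tsv(anc_path, ["curie", "ancestor_curie"]).itertuples(index=False):
            curie = normalize_identifier(row.curie, table)
            if curie in terms:
                terms[curie].ancestors.add(normalize_identifier(row.ancestor_curie, table))
    for term in terms.values():
        term.ancestors.discard(term.curie)
    return list(terms.values())


def load_ontology(path, format: str = "tsv",
                  table: NormalizationTable | None = None) -> OntologyIndex:
    """Load an :class:`OntologyIndex` from ``path``.

    ``format`` is ``"graph-json"`` (a single JSON file) or ``"tsv"`` (a
    directory holding the TSV dialect files).  All xrefs are normalized with
    ``table``; non-deprecated terms only.
    """
    if table is None:
        table = NormalizationTable.default()
    path = Path(path)
    if format == "graph-json":
        terms = _load_graph_json(path, table)
    elif format == "tsv":
        terms = _load_tsv_dir(path, table)
    else:
        raise OntologyLoadError(f"unknown ontology format {format!r}")
    return OntologyIndex.build(terms)


def save_ontology_tsv(index: OntologyIndex, path) -> None:
    """Serialize ``index`` to the TSV dialect (deterministic row order)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    terms = sorted(index.terms.values(), key=lambda t: t.curie)
    with open(path / "terms.tsv", "w", encoding="utf-8", newline="\n") as fh:
        fh.write("curie\tlabel\tdefinition\n")
        for t in terms:
            fh.write(f"{t.curie}\t{t.label}\t{t.definition or ''}\n")
    with open(path / "synonyms.tsv", "w", encoding="utf-8", newline="\n") as fh:
        fh.write("curie\tsynonym\ttype\n")
        for t in terms:
            for syn, stype in sorted(t.synonyms):
                fh.write(f"{t.curie}\t{syn}\t{stype}\n")
    with open(path / "xrefs.tsv", "w", encoding="utf-8", newline="\n") as fh:
        fh.write("curie\txref\n")
        for t in terms:
            for xref in sorted(t.xrefs):
                fh.write(f"{t.curie}\t{xref}\n")
    with open(path / "ancestors.tsv", "w", encoding="utf-8", newline="\n") as fh:
        fh.write("curie\tancestor_curie\n")
        for t in terms:
            for anc in sorted(t.ancestors):
                fh.write(f"{t.curie}\t{anc}\n")
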