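"""Shared fixtures: synthetic inputs generated once per session, plus the
independent brute-force TF-IDF oracle used to cross-check the embedding."""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest

from termbridge.coverage import PrevalenceRecord
from termbridge.fixtures import load_mapping_fixture, make_mapping_fixture, \
    make_prevalence_fixture
from termbridge.text import Preprocessor

FIXTURE_SEED = 7


@pytest.fixture(scope="session")
def mapping_fixture_dir(tmp_path_factory):
    path = tmp_path_factory.mktemp("mapping_fixture")
    make_mapping_fixture(path, seed=FIXTURE_SEED)
    return path


@pytest.fixture(scope="session")
def loaded_mapping(mapping_fixture_dir):
    """(ConceptSet, OntologyIndex, UmlsTables, manifest dict)."""
    return load_mapping_fixture(mapping_fixture_dir)


@pytest.fixture(scope="session")
def prevalence_fixture(tmp_path_factory):
    path = tmp_path_factory.mktemp("prevalence_fixture")
    manifest = make_prevalence_fixture(path, seed=FIXTURE_SEED)
    df = pd.read_csv(path / "prevalence.tsv", sep="\t")
    records = [PrevalenceRecord(str(r.site_id), int(r.concept_id), int(r.count))
               for r in df.itertuples(index=False)]
    mapper = {int(tok) for tok
              in (path / "mapper_concepts.txt").read_text().split()
              if tok.isdigit()}
    return records, mapper, manifest


def brute_force_tfidf_cosines(texts: list[str]) -> np.ndarray:
    """Independent pairwise-cosine oracle from the pinned TF-IDF definition:
    tf = raw in-string count, idf = ln((1+N)/(1+df)) + 1, L2-normalized."""
    pre = Preprocessor()
    docs = [pre(t) for t in texts]
    vocab = sorted({tok for d in docs for tok in d})
    n = len(docs)
    idf = {v: math.log((1 + n) / (1 + sum(v in d for d in docs))) + 1
           for v in vocab}
    rows = []
    for d in docs:
        vec = np.array([d.count(v) * idf[v] for v in vocab], dtype=float)
        norm = np.linalg.norm(vec)
        rows.append(vec / norm if norm > 0 else vec)
    mat = np.vstack(rows) if rows else np.zeros((0, 0))
    return mat @ mat.T


@pytest.fixture(scope="session")
def tfidf_oracle():
    return brute_force_tfidf_cosines
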