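"""Text preprocessing for the bag-of-words embedding.

Pipeline: lowercase, word-level tokenization, stop-word removal, English
lemmatization.  The stop-word list ships with the package and is
overridable; the lemmatizer is a small dictionary-plus-suffix-rule English
lemmatizer (irregular plurals first, then regular inflectional suffixes)
and can be replaced by any callable or disabled.  Keeping both pinned in
the package makes the embedding reproducible across environments.
"""

from __future__ import annotations

import re
from functools import lru_cache
from importlib import resources
from typing import Callable, Iterable

__all__ = ["default_stopwords", "lemmatize", "tokenize", "Preprocessor"]

_TOKEN = re.compile(r"[a-z0-9]+")

# irregular noun plurals and common clinical irregulars
_IRREGULAR = {
    "feet": "foot", "teeth": "tooth", "men": "man", "women": "woman",
    "children": "child", "mice": "mouse", "sera": "serum", "fungi": "fungus",
    "nuclei": "nucleus", "bacteria": "bacterium", "criteria": "criterion",
    "phenomena": "phenomenon", "analyses": "analysis", "diagnoses": "diagnosis",
    "prognoses": "prognosis", "stenoses": "stenosis", "neuroses": "neurosis",
    "metastases": "metastasis", "viscera": "viscus", "ganglia": "ganglion",
}

# words a naive 's' stripper would mangle
_KEEP_AS_IS = {
    "pancreas", "diabetes", "herpes", "rabies", "scabies", "measles",
    "species", "serum", "virus", "plus", "thrombus", "fetus", "uterus",
    "esophagus", "mucus", "pus", "lupus", "status", "bolus",
}


@lru_cache(maxsize=1)
def default_stopwords() -> frozenset[str]:
    text = resources.files("termbridge.data").joinpath("stopwords.txt").read_text("utf-8")
    return frozenset(w.strip() for w in text.splitlines() if w.strip())


def lemmatize(token: str) -> str:
    """Dictionary-first, then regular inflectional suffix stripping."""
    if token in _IRREGULAR:
        return _IRREGULAR[token]
    if token in _KEEP_AS_IS or len(token) <= 3:
        return token
    if token.endswith("ies") and len(token) > 4:
        return token[:-3] + "y"
    if token.endswith(("sses", "shes", "ches", "xes", "zes")):
        return token[:-2]
    if token.endswith("ss") or token.endswith("us") or token.endswith("is"):
        return token
    if token.endswith("s"):
        return token[:-1]
    return token


def tokenize(text: str) -> list[str]:
    return _TOKEN.findall(text.lower())


class Preprocessor:
    """Callable token analyzer: tokenize → drop stop words → lemmatize."""

    def __init__(self, stopwords: Iterable[str] | None = None,
                 lemmatizer: Callable[[str], str] | None = lemmatize):
        self.stopwords = frozenset(stopwords) if stopwords is not None \
            else default_stopwords()
        self.lemmatizer = lemmatizer or (lambda t: t)

    def __call__(self, text: str) -> list[str]:
        return [self.lemmatizer(t) for t in tokenize(text)
                if t not in self.stopwords]
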