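"""Identifier normalization.

Clinical vocabularies and ontology cross-references frequently refer to the
same code under different prefixes or separators (``SNOMED-CT:1234567``,
``sctid:1234567``, ``SNOMEDCT_US_1234567`` ...).  Joining across resources
therefore requires canonicalizing every identifier to a single CURIE form:
lowercase canonical prefix, unchanged local id, ``:`` separator.  The prefix
synonym table is a plain two-column TSV shipped with the package and
overridable by file.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

logger = logging.getLogger(__name__)

__all__ = ["IdentifierError", "NormalizationTable", "normalize_identifier"]


class IdentifierError(ValueError):
    """Raised for identifiers without a parsable prefix."""


# prefix then local id; separator is ':' (preferred) or the last '_'
_CURIE_COLON = re.compile(r"^\s*([A-Za-z][\w.\-]*?)\s*:\s*(\S+)\s*$")


@dataclass(frozen=True)
class NormalizationTable:
    """Prefix-synonym table mapping source prefixes to canonical prefixes.

    Unknown prefixes pass through lowercased (with a one-time warning) so
    that normalization is total and idempotent.
    """

    mapping: dict[str, str] = field(default_factory=dict)

    @classmethod
    def default(cls) -> "NormalizationTable":
        path = resources.files("termbridge.data").joinpath("normalization.tsv")
        return cls.from_file(path)

    @classmethod
    def from_file(cls, path) -> "NormalizationTable":
        mapping: dict[str, str] = {}
        text = Path(str(path)).read_text(encoding="utf-8") if not hasattr(path, "read_text") else path.read_text(encoding="utf-8")
        lines = text.splitlines()
        if not lines or "\t" not in lines[0]:
            raise IdentifierError(f"normalization table {path} is not tab-separated")
        for line in lines[1:]:
            if not line.strip():
                continue
            pattern, canonical = line.split("\t")[:2]
            mapping[pattern.strip().lower()] = canonical.strip().lower()
        return cls(mapping)

    def canonical_prefix(self, prefix: str) -> str:
        key = prefix.strip().lower()
        if key in self.mapping:
            return self.mapping[key]
        logger.warning("unknown identifier prefix %r passed through lowercased", prefix)
        return key


def split_identifier(raw: str) -> tuple[str, str]:
    """Split ``raw`` into (prefix, local id).

    The separator is ``:`` when present, otherwise the last ``_`` (the OBO
    flat convention, e.g. ``HP_0004398``).  Bare codes without any prefix are
    rejected: a code is only joinable once its vocabulary is explicit.
    """
    if raw is None or not str(raw).strip():
        raise IdentifierError("empty identifier")
    raw = str(raw).strip()
    m = _CURIE_COLON.match(raw)
    if m:
        return m.group(1), m.group(2)
    if "_" in raw:
        prefix, local = raw.rsplit("_", 1)
        if prefix and local:
            return prefix, local
    raise IdentifierError(f"identifier {raw!r} has no parsable prefix")


def normalize_identifier(raw: str, table: NormalizationTable | None = None) -> str:
    """Return the canonical CURIE for ``raw``.

    >>> normalize_identifier("SNOMED-CT:1234567") == normalize_identifier("sctid:1234567")
    True
    >>> normalize_identifier("HP:0004398")
    'hp:0004398'
    """
    if table is None:
        table = NormalizationTable.default()
    prefix, local = split_identifier(raw)
    return f"{table.canonical_prefix(prefix)}:{local}"
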