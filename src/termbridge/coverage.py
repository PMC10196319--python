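"""Generalizability / coverage evaluation.

Compares the set of mapped clinical concepts against multi-site concept
prevalence records (how often each standard concept occurs in practice at
each site).  Counts below a floor are raised to the floor before any
frequency weighting, mirroring the de-identification convention of
concept-prevalence releases.  Coverage is summarized three ways:

* **raw coverage** — the share of prevalence concepts present in the
  mapping set: |overlap| / (|overlap| + |prevalence-only|) × 100;
* **weighted coverage** — the share of total (floored, site-aggregated)
  occurrence counts carried by overlapped concepts;
* **per-site coverage** — raw coverage computed against each site's own
  concept set.

Concepts present only in the prevalence data are triaged into three
mutually exclusive categories (recovered in a newer data-model release,
purposefully excluded by the mapper, or truly missing), and between-site
coverage differences are tested with a chi-square test of independence
(Yates-corrected at one degree of freedom) plus Bonferroni-adjusted
pairwise post hoc tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["PrevalenceRecord", "CoverageReport", "MissingnessVerdict",
           "CoverageError", "floor_counts", "coverage", "classify_missing",
           "chisq_yates", "pairwise_bonferroni"]


class CoverageError(ValueError):
    pass


@dataclass(frozen=True)
class PrevalenceRecord:
    site_id: str
    concept_id: int
    count: int


@dataclass
class CoverageReport:
    overlap: set[int]
    mapper_only: set[int]
    prevalence_only: set[int]
    raw_coverage: float          # percent
    weighted_coverage: float     # percent
    per_site: dict[str, float] = field(default_factory=dict)


@dataclass(frozen=True)
class MissingnessVerdict:
    concept_id: int
    category: str        # recovered_newer_cdm | purposefully_excluded | truly_missing
    sites: int = 0
    mean_frequency: float = 0.0


def floor_counts(records: list[PrevalenceRecord],
                 floor: int = 100) -> list[PrevalenceRecord]:
    """Raise every count below ``floor`` to ``floor`` (order preserved)."""
    out = []
    for r in records:
        if r.count < 0:
            raise CoverageError(f"negative count for {r.site_id}/{r.concept_id}")
        out.append(PrevalenceRecord(r.site_id, r.concept_id, max(r.count, floor)))
    return out


def coverage(mapper_concepts: set[int],
             prevalence: list[PrevalenceRecord],
             floor: int = 100) -> CoverageReport:
    """Coverage of the prevalence concepts by the mapper concept set.

    ``mapper_concepts`` must already be filtered to concepts with at least
    one valid mapping (unmapped / not-yet-mapped excluded).  Counts are
    floored and aggregated across sites before weighting.
    """
    if not prevalence:
        raise CoverageError("empty prevalence records: coverage undefined")
    records = floor_counts(prevalence, floor)
    prev_concepts = {r.concept_id for r in records}
    overlap = mapper_concepts & prev_concepts
    prevalence_only = prev_concepts - mapper_concepts
    mapper_only = mapper_concepts - prev_concepts
    raw = 100.0 * len(overlap) / (len(overlap) + len(prevalence_only))
    totals: dict[int, int] = {}
    for r in records:
        totals[r.concept_id] = totals.get(r.concept_id, 0) + r.count
    total_mass = sum(totals.values())
    overlap_mass = sum(totals[c] for c in overlap)
    weighted = 100.0 * overlap_mass / total_mass
    per_site: dict[str, float] = {}
    for site in sorted({r.site_id for r in records}):
        site_concepts = {r.concept_id for r in records if r.site_id == site}
        per_site[site] = 100.0 * len(site_concepts & mapper_concepts) / len(site_concepts)
    return CoverageReport(overlap=overlap, mapper_only=mapper_only,
                          prevalence_only=prevalence_only, raw_coverage=raw,
                          weighted_coverage=weighted, per_site=per_site)


def classify_missing(concept_id: int, newer_cdm: set[int], excluded: set[int],
                     records: list[PrevalenceRecord] | None = None
                     ) -> MissingnessVerdict:
    """Triage a prevalence-only concept, in priority order: recovered in a
    newer CDM release, purposefully excluded, else truly missing."""
    if concept_id in newer_cdm:
        category = "recovered_newer_cdm"
    elif concept_id in excluded:
        category = "purposefully_excluded"
    else:
        category = "truly_missing"
    sites, mean_freq = 0, 0.0
    if records:
        mine = [r for r in records if r.concept_id == concept_id]
        sites = len({r.site_id for r in mine})
        if mine:
            mean_freq = float(np.mean([r.count for r in mine]))
    return MissingnessVerdict(concept_id, category, sites, mean_freq)


def chisq_yates(table) -> tuple[float, int, float]:
    """Chi-square test of independence on an r×c contingency table.

    Yates' continuity correction is applied at one degree of freedom (the
    2×2 case); larger tables use the uncorrected statistic.  A zero row or
    column marginal is an error (expected counts undefined).
    """
    table = np.asarray(table, dtype=float)
    if (table < 0).any():
        raise CoverageError("negative cell count")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise CoverageError("zero row/column marginal in contingency table")
    res = stats.chi2_contingency(table, correction=True)
    return float(res.statistic), int(res.dof), float(res.pvalue)


def pairwise_bonferroni(site_table: pd.DataFrame) -> pd.DataFrame:
    """Bonferroni-adjusted pairwise site comparisons.

    ``site_table`` has one row per site with columns ``covered`` and
    ``uncovered``.  Each pair of sites is tested with the Yates-corrected
    2×2 chi-square; p values are multiplied by the number of pairs and
    clipped at 1.  Returns a symmetric site×site matrix of adjusted
    p values (diagonal NaN).
    """
    sites = list(site_table.index)
    if len(sites) < 2:
        raise CoverageError("need at least 2 sites for pairwise comparisons")
    n_pairs = len(sites) * (len(sites) - 1) // 2
    mat = pd.DataFrame(np.nan, index=sites, columns=sites, dtype=float)
    for i, a in enumerate(sites):
        for b in sites[i + 1:]:
            sub = site_table.loc[[a, b], ["covered", "uncovered"]].to_numpy()
            _, _, p = chisq_yates(sub)
            p_adj = min(1.0, p * n_pairs)
            mat.loc[a, b] = mat.loc[b, a] = p_adj
    return mat
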