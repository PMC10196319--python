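"""Phenotype risk scoring (PheRS) and the case/control utility evaluation.

A disease profile is the union of phenotype terms annotated to the
disease's genes.  A patient's raw score for a disease is the sum, over the
profile phenotypes the patient exhibits at least once, of the weight
``w_p = -log10(prevalence_p)`` — the inverse-log cohort prevalence weight
of the phenotype risk score literature, so rarer phenotypes contribute
more.  Scores are standardized by regressing on age, sex and record
length and z-scoring the residuals, which removes covariate-driven
baseline differences before comparing groups.

Cases are patients with at least two occurrences of a disease-relevant
diagnosis code; controls have none (single-occurrence patients are
excluded as ambiguous).  Controls are greedily matched to cases on exact
sex and binned age / record length, and the case-versus-control score
difference is tested with a one-sided Wilcoxon rank-sum test (exact
enumeration for small samples, midrank normal approximation with tie and
continuity corrections otherwise).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy import stats

__all__ = ["DiseaseProfile", "Patient", "Cohort", "PheRSError",
           "build_profiles", "phers_score", "standardize",
           "define_cases_controls", "match_controls", "wilcoxon_one_sided"]


class PheRSError(ValueError):
    pass


@dataclass(frozen=True)
class DiseaseProfile:
    disease: str
    genes: tuple[str, ...]
    phenotypes: frozenset[str]       # HPO-style CURIEs


@dataclass
class Patient:
    patient_id: str
    age: float
    sex: str
    record_length_days: float
    phenotype_counts: dict[str, int] = field(default_factory=dict)
    diagnosis_counts: dict[str, int] = field(default_factory=dict)

    def has(self, phenotype: str) -> bool:
        return self.phenotype_counts.get(phenotype, 0) >= 1


@dataclass
class Cohort:
    patients: list[Patient] = field(default_factory=list)

    def __iter__(self):
        return iter(self.patients)

    def __len__(self):
        return len(self.patients)


def build_profiles(gene_annotations: dict[str, set[str]],
                   disease_gene_map: dict[str, list[str]]) -> list[DiseaseProfile]:
    """Disease profiles as per-disease unions of gene phenotype annotations."""
    profiles = []
    for disease, genes in disease_gene_map.items():
        phenotypes: set[str] = set()
        for gene in genes:
            phenotypes |= gene_annotations.get(gene, set())
        if not phenotypes:
            raise PheRSError(f"disease {disease!r} has no annotated phenotypes")
        profiles.append(DiseaseProfile(disease, tuple(genes),
                                       frozenset(phenotypes)))
    return profiles


def phers_score(patient: Patient, profile: DiseaseProfile,
                prevalence: dict[str, float]) -> float:
    """Raw score: sum of -log10(prevalence) over present profile phenotypes."""
    score = 0.0
    for p in profile.phenotypes:
        if patient.has(p):
            prev = prevalence.get(p)
            if prev is None or not (0.0 < prev <= 1.0):
                raise PheRSError(f"prevalence for {p} must be in (0, 1]; got {prev}")
            score += -math.log10(prev)
    return score


def standardize(scores, age, sex, record_length) -> np.ndarray:
    """Covariate-residual z-scores.

    Regress raw scores on (intercept, age, sex, record length) by ordinary
    least squares and return residuals divided by their sample standard
    deviation; output has mean 0 and sd 1 within the scoring stratum.
    """
    y = np.asarray(scores, dtype=float)
    if y.size < 2:
        raise PheRSError("need at least 2 patients to standardize")
    sex_arr = np.asarray(sex)
    if sex_arr.dtype.kind in "UOS":
        levels = sorted(set(sex_arr.tolist()))
        sex_num = np.array([levels.index(s) for s in sex_arr], dtype=float)
    else:
        sex_num = sex_arr.astype(float)
    X = np.column_stack([np.ones_like(y), np.asarray(age, dtype=float),
                         sex_num, np.asarray(record_length, dtype=float)])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    sd = resid.std(ddof=1)
    if not np.isfinite(sd) or sd < 1e-12 * max(1.0, float(np.abs(y).max())):
        raise PheRSError("zero residual variance; cannot standardize")
    return resid / sd


def define_cases_controls(cohort: Cohort, disease: str
                          ) -> tuple[list[Patient], list[Patient]]:
    """Cases: ≥2 occurrences of a relevant diagnosis code; controls: 0;
    single-occurrence patients excluded from both."""
    cases, controls = [], []
    for p in cohort:
        n = p.diagnosis_counts.get(disease, 0)
        if n >= 2:
            cases.append(p)
        elif n == 0:
            controls.append(p)
    return cases, controls


def _match_key(p: Patient, age_bin: float, length_bin: float) -> tuple:
    return (p.sex, int(p.age // age_bin), int(p.record_length_days // length_bin))


def match_controls(cases: list[Patient], pool: list[Patient],
                   ratio: int = 1, age_bin_years: float = 5.0,
                   record_length_bin_days: float = 365.0
                   ) -> tuple[list[Patient], list[Patient]]:
    """Greedy without-replacement matching on (sex, age bin, record-length
    bin); returns (matched controls, cases lacking a full match set)."""
    if ratio < 1:
        raise PheRSError(f"matching ratio must be >= 1; got {ratio}")
    case_ids = {c.patient_id for c in cases}
    buckets: dict[tuple, list[Patient]] = {}
    for p in pool:
        if p.patient_id in case_ids:
            raise PheRSError("control pool overlaps the case set")
        buckets.setdefault(_match_key(p, age_bin_years,
                                      record_length_bin_days), []).append(p)
    matched: list[Patient] = []
    unmatched: list[Patient] = []
    for case in cases:
        bucket = buckets.get(_match_key(case, age_bin_years,
                                        record_length_bin_days), [])
        if len(bucket) >= ratio:
            matched.extend(bucket.pop(0) for _ in range(ratio))
        else:
            unmatched.append(case)
    return matched, unmatched


def wilcoxon_one_sided(case_scores, control_scores,
                       exact_max_n: int = 12) -> tuple[float, float]:
    """One-sided Wilcoxon rank-sum test (alternative: cases > controls).

    W is the midrank sum of the case group.  When the combined sample size
    is at most ``exact_max_n`` the p value is computed by exact enumeration
    of all rank assignments (ties handled naturally by enumerating over the
    observed values); otherwise the normal approximation with tie-corrected
    variance and a 0.5 continuity correction is used.
    """
    x = np.asarray(case_scores, dtype=float)
    y = np.asarray(control_scores, dtype=float)
    if x.size == 0 or y.size == 0:
        raise PheRSError("both groups must be nonempty")
    pooled = np.concatenate([x, y])
    if np.ptp(pooled) == 0:
        raise PheRSError("all values identical; rank-sum test degenerate")
    n1, n2 = x.size, y.size
    n = n1 + n2
    ranks = stats.rankdata(pooled)
    w = float(ranks[:n1].sum())
    if n <= exact_max_n:
        # exact: enumerate all C(n, n1) assignments of ranks to the case group
        idx = range(n)
        count = 0
        total = 0
        for combo in combinations(idx, n1):
            total += 1
            if ranks[list(combo)].sum() >= w - 1e-12:
                count += 1
        return w, count / total
    mean = n1 * (n + 1) / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(((tie_counts ** 3 - tie_counts).sum())) / (n * (n - 1))
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var <= 0:
        raise PheRSError("zero rank variance; rank-sum test degenerate")
    z = (w - mean - 0.5) / math.sqrt(var)
    return w, float(stats.norm.sf(z))
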