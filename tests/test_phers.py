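"""Phenotype risk scoring: profiles, weights, standardization, matching and
the one-sided rank-sum test."""

import math
from itertools import combinations

import numpy as np
import pytest
from scipy import stats

from termbridge.phers import (Cohort, DiseaseProfile, Patient, PheRSError,
                              build_profiles, define_cases_controls,
                              match_controls, phers_score, standardize,
                              wilcoxon_one_sided)


def _patient(pid="p", phenotypes=(), dx=0, age=10.0, sex="F", length=1000.0):
    return Patient(pid, age, sex, length,
                   phenotype_counts={p: 1 for p in phenotypes},
                   diagnosis_counts={"d": dx} if dx else {})


class TestProfiles:
    def test_union_over_genes(self):
        ann = {"G1": {"hp:1", "hp:2"}, "G2": {"hp:2", "hp:3"}}
        (p,) = build_profiles(ann, {"d": ["G1", "G2"]})
        assert p.phenotypes == frozenset({"hp:1", "hp:2", "hp:3"})

    def test_single_gene_profile_equals_annotation(self):
        ann = {"G1": {"hp:1"}}
        (p,) = build_profiles(ann, {"d": ["G1"]})
        assert p.phenotypes == frozenset({"hp:1"})

    def test_unannotated_disease_is_error(self):
        with pytest.raises(PheRSError):
            build_profiles({"G1": set()}, {"d": ["G1"]})

    def test_profile_sizes_match_set_union_oracle(self):
        rng = np.random.default_rng(2)
        genes = {f"G{k}": {f"hp:{x}" for x in rng.integers(0, 40, 6)}
                 for k in range(11)}
        disease_map = {f"d{k}": [f"G{(2 * k) % 11}", f"G{(2 * k + 1) % 11}",
                                 f"G{(3 * k) % 11}"][: 2 + k % 2]
                       for k in range(5)}
        for p in build_profiles(genes, disease_map):
            expected = set().union(*(genes[g] for g in p.genes))
            assert p.phenotypes == frozenset(expected)


class TestScoring:
    PROFILE = DiseaseProfile("d", ("G1",), frozenset({"hp:1", "hp:2", "hp:3"}))
    PREV = {"hp:1": 0.01, "hp:2": 0.1, "hp:3": 0.5}

    def test_no_overlap_scores_zero(self):
        assert phers_score(_patient(), self.PROFILE, self.PREV) == 0.0

    def test_single_phenotype_weight(self):
        assert phers_score(_patient(phenotypes=["hp:1"]), self.PROFILE,
                           self.PREV) == pytest.approx(2.0)

    def test_zero_prevalence_is_error(self):
        with pytest.raises(PheRSError):
            phers_score(_patient(phenotypes=["hp:1"]), self.PROFILE, {"hp:1": 0.0})

    def test_monotone_in_added_phenotypes(self):
        s1 = phers_score(_patient(phenotypes=["hp:1"]), self.PROFILE, self.PREV)
        s2 = phers_score(_patient(phenotypes=["hp:1", "hp:3"]), self.PROFILE,
                         self.PREV)
        assert s2 > s1

    def test_fifty_patient_brute_force_oracle(self):
        rng = np.random.default_rng(4)
        patients = [_patient(pid=f"p{k}",
                             phenotypes=[p for p in self.PROFILE.phenotypes
                                         if rng.random() < 0.5])
                    for k in range(50)]
        for p in patients:
            expected = sum(-math.log10(self.PREV[ph])
                           for ph in ("hp:1", "hp:2", "hp:3")
                           if p.phenotype_counts.get(ph, 0) >= 1)
            assert phers_score(p, self.PROFILE, self.PREV) == pytest.approx(expected)


class TestStandardize:
    def _cov(self, n, rng):
        return (rng.uniform(0, 21, n), rng.integers(0, 2, n).astype(float),
                rng.uniform(30, 7300, n))

    def test_covariate_independent_scores_are_z_scores(self):
        rng = np.random.default_rng(8)
        age, sex, length = self._cov(200, rng)
        scores = rng.normal(10, 2, 200)  # independent of covariates
        std = standardize(scores, age, sex, length)
        z = (scores - scores.mean()) / scores.std(ddof=1)
        # slopes are ~0, so residual z-scores track plain z-scores up to the
        # small variance absorbed by chance covariate fit
        assert np.corrcoef(std, z)[0, 1] > 0.99

    def test_location_invariance(self):
        rng = np.random.default_rng(9)
        age, sex, length = self._cov(100, rng)
        scores = rng.normal(0, 1, 100)
        a = standardize(scores, age, sex, length)
        b = standardize(scores + 7.5, age, sex, length)
        assert np.allclose(a, b, atol=1e-9)

    def test_mean_zero_sd_one(self):
        rng = np.random.default_rng(10)
        age, sex, length = self._cov(150, rng)
        std = standardize(rng.normal(size=150) + 0.1 * age, age, sex, length)
        assert abs(std.mean()) < 1e-9
        assert std.std(ddof=1) == pytest.approx(1.0, abs=1e-9)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(12)
        age, sex, length = self._cov(80, rng)
        y = rng.normal(size=80) + 0.05 * age + 0.001 * length
        X = np.column_stack([np.ones(80), age, sex, length])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        resid = y - X @ beta
        expected = resid / resid.std(ddof=1)
        assert np.allclose(standardize(y, age, sex, length), expected, atol=1e-8)

    def test_zero_variance_is_error(self):
        with pytest.raises(PheRSError):
            standardize([1.0, 1.0, 1.0], [1, 2, 3], ["F", "M", "F"], [1, 2, 3])


class TestCasesControls:
    def test_thresholds(self):
        cohort = Cohort([_patient("a", dx=2), _patient("b", dx=1),
                         _patient("c", dx=0), _patient("d", dx=5)])
        cases, controls = define_cases_controls(cohort, "d")
        assert {p.patient_id for p in cases} == {"a", "d"}
        assert {p.patient_id for p in controls} == {"c"}

    def test_tallies_match_recount(self):
        rng = np.random.default_rng(13)
        counts = rng.integers(0, 4, 200)
        cohort = Cohort([_patient(f"p{k}", dx=int(c))
                         for k, c in enumerate(counts)])
        cases, controls = define_cases_controls(cohort, "d")
        assert len(cases) == int((counts >= 2).sum())
        assert len(controls) == int((counts == 0).sum())


class TestMatching:
    def test_exact_twins_all_matched(self):
        cases = [_patient(f"c{k}", age=5 * k, sex="F") for k in range(4)]
        pool = [_patient(f"x{k}", age=5 * k + 1, sex="F") for k in range(4)]
        matched, unmatched = match_controls(cases, pool, ratio=1)
        assert len(matched) == 4 and not unmatched

    def test_empty_pool_reports_all_unmatched(self):
        cases = [_patient("c")]
        matched, unmatched = match_controls(cases, [])
        assert matched == [] and unmatched == cases

    def test_bad_ratio_is_error(self):
        with pytest.raises(PheRSError):
            match_controls([_patient("c")], [], ratio=0)

    def test_matched_key_distribution_equals_cases(self):
        rng = np.random.default_rng(14)
        cases, pool = [], []
        for k in range(30):
            age = float(rng.integers(0, 20))
            sex = "F" if k % 2 else "M"
            length = float(rng.integers(100, 7000))
            cases.append(_patient(f"c{k}", age=age, sex=sex, length=length))
            pool.append(_patient(f"x{k}", age=age, sex=sex, length=length))
        matched, unmatched = match_controls(cases, pool, ratio=1)
        assert not unmatched

        def keys(ps):
            return sorted((p.sex, int(p.age // 5),
                           int(p.record_length_days // 365)) for p in ps)
        assert keys(matched) == keys(cases)


class TestWilcoxon:
    def test_complete_separation_exact(self):
        """Cases {3,4,5} vs controls {0,1,2}: maximal rank sum; exact p is
        1 of the 20 equally likely assignments = 0.05."""
        w, p = wilcoxon_one_sided([3, 4, 5], [0, 1, 2])
        assert w == 15.0
        assert p == pytest.approx(1 / 20)

    def test_exact_matches_enumeration_oracle(self):
        rng = np.random.default_rng(15)
        for _ in range(20):
            x = rng.integers(0, 6, 4).astype(float)
            y = rng.integers(0, 6, 5).astype(float)
            if np.ptp(np.concatenate([x, y])) == 0:
                continue
            w, p = wilcoxon_one_sided(x, y)
            ranks = stats.rankdata(np.concatenate([x, y]))
            total = count = 0
            for combo in combinations(range(9), 4):
                total += 1
                count += ranks[list(combo)].sum() >= w - 1e-12
            assert p == pytest.approx(count / total)

    def test_normal_approx_close_to_exact_at_6_per_group(self):
        """Normal-approximation p within 0.02 of the exact enumeration at
        n1 = n2 = 6 over 50 random data sets."""
        rng = np.random.default_rng(16)
        checked = 0
        while checked < 50:
            x = rng.normal(0.5, 1, 6)
            y = rng.normal(0.0, 1, 6)
            _, p_exact = wilcoxon_one_sided(x, y)               # n = 12 -> exact
            _, p_norm = wilcoxon_one_sided(x, y, exact_max_n=0)  # force approx
            assert abs(p_exact - p_norm) < 0.02
            checked += 1

    def test_agrees_with_mannwhitneyu(self):
        rng = np.random.default_rng(17)
        x = rng.normal(1, 1, 40)
        y = rng.normal(0, 1, 60)
        _, p = wilcoxon_one_sided(x, y)
        ref = stats.mannwhitneyu(x, y, alternative="greater",
                                 method="asymptotic", use_continuity=True)
        assert p == pytest.approx(ref.pvalue, abs=1e-9)

    def test_identical_values_degenerate(self):
        with pytest.raises(PheRSError):
            wilcoxon_one_sided([1.0, 1.0], [1.0, 1.0])

    def test_empty_group_is_error(self):
        with pytest.raises(PheRSError):
            wilcoxon_one_sided([], [1.0])
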