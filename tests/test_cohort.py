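import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from brim.cohort import (
    BrimScore,
    ClassificationRule,
    PatientSample,
    ashman_D,
    classify_patient,
    compare_single_vs_ratio,
    default_classification_rule,
    pareto_order,
    patient_score,
    pearson_r,
    read_counts_manifest,
    split_bimodal,
    student_t,
    welch_t,
    write_counts_manifest,
)


def _scores(values, pair="CD74/CD59"):
    return [BrimScore(f"P{i}", pair, v) for i, v in enumerate(values)]


class TestPatientScore:
    def test_max_over_micrographs(self):
        s = PatientSample("P1", "DCIS", counts={"CD74/CD59": [3, 7, 2]})
        assert patient_score(s, "CD74/CD59").score == 7

    def test_all_zero_and_singleton(self):
        s = PatientSample("P1", "DCIS",
                          counts={"A/B": [0, 0, 0], "C/D": [12]})
        assert patient_score(s, "A/B").score == 0
        assert patient_score(s, "C/D").score == 12

    def test_missing_pair_errors(self):
        s = PatientSample("P1", "DCIS", counts={"A/B": [1]})
        with pytest.raises(KeyError):
            patient_score(s, "X/Y")


class TestParetoOrder:
    def test_ascending_with_ranks(self):
        series = pareto_order(_scores([5, 1, 3]))
        assert [(r, s) for r, _, s in series.entries] == [(1, 1), (2, 3), (3, 5)]

    def test_ties_keep_input_order(self):
        series = pareto_order(_scores([4, 4, 4]))
        assert series.patient_ids() == ["P0", "P1", "P2"]

    def test_sorted_input_unchanged(self):
        series = pareto_order(_scores([1, 2, 9]))
        assert list(series.scores()) == [1, 2, 9]


class TestSplitBimodal:
    def test_recovers_exact_membership_on_gapped_scores(self):
        series = pareto_order(_scores([0, 1, 2, 3, 190, 200, 210]))
        for transform in ("log1p", "linear"):
            split = split_bimodal(series, transform=transform)
            assert split.low_members == ["P0", "P1", "P2", "P3"]
            assert split.high_members == ["P4", "P5", "P6"]
        assert split.low_mean == pytest.approx(1.5)
        assert split.high_mean == pytest.approx(200.0)
        assert split.bimodal

    def test_linear_cut_matches_exhaustive_sse_oracle(self, rng):
        for _ in range(30):
            values = np.sort(rng.integers(0, 300, size=rng.integers(4, 16)))
            series = pareto_order(_scores(list(values)))
            split = split_bimodal(series, transform="linear")
            k_star = len(split.low_members)
            sse = []
            for k in range(2, len(values) - 1):
                lo, hi = values[:k].astype(float), values[k:].astype(float)
                sse.append(((lo - lo.mean()) ** 2).sum()
                           + ((hi - hi.mean()) ** 2).sum())
            assert sse[k_star - 2] == pytest.approx(min(sse))

    def test_too_few_scores(self):
        with pytest.raises(ValueError):
            split_bimodal(pareto_order(_scores([1, 2, 3])))

    def test_identical_scores_reported_unimodal(self):
        split = split_bimodal(pareto_order(_scores([5, 5, 5, 5, 5])))
        assert split.ashman_D == 0.0
        assert not split.bimodal

    def test_forced_split_of_unimodal_gaussian_still_separates(self, rng):
        # A forced two-group split of one Gaussian manufactures conditional
        # means ~2.7 pooled-SD apart, so Ashman's D alone cannot certify
        # bimodality; the flag fires on nearly every unimodal sample.
        flagged = 0
        for _ in range(200):
            values = np.rint(rng.normal(100, 15, size=23)).astype(int)
            split = split_bimodal(pareto_order(_scores(sorted(values))))
            flagged += split.bimodal
        assert flagged / 200 > 0.9

    def test_separated_mixture_membership_recovery(self, rng):
        # clean gap (> 4 max sd): membership must be exact
        hits = 0
        for _ in range(200):
            low = np.clip(np.rint(rng.normal(5, 3, 12)), 0, None)
            high = np.rint(rng.normal(200, 20, 11))
            series = pareto_order(_scores(sorted(low) + sorted(high)))
            split = split_bimodal(series)
            hits += (len(split.low_members) == 12
                     and split.low_mean == pytest.approx(np.mean(low))
                     and split.bimodal)
        assert hits >= 198


class TestAshmanD:
    def test_equal_components_zero(self):
        assert ashman_D(10, 3, 10, 3) == 0.0

    def test_published_group_statistics(self):
        # components 4 +/- 6 and 190 +/- 100
        assert ashman_D(4, 6, 190, 100) == pytest.approx(2.6257151847, abs=1e-6)

    def test_zero_sd_sentinel(self):
        assert ashman_D(1, 0, 2, 0) == math.inf
        assert ashman_D(1, 0, 1, 0) == 0.0

    @given(st.floats(-50, 50), st.floats(0.1, 20), st.floats(-50, 50),
           st.floats(0.1, 20), st.floats(-30, 30))
    def test_symmetric_and_translation_invariant(self, m1, s1, m2, s2, shift):
        d = ashman_D(m1, s1, m2, s2)
        assert d == pytest.approx(ashman_D(m2, s2, m1, s1))
        assert d == pytest.approx(ashman_D(m1 + shift, s1, m2 + shift, s2))


class TestTTests:
    def test_welch_frozen_reference(self):
        t, df, p = welch_t([1, 2, 3, 4], [10, 11, 12, 13])
        assert t == pytest.approx(-9.8590060351, abs=1e-8)
        assert df == pytest.approx(6.0)
        assert p == pytest.approx(6.280126e-05, rel=1e-5)

    def test_identical_samples(self):
        for test in (welch_t, student_t):
            t, _, p = test([4, 4, 5, 5], [4, 4, 5, 5])
            assert t == 0.0 and p == 1.0

    def test_welch_equals_student_when_balanced(self, rng):
        a = rng.normal(0, 1, 10)
        b = a + 0.5  # same sample variance, equal n
        tw, _, _ = welch_t(a, b)
        ts, dfs, _ = student_t(a, b)
        assert tw == pytest.approx(ts)
        assert dfs == 18

    def test_sample_size_precondition(self):
        with pytest.raises(ValueError):
            welch_t([1], [2, 3])

    def test_cross_check_against_scipy(self, rng):
        from scipy import stats
        a, b = rng.normal(0, 1, 9), rng.normal(0.8, 2, 14)
        for ours, equal_var in ((welch_t, False), (student_t, True)):
            t, _, p = ours(a, b)
            ref = stats.ttest_ind(a, b, equal_var=equal_var)
            assert t == pytest.approx(ref.statistic)
            assert p == pytest.approx(ref.pvalue)

    def test_student_welch_agree_under_equal_variance(self, rng):
        # cohort-sized groups at the study's weakest significant contrast
        # (the 14-year age difference over sd 8, ~1.75 sd)
        agree = 0
        n_sim = 300
        for _ in range(n_sim):
            a = rng.normal(50.0, 8.0, 12)
            b = rng.normal(64.0, 8.0, 11)
            _, _, p_w = welch_t(a, b)
            _, _, p_s = student_t(a, b)
            agree += abs(p_w - p_s) < 0.01
        assert agree / n_sim >= 0.95


class TestPearson:
    def test_perfect_correlations(self):
        x = [1.0, 2.0, 5.0, 9.0]
        assert pearson_r(x, x) == pytest.approx(1.0)
        assert pearson_r(x, [-v for v in x]) == pytest.approx(-1.0)

    def test_frozen_reference(self):
        assert pearson_r([1, 2, 3], [1, 2, 4]) == pytest.approx(
            0.9819805061, abs=1e-9)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            pearson_r([1, 1, 1], [1, 2, 3])


class TestClassification:
    def test_published_rule_examples(self):
        rule = default_classification_rule()
        assert classify_patient(
            {"CD74/CD59": 2, "CD44/CD24": 1, "NCAD/ECAD": 40}, rule) == "low_BRIM"
        assert classify_patient(
            {"CD74/CD59": 3, "CD44/CD24": 0, "NCAD/ECAD": 0}, rule) == "high_BRIM"

    def test_boundaries(self):
        rule = default_classification_rule()
        assert classify_patient(
            {"CD74/CD59": 2, "CD44/CD24": 2, "NCAD/ECAD": 49}, rule) == "low_BRIM"
        assert classify_patient(
            {"CD74/CD59": 2, "CD44/CD24": 2, "NCAD/ECAD": 50}, rule) == "high_BRIM"

    def test_missing_pair_errors(self):
        with pytest.raises(KeyError):
            classify_patient({"CD74/CD59": 0}, default_classification_rule())

    @given(st.integers(0, 5), st.integers(0, 5), st.integers(0, 60),
           st.integers(1, 10))
    def test_monotone_raising_scores(self, a, b, c, bump):
        rule = default_classification_rule()
        base = {"CD74/CD59": a, "CD44/CD24": b, "NCAD/ECAD": c}
        if classify_patient(base, rule) == "high_BRIM":
            raised = {k: v + bump for k, v in base.items()}
            assert classify_patient(raised, rule) == "high_BRIM"

    def test_rule_validation(self):
        with pytest.raises(ValueError):
            ClassificationRule({})
        with pytest.raises(ValueError):
            ClassificationRule({"A/B": -1})


class TestSingleVsRatioCorrelation:
    def _cohort(self, rng, artifact_sd):
        samples = []
        for i in range(200):
            base = int(rng.poisson(30))
            single = max(0, int(round(base + rng.normal(0, artifact_sd))))
            samples.append(PatientSample(
                f"P{i}", "DCIS",
                counts={"NCAD/ECAD": [base], "NCAD": [single]}))
        return samples

    def test_identical_measures_correlate_perfectly(self):
        samples = [PatientSample(f"P{i}", "DCIS",
                                 counts={"A/B": [c], "A": [c]})
                   for i, c in enumerate([3, 9, 27, 5])]
        result = compare_single_vs_ratio(samples, "A/B", "A")
        assert result.r == pytest.approx(1.0) and result.n == 4

    def test_too_few_patients(self):
        samples = [PatientSample(f"P{i}", "DCIS",
                                 counts={"A/B": [i], "A": [i]})
                   for i in range(2)]
        with pytest.raises(ValueError):
            compare_single_vs_ratio(samples, "A/B", "A")

    def test_mismatched_micrograph_sets(self):
        bad = [PatientSample("P0", "DCIS", counts={"A/B": [1, 2], "A": [1]})]
        with pytest.raises(ValueError, match="mismatched"):
            compare_single_vs_ratio(bad, "A/B", "A")

    def test_artifact_degrades_correlation_monotonically(self, rng):
        # an artifact component in the single-marker channel decouples the
        # conventional count from the ratio count
        rs = [compare_single_vs_ratio(self._cohort(rng, sd), "NCAD/ECAD",
                                      "NCAD").r
              for sd in (0.0, 8.0, 25.0)]
        assert rs[0] == pytest.approx(1.0)
        assert 1.0 > rs[1] > rs[2]


class TestManifestIO:
    def test_round_trip(self, tmp_path):
        samples = [
            PatientSample("P0", "DCIS", 61.0,
                          {"CD74/CD59": [1, 5], "CD44/CD24": [0, 2]}),
            PatientSample("P1", "fibroadenoma", None, {"CD74/CD59": [0]}),
        ]
        path = tmp_path / "manifest.csv"
        write_counts_manifest(samples, path)
        back = read_counts_manifest(path)
        assert {s.patient_id: s.counts for s in back} == {
            "P0": {"CD74/CD59": [1, 5], "CD44/CD24": [0, 2]},
            "P1": {"CD74/CD59": [0]},
        }
        assert back[0].age == 61.0 and back[1].age is None

    def test_malformed_row_named(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("patient_id,diagnosis,age,pair,micrograph_count\n"
                        "P0,DCIS,50,A/B,3\n"
                        "P1,DCIS,51,A/B,not-a-number\n")
        with pytest.raises(ValueError, match="row 3"):
            read_counts_manifest(path)

    def test_unknown_diagnosis_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("patient_id,diagnosis,age,pair,micrograph_count\n"
                        "P0,carcinosarcoma,50,A/B,3\n")
        with pytest.raises(ValueError, match="row 2"):
            read_counts_manifest(path)
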