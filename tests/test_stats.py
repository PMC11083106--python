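import itertools

import numpy as np
import pandas as pd
import pytest

from skindwi.io import DataError
from skindwi.stats import (
    ks_normality,
    pairwise_group_tests,
    ranksum,
    roc_analysis,
    summarize_groups,
)


# --------------------------------------------------------------------------
# independent oracles


def ranksum_exact_oracle(x, y):
    """Two-sided exact rank-sum p by full enumeration of assignments.

    Enumerates all C(n+m, n) ways the pooled ranks could be split,
    counting arrangements whose U is at least as extreme (two-sided,
    by distance from the null mean) as the observed one.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    pooled = np.concatenate([x, y])
    ranks = pooled.argsort().argsort() + 1.0
    n, m = len(x), len(y)
    u_obs = ranks[:n].sum() - n * (n + 1) / 2
    mu = n * m / 2
    count = 0
    total = 0
    for combo in itertools.combinations(range(n + m), n):
        u = ranks[list(combo)].sum() - n * (n + 1) / 2
        total += 1
        if abs(u - mu) >= abs(u_obs - mu) - 1e-12:
            count += 1
    return count / total


def auc_u_oracle(pos, neg):
    """AUC as the midrank Mann-Whitney statistic, by brute-force pairs.

    Orientation: higher score indicates the positive class.
    """
    wins = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1.0
            elif p == q:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def _cohort(**group_values):
    rows = []
    for group, values in group_values.items():
        for i, v in enumerate(values):
            rows.append(
                {"case_id": f"{group}{i}", "group": group, "adc_mean": v}
            )
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------


class TestKsNormality:
    def test_uniform_rejected(self, rng):
        p = ks_normality(rng.uniform(0, 1, 10_000))
        assert p < 0.01

    def test_normal_calibration_band(self, rng):
        # rejection rate at alpha=0.05 in [2%, 12%] over 500 replicates
        # (parameters estimated from the sample inflate the rate)
        rejections = sum(
            ks_normality(rng.normal(0, 1, 50)) < 0.05 for _ in range(500)
        )
        assert 0.02 <= rejections / 500 <= 0.12

    def test_constant_sample_degenerate(self):
        with pytest.raises(DataError, match="degenerate"):
            ks_normality([1.0, 1.0, 1.0, 1.0])

    def test_too_small(self):
        with pytest.raises(DataError, match="n >= 4"):
            ks_normality([1.0, 2.0, 3.0])


class TestRanksum:
    def test_fully_separated_exact_p(self):
        # 20 arrangements, 2 as extreme -> p = 0.1
        _, p = ranksum([1, 2, 3], [4, 5, 6])
        assert p == pytest.approx(0.1, rel=1e-12)

    def test_identical_samples_p_one(self):
        _, p = ranksum([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert p == pytest.approx(1.0, abs=0.05)

    def test_two_sided_symmetry(self, rng):
        x = rng.normal(0, 1, 7)
        y = rng.normal(0.5, 1, 9)
        _, p_xy = ranksum(x, y)
        _, p_yx = ranksum(y, x)
        assert p_xy == pytest.approx(p_yx, rel=1e-12)

    def test_empty_sample_rejected(self):
        with pytest.raises(DataError, match="nonempty"):
            ranksum([], [1.0])

    def test_exact_matches_enumeration_oracle(self, rng):
        # 100 random tie-free instances with n1, n2 <= 8
        for _ in range(100):
            n1 = int(rng.integers(2, 9))
            n2 = int(rng.integers(2, 9))
            pooled = rng.normal(0, 1, n1 + n2)  # continuous => tie-free
            x, y = pooled[:n1], pooled[n1:]
            _, p = ranksum(x, y)
            assert p == pytest.approx(
                ranksum_exact_oracle(x, y), rel=1e-9
            ), (x, y)

    def test_type_one_error_calibrated(self):
        # under the null, rejection rate at alpha=0.05 stays inside the
        # binomial 95% band over 1000 replicates
        rng = np.random.default_rng(2024)
        rejections = 0
        n_rep = 1000
        for _ in range(n_rep):
            x = rng.normal(0, 1, 11)
            y = rng.normal(0, 1, 11)
            _, p = ranksum(x, y)
            rejections += p < 0.05
        band = 1.96 * np.sqrt(0.05 * 0.95 / n_rep)
        assert abs(rejections / n_rep - 0.05) <= band


class TestPairwiseGroupTests:
    def test_small_group_descriptive_only(self, rng):
        cohort = _cohort(
            PD=rng.normal(0.95, 0.2, 3),
            BSI=rng.normal(1.88, 0.3, 11),
            SIBC=rng.normal(1.38, 0.4, 11),
        )
        res = pairwise_group_tests(cohort, features=("adc_mean",))
        pd_rows = res[(res.group_a == "PD") | (res.group_b == "PD")]
        assert pd_rows["descriptive_only"].all()
        assert pd_rows["p_value"].isna().all()
        assert not pd_rows["significant"].any()
        other = res[~((res.group_a == "PD") | (res.group_b == "PD"))]
        assert (~other["descriptive_only"]).all()

    def test_single_group_empty_result(self, rng):
        cohort = _cohort(BSI=rng.normal(1.88, 0.3, 11))
        res = pairwise_group_tests(cohort, features=("adc_mean",))
        assert res.empty

    def test_row_count(self, rng):
        cohort = _cohort(
            A=rng.normal(0, 1, 6),
            B=rng.normal(0, 1, 6),
            C=rng.normal(0, 1, 6),
        )
        res = pairwise_group_tests(cohort, features=("adc_mean",))
        assert len(res) == 3  # C(3,2) pairs x 1 feature

    def test_null_type_one_rate(self):
        # two identical groups of n=11: significant in ~5% of replicates
        rng = np.random.default_rng(99)
        hits = 0
        n_rep = 400
        for _ in range(n_rep):
            cohort = _cohort(
                A=rng.normal(1.5, 0.3, 11), B=rng.normal(1.5, 0.3, 11)
            )
            res = pairwise_group_tests(cohort, features=("adc_mean",))
            hits += bool(res["significant"].iloc[0])
        assert 0.02 <= hits / n_rep <= 0.09

    def test_bonferroni_flag(self, rng):
        cohort = _cohort(
            A=rng.normal(0, 1, 8) + 10,
            B=rng.normal(0, 1, 8),
            C=rng.normal(0, 1, 8),
        )
        raw = pairwise_group_tests(cohort, features=("adc_mean",))
        adj = pairwise_group_tests(
            cohort, features=("adc_mean",), correction="bonferroni"
        )
        assert (
            adj["p_value"].dropna() >= raw["p_value"].dropna() - 1e-15
        ).all()

    def test_unknown_feature_rejected(self, rng):
        cohort = _cohort(A=rng.normal(0, 1, 6), B=rng.normal(0, 1, 6))
        with pytest.raises(DataError, match="not in cohort"):
            pairwise_group_tests(cohort, features=("nope",))


class TestRocAnalysis:
    def test_perfect_separation(self):
        cohort = _cohort(SIBC=[0.8, 0.9, 1.0], BSI=[1.8, 1.9, 2.0])
        r = roc_analysis(cohort, "adc_mean", "SIBC", "BSI")
        assert r.auc == 1.0
        assert r.sensitivity_at_youden == 1.0
        assert r.specificity_at_youden == 1.0

    def test_identical_groups_auc_half(self):
        cohort = _cohort(A=[1.0, 1.5, 2.0], B=[1.0, 1.5, 2.0])
        r = roc_analysis(cohort, "adc_mean", "A", "B")
        assert r.auc == pytest.approx(0.5)

    def test_auc_equals_u_oracle_on_random_instances(self, rng):
        for _ in range(100):
            n1 = int(rng.integers(2, 15))
            n2 = int(rng.integers(2, 15))
            # occasional ties via rounding
            pos = np.round(rng.normal(1.3, 0.4, n1), 1)
            neg = np.round(rng.normal(1.8, 0.4, n2), 1)
            cohort = _cohort(P=pos, N=neg)
            r = roc_analysis(cohort, "adc_mean", "P", "N")
            # lower ADC positive => score is -value; oracle on -values
            expect = auc_u_oracle(-pos, -neg)
            assert r.auc == pytest.approx(expect, abs=1e-12)

    def test_monotone_curve(self, rng):
        cohort = _cohort(
            P=rng.normal(1.3, 0.4, 20), N=rng.normal(1.8, 0.4, 20)
        )
        r = roc_analysis(cohort, "adc_mean", "P", "N")
        assert np.all(np.diff(r.sensitivities) >= 0)
        assert np.all(np.diff(1.0 - r.specificities) >= 0)

    def test_empty_class_rejected(self):
        cohort = _cohort(P=[1.0])
        with pytest.raises(DataError, match="nonempty"):
            roc_analysis(cohort, "adc_mean", "P", "N")

    def test_youden_threshold_classifies(self):
        cohort = _cohort(
            SIBC=[0.9, 1.1, 1.2, 1.6], BSI=[1.4, 1.8, 1.9, 2.1]
        )
        r = roc_analysis(cohort, "adc_mean", "SIBC", "BSI")
        # recompute sens/spec by applying the threshold directly
        pos = np.array([0.9, 1.1, 1.2, 1.6])
        neg = np.array([1.4, 1.8, 1.9, 2.1])
        sens = np.mean(pos <= r.youden_threshold)
        spec = np.mean(neg > r.youden_threshold)
        assert sens == pytest.approx(r.sensitivity_at_youden)
        assert spec == pytest.approx(r.specificity_at_youden)


class TestSummarizeGroups:
    def test_hand_arithmetic(self):
        cohort = _cohort(A=[1.0, 2.0, 3.0])
        res = summarize_groups(cohort, features=("adc_mean",))
        row = res.iloc[0]
        assert row["mean"] == pytest.approx(2.0)
        assert row["sd"] == pytest.approx(1.0)
        assert row["sem"] == pytest.approx(1.0 / np.sqrt(3))
        assert (row["min"], row["max"]) == (1.0, 3.0)

    def test_single_case_group_sem_absent(self):
        cohort = _cohort(A=[1.5])
        res = summarize_groups(cohort, features=("adc_mean",))
        assert np.isnan(res.iloc[0]["sem"])
        assert np.isnan(res.iloc[0]["sd"])

    def test_row_count(self, rng):
        cohort = _cohort(
            A=rng.normal(0, 1, 4), B=rng.normal(0, 1, 4)
        )
        cohort["adc_min"] = cohort["adc_mean"] - 0.1
        res = summarize_groups(cohort, features=("adc_mean", "adc_min"))
        assert len(res) == 2 * 2

    def test_empty_cohort_rejected(self):
        with pytest.raises(DataError, match="empty"):
            summarize_groups(pd.DataFrame())
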