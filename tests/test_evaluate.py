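"""Discrimination metrics against brute-force oracles and exact identities."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import screenfuse as sf
from conftest import aupr_oracle, auroc_oracle, confusion_oracle


def random_scored_cohort(rng, n_max=200, coarse=False):
    n = int(rng.integers(10, n_max))
    if coarse:
        scores = rng.choice(np.round(rng.random(5), 2), size=n)
    else:
        scores = rng.random(n)
    labels = rng.integers(0, 2, size=n)
    if labels.sum() == 0:
        labels[0] = 1
    if labels.sum() == n:
        labels[-1] = 0
    return scores, labels


class TestAuroc:
    def test_perfect_separation(self):
        assert sf.auroc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0

    def test_three_of_four_concordant(self):
        assert sf.auroc([0.9, 0.2, 0.1, 0.8], [1, 1, 0, 0]) == 0.75

    def test_all_ties_is_half(self):
        assert sf.auroc([0.3] * 6, [1, 0, 1, 0, 0, 0]) == 0.5

    def test_matches_pairwise_oracle(self):
        rng = np.random.default_rng(10)
        for _ in range(30):
            scores, labels = random_scored_cohort(rng, coarse=bool(rng.integers(2)))
            assert sf.auroc(scores, labels) == pytest.approx(
                auroc_oracle(scores, labels), abs=1e-12
            )

    @given(st.integers(0, 2**31 - 1))
    def test_invariant_under_monotone_transform(self, seed):
        rng = np.random.default_rng(seed)
        scores, labels = random_scored_cohort(rng)
        transformed = np.exp(3.0 * scores) + 1.5  # strictly increasing
        assert sf.auroc(scores, labels) == pytest.approx(
            sf.auroc(transformed, labels), abs=1e-12
        )

    def test_one_class_undefined(self):
        with pytest.raises(sf.MetricUndefinedError):
            sf.auroc([0.1, 0.2], [1, 1])


class TestAupr:
    def test_perfect_ranking(self):
        assert sf.aupr([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0

    def test_one_inversion_toy(self):
        # ranked: 0.9(+), 0.8(-), 0.7(+), 0.1(-): AP = 0.5*1 + 0.5*(2/3)
        assert sf.aupr([0.9, 0.8, 0.7, 0.1], [1, 0, 1, 0]) == pytest.approx(
            0.5 + 0.5 * 2 / 3
        )

    def test_null_limit_is_prevalence(self):
        rng = np.random.default_rng(11)
        scores = rng.random(20000)
        labels = rng.binomial(1, 0.1, 20000)
        assert sf.aupr(scores, labels) == pytest.approx(0.1, abs=0.02)

    def test_matches_threshold_walk_oracle(self):
        rng = np.random.default_rng(12)
        for _ in range(30):
            scores, labels = random_scored_cohort(rng, coarse=bool(rng.integers(2)))
            assert sf.aupr(scores, labels) == pytest.approx(
                aupr_oracle(scores, labels), abs=1e-12
            )

    def test_no_cases_undefined(self):
        with pytest.raises(sf.MetricUndefinedError):
            sf.aupr([0.1, 0.2], [0, 0])


class TestThresholdTable:
    def test_top_five_percent_catches_top_cases(self):
        scores = np.arange(1, 101) / 100.0
        labels = np.zeros(100, int)
        labels[-5:] = 1
        table = sf.threshold_table(scores, labels, [95]).iloc[0]
        assert table["sensitivity"] == 1.0
        assert table["flagged_fraction"] == pytest.approx(0.05)

    def test_null_ppv_near_prevalence(self):
        rng = np.random.default_rng(13)
        scores = rng.random(30000)
        labels = rng.binomial(1, 0.05, 30000)
        table = sf.threshold_table(scores, labels, [50, 75, 90])
        assert np.allclose(table["ppv"], 0.05, atol=0.01)

    def test_counts_match_exhaustive_scan_with_ties(self):
        rng = np.random.default_rng(14)
        for _ in range(20):
            scores, labels = random_scored_cohort(rng, n_max=40, coarse=True)
            table = sf.threshold_table(scores, labels, [50, 90])
            for _, row in table.iterrows():
                expected = confusion_oracle(scores, labels, row["threshold"])
                for k, v in expected.items():
                    assert row[k] == v

    def test_metrics_recompute_from_counts(self, small_sim, small_labels):
        _, cohort, _, _ = small_sim
        y = small_labels["si_30"].to_numpy()
        table = sf.threshold_table(cohort["ehr_score"].to_numpy(), y,
                                   [50, 75, 90, 95, 99])
        for _, r in table.iterrows():
            assert r["tp"] + r["fn"] == y.sum()
            assert r["tn"] + r["fp"] == (1 - y).sum()
            assert r["sensitivity"] == pytest.approx(r["tp"] / (r["tp"] + r["fn"]))
            assert r["ppv"] == pytest.approx(r["tp"] / (r["tp"] + r["fp"]))

    def test_degenerate_scores_warn_and_flag_nothing(self):
        with pytest.warns(UserWarning, match="degenerate"):
            table = sf.threshold_table([0.5] * 20, [0, 1] * 10, [90])
        assert table.iloc[0]["flagged_fraction"] == 0.0

    def test_npv_approaches_one_minus_prevalence(self):
        """As the flagged set grows toward everyone, NPV -> 1 - prevalence."""
        rng = np.random.default_rng(15)
        scores = rng.random(5000)
        labels = rng.binomial(1, 0.3, 5000)
        table = sf.threshold_table(scores, labels, [1, 99])
        wide = table.iloc[1]  # >99: almost nobody flagged -> NPV ~ 1 - prev
        assert wide["npv"] == pytest.approx(1 - labels.mean(), abs=0.02)


class TestTierTable:
    def test_cumulative_rows_and_monotone_sensitivity(self, small_sim, small_labels):
        _, cohort, _, _ = small_sim
        tiers = sf.assign_tiers(cohort)
        y = small_labels["sa_180"].to_numpy()
        table = sf.tier_table(tiers, y)
        assert list(table["cutoff"]) == ["yellow", "orange", "red"]
        sens = table["sensitivity"].to_numpy()
        assert sens[0] >= sens[1] >= sens[2]

    def test_all_green_cohort_zero_sensitivity(self):
        table = sf.tier_table(["green"] * 10, [0, 1] * 5)
        assert (table["sensitivity"] == 0).all()

    def test_single_red_case(self):
        tiers = ["red"] + ["green"] * 9
        labels = [1] + [0] * 9
        row = sf.tier_table(tiers, labels).set_index("cutoff").loc["red"]
        assert row["sensitivity"] == 1.0 and row["ppv"] == 1.0


class TestIdi:
    def test_defining_formula_toy(self):
        new = [0.8, 0.6, 0.2, 0.4]
        old = [0.5, 0.5, 0.5, 0.5]
        labels = [1, 1, 0, 0]
        r = sf.idi(new, old, labels)
        assert r.idi == pytest.approx(0.4)
        assert r.integrated_sensitivity_gain == pytest.approx(0.2)
        assert r.integrated_specificity_gain == pytest.approx(0.2)

    def test_self_zero_and_antisymmetry(self):
        rng = np.random.default_rng(16)
        new, old = rng.random(50), rng.random(50)
        labels = rng.integers(0, 2, 50)
        labels[:2] = [0, 1]
        assert sf.idi(new, new, labels).idi == 0.0
        assert sf.idi(new, old, labels).idi == pytest.approx(
            -sf.idi(old, new, labels).idi, abs=1e-15
        )

    def test_matches_direct_formula_random(self):
        rng = np.random.default_rng(17)
        for _ in range(50):
            n = int(rng.integers(6, 60))
            new, old = rng.random(n), rng.random(n)
            labels = rng.integers(0, 2, n)
            labels[:2] = [0, 1]
            case = labels == 1
            direct = (new[case].mean() - new[~case].mean()) - (
                old[case].mean() - old[~case].mean()
            )
            assert sf.idi(new, old, labels).idi == pytest.approx(direct, abs=1e-12)

    def test_bootstrap_ci_and_determinism(self):
        rng = np.random.default_rng(18)
        labels = rng.integers(0, 2, 300)
        old = rng.random(300)
        new = np.clip(old + 0.3 * labels - 0.1, 0, 1)
        r1 = sf.idi(new, old, labels, inference="bootstrap", n_boot=200, seed=5)
        r2 = sf.idi(new, old, labels, inference="bootstrap", n_boot=200, seed=5)
        assert r1.ci_low == r2.ci_low and r1.ci_high == r2.ci_high
        assert r1.ci_low <= r1.idi <= r1.ci_high

    def test_cluster_bootstrap_runs(self):
        rng = np.random.default_rng(19)
        labels = rng.integers(0, 2, 200)
        cluster = rng.integers(0, 50, 200)
        r = sf.idi(rng.random(200), rng.random(200), labels,
                   inference="bootstrap", n_boot=100, seed=1, cluster=cluster)
        assert np.isfinite(r.idi)

    def test_point_only_with_tiny_classes(self):
        r = sf.idi([0.3, 0.7], [0.4, 0.5], [0, 1])
        assert r.method == "point_only" and np.isnan(r.p_value)


class TestSubgroups:
    def test_single_stratum_equals_global(self, small_sim, small_labels):
        _, cohort, _, _ = small_sim
        y = small_labels["si_30"].to_numpy()
        scores = cohort["ehr_score"].to_numpy()
        table = sf.subgroup_eval(scores, y, np.repeat("all", len(y)))
        assert len(table) == 1
        assert table.iloc[0]["auroc"] == pytest.approx(sf.auroc(scores, y))
        assert table.iloc[0]["aupr"] == pytest.approx(sf.aupr(scores, y))

    def test_caseless_stratum_skipped(self):
        scores = np.r_[np.linspace(0, 1, 50), np.linspace(0, 1, 50)]
        labels = np.r_[np.zeros(50, int), np.random.default_rng(0).integers(0, 2, 50)]
        labels[50] = 1
        groups = np.r_[np.repeat("empty", 50), np.repeat("full", 50)]
        table = sf.subgroup_eval(scores, labels, groups).set_index("stratum")
        assert bool(table.loc["empty", "skipped"])
        assert not bool(table.loc["full", "skipped"])

    def test_signal_only_in_one_stratum(self):
        rng = np.random.default_rng(20)
        n = 4000
        x = rng.normal(size=n)
        groups = np.repeat(["A", "B"], n // 2)
        p = np.where(groups == "A", 1 / (1 + np.exp(-(-3 + 2 * x))), 0.05)
        labels = rng.binomial(1, p)
        scores = 1 / (1 + np.exp(-x))
        table = sf.subgroup_eval(scores, labels, groups).set_index("stratum")
        assert table.loc["A", "auroc"] > 0.8
        assert abs(table.loc["B", "auroc"] - 0.5) < 0.08


class TestReclassification:
    def test_identical_models_have_no_unique_cases(self):
        rng = np.random.default_rng(21)
        s = rng.random(200)
        y = rng.integers(0, 2, 200)
        rep = sf.reclassification(s, s, y)
        assert rep["groups"]["a_only"]["count"] == 0
        assert rep["groups"]["b_only"]["count"] == 0

    def test_partition_counts_brute_force(self):
        scores_a = np.linspace(0, 1, 20)
        scores_b = scores_a[::-1].copy()
        y = np.zeros(20, int)
        y[[0, 1, 18, 19]] = 1  # two cases at each extreme
        rep = sf.reclassification(scores_a, scores_b, y)
        in_a = scores_a > np.percentile(scores_a, 90)
        in_b = scores_b > np.percentile(scores_b, 90)
        case = y == 1
        assert rep["groups"]["a_only"]["count"] == int((case & in_a & ~in_b).sum())
        assert rep["groups"]["b_only"]["count"] == int((case & in_b & ~in_a).sum())
        assert rep["groups"]["both"]["count"] == int((case & in_a & in_b).sum())
        assert rep["groups"]["neither"]["count"] == int((case & ~in_a & ~in_b).sum())
        counts = [g["count"] for g in rep["groups"].values()]
        assert sum(counts) == rep["n_cases"]

    def test_covariate_summaries(self):
        rng = np.random.default_rng(22)
        n = 100
        a, b = rng.random(n), rng.random(n)
        y = np.ones(n, int)
        y[:50] = 0
        cov = pd.DataFrame({
            "male": rng.integers(0, 2, n),
            "total_visits": rng.integers(1, 30, n),
        })
        rep = sf.reclassification(a, b, y, covariates=cov)
        grp = rep["groups"]["neither"]
        assert {"count", "percent"} <= set(grp["covariates"]["male"])
        assert {"median", "iqr_low", "iqr_high"} <= set(
            grp["covariates"]["total_visits"]
        )

    def test_misaligned_covariates_rejected(self):
        with pytest.raises(sf.ConfigError):
            sf.reclassification(
                [0.1, 0.2], [0.2, 0.1], [0, 1],
                covariates=pd.DataFrame({"x": [1]}),
            )
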