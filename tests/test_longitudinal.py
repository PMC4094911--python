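import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from morphindex.evaluation import empirical_auc
from morphindex.longitudinal import (
    apoe_stratification,
    derive_longitudinal,
    descriptive_summary,
    paired_change_test,
    pattern_comparisons,
    rank_correlation,
    rank_sum_test,
    rate_anova,
    summarize_groups,
    zscore,
)
from morphindex.synthetic import CohortSpec, generate_cohort

from oracles import exact_rank_sum_p_two_sided, spearman_no_ties


def _index_frame(pairs):
    rows = []
    for sid, (b, m) in pairs.items():
        rows.append({"subject_id": sid, "timepoint": "baseline", "index": b})
        if m is not None:
            rows.append({"subject_id": sid, "timepoint": "m12", "index": m})
    return pd.DataFrame(rows)


class TestDeriveLongitudinal:
    def test_worked_example(self):
        out = derive_longitudinal(_index_frame({"s1": (0.70, 0.86)}))
        row = out.iloc[0]
        assert row["annual_rate"] == pytest.approx(0.16)
        assert row["average_index"] == pytest.approx(0.78)
        assert row["pattern"] == "AD-like"

    def test_constant_index(self):
        out = derive_longitudinal(_index_frame({"s1": (0.42, 0.42)}))
        assert out.iloc[0]["annual_rate"] == 0.0
        assert out.iloc[0]["average_index"] == 0.42

    def test_negative_values_ctl_like(self):
        out = derive_longitudinal(_index_frame({"s1": (-0.13, -0.03)}))
        assert out.iloc[0]["average_index"] == pytest.approx(-0.08)
        assert out.iloc[0]["pattern"] == "CTL-like"

    def test_missing_timepoint_dropped(self):
        out = derive_longitudinal(_index_frame({"s1": (0.7, 0.9), "s2": (0.5, None)}))
        assert list(out["subject_id"]) == ["s1"]

    def test_duplicate_timepoint_rejected(self):
        df = _index_frame({"s1": (0.7, 0.9)})
        df = pd.concat([df, df.iloc[[0]]], ignore_index=True)
        with pytest.raises(ValueError, match="s1"):
            derive_longitudinal(df)

    @given(
        b=st.floats(min_value=-2, max_value=2),
        m=st.floats(min_value=-2, max_value=2),
    )
    @settings(max_examples=50, deadline=None)
    def test_identities_machine_precision(self, b, m):
        out = derive_longitudinal(_index_frame({"s": (b, m)})).iloc[0]
        assert out["annual_rate"] == m - b
        assert out["average_index"] == (b + m) / 2.0
        assert out["pattern"] == ("AD-like" if out["average_index"] > 0.5 else "CTL-like")


class TestDescriptiveSummary:
    def test_simple(self):
        s = descriptive_summary(np.array([1.0, 2.0, 3.0, 4.0]))
        assert s["median"] == 2.5
        assert s["min"] == 1 and s["max"] == 4

    def test_single_value_degenerate(self):
        s = descriptive_summary(np.array([0.7]))
        assert s["mean"] == s["median"] == s["min"] == s["max"] == 0.7
        assert s["sd"] == 0.0 and s["sd_degenerate"]

    def test_quartile_ordering(self, rng):
        for _ in range(10):
            s = descriptive_summary(rng.normal(size=rng.integers(2, 40)))
            assert s["q1"] <= s["median"] <= s["q3"]

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            descriptive_summary(np.array([]))

    def test_group_summary_shape(self):
        df = pd.DataFrame({"g": list("aabb"), "v": [1.0, 2.0, 3.0, 5.0]})
        out = summarize_groups(df, "v", ["g"])
        assert len(out) == 2
        assert set(out.columns) >= {"g", "mean", "sd", "median", "q1", "q3"}


class TestRankSum:
    def test_identical_groups(self):
        a = np.array([1.0, 2.0, 5.0])
        res = rank_sum_test(a, a.copy())
        assert res.p_value >= 0.99

    def test_exact_small_sample(self):
        res = rank_sum_test(np.array([1.0, 2.0, 3.0]), np.array([4.0, 5.0, 6.0]))
        assert res.p_value == pytest.approx(0.1)
        assert "exact" in res.test

    def test_matches_enumeration_oracle(self, rng):
        a = rng.normal(size=5)
        b = rng.normal(size=4) + 0.5
        res = rank_sum_test(a, b)
        assert res.p_value == pytest.approx(exact_rank_sum_p_two_sided(a, b), abs=1e-10)

    def test_u_auc_identity(self, rng):
        for _ in range(20):
            a = rng.normal(size=rng.integers(3, 12))
            b = rng.normal(size=rng.integers(3, 12))
            res = rank_sum_test(a, b)
            pooled = np.r_[a, b]
            labels = np.r_[np.ones(len(a)), np.zeros(len(b))]
            auc = empirical_auc(pooled, labels).auc
            assert res.statistic / (len(a) * len(b)) == pytest.approx(auc, abs=1e-12)

    def test_ties_fall_back_to_asymptotic(self):
        a = np.array([1.0, 1.0, 2.0] * 8)
        b = np.array([1.0, 3.0, 3.0] * 8)
        res = rank_sum_test(a, b)
        assert "asymptotic" in res.test
        assert 0 <= res.p_value <= 1

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            rank_sum_test(np.array([]), np.array([1.0]))


class TestRankCorrelation:
    def test_perfect_positive(self):
        r, _ = rank_correlation(np.arange(6.0), np.arange(6.0) * 3 + 1)
        assert r == pytest.approx(1.0)

    def test_perfect_negative(self):
        r, _ = rank_correlation(np.arange(6.0), -np.arange(6.0))
        assert r == pytest.approx(-1.0)

    def test_hand_computed_example(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        y = np.array([2.0, 1.0, 4.0, 3.0])
        r, p = rank_correlation(x, y)
        assert r == pytest.approx(0.6)
        assert r == pytest.approx(spearman_no_ties(x, y))

    def test_exact_p_small_n(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        r, p = rank_correlation(x, x)
        # only the identity and reverse orderings reach |rho| = 1: 2/24
        assert p == pytest.approx(2 / 24)

    def test_large_n_t_approx(self, rng):
        x = rng.normal(size=50)
        y = x + rng.normal(size=50)
        r, p = rank_correlation(x, y)
        r_scipy, p_scipy = stats.spearmanr(x, y)
        assert r == pytest.approx(r_scipy)
        assert p == pytest.approx(p_scipy)

    def test_constant_rejected(self):
        with pytest.raises(ValueError):
            rank_correlation(np.ones(5), np.arange(5.0))


class TestPairedChange:
    def test_noise_free_shift_exact_signed_rank(self):
        base = np.array([0.1, 0.5, 0.2, 0.9, 0.4])
        res = paired_change_test(base, base + 0.2, alternative="greater")
        assert res["wilcoxon_p"] == pytest.approx(1 / 32)

    def test_no_change(self):
        base = np.array([0.3, 0.6, 0.1])
        res = paired_change_test(base, base.copy())
        assert res["t_statistic"] == 0 or np.isnan(res["t_statistic"])
        assert res["wilcoxon_p"] == 1.0

    def test_power_at_observed_decline(self):
        """Planted 0.16/yr change, noise SD 0.05, n=62: one-sided rejection
        at alpha = 0.003 in >= 95% of 100 seeds."""
        rejections = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            base = rng.normal(0.7, 0.3, size=62)
            m12 = base + 0.16 + rng.normal(0, 0.05, size=62)
            res = paired_change_test(base, m12, alternative="greater")
            if res["t_p"] < 0.003:
                rejections += 1
        assert rejections >= 95

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError):
            paired_change_test(np.zeros(3), np.zeros(4))

    def test_n1_rejected(self):
        with pytest.raises(ValueError):
            paired_change_test(np.array([1.0]), np.array([2.0]))


class TestZScore:
    def test_definition(self, rng):
        z = zscore(rng.normal(3, 2, size=40))
        assert z.mean() == pytest.approx(0, abs=1e-12)
        assert z.std(ddof=1) == pytest.approx(1)

    def test_constant_rejected(self):
        with pytest.raises(ValueError):
            zscore(np.ones(5))


def _mci_frame(n, carrier_effect, seed):
    rng = np.random.default_rng(seed)
    carriers = (np.arange(n) % 2).astype(int)
    rows = []
    for i in range(n):
        base = rng.normal(0.5 + carrier_effect * carriers[i], 0.2)
        for tp, val in (("baseline", base), ("m12", base + rng.normal(0.05, 0.05))):
            rows.append(
                {
                    "subject_id": f"m{i}",
                    "timepoint": tp,
                    "apoe_e4": carriers[i],
                    "index": val,
                    "mmse": rng.normal(27, 2),
                    "cdr_sob": rng.normal(1.5, 1),
                    "adas1": rng.normal(4, 1),
                }
            )
    return pd.DataFrame(rows)


class TestApoeStratification:
    def test_z_scores_standardized(self):
        df = _mci_frame(30, 0.0, 1)
        out = apoe_stratification(df)
        assert set(out["variable"]) == {"index", "mmse", "cdr_sob", "adas1"}
        assert (out["n_carrier"] + out["n_noncarrier"] == 30).all()

    def test_planted_carrier_effect_direction(self):
        wins = 0
        for seed in range(10):
            out = apoe_stratification(_mci_frame(40, 0.5, seed))
            row = out[out["variable"] == "index"].iloc[0]
            if row["median_z_carrier"] > row["median_z_noncarrier"]:
                wins += 1
        assert wins >= 9

    def test_empty_stratum_rejected(self):
        df = _mci_frame(10, 0.0, 2)
        df["apoe_e4"] = 1
        with pytest.raises(ValueError, match="stratum"):
            apoe_stratification(df)

    def test_missing_columns_rejected(self):
        df = _mci_frame(10, 0.0, 3).drop(columns=["mmse"])
        with pytest.raises(ValueError, match="mmse"):
            apoe_stratification(df)


class TestPatternAndAnova:
    def test_pattern_partition(self):
        longit = derive_longitudinal(
            _index_frame({f"s{i}": (v, v) for i, v in enumerate([0.2, 0.4, 0.6, 0.9])})
        )
        assert set(longit["pattern"]) == {"AD-like", "CTL-like"}
        assert (longit["pattern"] == "AD-like").sum() + (
            longit["pattern"] == "CTL-like"
        ).sum() == len(longit)

    def test_pattern_comparisons_runs(self, rng):
        longit = derive_longitudinal(
            _index_frame(
                {f"s{i}": (v, v + rng.normal(0.1, 0.05)) for i, v in
                 enumerate(rng.uniform(0, 1, size=40))}
            )
        )
        meta = pd.DataFrame(
            {"subject_id": longit["subject_id"], "dx": ["AD", "CTL"] * 20}
        )
        out = pattern_comparisons(longit, meta)
        assert set(out["dx"]) <= {"AD", "CTL"}
        assert ((out["p_value"] >= 0) & (out["p_value"] <= 1)).all()

    def test_rate_anova(self, rng):
        df = pd.DataFrame(
            {
                "dx": ["AD"] * 20 + ["CTL"] * 20,
                "annual_rate": np.r_[rng.normal(0.2, 0.05, 20), rng.normal(0.05, 0.05, 20)],
            }
        )
        out = rate_anova(df)
        assert out["p_value"] < 0.01


def test_type_one_error_calibration_smoke():
    """Short null-calibration run; the full 200-seed version is in the
    acceptance suite."""
    rej_rank, rej_paired = 0, 0
    n_rep = 50
    for seed in range(n_rep):
        rng = np.random.default_rng(1000 + seed)
        a, b = rng.normal(size=15), rng.normal(size=15)
        if rank_sum_test(a, b).p_value < 0.05:
            rej_rank += 1
        base = rng.normal(size=15)
        if paired_change_test(base, base + rng.normal(0, 1, 15))["t_p"] < 0.05:
            rej_paired += 1
    assert rej_rank <= 9
    assert rej_paired <= 9
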