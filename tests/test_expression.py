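import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import ecfoam as e


def _table(rows):
    return pd.DataFrame(rows, columns=["sample", "group", "gene", "replicate", "ct"])


class TestFoldChange:
    def test_reference_group_fold_is_exactly_one(self):
        t = e.generate_ct_table(
            e.CtSpec(log2_fold_changes={"MYC": {"foam": 2.0}}, seed=3)
        )
        fc = e.fold_change(t, "GAPDH", "bulk")
        ref = fc[fc.group == "bulk"]
        assert (ref.fold_change == 1.0).all()

    def test_delta_delta_ct_of_minus_one_doubles(self):
        rows = [
            ("b1", "bulk", "GAPDH", 1, 18.0), ("b1", "bulk", "MYC", 1, 22.0),
            ("f1", "foam", "GAPDH", 1, 18.0), ("f1", "foam", "MYC", 1, 21.0),
        ]
        fc = e.fold_change(_table(rows), "GAPDH", "bulk")
        foam = fc[(fc.gene == "MYC") & (fc.group == "foam")].iloc[0]
        assert foam.delta_delta_ct == -1.0 and foam.fold_change == 2.0

    def test_planted_log2fc_recovered_exactly_at_zero_noise(self):
        spec = e.CtSpec(
            log2_fold_changes={"MYC": {"foam": 1.5}},
            noise_sd_ct=0.0, sample_shift_sd=0.8, seed=2,
        )
        fc = e.fold_change(e.generate_ct_table(spec), "GAPDH", "bulk")
        got = fc[(fc.gene == "MYC") & (fc.group == "foam")].fold_change.iloc[0]
        assert got == pytest.approx(2**1.5, rel=1e-12)

    def test_invariant_to_per_sample_ct_shift(self):
        rows = [
            ("b1", "bulk", "GAPDH", 1, 18.0), ("b1", "bulk", "MYC", 1, 22.0),
            ("f1", "foam", "GAPDH", 1, 18.4), ("f1", "foam", "MYC", 1, 20.9),
        ]
        base = e.fold_change(_table(rows), "GAPDH", "bulk")
        shifted_rows = [
            (s, g, gene, r, ct + (3.3 if s == "f1" else -1.1))
            for s, g, gene, r, ct in rows
        ]
        shifted = e.fold_change(_table(shifted_rows), "GAPDH", "bulk")
        pd.testing.assert_frame_equal(base, shifted)

    def test_technical_replicates_averaged_per_sample(self):
        rows = [
            ("b1", "bulk", "GAPDH", 1, 18.0), ("b1", "bulk", "GAPDH", 2, 19.0),
            ("b1", "bulk", "MYC", 1, 22.0), ("b1", "bulk", "MYC", 2, 23.0),
            ("f1", "foam", "GAPDH", 1, 18.5), ("f1", "foam", "MYC", 1, 21.5),
        ]
        fc = e.fold_change(_table(rows), "GAPDH", "bulk")
        foam = fc[fc.group == "foam"].iloc[0]
        # bulk dCt = 22.5 - 18.5 = 4.0, foam dCt = 3.0 -> fold 2
        assert foam.fold_change == pytest.approx(2.0)

    def test_missing_housekeeping_names_sample(self):
        rows = [("b1", "bulk", "MYC", 1, 22.0), ("f1", "foam", "MYC", 1, 21.0),
                ("f1", "foam", "GAPDH", 1, 18.0)]
        with pytest.raises(ValueError, match="b1"):
            e.fold_change(_table(rows), "GAPDH", "bulk")

    def test_reference_group_is_mandatory(self):
        with pytest.raises(ValueError):
            e.fold_change(_table([("b1", "bulk", "GAPDH", 1, 18.0)]), "GAPDH")


class TestSpearmanTrend:
    def test_strictly_increasing_n4(self):
        r = e.spearman_trend([1.0, 2.0, 3.0, 4.0])
        assert r.rho == pytest.approx(1.0)
        assert r.p_value == pytest.approx(1 / 24)
        assert r.passes_screen

    def test_strictly_decreasing_fails_screen(self):
        r = e.spearman_trend([4.0, 3.0, 2.0, 1.0])
        assert r.rho == pytest.approx(-1.0) and not r.passes_screen

    def test_one_inversion_rho_08(self):
        r = e.spearman_trend([1.0, 2.0, 4.0, 3.0])
        assert r.rho == pytest.approx(0.8)
        assert not r.passes_screen  # rho threshold 0.9 not exceeded

    def test_all_tied_reported_not_passing(self):
        r = e.spearman_trend([5.0, 5.0, 5.0, 5.0])
        assert r.all_tied and not r.passes_screen and np.isnan(r.rho)

    def test_exact_p_matches_enumeration_oracle(self):
        # independent oracle: enumerate all orderings, count rho >= observed
        values = [2.0, 1.0, 3.0, 5.0, 4.0]
        obs = stats.spearmanr(range(5), values).statistic
        count = sum(
            stats.spearmanr(range(5), perm).statistic >= obs - 1e-12
            for perm in itertools.permutations(values)
        )
        expected = count / math.factorial(5)
        assert e.spearman_trend(values).p_value == pytest.approx(expected)

    def test_permutation_p_values_are_uniform_over_orbits(self):
        # exact p of the maximal ordering times n! counts one permutation
        r = e.spearman_trend([1.0, 2.0, 3.0])
        assert r.p_value == pytest.approx(1 / 6)

    def test_null_pass_rate_is_one_in_24(self):
        rng = np.random.default_rng(17)
        n_draws = 10_000
        passes = sum(
            e.spearman_trend(rng.permutation(4).astype(float)).passes_screen
            for _ in range(n_draws)
        )
        p0 = 1 / 24
        se = np.sqrt(p0 * (1 - p0) / n_draws)
        assert abs(passes / n_draws - p0) < 3 * se

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError):
            e.spearman_trend([1.0, 2.0])


class TestKsTwoSample:
    def test_identical_samples_d_zero(self):
        r = e.ks_two_sample([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert r.statistic == 0.0

    def test_disjoint_supports_d_one(self):
        r = e.ks_two_sample([1.0, 2.0], [10.0, 11.0])
        assert r.statistic == 1.0 and r.p_value < 0.5

    def test_symmetry(self):
        a, b = [1.0, 3.0, 5.0, 9.0], [2.0, 4.0, 6.0]
        assert e.ks_two_sample(a, b).statistic == e.ks_two_sample(b, a).statistic

    def test_monotone_transform_invariance(self):
        a, b = [1.0, 3.0, 5.0, 9.0], [2.0, 4.0, 6.0, 8.0]
        r1 = e.ks_two_sample(a, b)
        r2 = e.ks_two_sample(np.exp(a), np.exp(b))
        assert r1.statistic == r2.statistic and r1.p_value == r2.p_value

    def test_small_n_matches_enumeration_oracle(self):
        # brute-force D over all ECDF step points and exact p over all
        # C(8,4) equally likely rank assignments under the null
        a = np.array([0.3, 1.2, 2.5, 4.0])
        b = np.array([0.8, 1.9, 3.1, 5.5])

        def ks_d(x, y):
            pts = np.concatenate([x, y])
            return max(
                abs(np.mean(x <= t) - np.mean(y <= t)) for t in pts
            )

        d_obs = ks_d(a, b)
        pooled = np.concatenate([a, b])
        n = len(a)
        count = total = 0
        for idx in itertools.combinations(range(len(pooled)), n):
            mask = np.zeros(len(pooled), bool)
            mask[list(idx)] = True
            d = ks_d(pooled[mask], pooled[~mask])
            count += d >= d_obs - 1e-12
            total += 1
        r = e.ks_two_sample(a, b)
        assert r.statistic == pytest.approx(d_obs)
        assert r.p_value == pytest.approx(count / total)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            e.ks_two_sample([], [1.0])


class TestGroupTests:
    def test_two_identical_groups(self):
        r = e.group_tests({"a": [1.0, 2.0, 3.0], "b": [1.0, 2.0, 3.0]})
        assert r[0].test == "t" and r[0].p_value == pytest.approx(1.0)
        assert r[0].tier == ""

    def test_shifted_group_flagged_by_tukey_only(self):
        rng = np.random.default_rng(0)
        base = rng.normal(0, 0.01, 5)
        groups = {"a": base, "b": base + rng.normal(0, 0.01, 5), "c": base + 10}
        results = e.group_tests(groups)
        anova = results[0]
        assert anova.test == "ANOVA" and anova.tier == "***"
        tukey = {r.comparison: r for r in results[1:]}
        assert tukey["a_vs_b"].tier == ""
        assert tukey["a_vs_c"].tier == "***" and tukey["b_vs_c"].tier == "***"

    def test_t_test_agrees_with_permutation_oracle(self):
        # exact permutation reference on overlapping small samples; the
        # Student p can differ by at most the permutation granularity
        a = np.array([1.0, 2.0, 4.0, 6.0, 7.0])
        b = np.array([3.0, 5.0, 8.0, 9.0, 10.0])
        res = stats.permutation_test(
            (a, b), lambda x, y, axis=-1: np.mean(x, axis=axis) - np.mean(y, axis=axis),
            permutation_type="independent", n_resamples=np.inf,
        )
        t = e.group_tests({"a": a, "b": b})[0]
        assert abs(t.p_value - res.pvalue) < 0.05

    def test_small_group_rejected(self):
        with pytest.raises(ValueError):
            e.group_tests({"a": [1.0], "b": [1.0, 2.0]})

    @pytest.mark.parametrize(
        "p,tier", [(0.04, "*"), (0.004, "**"), (0.0004, "***"), (0.2, "")]
    )
    def test_significance_tiers(self, p, tier):
        assert e.significance_tier(p) == tier


class TestScreenTrends:
    def test_many_features_and_bh_option(self):
        feats = {"up": [1.0, 2.0, 3.0, 4.0], "down": [4.0, 3.0, 2.0, 1.0],
                 "flat": [1.0, 1.0, 1.0, 1.0]}
        out = e.screen_trends(feats)
        assert out.set_index("feature").passes_screen.to_dict() == {
            "up": True, "down": False, "flat": False
        }
        bh = e.screen_trends(feats, fdr=True)
        assert "p_adjusted" in bh.columns
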