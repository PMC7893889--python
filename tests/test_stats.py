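"""Error-decomposition estimators and hypothesis tests vs oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from fidburn import (
    StudyDesign,
    ioe_summary,
    levene_nonparametric,
    paired_wilcoxon,
    population_errors,
    registration_difference_stats,
    simulate_registration_study,
)
from fidburn.stats import PARAM_COLUMNS


def records_from_values(values_by_patient, workflow="wf", param="tRL_mm"):
    """Minimal record table with one informative parameter."""
    rows = []
    for pat, vals in values_by_patient.items():
        for i, v in enumerate(vals):
            row = {"patient_id": pat, "rater_or_fraction_id": f"F{i}",
                   "workflow": workflow}
            row.update({p: 0.0 for p in PARAM_COLUMNS})
            row[param] = v
            rows.append(row)
    return pd.DataFrame(rows)


def enumeration_wilcoxon(d):
    """Oracle: exact two-sided p by enumerating all sign assignments."""
    d = np.asarray(d, dtype=float)
    d = d[d != 0]
    ranks = sps.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    ws = [
        sum(r for r, s in zip(ranks, signs) if s)
        for signs in itertools.product([False, True], repeat=len(d))
    ]
    ws = np.array(ws)
    p_le = np.mean(ws <= w_obs + 1e-9)
    p_ge = np.mean(ws >= w_obs - 1e-9)
    return min(1.0, 2 * min(p_le, p_ge))


class TestPairedWilcoxon:
    def test_equal_samples_degenerate(self):
        res = paired_wilcoxon([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.pvalue == 1.0 and res.degenerate

    def test_five_positive_distinct_differences(self):
        res = paired_wilcoxon(np.array([1.0, 2.0, 3.0, 4.0, 5.0]),
                              np.zeros(5))
        assert res.method == "exact"
        assert res.pvalue == pytest.approx(0.0625, abs=1e-15)

    @pytest.mark.parametrize("seed", range(5))
    def test_exact_matches_sign_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        # integer-valued differences force ties, exercising midranks
        d = rng.integers(-4, 5, size=12).astype(float)
        if np.all(d == 0):
            d[0] = 1.0
        res = paired_wilcoxon(d)
        assert res.method == "exact"
        assert res.pvalue == pytest.approx(enumeration_wilcoxon(d), abs=1e-12)

    def test_symmetry_in_arguments(self, rng):
        x = rng.normal(size=20)
        y = rng.normal(size=20)
        assert paired_wilcoxon(x, y).pvalue == pytest.approx(
            paired_wilcoxon(y, x).pvalue, abs=1e-12
        )

    def test_normal_approximation_matches_scipy_on_tie_free_data(self, rng):
        d = rng.normal(0.3, 1.0, size=40)  # continuous: no ties, no zeros
        res = paired_wilcoxon(d)
        assert res.method == "normal"
        ref = sps.wilcoxon(d, correction=True, mode="approx")
        assert res.pvalue == pytest.approx(ref.pvalue, rel=1e-9)


class TestLeveneNonparametric:
    def test_identical_groups(self):
        res = levene_nonparametric([1.0, 2, 3, 4], [1.0, 2, 3, 4])
        assert res.statistic == 0.0 and res.pvalue == 1.0

    def test_hand_computed_anova_example(self):
        # |dev from median|: {1.5, .5, .5, 1.5} and {15, 5, 5, 15}
        # between-group SS = 162, within = 101 -> F = 972/101 on (1, 6) df
        res = levene_nonparametric([1.0, 2, 3, 4], [10.0, 20, 30, 40])
        f_expected = 972.0 / 101.0
        assert res.statistic == pytest.approx(f_expected, rel=1e-12)
        assert res.pvalue == pytest.approx(sps.f.sf(f_expected, 1, 6), rel=1e-12)

    def test_all_zero_deviations_degenerate(self):
        res = levene_nonparametric([2.0, 2.0, 2.0], [5.0, 5.0, 5.0])
        assert res.degenerate and res.pvalue == 1.0

    def test_power_at_sd_ratio_3_pooled_design(self):
        # 200 seeded replicates of two n=140 groups with SD ratio 3:
        # the test should reject at p < 0.001 in at least 95% of them
        n_reject = 0
        for rep in range(200):
            rng = np.random.default_rng(1000 + rep)
            a = rng.normal(0, 0.87, 140)
            b = rng.normal(0, 0.25, 140)
            if levene_nonparametric(a, b).pvalue < 0.001:
                n_reject += 1
        assert n_reject >= 190

    def test_rank_variant_runs_and_detects_spread(self, rng):
        a = rng.normal(0, 3.0, 100)
        b = rng.normal(0, 1.0, 100)
        res = levene_nonparametric(a, b, variant="rank")
        assert res.pvalue < 0.01


class TestPopulationErrors:
    def test_constant_records(self):
        rec = records_from_values({"P1": [2.0, 2.0], "P2": [2.0, 2.0]})
        t = population_errors(rec).table.loc["tRL_mm"]
        assert t["mean"] == 2.0 and t["systematic"] == 0.0 and t["random"] == 0.0

    def test_two_patient_hand_computation(self):
        rec = records_from_values({"P1": [0.0, 0.0], "P2": [2.0, 2.0]})
        t = population_errors(rec).table.loc["tRL_mm"]
        assert t["mean"] == pytest.approx(1.0)
        assert t["systematic"] == pytest.approx(np.sqrt(2.0))
        assert t["random"] == 0.0

    def test_single_record_patient_excluded_from_random(self):
        rec = records_from_values({"P1": [1.0, 3.0], "P2": [10.0]})
        res = population_errors(rec)
        assert res.n_excluded == 1
        t = res.table.loc["tRL_mm"]
        assert t["mean"] == pytest.approx((2.0 + 10.0) / 2)
        assert t["random"] == pytest.approx(np.sqrt(2.0))  # only P1's SD

    def test_recovers_generator_at_cohort_scale(self):
        # cohort of 26 patients x 24 records from the position-verification
        # RL generating parameters (M=-0.2, Sigma=2.8, sigma=3.3 mm)
        design = StudyDesign(
            n_patients=26, n_raters_or_fractions=24,
            population_mean=np.full(6, -0.2), systematic_sd=np.full(6, 2.8),
            random_sd=np.full(6, 3.3), seed=11,
        )
        t = population_errors(simulate_registration_study(design)).table
        se_sigma_sys = 2.8 / np.sqrt(2 * (26 - 1))
        se_sigma_rand = 3.3 / np.sqrt(2 * 26 * (24 - 1))
        for p in PARAM_COLUMNS:
            assert abs(t.loc[p, "systematic"] - 2.8) < 3 * se_sigma_sys
            assert abs(t.loc[p, "random"] - 3.3) < 3 * se_sigma_rand

    def test_consistency_at_large_n(self):
        design = StudyDesign(
            n_patients=2000, n_raters_or_fractions=50,
            population_mean=np.zeros(6), systematic_sd=np.ones(6),
            random_sd=np.full(6, 2.0), seed=3,
        )
        t = population_errors(simulate_registration_study(design)).table
        # the SD of patient means estimates sqrt(Sigma^2 + sigma^2/m): the
        # per-fraction noise inflates the per-patient means by sigma^2/m
        sys_limit = np.sqrt(1.0 + 2.0**2 / 50)
        assert np.all(np.abs(t["systematic"] - sys_limit) < 0.05)
        assert np.all(np.abs(t["random"] - 2.0) < 0.05)

    def test_invariant_to_record_order(self, rng):
        design = StudyDesign(n_patients=5, n_raters_or_fractions=4,
                             random_sd=np.ones(6), systematic_sd=np.ones(6),
                             seed=9)
        rec = simulate_registration_study(design)
        shuffled = rec.sample(frac=1.0, random_state=1).reset_index(drop=True)
        pd.testing.assert_frame_equal(
            population_errors(rec).table, population_errors(shuffled).table
        )


class TestIoeSummary:
    def test_identical_observers_give_zero_iqr_and_sd(self):
        rec = pd.concat([
            records_from_values({"P1": [1.0] * 3, "P2": [2.0] * 3}, workflow="A"),
            records_from_values({"P1": [5.0] * 3, "P2": [0.0] * 3}, workflow="B"),
        ])
        res = ioe_summary(rec, workflows=("A", "B"))
        row = res.table.loc["tRL_mm"]
        assert row["mean_iqr_A"] == 0.0 and row["pooled_sd_A"] == 0.0

    def test_iqr_uses_linear_interpolation_quantiles(self):
        rec = pd.concat([
            records_from_values({"P1": [1.0, 2, 3, 4, 5, 6, 7]}, workflow="A"),
            records_from_values({"P1": [0.0] * 7}, workflow="B"),
        ])
        res = ioe_summary(rec, workflows=("A", "B"))
        # {1..7}: Q1=2.5, Q3=5.5 under the type-7 rule
        assert res.table.loc["tRL_mm", "mean_iqr_A"] == pytest.approx(3.0)

    def test_pooled_sd_invariant_to_per_patient_shifts(self, rng):
        base = records_from_values(
            {f"P{i}": rng.normal(0, 1, 7).tolist() for i in range(6)}, workflow="A"
        )
        other = records_from_values(
            {f"P{i}": rng.normal(0, 1, 7).tolist() for i in range(6)}, workflow="B"
        )
        rec = pd.concat([base, other], ignore_index=True)
        res1 = ioe_summary(rec, workflows=("A", "B"))
        shifted = rec.copy()
        offsets = {f"P{i}": 100.0 * i for i in range(6)}
        shifted["tRL_mm"] += shifted["patient_id"].map(offsets)
        res2 = ioe_summary(shifted, workflows=("A", "B"))
        assert res1.table.loc["tRL_mm", "pooled_sd_A"] == pytest.approx(
            res2.table.loc["tRL_mm", "pooled_sd_A"]
        )

    def test_recovers_observer_scatter_of_the_two_workflows(self):
        # 20 patients x 7 observers with RL observer SDs 0.87 vs 0.25 mm:
        # pooled SDs recovered within 3 SE and spread difference detected
        common = dict(n_patients=20, n_raters_or_fractions=7,
                      population_mean=np.zeros(6),
                      systematic_sd=np.full(6, 2.0))
        rec = pd.concat([
            simulate_registration_study(
                StudyDesign(**common, random_sd=np.full(6, 0.87), seed=21),
                workflow="CT/MR"),
            simulate_registration_study(
                StudyDesign(**common, random_sd=np.full(6, 0.25), seed=22),
                workflow="MR-only"),
        ], ignore_index=True)
        res = ioe_summary(rec, workflows=("CT/MR", "MR-only"))
        row = res.table.loc["tRL_mm"]
        df_pool = 20 * (7 - 1)
        assert abs(row["pooled_sd_CT/MR"] - 0.87) < 3 * 0.87 / np.sqrt(2 * df_pool)
        assert abs(row["pooled_sd_MR-only"] - 0.25) < 3 * 0.25 / np.sqrt(2 * df_pool)
        assert row["p_group"] < 0.05
        assert row["p_patient"] < 0.05

    def test_requires_two_observers_per_patient(self):
        rec = pd.concat([
            records_from_values({"P1": [1.0]}, workflow="A"),
            records_from_values({"P1": [1.0, 2.0]}, workflow="B"),
        ])
        with pytest.raises(ValueError, match="need >= 2"):
            ioe_summary(rec, workflows=("A", "B"))


class TestRegistrationDifferenceStats:
    def _paired(self, shift=0.0, workflow_b_vals=None):
        vals = {"P1": [0.5, 1.0, -0.5], "P2": [0.2, -0.2, 0.0]}
        a = records_from_values(vals, workflow="sCT")
        b = records_from_values(
            workflow_b_vals if workflow_b_vals is not None else vals, workflow="CT"
        )
        a["tRL_mm"] += shift
        return pd.concat([a, b], ignore_index=True)

    def test_identical_workflows_give_all_zero(self):
        res = registration_difference_stats(self._paired(), workflows=("sCT", "CT"))
        t = res.table.loc["tRL_mm"]
        assert t["mean"] == 0.0 and t["systematic"] == 0.0 and t["random"] == 0.0

    def test_constant_offset_appears_in_mean_only(self):
        res = registration_difference_stats(
            self._paired(shift=0.7), workflows=("sCT", "CT")
        )
        t = res.table.loc["tRL_mm"]
        assert t["mean"] == pytest.approx(0.7)
        assert t["systematic"] == pytest.approx(0.0, abs=1e-12)
        assert t["random"] == pytest.approx(0.0, abs=1e-12)

    def test_unpaired_fractions_excluded_and_counted(self):
        rec = self._paired()
        rec = rec.drop(rec[(rec.workflow == "CT") & (rec.patient_id == "P2")
                           & (rec.rater_or_fraction_id == "F2")].index)
        res = registration_difference_stats(rec, workflows=("sCT", "CT"))
        assert res.n_excluded == 1

    def test_recovers_difference_error_structure(self):
        # differences drawn with Sigma=0.2, sigma=0.3 mm (RL translation
        # scale of the workflow-difference decomposition)
        design = StudyDesign(
            n_patients=26, n_raters_or_fractions=24,
            population_mean=np.zeros(6), systematic_sd=np.full(6, 0.2),
            random_sd=np.full(6, 0.3), seed=5,
        )
        diff = simulate_registration_study(design, workflow="sCT")
        zero = diff.copy()
        zero[PARAM_COLUMNS] = 0.0
        zero["workflow"] = "CT"
        res = registration_difference_stats(
            pd.concat([diff, zero], ignore_index=True), workflows=("sCT", "CT")
        )
        t = res.table.loc["tRL_mm"]
        # SD of patient means estimates sqrt(Sigma^2 + sigma^2/m)
        sys_limit = np.sqrt(0.2**2 + 0.3**2 / 24)
        assert abs(t["systematic"] - sys_limit) < 3 * sys_limit / np.sqrt(2 * 25)
        assert abs(t["random"] - 0.3) < 3 * 0.3 / np.sqrt(2 * 26 * 23)
        assert res.pvalues is not None and len(res.pvalues) == 6
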