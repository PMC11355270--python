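"""Eligibility filtering, eye selection and two-group statistics."""

import numpy as np
import pandas as pd
import pytest

from octaquant import (
    GroupSummary,
    adjusted_group_difference,
    apply_exclusions,
    build_comparison_tables,
    chi_square_2x2,
    generate_cohort,
    select_random_eye,
    spherical_equivalent,
    t_test_from_raw,
    t_test_from_summary,
    table_preset,
)
from octaquant.errors import DegenerateInputError, SingularDesignError, ValidationError


class TestSphericalEquivalent:
    @pytest.mark.parametrize(
        "sphere, cyl, expected", [(0, 0, 0), (-2.0, -1.0, -2.5), (1.0, -0.5, 0.75)]
    )
    def test_formula(self, sphere, cyl, expected):
        assert spherical_equivalent(sphere, cyl) == pytest.approx(expected)


class TestExclusions:
    def frame(self, **cols):
        base = dict(
            participant_id=["p1", "p2", "p3"],
            signal_strength=[9, 9, 9],
            motion=[False] * 3,
            floater=[False] * 3,
            misalignment=[False] * 3,
            segmentation=[False] * 3,
        )
        base.update(cols)
        return pd.DataFrame(base)

    def test_low_signal_excluded_at_boundary(self):
        kept, excl = apply_exclusions(self.frame(signal_strength=[5, 6, 7]))
        assert list(kept["participant_id"]) == ["p2", "p3"]
        assert list(excl["exclusion_reason"]) == ["signal_strength"]

    def test_quality_flag_wins_reason(self):
        kept, excl = apply_exclusions(self.frame(motion=[True, False, False]))
        assert list(excl["exclusion_reason"]) == ["motion"]
        assert len(kept) == 2

    def test_clean_records_kept(self):
        kept, excl = apply_exclusions(self.frame())
        assert len(kept) == 3 and len(excl) == 0


class TestRandomEyeSelection:
    def test_single_eye_returned(self):
        assert select_random_eye(["OD"], "p1", seed=0) == "OD"

    def test_zero_eyes_dropped(self):
        assert select_random_eye([], "p1", seed=0) is None

    def test_reproducible(self):
        picks = {select_random_eye(["OD", "OS"], "p7", seed=42) for _ in range(5)}
        assert len(picks) == 1

    def test_balanced_across_participants(self):
        choices = [
            select_random_eye(["OD", "OS"], f"participant{i}", seed=1) for i in range(1000)
        ]
        frac_od = np.mean([c == "OD" for c in choices])
        assert frac_od == pytest.approx(0.5, abs=0.05)


class TestTTest:
    def test_axial_length_groups_significant(self):
        res = t_test_from_summary(GroupSummary(24.7, 1.5, 92), GroupSummary(23.2, 0.9, 99))
        assert res.p_value < 0.001
        assert res.df == 189

    def test_identical_summaries(self):
        res = t_test_from_summary(GroupSummary(5, 1, 10), GroupSummary(5, 1, 10))
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_scp_groups_closed_form(self):
        res = t_test_from_summary(GroupSummary(42.4, 2.6, 92), GroupSummary(40.9, 2.5, 99))
        assert res.statistic == pytest.approx(4.06, abs=0.01)
        assert res.p_value < 0.001

    def test_antisymmetric_in_group_order(self):
        g1, g2 = GroupSummary(10.0, 2.0, 30), GroupSummary(11.5, 2.5, 40)
        a, b = t_test_from_summary(g1, g2), t_test_from_summary(g2, g1)
        assert a.statistic == pytest.approx(-b.statistic)
        assert a.p_value == pytest.approx(b.p_value)

    def test_raw_equals_summary_path(self):
        rng = np.random.default_rng(0)
        x, y = rng.normal(0, 1, 40), rng.normal(0.5, 1.2, 50)
        raw = t_test_from_raw(x, y)
        summ = t_test_from_summary(GroupSummary.from_raw(x), GroupSummary.from_raw(y))
        assert raw.statistic == pytest.approx(summ.statistic, abs=1e-12)
        assert raw.p_value == pytest.approx(summ.p_value, abs=1e-12)

    def test_zero_variance_unequal_means(self):
        with pytest.warns(UserWarning):
            res = t_test_from_summary(GroupSummary(1, 0, 5), GroupSummary(2, 0, 5))
        assert res.p_value == 0.0

    def test_welch_differs_under_unequal_variance(self):
        g1, g2 = GroupSummary(10, 1.0, 20), GroupSummary(11, 5.0, 80)
        pooled = t_test_from_summary(g1, g2, equal_var=True)
        welch = t_test_from_summary(g1, g2, equal_var=False)
        assert pooled.p_value != pytest.approx(welch.p_value, rel=1e-3)


class TestChiSquare:
    def test_sex_counts(self):
        assert chi_square_2x2(63, 29, 63, 36).p_value == pytest.approx(0.480, abs=5e-4)

    def test_diabetes_counts(self):
        assert chi_square_2x2(92, 0, 97, 2).p_value == pytest.approx(0.171, abs=5e-4)

    def test_hypertension_counts(self):
        assert chi_square_2x2(75, 17, 88, 11).p_value == pytest.approx(0.150, abs=5e-4)

    def test_no_association(self):
        res = chi_square_2x2(10, 10, 10, 10)
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_invariant_to_transpose_and_group_swap(self):
        a = chi_square_2x2(12, 5, 30, 21)
        assert chi_square_2x2(12, 30, 5, 21).p_value == pytest.approx(a.p_value)
        assert chi_square_2x2(30, 21, 12, 5).p_value == pytest.approx(a.p_value)

    def test_zero_margin(self):
        with pytest.raises(DegenerateInputError):
            chi_square_2x2(0, 0, 5, 5)


def _simulate_table(rng, n=200, effect=2.0):
    group = rng.integers(0, 2, n).astype(float)
    age = rng.normal(43, 13, n)
    covar = rng.normal(0, 1, n)
    outcome = effect * group + 0.05 * age + 0.8 * covar + rng.normal(0, 1, n)
    return pd.DataFrame({"y": outcome, "group": group, "age": age, "covar": covar})


class TestAdjustedDifference:
    def test_recovers_planted_effect(self):
        rng = np.random.default_rng(5)
        hits = 0
        for _ in range(100):
            tab = _simulate_table(rng)
            res = adjusted_group_difference(tab, "y", "group", ["age", "covar"])
            se = abs(res.estimate / res.statistic)
            hits += abs(res.estimate - 2.0) <= 3 * se
        assert hits >= 99

    def test_matches_mean_difference_without_covariates(self):
        rng = np.random.default_rng(6)
        tab = _simulate_table(rng)
        res = adjusted_group_difference(tab, "y", "group", [])
        diff = tab.loc[tab.group == 1, "y"].mean() - tab.loc[tab.group == 0, "y"].mean()
        assert res.estimate == pytest.approx(diff, abs=1e-9)

    def test_zero_variance_covariate_singular(self):
        rng = np.random.default_rng(7)
        tab = _simulate_table(rng)
        tab["flat"] = 3.0
        with pytest.raises(SingularDesignError, match="flat"):
            adjusted_group_difference(tab, "y", "group", ["age", "flat"])


@pytest.fixture(scope="module")
def cohort():
    tab = generate_cohort(table_preset(seed=20))
    tab["diabetes"] = tab["diabetes"].astype(bool)
    tab["hypertension"] = tab["hypertension"].astype(bool)
    return tab


class TestComparisonTables:

    def test_group_means_near_generator_values(self, cohort):
        t1, t2 = build_comparison_tables(cohort)
        scp = t2.set_index("metric").loc["pd_scp_pct"]
        # Caucasian sorts before Chinese, so g1 = Caucasian (40.9), g2 = Chinese (42.4)
        sem = 2.6 / np.sqrt(92)
        assert scp["mean_g2"] == pytest.approx(42.4, abs=2 * sem)
        assert scp["mean_g1"] == pytest.approx(40.9, abs=2 * 2.5 / np.sqrt(99))
        assert len(t2) == 13

    def test_identical_groups_rarely_significant(self):
        from octaquant import null_preset

        sig = []
        for seed in range(30):
            tab = generate_cohort(null_preset(seed=seed))
            _, t2 = build_comparison_tables(tab)
            sig.append((t2["p_value"] < 0.05).mean())
        assert np.mean(sig) < 0.15  # near the nominal 5% false-positive rate

    def test_single_group_rejected(self, cohort):
        solo = cohort[cohort["ethnicity"] == "Chinese"]
        with pytest.raises(ValidationError):
            build_comparison_tables(solo)
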