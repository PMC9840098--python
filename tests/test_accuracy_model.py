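"""Misclassification propagation: closed form vs expected-count cross-tabulation."""

from random import Random

import pytest

from pddi.accuracy_model import (
    DEFAULT_PREVALENCE,
    ApparentAccuracy,
    MatchingScenario,
    ScreeningScenario,
    UndefinedMetricError,
    apparent_case_control_or,
    apparent_cohort_rr,
    apparent_screening_accuracy,
    round_half_up,
    scenario_table,
    true_ppv,
)

S90 = ScreeningScenario(se_s=0.9, sp_s=0.9)
S60 = ScreeningScenario(se_s=0.6, sp_s=0.9)


def crosstab_oracle(s: ScreeningScenario, m: MatchingScenario, n: float = 1e7):
    """Independent oracle: explicit 2x2x2 expected-count table, cross-tabulated.

    Population stratified by (disease, screen result, linked status) with
    linkage independent of the screen result; apparent accuracy read off
    the margins, exactly as a cohort analysis would.
    """
    p = s.prevalence
    cells = {}
    for disease in (1, 0):
        n_d = n * (p if disease else 1 - p)
        for screen in (1, 0):
            pr_screen = (s.se_s if screen else 1 - s.se_s) if disease else (
                1 - s.sp_s if screen else s.sp_s
            )
            for linked in (1, 0):
                pr_link = (m.se_m if linked else 1 - m.se_m) if disease else (
                    1 - m.sp_m if linked else m.sp_m
                )
                cells[disease, screen, linked] = n_d * pr_screen * pr_link
    linked_pos = sum(cells[d, sc, 1] for d in (0, 1) for sc in (0, 1))
    linked_neg = sum(cells[d, sc, 0] for d in (0, 1) for sc in (0, 1))
    screen_pos = sum(cells[d, 1, li] for d in (0, 1) for li in (0, 1))
    se = sum(cells[d, 1, 1] for d in (0, 1)) / linked_pos
    sp = sum(cells[d, 0, 0] for d in (0, 1)) / linked_neg
    ppv = sum(cells[d, 1, 1] for d in (0, 1)) / screen_pos
    return 100 * se, 100 * sp, 100 * ppv


class TestReferenceCells:
    """Every non-identity scenario cell of the built-in grid."""

    @pytest.mark.parametrize(
        "scenario,se_m,sp_m,field,expected",
        [
            (S90, 0.90, 1.0, "specificity", 89.94),
            (S90, 0.85, 1.0, "specificity", 89.91),
            (S90, 0.50, 1.0, "specificity", 89.69),
            (S90, 1.0, 0.9999, "sensitivity", 88.99),
            (S90, 1.0, 0.999, "sensitivity", 80.93),
            (S90, 1.0, 0.998, "sensitivity", 73.70),
            (S60, 0.90, 1.0, "specificity", 89.96),
            (S60, 0.85, 1.0, "specificity", 89.94),
            (S60, 0.50, 1.0, "specificity", 89.81),
            (S60, 1.0, 0.9999, "sensitivity", 59.37),
            (S60, 1.0, 0.999, "sensitivity", 54.33),
            (S60, 1.0, 0.998, "sensitivity", 49.81),
            (S90, 0.90, 1.0, "ppv", 5.92),
            (S90, 0.85, 1.0, "ppv", 5.59),
            (S90, 0.50, 1.0, "ppv", 3.29),
            (S90, 1.0, 0.9999, "ppv", 6.58),
            (S90, 1.0, 0.999, "ppv", 6.67),
            (S90, 1.0, 0.998, "ppv", 6.76),
            (S60, 0.90, 1.0, "ppv", 4.03),
            (S60, 0.85, 1.0, "ppv", 3.81),
            (S60, 0.50, 1.0, "ppv", 2.24),
            (S60, 1.0, 0.9999, "ppv", 4.49),
            (S60, 1.0, 0.999, "ppv", 4.58),
            (S60, 1.0, 0.998, "ppv", 4.67),
        ],
    )
    def test_grid_cell(self, scenario, se_m, sp_m, field, expected):
        app = apparent_screening_accuracy(scenario, MatchingScenario(se_m, sp_m))
        assert getattr(app, field) == expected

    def test_breast_experimental_accuracies(self):
        app = apparent_screening_accuracy(S90, MatchingScenario(0.8871, 0.998))
        assert (app.sensitivity, app.specificity, app.ppv) == (72.09, 89.93, 6.02)
        app = apparent_screening_accuracy(S90, MatchingScenario(0.8226, 1.0))
        assert (app.sensitivity, app.specificity, app.ppv) == (90.00, 89.89, 5.41)
        app = apparent_screening_accuracy(S60, MatchingScenario(0.8871, 0.998))
        assert (app.sensitivity, app.specificity) == (48.81, 89.96)

    def test_true_ppv_values(self):
        assert true_ppv(S90) == 6.6
        assert true_ppv(S60) == 4.5
        assert true_ppv(ScreeningScenario(se_s=0.9, sp_s=1.0)) == 100.0


class TestBoundaryIdentities:
    def test_perfect_matching_is_identity(self):
        app = apparent_screening_accuracy(S90, MatchingScenario(1.0, 1.0))
        assert (app.sensitivity, app.specificity) == (90.0, 90.0)
        assert app.ppv == true_ppv(S90, ndigits=2)

    def test_perfect_matching_sensitivity_leaves_specificity(self):
        for sp_m in (0.999, 0.99, 0.9):
            app = apparent_screening_accuracy(S90, MatchingScenario(1.0, sp_m))
            assert app.specificity == 90.0
            assert app.specificity_unaffected

    def test_perfect_matching_specificity_leaves_sensitivity(self):
        for se_m in (0.9, 0.5, 0.8226):
            app = apparent_screening_accuracy(S90, MatchingScenario(se_m, 1.0))
            assert app.sensitivity == 90.0
            assert app.sensitivity_unaffected


class TestOracleEquivalence:
    def test_closed_form_matches_crosstab_on_random_scenarios(self):
        rng = Random(2024)
        for _ in range(100):
            s = ScreeningScenario(
                se_s=rng.uniform(0.3, 0.99),
                sp_s=rng.uniform(0.3, 0.99),
                prevalence=rng.uniform(1e-4, 0.2),
            )
            m = MatchingScenario(rng.uniform(0.3, 1.0), rng.uniform(0.9, 1.0))
            se, sp, ppv = crosstab_oracle(s, m)
            app = apparent_screening_accuracy(s, m)
            assert app.sensitivity == pytest.approx(se, abs=5.1e-3)
            assert app.specificity == pytest.approx(sp, abs=5.1e-3)
            assert app.ppv == pytest.approx(ppv, abs=5.1e-3)

    def test_cohort_size_invariance(self):
        small = ScreeningScenario(0.9, 0.9, cohort_size=1_000)
        large = ScreeningScenario(0.9, 0.9, cohort_size=1_000_000)
        m = MatchingScenario(0.8871, 0.998)
        assert apparent_screening_accuracy(small, m) == apparent_screening_accuracy(large, m)


class TestMonotonicity:
    def test_apparent_sensitivity_decreases_with_matching_specificity(self):
        values = [
            apparent_screening_accuracy(S90, MatchingScenario(1.0, sp_m)).sensitivity
            for sp_m in (1.0, 0.9999, 0.999, 0.998)
        ]
        assert values == sorted(values, reverse=True) and len(set(values)) == 4

    def test_apparent_specificity_decreases_with_matching_sensitivity(self):
        values = [
            apparent_screening_accuracy(S90, MatchingScenario(se_m, 1.0)).specificity
            for se_m in (1.0, 0.9, 0.85, 0.5)
        ]
        assert values == sorted(values, reverse=True) and len(set(values)) == 4


class TestEpidemiologicalMeasures:
    def test_rr_unchanged_when_matching_specificity_perfect(self):
        for se_m in (0.9, 0.5):
            rr = apparent_cohort_rr(2.0, 0.007757, MatchingScenario(se_m, 1.0))
            assert rr == pytest.approx(2.0)

    def test_rr_attenuated_by_imperfect_specificity(self):
        rr = apparent_cohort_rr(2.0, 0.007757, MatchingScenario(0.8871, 0.998))
        assert 1.0 < rr < 2.0

    def test_or_identity_and_fixed_point(self):
        m = MatchingScenario(0.9, 0.99)
        assert apparent_case_control_or(3.0, 0.1, MatchingScenario(1, 1)) == pytest.approx(3.0)
        assert apparent_case_control_or(1.0, 0.1, m) == pytest.approx(1.0)

    def test_or_attenuated_toward_null(self):
        or_app = apparent_case_control_or(3.0, 0.1, MatchingScenario(0.9, 0.99))
        assert 1.0 < or_app < 3.0


class TestScenarioTable:
    def test_sixteen_rows(self):
        assert len(scenario_table()) == 16

    def test_identity_cells_flagged_na(self):
        rows = scenario_table()
        for row in rows:
            if row["experimental"]:
                assert row["screening_sensitivity_estimate"] is not None
                assert row["screening_specificity_estimate"] is not None
            else:
                assert (row["matching_specificity"] == 100.0) == (
                    row["screening_sensitivity_estimate"] is None
                )
                assert (row["matching_sensitivity"] == 100.0) == (
                    row["screening_specificity_estimate"] is None
                )

    def test_reference_row_values(self):
        rows = scenario_table()
        first = rows[0]  # matching 90/100 on the 90/90 scenario
        assert first["screening_specificity_estimate"] == 89.94
        assert first["ppv_estimate"] == 5.92
        sixty = rows[8 + 3]  # matching 100/99.99 on the 60/90 scenario
        assert sixty["screening_sensitivity_estimate"] == 59.37


class TestValidation:
    def test_fraction_bounds_enforced(self):
        with pytest.raises(ValueError):
            ScreeningScenario(se_s=1.5, sp_s=0.9)
        with pytest.raises(ValueError):
            MatchingScenario(se_m=-0.1, sp_m=0.9)

    def test_degenerate_prevalence(self):
        s = ScreeningScenario(se_s=0.9, sp_s=0.9, prevalence=0.0)
        with pytest.raises(UndefinedMetricError):
            apparent_screening_accuracy(s, MatchingScenario(1.0, 1.0))

    def test_round_half_up(self):
        assert round_half_up(2.005, 2) == 2.01
        assert round_half_up(2.004999, 2) == 2.00
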