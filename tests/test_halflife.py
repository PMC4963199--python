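"""Closed-form half-times, subtraction estimators, error propagation, and
the full table builder."""

import numpy as np
import pytest

from ireskinetics import (
    HalfLifeEstimate,
    LN2,
    SpeciesState,
    analytic_linear_solution,
    default_observables,
    equilibrium_fold,
    halflife_numeric,
    project,
    propagate_error,
    t_half_by_subtraction,
    t_half_step1,
    t_half_step2,
    table2_report,
)
from ireskinetics.constants import APPARENT_RATE_CONSTANTS
from ireskinetics.halflife import report_frame


def k_of(eEF2, name):
    return APPARENT_RATE_CONSTANTS[eEF2][name][0]


class TestClosedForms:
    @pytest.mark.parametrize(
        "eEF2,expected", [(False, 230), (True, 237)], ids=["-eEF2", "+eEF2"]
    )
    def test_step1_half_time(self, eEF2, expected):
        value = t_half_step1(k_of(eEF2, "k1"), k_of(eEF2, "k_rev1"), k_of(eEF2, "k2"))
        assert round(value) == expected

    @pytest.mark.parametrize(
        "eEF2,expected", [(False, 14.8), (True, 30.5)], ids=["-eEF2", "+eEF2"]
    )
    def test_step2_half_time(self, eEF2, expected):
        value = t_half_step2(k_of(eEF2, "k_rev1"), k_of(eEF2, "k2"))
        assert value == pytest.approx(expected, abs=0.05)

    def test_committed_step_limit(self):
        assert t_half_step1(0.01, 0.0, 0.5) == pytest.approx(0.69 / 0.01)
        assert t_half_step2(0.0, 0.5) == pytest.approx(0.69 / 0.5)

    def test_zero_rates_rejected(self):
        with pytest.raises(ValueError):
            t_half_step1(0.0, 0.1, 0.1)
        with pytest.raises(ValueError):
            t_half_step2(0.1, 0.0)

    def test_with_ln2_composite_never_faster_than_committed_step(self):
        # c = ln2, k_rev1 = 0: t_half >= ln2/k1, equality as k2 -> inf
        k1 = 0.01
        for k2 in (0.01, 0.1, 10.0, 1e6):
            assert t_half_step1(k1, 0.0, k2, c=LN2) >= LN2 / k1 - 1e-12
        assert t_half_step1(k1, 0.0, 1e9, c=LN2) == pytest.approx(LN2 / k1, rel=1e-6)


class TestSubtraction:
    def test_first_cycle_translocation_step(self):
        composite = HalfLifeEstimate("4-8", 98, 15)
        parts = [HalfLifeEstimate("4+5", 8, 2), HalfLifeEstimate("7+8", 6, 2)]
        est = t_half_by_subtraction(composite, parts, step_label="6")
        assert est.value == pytest.approx(84)
        assert est.method == "subtraction"

    def test_second_cycle_peptide_bond_step(self):
        est = t_half_by_subtraction(
            HalfLifeEstimate("10+11", 9, 2), [HalfLifeEstimate("10", 2, 1)], step_label="11"
        )
        assert est.value == pytest.approx(7)

    def test_empty_component_list_is_identity(self):
        composite = HalfLifeEstimate("4-8", 98, 15)
        assert t_half_by_subtraction(composite, []) is composite

    def test_non_positive_result_flagged_not_dropped(self):
        with pytest.warns(UserWarning, match="non-positive"):
            est = t_half_by_subtraction(
                HalfLifeEstimate("a", 5, 1), [HalfLifeEstimate("b", 7, 1)]
            )
        assert est.value == pytest.approx(-2)
        assert est.note

    def test_round_trip_with_exact_inputs(self):
        a, b = 42.0, 13.0
        est = t_half_by_subtraction(
            HalfLifeEstimate("ab", a + b, 0.0), [HalfLifeEstimate("b", b, 0.0)]
        )
        assert est.value == pytest.approx(a, abs=1e-12)


class TestErrorPropagation:
    def test_quadrature(self):
        assert propagate_error([15, 2, 2]) == pytest.approx(np.sqrt(233), abs=1e-9)

    def test_linear_matches_second_cycle_translocation_error(self):
        assert propagate_error([26, 2, 2], method="linear") == 30

    def test_all_zero(self):
        assert propagate_error([0, 0, 0]) == 0.0

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            propagate_error([-1.0])


class TestEquilibriumFold:
    def test_published_constants_give_about_twenty_fold(self):
        assert equilibrium_fold(k_of(False, "k1"), k_of(False, "k_rev1")) == pytest.approx(
            21.1, abs=0.05
        )

    def test_symmetric_rates_give_unity(self):
        assert equilibrium_fold(0.2, 0.2) == 1.0

    def test_eEF2_shifts_equilibrium_to_even_split(self):
        fold = equilibrium_fold(k_of(True, "k1"), k_of(True, "k_rev1"))
        assert fold == pytest.approx(1.0, abs=0.05)


class TestTableReport:
    def test_all_rows_present_in_order(self):
        rows = table2_report()
        assert list(rows) == [
            "1", "1 (+eEF2)", "2", "2 (+eEF2)", "3", "4+5", "4-8", "6", "7",
            "7+8", "8", "7-11", "9", "10", "10+11", "11", "12",
        ]

    def test_subtraction_rows_from_published_inputs(self):
        rows = table2_report()
        assert rows["6"].value == pytest.approx(84)
        assert rows["11"].value == pytest.approx(7)
        assert rows["9"].value == pytest.approx(113)  # published rounds to 110
        assert rows["8"].value == pytest.approx(3)  # published rounds to 4

    def test_step12_is_upper_bound(self):
        est = table2_report()["12"]
        assert est.is_upper_bound and est.value == 10

    def test_missing_composite_names_affected_rows(self):
        composites = {
            label: HalfLifeEstimate(label, 10.0, 1.0)
            for label in ("3", "4+5", "7", "7+8", "7-11", "10", "10+11")
        }
        with pytest.raises(ValueError, match=r"4-8.*\b6\b"):
            table2_report(composites=composites)

    def test_report_frame_annotates_divergence_from_published(self):
        frame = report_frame(table2_report()).set_index("step")
        assert "differs" in frame.loc["9", "note"]
        assert frame.loc["6", "note"] == ""


class TestFormulaVsSimulation:
    """The closed forms are steady-state approximations; the mechanistic
    half-time from integrating the initial-binding subsystem should agree
    within a bounded discrepancy wherever the approximation's premise holds
    (fast pre-equilibrium for Step 1 in both conditions; dominant forward
    branching for Step 2, which only the +eEF2 constants satisfy)."""

    @staticmethod
    def _simulated_t_half(eEF2, start):
        from ireskinetics import make_truth_from_tables

        truth = make_truth_from_tables(eEF2).with_rates(
            **{f"k{i}": 0.0 for i in range(3, 13)}
        )
        times = np.concatenate([[0.0], np.geomspace(0.01, 5e4, 600)])
        traj = analytic_linear_solution(truth, SpeciesState.point(start), times)
        spec = default_observables()["anisotropy"]
        return halflife_numeric(project(traj, spec))

    @pytest.mark.parametrize("eEF2", [False, True], ids=["-eEF2", "+eEF2"])
    def test_step1_formula_within_15_percent_of_simulation(self, eEF2):
        formula = t_half_step1(k_of(eEF2, "k1"), k_of(eEF2, "k_rev1"), k_of(eEF2, "k2"))
        simulated = self._simulated_t_half(eEF2, start=1)
        assert abs(formula - simulated) / simulated < 0.15

    def test_step2_formula_within_15_percent_where_branching_is_forward(self):
        formula = t_half_step2(k_of(True, "k_rev1"), k_of(True, "k2"))
        simulated = self._simulated_t_half(True, start=2)
        assert abs(formula - simulated) / simulated < 0.15
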