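"""Background subtraction, exponential fits, phase selection, scheme fits,
and numeric half-times."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import brentq

from ireskinetics import (
    LN2,
    SpeciesState,
    TimeCourse,
    fit_exponential,
    fit_scheme,
    halflife_numeric,
    select_phases,
    subtract_background,
)
from ireskinetics.synthetic import SyntheticConfig, generate_anisotropy, generate_quench


def tc_of(times, signal, assay="peptide_di"):
    return TimeCourse(np.asarray(times, float), np.asarray(signal, float), assay=assay)


class TestSubtractBackground:
    def test_sample_equal_to_control_gives_zero(self):
        t = np.arange(5.0)
        tc = subtract_background(tc_of(t, t + 3), tc_of(t, t + 3))
        assert tc.signal == pytest.approx(np.zeros(5))

    def test_pointwise_arithmetic(self):
        out = subtract_background(tc_of([0, 1, 2], [5, 7, 9]), tc_of([0, 1, 2], [5, 5, 5]))
        assert out.signal == pytest.approx([0, 2, 4])

    def test_control_interpolated_onto_sample_grid(self):
        sample = tc_of([0.5, 1.5], [2.0, 3.0])
        control = tc_of([0, 1, 2], [0.0, 1.0, 2.0])
        out = subtract_background(sample, control)
        assert out.signal == pytest.approx([1.5, 1.5])

    def test_disjoint_or_extrapolating_ranges_rejected(self):
        with pytest.raises(ValueError, match="disjoint"):
            subtract_background(tc_of([10, 11], [1, 1]), tc_of([0, 1], [0, 0]))
        with pytest.raises(ValueError, match="extrapolate"):
            subtract_background(tc_of([0, 5], [1, 1]), tc_of([0, 1], [0, 0]))

    def test_assay_mismatch_rejected(self):
        with pytest.raises(ValueError, match="assay"):
            subtract_background(tc_of([0, 1], [1, 1], "anisotropy"), tc_of([0, 1], [0, 0]))

    def test_recovers_clean_model_curve_from_synthetic_pair(self):
        cfg = SyntheticConfig(seed=5, noise_sd=0.0)
        sample, control = generate_anisotropy(cfg, eEF2=False)
        corrected = subtract_background(sample, control)
        clean = sample.meta["clean_signal"] - sample.meta["observable"].baseline
        assert corrected.signal == pytest.approx(clean, abs=1e-12)


class TestFitExponential:
    def test_exact_single_exponential_recovery(self):
        t = np.linspace(0, 60, 30)
        fit = fit_exponential(tc_of(t, 1 - np.exp(-0.1 * t)), n_phases=1)
        assert fit.rates[0] == pytest.approx(0.1, rel=1e-6)
        assert fit.t_half[0] == pytest.approx(LN2 / 0.1, rel=1e-6)

    def test_double_exponential_recovers_fast_fraction(self):
        # major fast phase (65%) plus slow minor phase, as in the quench assays
        t = np.concatenate([np.linspace(0, 50, 25), np.linspace(60, 1500, 25)])
        y = 0.65 * (1 - np.exp(-0.099 * t)) + 0.35 * (1 - np.exp(-0.0031 * t))
        fit = fit_exponential(tc_of(t, y), n_phases=2)
        assert fit.fast_fraction == pytest.approx(0.65, abs=1e-4)
        assert fit.rates[0] == pytest.approx(0.099, rel=1e-3)
        assert fit.rates[1] == pytest.approx(0.0031, rel=1e-3)

    def test_decay_direction(self):
        t = np.linspace(0, 400, 25)
        fit = fit_exponential(tc_of(t, np.exp(-LN2 / 76 * t)), n_phases=1, direction="decay")
        assert fit.t_half[0] == pytest.approx(76.0, rel=1e-6)

    def test_constant_trace_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            fit_exponential(tc_of(np.arange(10.0), np.ones(10)), n_phases=1)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match="points"):
            fit_exponential(tc_of([0, 1, 2], [0, 0.5, 0.8]), n_phases=1)

    @given(scale=st.floats(0.01, 100.0))
    @settings(max_examples=20)
    def test_invariant_to_uniform_time_rescaling(self, scale):
        t = np.linspace(0, 60, 30)
        y = 1 - np.exp(-0.1 * t)
        fit = fit_exponential(tc_of(t * scale, y), n_phases=1)
        assert fit.rates[0] * scale == pytest.approx(0.1, rel=1e-5)


class TestSelectPhases:
    def test_clean_single_exponential_selects_one(self):
        t = np.linspace(0, 80, 40)
        assert select_phases(tc_of(t, 1 - np.exp(-0.1 * t))) == 1

    def test_biphasic_generator_output_selects_two(self):
        cfg = SyntheticConfig(seed=11)
        sample, control = generate_quench(cfg, "dipeptide_from_4")
        assert select_phases(subtract_background(sample, control)) == 2

    def test_pure_noise_selects_one_and_warns(self, rng):
        t = np.linspace(0, 100, 40)
        noisy = tc_of(t, 0.5 + rng.normal(0, 0.2, 40))
        with pytest.warns(UserWarning, match="poor fit"):
            assert select_phases(noisy) == 1


class TestFitScheme:
    def test_noiseless_recovery_within_0p1_percent(self, truth_minus, observables):
        cfg = SyntheticConfig(seed=0, noise_sd=0.0, background_fraction=0.0)
        sample, _ = generate_anisotropy(cfg, eEF2=False)
        sample.meta["fit_observable"] = sample.meta["observable"]
        truth = sample.meta["truth"]
        res = fit_scheme(
            [sample], free=["k1", "k_rev1", "k2"], fixed=truth, init=truth,
            initial_state=sample.meta["initial_state"], n_starts=1,
        )
        assert res.rates.k(1) == pytest.approx(truth.k(1), rel=1e-3)
        assert res.rates.k_rev1 == pytest.approx(truth.k_rev1, rel=1e-3)
        assert res.rates.k(2) == pytest.approx(truth.k(2), rel=1e-3)
        assert all(np.isfinite(e) and e >= 0 for e in res.stderr.values())

    def test_eEF2_preincubation_fit_predicts_rapid_phase_near_half(self, observables):
        # preincubation splits the initial state ~50/50 between closed and
        # open A-site structures; the fitted model's rapid phase carries
        # about half the binding amplitude
        cfg = SyntheticConfig(seed=2, noise_sd=0.0, background_fraction=0.0)
        sample, _ = generate_anisotropy(cfg, eEF2=True)
        signal = sample.signal - sample.meta["observable"].baseline
        amplitude = signal[-1]
        # rapid phase amplitude = signal once the fast binding exhausts the
        # pre-opened pool (~5 half-lives of k2)
        t_fast = 5.0 * LN2 / sample.meta["truth"].k(2)
        rapid = np.interp(t_fast, sample.times, signal)
        assert rapid / amplitude == pytest.approx(0.5, abs=0.15)

    def test_underdetermined_single_point_rejected(self, truth_minus):
        tc = TimeCourse(np.array([10.0]), np.array([0.1]), assay="anisotropy")
        with pytest.raises(ValueError, match="nder-determined"):
            fit_scheme([tc], free=["k1"], fixed=truth_minus, initial_state=SpeciesState.point(1))

    def test_unknown_free_parameter_rejected(self, truth_minus):
        tc = TimeCourse(np.arange(4.0), np.zeros(4), assay="anisotropy")
        with pytest.raises(ValueError, match="k99"):
            fit_scheme([tc], free=["k99"], fixed=truth_minus)


class TestHalflifeNumeric:
    def test_single_exponential_closed_form(self):
        k = 0.05
        assert halflife_numeric(lambda t: 1 - np.exp(-k * t)) == pytest.approx(LN2 / k, rel=1e-6)

    def test_two_step_chain_matches_independent_root(self):
        # sequential k,k chain: completion 1-(1+kt)e^{-kt}; independent
        # closed-form root via brentq on that expression
        k = 0.1
        expected = brentq(lambda t: (1 + k * t) * np.exp(-k * t) - 0.5, 1e-9, 1e3)
        curve = lambda t: 1 - (1 + k * t) * np.exp(-k * t)
        assert halflife_numeric(curve) == pytest.approx(expected, rel=1e-6)

    def test_decreasing_curve_handled_symmetrically(self):
        k = LN2 / 76
        assert halflife_numeric(lambda t: np.exp(-k * t)) == pytest.approx(76.0, rel=1e-6)

    def test_timecourse_input(self):
        t = np.linspace(0, 200, 400)
        tc = tc_of(t, 1 - np.exp(-0.05 * t))
        assert halflife_numeric(tc) == pytest.approx(LN2 / 0.05, rel=1e-2)

    def test_curve_never_reaching_half_rejected(self):
        t = np.linspace(0, 10, 20)
        with pytest.raises(ValueError, match="half"):
            halflife_numeric(tc_of(t, 0.4 * (1 - np.exp(-0.05 * t))), plateau=1.0)
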