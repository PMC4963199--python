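"""Synthetic assay time courses with the statistical structure the analysis
assumes.

The generator emulates the four experimental readouts so every fitting stage
is testable without laboratory data:

- stopped-flow anisotropy traces of initial Phe-TC binding, with and without
  eEF2 preincubation, on top of an IRES-independent background shared with a
  matched 80S-only control;
- quench-flow Phe cosedimentation (stable P-site binding only, plateau
  scaled to the measured 0.29 per 40S stoichiometry);
- quench-flow peptide-formation courses, generated as a mixture of an active
  population reacting at the truth rates (65%) and a kinetically slow
  population (35%, half-life ~230 s) emulating defective ribosomes;
- puromycin loss-of-cosedimentation traces for A-site, P-site, and
  translocating peptidyl-tRNA.

Noise is Gaussian and homoscedastic, with a standard deviation expressed as
a fraction of each trace's dynamic range. Identical config and seed give
bit-identical output.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from . import constants
from .constants import LN2
from .puromycin import PuromycinParams, bound_fraction
from .scheme import RateConstantSet, SpeciesState, default_observables
from .simulate import analytic_linear_solution, project
from .timecourse import TimeCourse


def make_truth_from_tables(eEF2: bool = True) -> RateConstantSet:
    """Ground-truth rate constants from the published tables.

    Steps 1-2 take the measured apparent constants for the requested eEF2
    condition; Steps 3-12 are ``ln 2 / t_half`` from the per-step half-life
    table (the Step 12 upper bound is treated as an equality for
    simulation).
    """
    t1 = constants.APPARENT_RATE_CONSTANTS[eEF2]
    fwd = [0.0] * 12
    fwd[0] = t1["k1"][0]
    fwd[1] = t1["k2"][0]
    for step, t_half in constants.TRUTH_STEP_T_HALF.items():
        fwd[step - 1] = LN2 / t_half
    return RateConstantSet(
        k_fwd=tuple(fwd),
        k_rev1=t1["k_rev1"][0],
        tc_concentration=constants.TC_CONCENTRATION_ANISOTROPY_UM,
        eEF2_present=eEF2,
    )


def _default_anisotropy_times() -> np.ndarray:
    # stopped-flow style: dense log sampling from 50 ms to 600 s
    return np.concatenate([[0.0], np.geomspace(0.05, 600.0, 200)])


def _default_cosed_times() -> np.ndarray:
    # 10 quench points out to 1200 s, concentrated where the stable P-site
    # species actually accumulates (overall process half-time ~400 s)
    return np.array([15.0, 30.0, 60.0, 120.0, 240.0, 360.0, 520.0, 720.0, 950.0, 1200.0])


def _default_peptide_times() -> np.ndarray:
    # quench-flow design: dense early points across the fast phase plus a
    # tail long enough to pin the slow minor phase
    return np.array(
        [1.0, 2.0, 3.0, 4.5, 6.5, 9.0, 13.0, 18.0, 26.0, 38.0, 55.0, 80.0,
         120.0, 180.0, 270.0, 400.0, 600.0, 900.0]
    )


@dataclass
class SyntheticConfig:
    """Study design for the generator.

    ``noise_sd`` is a fraction of each trace's dynamic range;
    ``defective_fraction`` of complexes in the quench assays react with the
    single slow rate ``k_slow``; ``background_fraction`` sets the
    IRES-independent signal amplitude relative to the sample amplitude.
    """

    truth_minus: RateConstantSet = field(default_factory=lambda: make_truth_from_tables(False))
    truth_plus: RateConstantSet = field(default_factory=lambda: make_truth_from_tables(True))
    noise_sd: float = 0.02
    defective_fraction: float = 0.35
    k_slow: float = LN2 / constants.SLOW_PHASE_T_HALF
    replicates: int = 3
    background_fraction: float = 0.2
    background_rate: float = 0.01
    anisotropy_baseline: float = 0.15
    anisotropy_amplitude: float = 0.10
    cosed_plateau: float = constants.COSED_PLATEAU_PER_40S
    anisotropy_times: np.ndarray = field(default_factory=_default_anisotropy_times)
    cosed_times: np.ndarray = field(default_factory=_default_cosed_times)
    peptide_times: np.ndarray = field(default_factory=_default_peptide_times)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if not 0 <= self.defective_fraction < 1:
            raise ValueError("defective_fraction must be in [0, 1)")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def add_noise(tc: TimeCourse, sd: float, seed_or_rng) -> TimeCourse:
    """Independent Gaussian perturbation of the signal (sd in signal units)."""
    if sd < 0:
        raise ValueError("sd must be non-negative")
    if sd == 0:
        return tc
    rng = (
        seed_or_rng
        if isinstance(seed_or_rng, np.random.Generator)
        else np.random.default_rng(seed_or_rng)
    )
    noisy = tc.signal + rng.normal(0.0, sd, size=tc.signal.shape)
    return dataclasses.replace(tc, signal=noisy, noise_sd=sd, meta=dict(tc.meta))


def _background(times: np.ndarray, amplitude: float, rate: float) -> np.ndarray:
    return amplitude * (1.0 - np.exp(-rate * times))


def _finish(tc, cfg, rng, amplitude, truth, clean, replicate, extra_meta=None):
    """Attach background + noise to a clean sample and emit matched control."""
    bg_amp = cfg.background_fraction * amplitude
    bg = _background(tc.times, bg_amp, cfg.background_rate)
    baseline = tc.meta["observable"].baseline
    sd = cfg.noise_sd * amplitude
    meta = {
        "truth": truth,
        "observable": tc.meta["observable"],
        "clean_signal": clean,
        "background_amplitude": bg_amp,
    }
    if extra_meta:
        meta.update(extra_meta)
    sample = TimeCourse(
        tc.times.copy(), clean + bg, assay=tc.assay, replicate=replicate,
        condition="ires", meta=meta,
    )
    control = TimeCourse(
        tc.times.copy(), baseline + bg, assay=tc.assay, replicate=replicate,
        condition="no_ires", meta={"background_amplitude": bg_amp},
    )
    return add_noise(sample, sd, rng), add_noise(control, sd, rng)


def _initial_binding_rates(truth: RateConstantSet) -> RateConstantSet:
    """Rates for the initial-binding experiments: only Phe-TC is present, so
    every step past the second pseudo-translocation is switched off."""
    return truth.with_rates(**{f"k{i}": 0.0 for i in range(4, 13)})


def generate_anisotropy(
    cfg: SyntheticConfig, eEF2: bool, replicate: int = 0, rng=None
) -> tuple[TimeCourse, TimeCourse]:
    """Anisotropy binding trace plus matched 80S-only control.

    Without eEF2 all complexes start with the IRES closing the A site
    (structure 1); after eEF2 preincubation the pseudo-translocation
    equilibrium is near 50/50, so the initial state splits evenly between
    structures 1 and 2, producing the rapid ~50% binding phase.
    """
    rng = rng if rng is not None else cfg.rng()
    truth = _initial_binding_rates(cfg.truth_plus if eEF2 else cfg.truth_minus)
    initial = SpeciesState.mixture({1: 0.5, 2: 0.5}) if eEF2 else SpeciesState.point(1)
    spec = default_observables()["anisotropy"].replace(
        baseline=cfg.anisotropy_baseline, amplitude=cfg.anisotropy_amplitude
    )
    traj = analytic_linear_solution(truth, initial, cfg.anisotropy_times)
    tc = project(traj, spec, replicate=replicate)
    clean = tc.signal.copy()
    return _finish(
        tc, cfg, rng, spec.amplitude, truth, clean, replicate,
        {"initial_state": initial, "eEF2": eEF2},
    )


def generate_cosedimentation(
    cfg: SyntheticConfig,
    replicate: int = 0,
    rng=None,
    step3_t_half: float | None = None,
) -> tuple[TimeCourse, TimeCourse]:
    """Phe cosedimentation through Steps 1-3 (stable P-site species only).

    Requires eEF2 (the second pseudo-translocation is eEF2-dependent), so
    the +eEF2 constants apply. The plateau is scaled to the measured
    end-point stoichiometry per 40S.
    """
    rng = rng if rng is not None else cfg.rng()
    truth = _initial_binding_rates(cfg.truth_plus)
    if step3_t_half is not None:
        truth = truth.with_rates(k3=LN2 / step3_t_half)
    spec = default_observables()["cosed_phe"].replace(amplitude=cfg.cosed_plateau)
    traj = analytic_linear_solution(truth, SpeciesState.point(1), cfg.cosed_times)
    tc = project(traj, spec, replicate=replicate)
    return _finish(
        tc, cfg, rng, spec.amplitude, truth, tc.signal.copy(), replicate,
        {"initial_state": SpeciesState.point(1)},
    )


#: Quench-flow experiment designs: name -> (start structure, observable,
#: label-bearing structures or None for the observable's default mask).
#: The radiolabel enters with the Met-TC of the cycle under study, so the
#: Met-cosedimentation mask depends on the start point: label is present
#: only downstream of that cycle's binding step, and the labile structures
#: 5-6 never pellet.
PEPTIDE_DESIGNS = {
    "dipeptide_from_4": (4, "peptide_di", None),
    "tripeptide_from_4": (4, "peptide_tri", None),
    "tripeptide_from_7": (7, "peptide_tri", None),
    "tetrapeptide_from_7": (7, "peptide_tetra", None),
    "tetrapeptide_from_10": (10, "peptide_tetra", None),
    "cosed_met_from_4": (4, "cosed_met", range(7, 14)),
    "cosed_met_from_7": (7, "cosed_met", range(8, 14)),
    "cosed_met_from_10": (10, "cosed_met", range(11, 14)),
}


def generate_quench(
    cfg: SyntheticConfig, design: str, replicate: int = 0, rng=None
) -> tuple[TimeCourse, TimeCourse]:
    """Peptide-formation or Met cosedimentation course for one design.

    The signal is a mixture: ``1 - defective_fraction`` of complexes follow
    the truth rates, the rest rise as a single slow exponential at
    ``k_slow`` toward the same plateau, reproducing the biphasic pattern of
    the quench assays (~65% fast phase).
    """
    rng = rng if rng is not None else cfg.rng()
    start, obs_name, label_mask = PEPTIDE_DESIGNS[design]
    truth = cfg.truth_plus
    spec = default_observables()[obs_name]
    if label_mask is not None:
        weights = np.zeros(len(spec.weights))
        weights[[s - 1 for s in label_mask]] = 1.0
        spec = spec.replace(weights=weights)
    initial = SpeciesState.point(start)
    traj = analytic_linear_solution(truth, initial, cfg.peptide_times)
    active = spec.signal(traj.occupancies)
    slow = spec.baseline + spec.amplitude * (1.0 - np.exp(-cfg.k_slow * cfg.peptide_times))
    d = cfg.defective_fraction
    clean = (1.0 - d) * active + d * slow
    tc = TimeCourse(
        cfg.peptide_times.copy(), clean, assay=obs_name, replicate=replicate,
        meta={"observable": spec},
    )
    return _finish(
        tc, cfg, rng, spec.amplitude, truth, clean, replicate,
        {"initial_state": initial, "design": design, "fast_fraction": 1.0 - d},
    )


#: Puromycin scenarios: name -> (initial_site, (k_trans, k_puro_A, k_puro_P)).
PUROMYCIN_SCENARIOS = {
    "FVK_A_site": ("A", (0.0, LN2 / 1400.0, 0.0)),
    "FVK_P_site": ("P", (0.0, 0.0, LN2 / 76.0)),
    "FVK_translocating": ("translocating", (LN2 / 110.0, LN2 / 1400.0, LN2 / 76.0)),
    "FVKM_P_site": ("P", (0.0, 0.0, LN2 / 46.0)),
    "FVKM_translocating": ("translocating", (LN2 / 10.0, LN2 / 1400.0, LN2 / 46.0)),
}


def generate_puromycin(
    cfg: SyntheticConfig, scenario: str, replicate: int = 0, rng=None
) -> TimeCourse:
    """Loss-of-cosedimentation trace for one puromycin scenario.

    Time points span ~5% to 5 half-lives of the scenario's own time scale;
    no IRES-free control is generated (no label pellets without ribosomes).
    """
    rng = rng if rng is not None else cfg.rng()
    site, (k_trans, kA, kP) = PUROMYCIN_SCENARIOS[scenario]
    p = PuromycinParams(k_trans=k_trans, k_puro_A=kA, k_puro_P=kP, initial_site=site)
    scale = 1.0 / max(k_trans + kA, kP)
    times = np.concatenate([[0.0], np.round(np.geomspace(0.05 * scale, 5.0 * scale, 11), 2)])
    clean = bound_fraction(times, p)
    tc = TimeCourse(
        times, clean, assay="puromycin_bound", replicate=replicate,
        meta={"scenario": scenario, "params": p, "clean_signal": clean.copy()},
    )
    return add_noise(tc, cfg.noise_sd * 1.0, rng)


def generate_assay_suite(cfg: SyntheticConfig) -> list[TimeCourse]:
    """All assays, ``cfg.replicates`` times each, under one seeded stream.

    Sample and matched 80S-only control are emitted for every anisotropy,
    cosedimentation, and quench design, flagged by ``condition``
    (``ires`` / ``no_ires``).
    """
    rng = cfg.rng()
    out: list[TimeCourse] = []
    counters: dict[str, int] = {}

    def emit(traces):
        # distinct experiments sharing an observable (e.g. tripeptide from
        # structure 4 vs 7) get distinct replicate ids so tidy-CSV groups
        # stay uniquely keyed by (assay, replicate, condition)
        rep = counters.get(traces[0].assay, 0)
        counters[traces[0].assay] = rep + 1
        for tc in traces:
            tc.replicate = rep
        out.extend(traces)

    for r in range(cfg.replicates):
        for eEF2 in (False, True):
            emit(generate_anisotropy(cfg, eEF2, replicate=r, rng=rng))
        emit(generate_cosedimentation(cfg, replicate=r, rng=rng))
        for design in PEPTIDE_DESIGNS:
            emit(generate_quench(cfg, design, replicate=r, rng=rng))
        for scenario in PUROMYCIN_SCENARIOS:
            emit([generate_puromycin(cfg, scenario, replicate=r, rng=rng)])
    return out
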