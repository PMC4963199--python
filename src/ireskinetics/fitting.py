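"""Least-squares recovery of rate constants from assay time courses.

Three fitting layers:

- :func:`fit_exponential` / :func:`select_phases` — single or double
  exponential fits of formation (``A (1 - e^{-kt})``) or loss (``A e^{-kt}``)
  traces, with corrected-AIC phase selection.
- :func:`fit_scheme` — direct least-squares fit of the mass-action scheme to
  one or more projected time courses (joint fits share whichever rate
  constants are declared free), using the closed-form linear solution for
  speed and the local curvature for parameter errors.
- :func:`subtract_background` / :func:`halflife_numeric` — trace correction
  against an IRES-free control, and half-times of arbitrary monotone model
  curves by bracketed root-finding.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import lmfit
import numpy as np
from scipy.optimize import brentq

from .scheme import (
    N_STEPS,
    ObservableSpec,
    RateConstantSet,
    SpeciesState,
    default_observables,
)
from .simulate import analytic_linear_solution, integrate, project
from .timecourse import TimeCourse

LN2 = math.log(2.0)
_RATE_NAMES = tuple(f"k{i}" for i in range(1, N_STEPS + 1)) + ("k_rev1",)


# ---------------------------------------------------------------------------
# background subtraction


def subtract_background(sample: TimeCourse, control: TimeCourse) -> TimeCourse:
    """IRES-dependent trace: sample minus the 80S-only control.

    The control is linearly interpolated onto the sample's grid; the sample
    must lie within the control's time range (no extrapolation).
    """
    if sample.assay != control.assay:
        raise ValueError(
            f"assay mismatch: sample {sample.assay!r} vs control {control.assay!r}"
        )
    lo, hi = control.times[0], control.times[-1]
    if sample.times[-1] < lo or sample.times[0] > hi:
        raise ValueError("sample and control time ranges are disjoint")
    if sample.times[0] < lo - 1e-12 or sample.times[-1] > hi + 1e-12:
        raise ValueError(
            "sample extends beyond the control's time range; refusing to extrapolate"
        )
    corrected = sample.signal - np.interp(sample.times, control.times, control.signal)
    return TimeCourse(
        sample.times.copy(),
        corrected,
        assay=sample.assay,
        replicate=sample.replicate,
        condition="corrected",
        noise_sd=sample.noise_sd,
        meta=dict(sample.meta),
    )


# ---------------------------------------------------------------------------
# exponential fits


@dataclass
class ExpFitResult:
    """Single/double exponential fit, phases ordered fast-first."""

    n_phases: int
    amplitudes: tuple[float, ...]
    rates: tuple[float, ...]
    fast_fraction: float
    t_half: tuple[float, ...]
    residual_sd: float
    offset: float
    direction: str
    aicc: float
    at_bound: bool = False

    def __post_init__(self) -> None:
        if any(k <= 0 for k in self.rates):
            raise ValueError("fitted rates must be positive")
        if any(a < 0 for a in self.amplitudes):
            raise ValueError("fitted amplitudes must be non-negative")


def _exp_model(t, params, n_phases, direction):
    y = np.full_like(t, params["offset"].value, dtype=float)
    for i in range(1, n_phases + 1):
        A, k = params[f"A{i}"].value, params[f"k{i}"].value
        if direction == "rise":
            y += A * (1.0 - np.exp(-k * t))
        else:
            y += A * np.exp(-k * t)
    return y


def _aicc(chisqr: float, n: int, nvar: int) -> float:
    # lmfit-style AIC on Gaussian residuals, with the small-sample correction
    aic = n * math.log(max(chisqr, 1e-300) / n) + 2 * nvar
    denom = n - nvar - 1
    return aic + (2 * nvar * (nvar + 1) / denom if denom > 0 else math.inf)


def fit_exponential(
    tc: TimeCourse,
    n_phases: int = 1,
    direction: str = "auto",
    fit_offset: bool = False,
) -> ExpFitResult:
    """Least-squares exponential fit of a formation or loss trace.

    ``direction='rise'`` fits ``offset + sum A_i (1 - e^{-k_i t})``,
    ``'decay'`` fits ``offset + sum A_i e^{-k_i t}``; ``'auto'`` picks by the
    sign of the net signal change. The offset is fixed at zero unless
    ``fit_offset``. A fitted rate pinned at a parameter bound is flagged.
    """
    if n_phases not in (1, 2):
        raise ValueError("n_phases must be 1 or 2")
    t, y = tc.times, tc.signal
    if len(tc) < 2 * (2 * n_phases):
        raise ValueError(f"need at least {2 * (2 * n_phases)} points for {n_phases} phase(s)")
    span = float(np.ptp(y))
    scale = max(abs(y).max(), 1.0)
    if span < 1e-10 * scale:
        raise ValueError("constant trace: no decay or rise to fit")
    if direction == "auto":
        direction = "rise" if y[-1] >= y[0] else "decay"
    if direction not in ("rise", "decay"):
        raise ValueError("direction must be 'rise', 'decay', or 'auto'")

    t_pos = t[t > 0]
    t_scale = float(np.median(t_pos)) if t_pos.size else 1.0
    k_lo, k_hi = 1e-7 / t_scale, 1e5 / t_scale
    params = lmfit.Parameters()
    params.add("offset", value=0.0, vary=fit_offset)
    if n_phases == 1:
        params.add("A1", value=span, min=0.0)
        params.add("k1", value=LN2 / t_scale, min=k_lo, max=k_hi)
    else:
        params.add("A1", value=0.65 * span, min=0.0)
        params.add("A2", value=0.35 * span, min=0.0)
        params.add("k1", value=10.0 * LN2 / t_scale, min=k_lo, max=k_hi)
        params.add("k2", value=0.1 * LN2 / t_scale, min=k_lo, max=k_hi)

    out = lmfit.minimize(
        lambda p: _exp_model(t, p, n_phases, direction) - y, params, method="least_squares"
    )
    if not out.success:
        raise RuntimeError(f"exponential fit did not converge: {out.message}")

    pairs = sorted(
        ((out.params[f"k{i}"].value, out.params[f"A{i}"].value) for i in range(1, n_phases + 1)),
        reverse=True,
    )
    rates = tuple(k for k, _ in pairs)
    amps = tuple(a for _, a in pairs)
    total_amp = sum(amps)
    fast_fraction = amps[0] / total_amp if total_amp > 0 else float("nan")
    at_bound = any(
        math.isclose(k, b, rel_tol=1e-6) for k in rates for b in (k_lo, k_hi)
    )
    if at_bound:
        warnings.warn("fitted rate at parameter bound", stacklevel=2)
    nvar = out.nvarys
    # floor the objective at numerical-noise scale so AICc comparisons on
    # effectively perfect fits reward parsimony instead of round-off
    chisqr = max(out.chisqr, len(tc) * (1e-9 * span) ** 2)
    residual_sd = math.sqrt(out.chisqr / max(len(tc) - nvar, 1))
    return ExpFitResult(
        n_phases=n_phases,
        amplitudes=amps,
        rates=rates,
        fast_fraction=fast_fraction,
        t_half=tuple(LN2 / k for k in rates),
        residual_sd=residual_sd,
        offset=out.params["offset"].value,
        direction=direction,
        aicc=_aicc(chisqr, len(tc), nvar),
        at_bound=at_bound,
    )


def select_phases(tc: TimeCourse, delta_aicc: float = 6.0, **kwargs) -> int:
    """Choose 1 or 2 exponential phases by corrected AIC.

    Returns 2 only when the two-phase fit improves AICc by more than
    ``delta_aicc``. A poor fit of even the selected model (explained
    variance below 20%) is reported as a warning.
    """
    one = fit_exponential(tc, 1, **kwargs)
    try:
        two = fit_exponential(tc, 2, **kwargs)
    except (RuntimeError, ValueError):
        two = None
    n = 2 if two is not None and one.aicc - two.aicc > delta_aicc else 1
    best = two if n == 2 else one
    total_var = float(np.var(tc.signal))
    if total_var > 0:
        r_squared = 1.0 - best.residual_sd**2 / total_var
        if r_squared < 0.2:
            warnings.warn(
                f"poor fit: R^2 = {r_squared:.2f}; trace may be noise about a constant",
                stacklevel=2,
            )
    return n


# ---------------------------------------------------------------------------
# scheme fits


@dataclass
class SchemeFitResult:
    """Outcome of a direct scheme fit."""

    rates: RateConstantSet
    stderr: dict[str, float]
    objective: float
    success: bool
    n_points: int = 0
    n_starts_used: int = 1
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if any(e < 0 for e in self.stderr.values() if np.isfinite(e)):
            raise ValueError("reported errors must be non-negative")


def _tc_design(tc, initial_state, observables):
    spec = tc.meta.get("fit_observable") or observables[tc.assay]
    init = tc.meta.get("initial_state", initial_state)
    return spec, init


def fit_scheme(
    tcs: list[TimeCourse],
    free: list[str],
    fixed: RateConstantSet,
    init: RateConstantSet | None = None,
    initial_state: SpeciesState | None = None,
    observables: dict[str, ObservableSpec] | None = None,
    solver: str = "analytic",
    n_starts: int = 10,
    seed: int = 0,
) -> SchemeFitResult:
    """Fit free rate constants of the scheme to projected time courses.

    All supplied courses enter one summed-squared-residual objective, so a
    joint fit across conditions shares every free parameter. Each course is
    projected through the observable registered for its assay (overridable
    per trace via ``meta['fit_observable']``); a per-trace initial state may
    be supplied via ``meta['initial_state']``.

    Initialization is multi-start: the first start is ``init`` (default:
    ``fixed``), the rest are drawn log-uniformly within a factor of ~30 of
    it, under a fixed ``seed``. Parameter errors come from the Jacobian-based
    covariance at the optimum.
    """
    if not tcs:
        raise ValueError("at least one time course is required")
    if not free:
        raise ValueError("at least one free parameter is required")
    for name in free:
        if name not in _RATE_NAMES:
            raise ValueError(f"unknown scheme parameter {name!r}")
    n_points = sum(len(tc) for tc in tcs)
    if n_points <= len(free):
        raise ValueError(
            f"under-determined fit: {len(free)} free parameter(s) but only "
            f"{n_points} data point(s)"
        )
    observables = observables or default_observables()
    if initial_state is None:
        initial_state = SpeciesState.point(1)
    init = init or fixed
    solve = analytic_linear_solution if solver == "analytic" else integrate

    designs = [_tc_design(tc, initial_state, observables) for tc in tcs]

    def residual(params):
        updates = {name: params[name].value for name in free}
        rs = fixed.with_rates(**updates)
        chunks = []
        for tc, (spec, state) in zip(tcs, designs):
            traj = solve(rs, state, tc.times)
            chunks.append(spec.signal(traj.occupancies, total=state.total) - tc.signal)
        return np.concatenate(chunks)

    rng = np.random.default_rng(seed)
    init_values = {name: _get_rate(init, name) for name in free}
    starts = [init_values]
    for _ in range(max(n_starts, 1) - 1):
        starts.append(
            {
                name: v * 10.0 ** rng.uniform(-1.5, 1.5) if v > 0 else 10.0 ** rng.uniform(-4, 0)
                for name, v in init_values.items()
            }
        )

    best = None
    for start in starts:
        params = lmfit.Parameters()
        for name, v in start.items():
            params.add(name, value=max(v, 1e-12), min=0.0)
        try:
            out = lmfit.minimize(residual, params, method="leastsq")
        except Exception:
            continue
        if out.success and (best is None or out.chisqr < best.chisqr):
            best = out
    if best is None:
        raise RuntimeError("scheme fit did not converge from any start")

    fitted = fixed.with_rates(**{name: best.params[name].value for name in free})
    stderr = {
        name: (best.params[name].stderr if best.params[name].stderr is not None else float("nan"))
        for name in free
    }
    return SchemeFitResult(
        rates=fitted,
        stderr=stderr,
        objective=best.chisqr,
        success=True,
        n_points=n_points,
        n_starts_used=len(starts),
        meta={"nfev": best.nfev},
    )


def _get_rate(rates: RateConstantSet, name: str) -> float:
    return rates.k_rev1 if name == "k_rev1" else rates.k(int(name[1:]))


# ---------------------------------------------------------------------------
# numeric half-times


def halflife_numeric(
    curve,
    t_max: float = 1e8,
    plateau: float | None = None,
    baseline: float | None = None,
) -> float:
    """Time at which a monotone model curve reaches half of its total change.

    ``curve`` is either a callable ``f(t)`` or a :class:`TimeCourse`. The
    half-signal level is ``baseline + 0.5 * (plateau - baseline)``; baseline
    defaults to the value at t=0 and the plateau is detected by doubling the
    horizon until the curve stops changing (callable) or taken as the final
    sample (time course). Decreasing curves are handled symmetrically.
    Raises if half-amplitude is never reached.
    """
    if isinstance(curve, TimeCourse):
        t, y = curve.times, curve.signal
        y0 = y[0] if baseline is None else baseline
        yinf = y[-1] if plateau is None else plateau
        target = y0 + 0.5 * (yinf - y0)
        f = lambda x: np.interp(x, t, y) - target
        crossings = np.nonzero(np.diff(np.sign(y - target)))[0]
        if (y[0] - target) == 0:
            return float(t[0])
        if crossings.size == 0:
            raise ValueError("curve never reaches half-amplitude within its range")
        i = crossings[0]
        return float(brentq(f, t[i], t[i + 1], xtol=1e-9, rtol=1e-12))

    f = curve
    y0 = float(f(0.0)) if baseline is None else baseline
    if plateau is None:
        T, yinf = 1.0, float(f(1.0))
        for _ in range(64):
            y_next = float(f(2.0 * T))
            if abs(y_next - yinf) <= 1e-9 + 1e-7 * abs(y_next - y0):
                yinf = y_next
                break
            T, yinf = 2.0 * T, y_next
            if T > t_max:
                raise ValueError("curve does not plateau within t_max")
        horizon = 2.0 * T
    else:
        yinf = plateau
        horizon = t_max
    if yinf == y0:
        raise ValueError("flat curve: no half-amplitude to reach")
    target = y0 + 0.5 * (yinf - y0)
    g = lambda x: float(f(x)) - target
    hi = 1.0
    while g(hi) * g(0.0) > 0:
        hi *= 2.0
        if hi > horizon * 1.01:
            raise ValueError("curve never reaches half-amplitude")
    return float(brentq(g, 0.0, hi, xtol=1e-9, rtol=1e-12))
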