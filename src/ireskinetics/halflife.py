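"""Half-life calculus for the elongation scheme.

Closed-form half-times for the initial pseudo-translocation/binding steps,
subtraction estimators for steps that are not observed directly (a
composite's half-time minus the sum of its observed components), error
propagation for those derived rows, and the full half-life table builder.

The closed forms use the constant ``c = 0.69`` (the conventional two-digit
rounding of ln 2 used in the published table); ``ln 2`` itself can be passed
explicitly.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace

import pandas as pd

from . import constants

C_DEFAULT = 0.69

#: Subtraction rows of the half-life table: step -> (composite, components).
SUBTRACTION_ROWS: dict[str, tuple[str, tuple[str, ...]]] = {
    "6": ("4-8", ("4+5", "7+8")),
    "8": ("7+8", ("7",)),
    "9": ("7-11", ("7+8", "10+11")),
    "11": ("10+11", ("10",)),
}

#: Presentation order of the full table.
TABLE_ORDER = (
    "1",
    "1 (+eEF2)",
    "2",
    "2 (+eEF2)",
    "3",
    "4+5",
    "4-8",
    "6",
    "7",
    "7+8",
    "8",
    "7-11",
    "9",
    "10",
    "10+11",
    "11",
    "12",
)


@dataclass(frozen=True)
class HalfLifeEstimate:
    """A step's half-life (s) with error and provenance.

    ``step_label`` is a step number or a composite label ("4+5" = steps 4
    and 5 jointly, "4-8" = steps 4 through 8). ``method`` records how the
    value was obtained: ``direct_fit``, ``formula``, ``subtraction``, or
    ``bound``. Upper bounds (``is_upper_bound``) store the limit itself.
    ``note`` carries annotations, e.g. divergence from a published value or
    a non-positive subtraction flag.
    """

    step_label: str
    value: float
    error: float = 0.0
    method: str = "direct_fit"
    is_upper_bound: bool = False
    note: str = ""

    def __post_init__(self) -> None:
        if self.error < 0:
            raise ValueError("error must be non-negative")
        if self.method not in ("direct_fit", "formula", "subtraction", "bound"):
            raise ValueError(f"unknown method {self.method!r}")
        if self.value <= 0 and not self.is_upper_bound and not self.note:
            raise ValueError("half-life must be positive unless flagged or a bound")


def t_half_step1(k1: float, k_rev1: float, k2: float, c: float = C_DEFAULT) -> float:
    """Half-time of Step 1: ``c * (k_rev1 + k2) / (k1 * k2)``.

    This is the overall half-time of A-site opening followed by
    ternary-complex capture when Step 1 is rate-limiting under the
    steady-state treatment of the intermediate.
    """
    if k1 <= 0 or k2 <= 0:
        raise ValueError("k1 and k2 must be positive")
    if k_rev1 < 0:
        raise ValueError("k_rev1 must be non-negative")
    return c * (k_rev1 + k2) / (k1 * k2)


def t_half_step2(k_rev1: float, k2: float, c: float = C_DEFAULT) -> float:
    """Half-time of Step 2: ``c * (k_rev1 + k2) / k2**2``."""
    if k2 <= 0:
        raise ValueError("k2 must be positive")
    if k_rev1 < 0:
        raise ValueError("k_rev1 must be non-negative")
    return c * (k_rev1 + k2) / (k2 * k2)


def propagate_error(errors, method: str = "quadrature") -> float:
    """Combine component errors: ``quadrature`` sqrt(sum e^2) or ``linear`` sum e."""
    errors = [float(e) for e in errors]
    if any(e < 0 for e in errors):
        raise ValueError("errors must be non-negative")
    if method == "quadrature":
        return math.sqrt(sum(e * e for e in errors))
    if method == "linear":
        return float(sum(errors))
    raise ValueError(f"unknown error method {method!r}")


def t_half_by_subtraction(
    composite: HalfLifeEstimate,
    components: list[HalfLifeEstimate],
    step_label: str | None = None,
    error_method: str = "quadrature",
) -> HalfLifeEstimate:
    """Estimate an unobserved step as composite minus the sum of components.

    A non-positive result is returned flagged (with a warning), never
    silently dropped.
    """
    if not components:
        return composite
    value = composite.value - sum(c.value for c in components)
    error = propagate_error([composite.error] + [c.error for c in components], error_method)
    label = step_label if step_label is not None else composite.step_label
    note = ""
    if value <= 0:
        note = "non-positive subtraction result; components exceed composite"
        warnings.warn(f"step {label}: {note} ({value:.3g} s)", stacklevel=2)
    return HalfLifeEstimate(label, value, error, method="subtraction", note=note)


def equilibrium_fold(k1: float, k_rev1: float) -> float:
    """Fold by which the closed-A-site structure is favored: ``k_rev1 / k1``."""
    if k1 <= 0:
        raise ValueError("k1 must be positive")
    if k_rev1 < 0:
        raise ValueError("k_rev1 must be non-negative")
    return k_rev1 / k1


def table2_report(
    rate_constants: dict[bool, dict[str, float]] | None = None,
    composites: dict[str, HalfLifeEstimate] | None = None,
    c: float = C_DEFAULT,
    error_method: str = "quadrature",
    step12_bound: float = 10.0,
) -> dict[str, HalfLifeEstimate]:
    """Build the full half-life table.

    Parameters
    ----------
    rate_constants
        ``{eEF2_present: {"k1": .., "k_rev1": .., "k2": ..}}`` (values may be
        floats or ``(value, error)`` pairs). Defaults to the published
        apparent constants.
    composites
        Directly observed half-lives for labels
        ``3, 4+5, 4-8, 7, 7+8, 7-11, 10, 10+11``. Defaults to the published
        values. Missing labels raise, naming every affected row.
    """
    if rate_constants is None:
        rate_constants = constants.APPARENT_RATE_CONSTANTS
    if composites is None:
        composites = {
            label: HalfLifeEstimate(label, v, e, method="direct_fit")
            for label, (v, e) in constants.OBSERVED_COMPOSITE_T_HALF.items()
        }

    required = {"3", "4+5", "4-8", "7", "7+8", "7-11", "10", "10+11"}
    missing = required - set(composites)
    if missing:
        affected = set(missing)
        for step, (comp, parts) in SUBTRACTION_ROWS.items():
            if comp in missing or any(p in missing for p in parts):
                affected.add(step)
        raise ValueError(
            "missing composite half-lives "
            f"{sorted(missing)}; affected rows {sorted(affected)}"
        )

    rows: dict[str, HalfLifeEstimate] = {}
    for eEF2, suffix in ((False, ""), (True, " (+eEF2)")):
        ks = {name: _value(v) for name, v in rate_constants[eEF2].items()}
        rows["1" + suffix] = HalfLifeEstimate(
            "1" + suffix, t_half_step1(ks["k1"], ks["k_rev1"], ks["k2"], c), method="formula"
        )
        rows["2" + suffix] = HalfLifeEstimate(
            "2" + suffix, t_half_step2(ks["k_rev1"], ks["k2"], c), method="formula"
        )

    for label in required:
        est = composites[label]
        rows[label] = replace(est, step_label=label)

    for step, (comp, parts) in SUBTRACTION_ROWS.items():
        rows[step] = t_half_by_subtraction(
            rows[comp], [rows[p] for p in parts], step_label=step, error_method=error_method
        )

    rows["12"] = HalfLifeEstimate(
        "12", step12_bound, method="bound", is_upper_bound=True
    )
    return {label: rows[label] for label in TABLE_ORDER}


def _value(v) -> float:
    return float(v[0]) if isinstance(v, (tuple, list)) else float(v)


def report_frame(
    rows: dict[str, HalfLifeEstimate],
    published: dict[str, tuple[float, float, bool]] | None = None,
) -> pd.DataFrame:
    """Tabulate estimates, annotating divergence from published values."""
    if published is None:
        published = constants.PUBLISHED_T_HALF
    records = []
    for label, est in rows.items():
        pub = published.get(label)
        div = ""
        if pub is not None and not est.is_upper_bound:
            delta = est.value - pub[0]
            if abs(delta) > 0.5:
                div = f"differs from published {pub[0]:g} by {delta:+.1f} s"
        records.append(
            {
                "step": label,
                "t_half_s": est.value,
                "error_s": est.error,
                "method": est.method,
                "is_upper_bound": est.is_upper_bound,
                "published_s": pub[0] if pub else float("nan"),
                "published_error_s": pub[1] if pub else float("nan"),
                "note": est.note or div,
            }
        )
    return pd.DataFrame.from_records(records)
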