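"""The 13-structure, 12-step mass-action scheme of initial IRES-dependent
tetrapeptide synthesis.

The scheme is a linear chain of structures 1..13: an eEF2-modulated
pseudo-translocation equilibrium opening the A site (Step 1, the only
reversible step), ternary-complex binding (Steps 2, 4, 7, 10, apparent
first-order at a stated TC concentration), peptidyl transfer (Steps 5, 8,
11), and pseudo-translocation/translocation (Steps 3, 6, 9, 12). Structure
indexing is 1-based everywhere at the interface.

Assay readouts are linear projections of the occupancy vector: an
:class:`ObservableSpec` assigns each structure a weight in [0, 1] (e.g. the
cosedimentation masks exclude the labile A-site species of the first
elongation cycle) plus a baseline and amplitude in signal units.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

N_STRUCTURES = 13
N_STEPS = 12

#: Steps whose apparent rate is proportional to ternary-complex concentration.
BINDING_STEPS = (2, 4, 7, 10)

_RATE_KEYS = tuple(f"k{i}" for i in range(1, N_STEPS + 1))


@dataclass(frozen=True)
class RateConstantSet:
    """Per-step apparent first-order rate constants (s^-1) of the scheme.

    Parameters
    ----------
    k_fwd
        Forward rate constants for Steps 1..12.
    k_rev1
        Reverse rate of Step 1, the only reversible step.
    tc_concentration
        Ternary-complex concentration (uM) at which the binding steps
        (2, 4, 7, 10) are apparent first-order.
    eEF2_present
        Condition label: whether the complex was preincubated with
        eEF2.GTP. eEF2 is not an explicit species; its presence selects a
        different set of apparent constants.
    """

    k_fwd: tuple[float, ...]
    k_rev1: float = 0.0
    tc_concentration: float = 0.1
    eEF2_present: bool = False

    def __post_init__(self) -> None:
        fwd = tuple(float(k) for k in self.k_fwd)
        if len(fwd) != N_STEPS:
            raise ValueError(f"expected {N_STEPS} forward rates, got {len(fwd)}")
        if not all(np.isfinite(fwd)) or not np.isfinite(self.k_rev1):
            raise ValueError("rate constants must be finite")
        if any(k < 0 for k in fwd) or self.k_rev1 < 0:
            raise ValueError("rate constants must be non-negative")
        if any(fwd[s - 1] > 0 for s in BINDING_STEPS) and self.tc_concentration <= 0:
            raise ValueError("tc_concentration must be > 0 when binding steps are active")
        object.__setattr__(self, "k_fwd", fwd)
        object.__setattr__(self, "k_rev1", float(self.k_rev1))

    def k(self, step: int) -> float:
        """Forward rate constant of ``step`` (1-based)."""
        if not 1 <= step <= N_STEPS:
            raise ValueError(f"step must be in 1..{N_STEPS}, got {step}")
        return self.k_fwd[step - 1]

    def with_rates(self, **rates: float) -> "RateConstantSet":
        """Copy with named rates replaced (keys ``k1``..``k12``, ``k_rev1``)."""
        fwd = list(self.k_fwd)
        k_rev1 = self.k_rev1
        for name, value in rates.items():
            if name == "k_rev1":
                k_rev1 = float(value)
            elif name in _RATE_KEYS:
                fwd[int(name[1:]) - 1] = float(value)
            else:
                raise KeyError(f"unknown rate constant {name!r}")
        return dataclasses.replace(self, k_fwd=tuple(fwd), k_rev1=k_rev1)

    def at_concentration(self, tc_concentration: float) -> "RateConstantSet":
        """Linearly rescale the binding-step constants to a new TC concentration.

        This assumes the apparent binding rate is proportional to [TC]; the
        hook is provided for exploration but is never applied implicitly.
        """
        if tc_concentration <= 0:
            raise ValueError("tc_concentration must be > 0")
        scale = tc_concentration / self.tc_concentration
        fwd = list(self.k_fwd)
        for s in BINDING_STEPS:
            fwd[s - 1] *= scale
        return dataclasses.replace(
            self, k_fwd=tuple(fwd), tc_concentration=float(tc_concentration)
        )

    def rate_matrix(self) -> np.ndarray:
        """Generator matrix ``A`` of the linear system ``dx/dt = A x``.

        Columns are source structures (0-based internally); column sums are
        zero, so total occupancy is conserved.
        """
        A = np.zeros((N_STRUCTURES, N_STRUCTURES))
        for step in range(1, N_STEPS + 1):
            k = self.k_fwd[step - 1]
            src, dst = step - 1, step
            A[src, src] -= k
            A[dst, src] += k
        A[1, 1] -= self.k_rev1
        A[0, 1] += self.k_rev1
        return A

    def as_dict(self) -> dict:
        d = {key: self.k_fwd[i] for i, key in enumerate(_RATE_KEYS)}
        d["k_rev1"] = self.k_rev1
        d["tc_concentration_uM"] = self.tc_concentration
        d["eEF2"] = self.eEF2_present
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RateConstantSet":
        fwd = tuple(float(d.get(key, 0.0)) for key in _RATE_KEYS)
        return cls(
            k_fwd=fwd,
            k_rev1=float(d.get("k_rev1", 0.0)),
            tc_concentration=float(d.get("tc_concentration_uM", 0.1)),
            eEF2_present=bool(d.get("eEF2", False)),
        )


@dataclass(frozen=True)
class SpeciesState:
    """Occupancy over structures 1..13 as fractions of the total complex."""

    occupancy: np.ndarray
    total: float = 1.0

    def __post_init__(self) -> None:
        occ = np.asarray(self.occupancy, dtype=float)
        if occ.shape != (N_STRUCTURES,):
            raise ValueError(f"occupancy must have shape ({N_STRUCTURES},)")
        if np.any(occ < -1e-9) or np.any(occ > self.total + 1e-9):
            raise ValueError("occupancies must lie in [0, total]")
        if not np.isclose(occ.sum(), self.total, rtol=1e-6, atol=1e-9):
            raise ValueError("occupancies must sum to total")
        occ.flags.writeable = False
        object.__setattr__(self, "occupancy", occ)
        object.__setattr__(self, "total", float(self.total))

    @classmethod
    def point(cls, structure: int, total: float = 1.0) -> "SpeciesState":
        """All complexes in one structure (1-based)."""
        if not 1 <= structure <= N_STRUCTURES:
            raise ValueError(f"structure must be in 1..{N_STRUCTURES}")
        occ = np.zeros(N_STRUCTURES)
        occ[structure - 1] = total
        return cls(occ, total)

    @classmethod
    def mixture(cls, fractions: dict[int, float], total: float = 1.0) -> "SpeciesState":
        """State from a {structure: fraction} mapping; fractions must sum to 1."""
        occ = np.zeros(N_STRUCTURES)
        for structure, frac in fractions.items():
            if not 1 <= structure <= N_STRUCTURES:
                raise ValueError(f"structure must be in 1..{N_STRUCTURES}")
            occ[structure - 1] = frac * total
        return cls(occ, total)

    def fraction(self, structure: int) -> float:
        """Occupancy of ``structure`` (1-based) as a fraction of total."""
        return float(self.occupancy[structure - 1] / self.total)


@dataclass(frozen=True)
class ObservableSpec:
    """Projection of a :class:`SpeciesState` onto one assay signal.

    ``signal = baseline + amplitude * sum_i weight[i] * occupancy[i] / total``
    """

    name: str
    weights: np.ndarray
    baseline: float = 0.0
    amplitude: float = 1.0

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.shape != (N_STRUCTURES,):
            raise ValueError(f"weights must have shape ({N_STRUCTURES},)")
        if np.any(w < 0) or np.any(w > 1):
            raise ValueError("weights must lie in [0, 1]")
        w.flags.writeable = False
        object.__setattr__(self, "weights", w)

    def signal(self, state: "SpeciesState | np.ndarray", total: float = 1.0):
        """Signal for a single state or an (n_times, 13) occupancy array."""
        if isinstance(state, SpeciesState):
            occ, total = state.occupancy, state.total
        else:
            occ = np.asarray(state, dtype=float)
        return self.baseline + self.amplitude * (occ @ self.weights) / total

    def replace(self, **changes) -> "ObservableSpec":
        return dataclasses.replace(self, **changes)


def _mask(structures) -> np.ndarray:
    w = np.zeros(N_STRUCTURES)
    for s in structures:
        w[s - 1] = 1.0
    return w


def default_observables() -> dict[str, ObservableSpec]:
    """The assay projections used throughout.

    - ``anisotropy``: labeled Phe-tRNA bound to the A or P site (structures
      3 and 4; the assay is only used for the initial-binding experiments,
      where no later structure is populated).
    - ``cosed_phe``: labeled Phe species that survive ultracentrifugation.
      A-site binding in structure 3 is too labile to pellet, as are the
      A-site peptidyl-tRNAs of the first elongation cycle (structures 5, 6).
    - ``cosed_met``: labeled Met species that cosediment. Structures 5 and 6
      are labile; the A-site Met/peptidyl-tRNAs of the later cycles
      (structures 8, 9, 11, 12) pellet efficiently.
    - ``peptide_di``/``peptide_tri``/``peptide_tetra``: cumulative peptide-bond
      formation (first bond at structure 6, second at 9, third at 12).
    - ``puromycin_bound``: label still ribosome-bound in the puromycin
      loss-of-cosedimentation assay; the reacted adduct is released. The
      kinetics of that assay are modeled in :mod:`ireskinetics.puromycin`.
    """
    return {
        "anisotropy": ObservableSpec("anisotropy", _mask([3, 4])),
        "cosed_phe": ObservableSpec("cosed_phe", _mask([4] + list(range(7, 14)))),
        "cosed_met": ObservableSpec("cosed_met", _mask(range(7, 14))),
        "peptide_di": ObservableSpec("peptide_di", _mask(range(6, 14))),
        "peptide_tri": ObservableSpec("peptide_tri", _mask(range(9, 14))),
        "peptide_tetra": ObservableSpec("peptide_tetra", _mask(range(12, 14))),
        "puromycin_bound": ObservableSpec("puromycin_bound", np.ones(N_STRUCTURES)),
    }


@dataclass(frozen=True)
class Reaction:
    """One step of the chain: ``source -> target`` at rate ``rate`` (s^-1)."""

    step: int
    source: int
    target: int
    rate: float
    reverse_rate: float = 0.0


@dataclass(frozen=True)
class Scheme:
    """An ordered set of reactions, possibly truncated to start mid-chain."""

    start_structure: int
    reactions: tuple[Reaction, ...]
    rates: RateConstantSet

    def rate_matrix(self) -> np.ndarray:
        """Generator matrix including only this scheme's reactions."""
        A = np.zeros((N_STRUCTURES, N_STRUCTURES))
        for r in self.reactions:
            A[r.source - 1, r.source - 1] -= r.rate
            A[r.target - 1, r.source - 1] += r.rate
            if r.reverse_rate:
                A[r.target - 1, r.target - 1] -= r.reverse_rate
                A[r.source - 1, r.target - 1] += r.reverse_rate
        return A


def build_scheme(start_structure: int, rates: RateConstantSet) -> Scheme:
    """The linear chain truncated to begin at ``start_structure``.

    Returns the ``13 - start_structure`` forward reactions from
    ``start_structure`` onward; the Step 1 reverse reaction is included only
    when the chain starts at structure 1.
    """
    if not isinstance(start_structure, (int, np.integer)) or not 1 <= start_structure <= N_STRUCTURES:
        raise ValueError(f"start_structure must be in 1..{N_STRUCTURES}, got {start_structure}")
    reactions = []
    for step in range(start_structure, N_STEPS + 1):
        rev = rates.k_rev1 if step == 1 else 0.0
        reactions.append(Reaction(step, step, step + 1, rates.k(step), rev))
    return Scheme(int(start_structure), tuple(reactions), rates)


def ode_rhs(state: SpeciesState, rates: RateConstantSet) -> np.ndarray:
    """Mass-action occupancy derivatives (per second); sums to zero."""
    return rates.rate_matrix() @ state.occupancy


def load_rate_constants(path: str | Path) -> RateConstantSet:
    """Read a rate-constant config (YAML/JSON dialect).

    Keys: ``k1``..``k12``, ``k_rev1``, ``tc_concentration_uM``, ``eEF2``.
    Missing rate keys default to zero.
    """
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ValueError(f"{path}: expected a mapping of rate constants")
    unknown = set(data) - set(_RATE_KEYS) - {"k_rev1", "tc_concentration_uM", "eEF2"}
    if unknown:
        raise ValueError(f"{path}: unknown keys {sorted(unknown)}")
    return RateConstantSet.from_dict(data)


def save_rate_constants(rates: RateConstantSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(rates.as_dict(), fh, sort_keys=False)
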