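"""Theoretical ion m/z for PTR-MS soft-ionization channels.

Reagent ions (H₃O⁺, O₂⁺, NO⁺) ionize a neutral M through one of five
channels, each shifting the detected mass by a fixed amount:

=====================  =======================  ==================
channel                product ion              label m/z shift (u)
=====================  =======================  ==================
protonation            M·H⁺                     +1.007825
charge transfer        M⁺                        0
hydride abstraction    (M−H)⁺                   −1.007825
hydroxide abstraction  (M−OH)⁺                  −17.002740
NO⁺ clustering         M·NO⁺                    +29.997989
=====================  =======================  ==================

Two mass conventions are supported.  ``LABEL`` (default) adds/removes
whole-atom masses and neglects the electron mass — this is how PTR-MS
peak labels are conventionally printed.  ``PHYSICAL`` additionally
subtracts one electron mass per positive charge, giving the exact ion
mass (protonation = M + 1.007276).  The two differ by exactly
0.000549 u.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from typing import Dict, List, Mapping, Sequence

from .errors import InputError, InvalidParameterError, ModeError, UnknownElementError
from .units import ELECTRON_MASS_U, MONOISOTOPIC_MASS_U

__all__ = [
    "SumFormula",
    "IonMode",
    "MassConvention",
    "IonSpecies",
    "PeakMatch",
    "monoisotopic_mass",
    "ion_mz",
    "round_half_up",
    "assign_peak",
]

_FORMULA_RE = re.compile(r"([A-Z][a-z]?)(\d*)")

_H = MONOISOTOPIC_MASS_U["H"]
_OH = MONOISOTOPIC_MASS_U["O"] + _H
_NO = MONOISOTOPIC_MASS_U["N"] + MONOISOTOPIC_MASS_U["O"]


class IonMode(str, enum.Enum):
    PROTONATION = "protonation"
    CHARGE_TRANSFER = "charge_transfer"
    HYDRIDE_ABSTRACTION = "hydride_abstraction"
    HYDROXIDE_ABSTRACTION = "hydroxide_abstraction"
    NO_CLUSTER = "no_cluster"


class MassConvention(str, enum.Enum):
    LABEL = "label"        # whole-atom masses, electron mass neglected
    PHYSICAL = "physical"  # exact ion mass (electron mass accounted)


_MODE_SHIFT_U: Dict[IonMode, float] = {
    IonMode.PROTONATION: +_H,
    IonMode.CHARGE_TRANSFER: 0.0,
    IonMode.HYDRIDE_ABSTRACTION: -_H,
    IonMode.HYDROXIDE_ABSTRACTION: -_OH,
    IonMode.NO_CLUSTER: +_NO,
}


@dataclass(frozen=True)
class SumFormula:
    """Elemental composition of a neutral molecule (or bare cation skeleton)."""

    element_counts: Mapping[str, int]

    def __post_init__(self) -> None:
        counts = {e: int(n) for e, n in self.element_counts.items() if n}
        unknown = set(counts) - set(MONOISOTOPIC_MASS_U)
        if unknown:
            raise UnknownElementError(
                f"unsupported element(s): {sorted(unknown)}; "
                f"supported: {sorted(MONOISOTOPIC_MASS_U)}")
        if any(n < 0 for n in counts.values()):
            raise InvalidParameterError("element counts must be non-negative")
        if not counts:
            raise InvalidParameterError("formula must contain at least one atom")
        object.__setattr__(self, "element_counts", dict(counts))

    @classmethod
    def parse(cls, text: str) -> "SumFormula":
        """Parse Hill-style notation like ``'C10H16'`` or ``'CH4S'``."""
        text = text.strip()
        counts: Dict[str, int] = {}
        pos = 0
        for match in _FORMULA_RE.finditer(text):
            if not match.group(0):
                continue
            if match.start() != pos:
                raise InputError(f"cannot parse formula {text!r}")
            pos = match.end()
            element = match.group(1)
            counts[element] = counts.get(element, 0) + int(match.group(2) or 1)
        if pos != len(text) or not counts:
            raise InputError(f"cannot parse formula {text!r}")
        return cls(counts)

    def count(self, element: str) -> int:
        return self.element_counts.get(element, 0)

    def __str__(self) -> str:
        order = ["C", "H"] + sorted(set(self.element_counts) - {"C", "H"})
        return "".join(f"{e}{self.element_counts[e] if self.element_counts[e] > 1 else ''}"
                       for e in order if e in self.element_counts)


def monoisotopic_mass(formula: SumFormula) -> float:
    """Sum of most-abundant-isotope atomic masses, u."""
    return sum(MONOISOTOPIC_MASS_U[e] * n for e, n in formula.element_counts.items())


def _check_mode(formula: SumFormula, mode: IonMode) -> None:
    if mode is IonMode.HYDRIDE_ABSTRACTION and formula.count("H") < 1:
        raise ModeError(f"hydride abstraction needs >= 1 H in {formula}")
    if mode is IonMode.HYDROXIDE_ABSTRACTION and (
            formula.count("O") < 1 or formula.count("H") < 1):
        raise ModeError(f"hydroxide abstraction needs >= 1 O and >= 1 H in {formula}")


def ion_mz(formula: SumFormula, mode: IonMode | str,
           convention: MassConvention | str = MassConvention.LABEL) -> float:
    """Theoretical m/z (u, singly charged) of the ion produced by ``mode``."""
    mode = IonMode(mode)
    convention = MassConvention(convention)
    _check_mode(formula, mode)
    mz = monoisotopic_mass(formula) + _MODE_SHIFT_U[mode]
    if convention is MassConvention.PHYSICAL:
        mz -= ELECTRON_MASS_U
    return mz


def round_half_up(value: float, ndigits: int = 3) -> float:
    """Round half away from zero (matches printed peak labels)."""
    quantum = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(quantum, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class IonSpecies:
    """A candidate ion: neutral formula, ionization mode, theoretical m/z."""

    neutral: SumFormula
    mode: IonMode
    convention: MassConvention = MassConvention.LABEL
    name: str = ""
    mz: float = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "mode", IonMode(self.mode))
        object.__setattr__(self, "convention", MassConvention(self.convention))
        object.__setattr__(self, "mz",
                           ion_mz(self.neutral, self.mode, self.convention))

    @property
    def label(self) -> float:
        """m/z rounded half-up to 3 decimals, as printed on spectra."""
        return round_half_up(self.mz, 3)


@dataclass(frozen=True)
class PeakMatch:
    species: IonSpecies
    delta_mda: float  # signed measured - theoretical, milli-dalton


def assign_peak(measured_mz: float, candidates: Sequence[IonSpecies],
                tolerance_mda: float = 5.0) -> List[PeakMatch]:
    """Candidates within ``tolerance_mda`` of ``measured_mz``, best first.

    Returns an empty list when no candidate matches.
    """
    if tolerance_mda <= 0:
        raise InvalidParameterError("tolerance must be positive")
    matches = []
    for species in candidates:
        delta_mda = (measured_mz - species.mz) * 1.0e3
        if abs(delta_mda) <= tolerance_mda:
            matches.append(PeakMatch(species, delta_mda))
    return sorted(matches, key=lambda m: abs(m.delta_mda))
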