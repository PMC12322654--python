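"""Eyring thermokinetics for thermal cis->trans relaxation.

Converts between relaxation half-lives, first-order rate constants and
activation free energies via the Eyring equation

    k = kappa * (kB*T/h) * exp(-dG/(R*T)),    kappa = 1,

and extrapolates half-lives across temperatures under the assumption that
dG (the activation free energy) is temperature-independent.  Single-
temperature measurements cannot separate the enthalpic and entropic parts of
the barrier, so this is the only defensible default; an Arrhenius mode with a
fixed pre-exponential factor is available for sensitivity checks.
"""

from __future__ import annotations

import logging
import math
import re
import warnings
from dataclasses import dataclass
from enum import Enum
from typing import Iterable

import pandas as pd

from .constants import H, KAPPA, KB, LN2, R_KCAL

logger = logging.getLogger(__name__)

__all__ = [
    "Temperature",
    "HalfLife",
    "RateConstant",
    "Provenance",
    "BarrierEstimate",
    "barrier_from_halflife",
    "halflife_from_barrier",
    "extrapolate_halflife",
    "batch_barrier_table",
]

CELSIUS_OFFSET = 273.15

#: seconds per unit, year = 365.25 days
_UNIT_SECONDS = {
    "s": 1.0,
    "sec": 1.0,
    "min": 60.0,
    "h": 3600.0,
    "hr": 3600.0,
    "d": 86400.0,
    "day": 86400.0,
    "y": 365.25 * 86400.0,
    "yr": 365.25 * 86400.0,
}

_HALFLIFE_RE = re.compile(r"^\s*([0-9.eE+-]+)\s*([a-zA-Z]+)\s*$")


@dataclass(frozen=True)
class Temperature:
    """Absolute temperature in kelvin."""

    kelvin: float

    def __post_init__(self) -> None:
        if not (self.kelvin > 0 and math.isfinite(self.kelvin)):
            raise ValueError(f"temperature must be positive and finite, got {self.kelvin} K")

    @classmethod
    def from_celsius(cls, celsius: float) -> "Temperature":
        return cls(celsius + CELSIUS_OFFSET)

    @property
    def celsius(self) -> float:
        return self.kelvin - CELSIUS_OFFSET

    #: room temperature convention used for "rt" entries
    @classmethod
    def room(cls) -> "Temperature":
        return cls(298.15)


@dataclass(frozen=True)
class HalfLife:
    """First-order half-life, stored in seconds."""

    seconds: float

    def __post_init__(self) -> None:
        if not (self.seconds > 0):
            raise ValueError(f"half-life must be positive, got {self.seconds} s")

    @classmethod
    def parse(cls, text: str) -> "HalfLife":
        """Parse strings like ``"3.16 h"``, ``"12.6s"``, ``"7.65 y"``."""
        m = _HALFLIFE_RE.match(text)
        if m is None:
            raise ValueError(f"cannot parse half-life {text!r}")
        value, unit = float(m.group(1)), m.group(2).lower()
        if unit not in _UNIT_SECONDS:
            raise ValueError(f"unknown time unit {unit!r} in {text!r}")
        return cls(value * _UNIT_SECONDS[unit])

    @classmethod
    def from_value(cls, value: float, unit: str = "s") -> "HalfLife":
        unit = unit.lower()
        if unit not in _UNIT_SECONDS:
            raise ValueError(f"unknown time unit {unit!r}")
        return cls(value * _UNIT_SECONDS[unit])

    def to(self, unit: str) -> float:
        return self.seconds / _UNIT_SECONDS[unit.lower()]

    def human(self) -> str:
        """Render with the largest unit keeping the value >= 1."""
        for unit in ("y", "d", "h", "min", "s"):
            v = self.to(unit)
            if v >= 1:
                return f"{v:.3g} {unit}"
        return f"{self.seconds:.3g} s"

    @property
    def rate(self) -> "RateConstant":
        return RateConstant(LN2 / self.seconds)


@dataclass(frozen=True)
class RateConstant:
    """First-order rate constant in 1/s."""

    per_second: float

    def __post_init__(self) -> None:
        if not (self.per_second > 0):
            raise ValueError(f"rate constant must be positive, got {self.per_second} /s")

    @property
    def half_life(self) -> HalfLife:
        return HalfLife(LN2 / self.per_second)


class Provenance(str, Enum):
    from_experiment = "from_experiment"
    supplied_computed = "supplied_computed"


@dataclass(frozen=True)
class BarrierEstimate:
    """Activation free energy dG (kcal/mol) bound to a temperature."""

    delta_g: float
    at_temperature: Temperature
    provenance: Provenance = Provenance.from_experiment

    def __post_init__(self) -> None:
        if not math.isfinite(self.delta_g):
            raise ValueError(f"barrier must be finite, got {self.delta_g}")


def _eyring_prefactor(T: Temperature) -> float:
    """kappa * kB * T / h, in 1/s."""
    return KAPPA * KB * T.kelvin / H


def barrier_from_halflife(t_half: HalfLife, T: Temperature) -> BarrierEstimate:
    """Invert the Eyring equation: dG = R*T*ln(kB*T/(h*k)) with k = ln2/t1/2."""
    k = t_half.rate.per_second
    dg = R_KCAL * T.kelvin * math.log(_eyring_prefactor(T) / k)
    return BarrierEstimate(dg, T, Provenance.from_experiment)


def halflife_from_barrier(dg: BarrierEstimate | float, T: Temperature) -> HalfLife:
    """Eyring equation forward: t1/2 = ln2*h/(kB*T) * exp(dG/(R*T)).

    Very large barriers overflow the exponential; the result is reported as
    ``+inf`` seconds with a warning rather than raising.
    """
    delta_g = dg.delta_g if isinstance(dg, BarrierEstimate) else float(dg)
    exponent = delta_g / (R_KCAL * T.kelvin)
    try:
        t = LN2 / _eyring_prefactor(T) * math.exp(exponent)
    except OverflowError:
        warnings.warn(
            f"barrier {delta_g} kcal/mol at {T.kelvin} K overflows; reporting +inf",
            RuntimeWarning,
            stacklevel=2,
        )
        return HalfLife(math.inf)
    return HalfLife(t)


def extrapolate_halflife(
    t_half: HalfLife,
    T_meas: Temperature,
    T_target: Temperature,
    mode: str = "eyring",
    prefactor: float = 1e13,
) -> HalfLife:
    """Extrapolate a half-life measured at ``T_meas`` to ``T_target``.

    ``mode="eyring"`` (default) assumes the activation free energy is
    temperature-independent.  ``mode="arrhenius"`` assumes a fixed
    pre-exponential factor A (default 1e13 1/s) and a temperature-independent
    activation energy Ea instead.

    Note: the two assumptions give different answers; with single-temperature
    input neither can be validated, so the choice is a modelling one.
    """
    if mode == "eyring":
        dg = barrier_from_halflife(t_half, T_meas)
        return halflife_from_barrier(dg, T_target)
    if mode == "arrhenius":
        k_meas = t_half.rate.per_second
        if k_meas >= prefactor:
            raise ValueError("measured rate exceeds the assumed pre-exponential factor")
        ea_over_r = -T_meas.kelvin * math.log(k_meas / prefactor)  # Ea/R in K
        k_target = prefactor * math.exp(-ea_over_r / T_target.kelvin)
        return RateConstant(k_target).half_life
    raise ValueError(f"unknown extrapolation mode {mode!r}")


def batch_barrier_table(
    records: Iterable[tuple[object, HalfLife | str, Temperature | float]],
) -> pd.DataFrame:
    """Compute barriers for a batch of (compound id, half-life, temperature) rows.

    Half-lives may be :class:`HalfLife` or parseable strings; temperatures may
    be :class:`Temperature` or kelvin floats.  Per-row failures are collected
    in an ``error`` column instead of aborting the batch.  Returns a DataFrame
    with columns ``compound, t_half_s, temp_K, k_per_s, dG_kcal_mol,
    dG_rounded, error``.
    """
    records = list(records)
    if not records:
        raise ValueError("batch_barrier_table requires at least one record")

    ids = [r[0] for r in records]
    dupes = {i for i in ids if ids.count(i) > 1}
    if dupes:
        logger.warning("duplicate compound ids kept as-is: %s", sorted(map(str, dupes)))

    rows = []
    for compound, th, temp in records:
        row: dict[str, object] = {"compound": compound}
        try:
            t_half = HalfLife.parse(th) if isinstance(th, str) else th
            T = temp if isinstance(temp, Temperature) else Temperature(float(temp))
            est = barrier_from_halflife(t_half, T)
            row.update(
                t_half_s=t_half.seconds,
                temp_K=T.kelvin,
                k_per_s=t_half.rate.per_second,
                dG_kcal_mol=est.delta_g,
                dG_rounded=round(est.delta_g, 1),
                error=None,
            )
        except (ValueError, TypeError) as exc:
            row.update(
                t_half_s=float("nan"),
                temp_K=float("nan"),
                k_per_s=float("nan"),
                dG_kcal_mol=float("nan"),
                dG_rounded=float("nan"),
                error=str(exc),
            )
        rows.append(row)
    return pd.DataFrame(rows)
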