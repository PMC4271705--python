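"""Type II functional responses for root nutrient uptake.

Two algebraically identical parameterizations of the same saturating
(Type II) functional response are supported:

* the Michaelis-Menten form used by plant physiologists,
  ``dH/dt = r * Vmax * N / (Km + N)``, whose parameters describe the
  *shape* of the curve (asymptote ``Vmax``, half-saturation ``Km``); and
* the Holling disc-equation form used by foraging ecologists,
  ``dH/dt = r * a * N / (1 + a*h*N)``, whose parameters describe the
  *forager* (encounter rate / search efficiency ``a``, handling time
  ``h``), with a unit of root standing in for the individual forager.

The exact translation between the two is ``a = Vmax/Km`` and
``h = 1/Vmax`` (equivalently ``Vmax = 1/h``, ``Km = 1/(a*h)``); units
translate with the parameters.  Canonical internal units throughout the
package are µmol g⁻¹ min⁻¹ for Vmax, µmol L⁻¹ (µM) for Km and nutrient
concentrations, L g⁻¹ min⁻¹ for ``a`` and min g µmol⁻¹ for ``h``.

The multi-resource disc equation for ``j`` substitutable nutrient forms
(e.g. nitrate and ammonium) is

    dH/dt = r * sum_j(a_j N_j) / (1 + sum_j(a_j h_j N_j)).
"""

from __future__ import annotations

import math
from collections.abc import Mapping, Sequence
from dataclasses import dataclass

import numpy as np

from .exceptions import DomainError, StructuralError

__all__ = [
    "UptakeKinetics",
    "ForagerTraits",
    "NutrientProfile",
    "mm_to_holling",
    "holling_to_mm",
    "harvest_rate_mm",
    "harvest_rate_holling",
    "harvest_rate_multi",
]


def _check_positive_finite(name: str, value: float) -> None:
    if not math.isfinite(value) or value <= 0:
        raise DomainError(f"{name} must be a positive finite number, got {value!r}")


@dataclass(frozen=True)
class UptakeKinetics:
    """Michaelis-Menten uptake parameters per gram of root.

    Parameters
    ----------
    v_max : float
        Maximum influx rate, µmol g⁻¹(root) min⁻¹.
    k_m : float
        Half-saturation constant, µmol L⁻¹ (µM).
    """

    v_max: float
    k_m: float

    def __post_init__(self) -> None:
        _check_positive_finite("v_max", self.v_max)
        _check_positive_finite("k_m", self.k_m)


@dataclass(frozen=True)
class ForagerTraits:
    """Holling disc-equation traits per gram of root.

    Parameters
    ----------
    a : float
        Effective encounter rate (search efficiency), L g⁻¹ min⁻¹.
    h : float
        Handling time, min g µmol⁻¹.
    """

    a: float
    h: float

    def __post_init__(self) -> None:
        _check_positive_finite("a", self.a)
        _check_positive_finite("h", self.h)


@dataclass(frozen=True)
class NutrientProfile:
    """Concentrations of one or more nutrient forms at a location.

    ``concentrations`` are in µmol L⁻¹, aligned with unique ``labels``
    (nutrient form names such as ``"NO3"``, ``"NH4"``).
    """

    concentrations: tuple[float, ...]
    labels: tuple[str, ...]

    def __init__(self, concentrations: Sequence[float], labels: Sequence[str]):
        conc = tuple(float(c) for c in concentrations)
        labs = tuple(str(l) for l in labels)
        if len(conc) != len(labs):
            raise StructuralError(
                f"{len(conc)} concentrations but {len(labs)} labels"
            )
        if len(conc) == 0:
            raise StructuralError("a nutrient profile needs at least one nutrient")
        if len(set(labs)) != len(labs):
            raise StructuralError(f"nutrient labels are not unique: {labs}")
        for lab, c in zip(labs, conc):
            if not math.isfinite(c) or c < 0:
                raise DomainError(
                    f"concentration for {lab!r} must be finite and >= 0, got {c!r}"
                )
        object.__setattr__(self, "concentrations", conc)
        object.__setattr__(self, "labels", labs)

    @property
    def total(self) -> float:
        return float(sum(self.concentrations))

    def as_array(self) -> np.ndarray:
        return np.asarray(self.concentrations, dtype=float)


def mm_to_holling(k: UptakeKinetics) -> ForagerTraits:
    """Translate Michaelis-Menten parameters into foraging traits.

    ``a = Vmax/Km`` (L g⁻¹ min⁻¹) and ``h = 1/Vmax`` (min g µmol⁻¹).
    The translation is exact: both parameterizations draw the same
    functional response.
    """
    return ForagerTraits(a=k.v_max / k.k_m, h=1.0 / k.v_max)


def holling_to_mm(t: ForagerTraits) -> UptakeKinetics:
    """Inverse translation: ``Vmax = 1/h``, ``Km = 1/(a*h)``."""
    return UptakeKinetics(v_max=1.0 / t.h, k_m=1.0 / (t.a * t.h))


def _check_concentration(n: float) -> float:
    n = float(n)
    if not math.isfinite(n) or n < 0:
        raise DomainError(f"nutrient concentration must be finite and >= 0, got {n!r}")
    return n


def _check_root(r: float) -> float:
    r = float(r)
    if not math.isfinite(r) or r < 0:
        raise DomainError(f"root amount must be finite and >= 0, got {r!r}")
    return r


def harvest_rate_mm(r: float, k: UptakeKinetics, n: float) -> float:
    """Whole-root-system harvest rate in the Michaelis-Menten form.

    Parameters
    ----------
    r : float
        Foraging root biomass, g.
    k : UptakeKinetics
        Uptake parameters.
    n : float
        Nutrient concentration, µmol L⁻¹.

    Returns
    -------
    float
        Harvest rate ``r * Vmax * n / (Km + n)``, µmol min⁻¹.
    """
    r = _check_root(r)
    n = _check_concentration(n)
    return r * k.v_max * n / (k.k_m + n)


def harvest_rate_holling(r: float, t: ForagerTraits, n: float) -> float:
    """Per-root Holling disc equation: ``r * a * n / (1 + a*h*n)``."""
    r = _check_root(r)
    n = _check_concentration(n)
    return r * t.a * n / (1.0 + t.a * t.h * n)


def _align_traits(
    traits: Mapping[str, ForagerTraits] | Sequence[ForagerTraits],
    profile: NutrientProfile,
) -> list[ForagerTraits]:
    """Order traits to match the profile's nutrient labels."""
    if isinstance(traits, Mapping):
        missing = [l for l in profile.labels if l not in traits]
        extra = [l for l in traits if l not in profile.labels]
        if missing or extra:
            raise StructuralError(
                f"trait/profile label mismatch: missing traits for {missing}, "
                f"unused traits for {extra}"
            )
        return [traits[l] for l in profile.labels]
    traits = list(traits)
    if len(traits) != len(profile.labels):
        raise StructuralError(
            f"{len(traits)} trait sets for {len(profile.labels)} nutrients"
        )
    return traits


def harvest_rate_multi(
    r: float,
    traits: Mapping[str, ForagerTraits] | Sequence[ForagerTraits],
    profile: NutrientProfile,
) -> float:
    """Multi-resource disc equation over substitutable nutrient forms.

    ``traits`` may be a mapping keyed by nutrient label (checked against
    the profile's labels) or a sequence aligned positionally.  Returns
    ``r * Σ_j a_j N_j / (1 + Σ_j a_j h_j N_j)`` in µmol min⁻¹.
    """
    r = _check_root(r)
    ordered = _align_traits(traits, profile)
    num = 0.0
    denom = 1.0
    for t, n in zip(ordered, profile.concentrations):
        num += t.a * n
        denom += t.a * t.h * n
    return r * num / denom
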