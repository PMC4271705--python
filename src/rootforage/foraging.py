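"""Root foraging precision from the marginal value theorem.

A plant forages for ``j`` substitutable nitrogen forms in a two-habitat
world: one nutrient-rich patch ``p`` and nutrient-poor background soil
``b`` of equal volume, with concentrations held constant (no depletion).
The marginal value theorem says roots should be allocated so the uptake
rates equalize across locations.  Foraging precision is the resulting
optimal ratio of root production in the patch to that in the background,

    P* = r_p*/r_b*
       = [Σ_j N_pj / (1 + Σ_j a_j h_j N_pj)]
         * [(1 + Σ_j a_j h_j N_bj) / Σ_j N_bj],

a dimensionless quantity between 1 (no discrimination) and, in the
single-nutrient case, N_p/N_b (the habitat-matching limit reached as the
interaction term a*h -> 0).  Large encounter rates or handling times
drive P* toward 1: efficient encounterers need little extra root surface
in rich patches, and slow handlers cannot capitalize on them.

The raw equal-rate root ratio implied by literally equating the two
per-unit-root uptake rates is the reciprocal of the expression above; it
is retained on the result object as a diagnostic (``equal_rate_ratio``)
but the model's prediction is P* as defined here, which is what produces
the expected increase of precision with patch quality.
"""

from __future__ import annotations

from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import DomainError, StructuralError
from .kinetics import (
    ForagerTraits,
    NutrientProfile,
    UptakeKinetics,
    mm_to_holling,
)

__all__ = [
    "PatchScenario",
    "PrecisionResult",
    "SweepSpec",
    "precision",
    "allocate_roots",
    "precision_sweep",
    "DRY_NO3_MEANS",
    "DRY_NO3_MEDIANS",
]

#: Mean dry-weight nitrate trait values from the literature compilation
#: of uptake studies; used as defaults for held parameters in sweeps.
DRY_NO3_MEANS: Mapping[str, float] = {
    "a": 0.0511,   # L g^-1 min^-1
    "h": 11.241,   # min g µmol^-1
    "v_max": 2.206,  # µmol g^-1 min^-1
    "k_m": 480.3,    # µmol L^-1
}

#: Median dry-weight nitrate trait values from the same compilation.
DRY_NO3_MEDIANS: Mapping[str, float] = {
    "a": 0.011,
    "h": 1.901,
    "v_max": 0.526,
    "k_m": 44.0,
}


@dataclass(frozen=True)
class PatchScenario:
    """A patch/background pair with the forager's traits.

    ``patch`` and ``background`` must share the same nutrient labels, and
    ``traits`` maps each label to the plant's :class:`ForagerTraits` for
    that nutrient form.
    """

    patch: NutrientProfile
    background: NutrientProfile
    traits: Mapping[str, ForagerTraits]

    def __post_init__(self) -> None:
        if self.patch.labels != self.background.labels:
            raise StructuralError(
                "patch and background nutrient labels differ: "
                f"{self.patch.labels} vs {self.background.labels}"
            )
        missing = [l for l in self.patch.labels if l not in self.traits]
        if missing:
            raise StructuralError(f"no traits supplied for nutrients {missing}")
        if self.background.total <= 0:
            raise DomainError(
                "background concentrations are all zero; the precision "
                "ratio is undefined"
            )

    @classmethod
    def single(
        cls,
        traits: ForagerTraits,
        n_patch: float,
        n_background: float,
        label: str = "N",
    ) -> "PatchScenario":
        """Convenience constructor for a single nutrient form."""
        return cls(
            patch=NutrientProfile([n_patch], [label]),
            background=NutrientProfile([n_background], [label]),
            traits={label: traits},
        )

    def _ordered_traits(self) -> list[ForagerTraits]:
        return [self.traits[l] for l in self.patch.labels]


@dataclass(frozen=True)
class PrecisionResult:
    """Predicted foraging precision plus the terms that built it."""

    p_star: float
    components: Mapping[str, float] = field(default_factory=dict)

    @property
    def equal_rate_ratio(self) -> float:
        """Root ratio from literally equating per-root uptake rates."""
        return self.components["equal_rate_ratio"]


def precision(s: PatchScenario) -> PrecisionResult:
    """Predicted root foraging precision P* for a patch scenario.

    For a single nutrient this equals the ratio of per-unit-root harvest
    rates patch:background.  Raises :class:`DomainError` when the
    background holds no nutrients (the ratio is undefined).
    """
    traits = s._ordered_traits()
    n_p = s.patch.as_array()
    n_b = s.background.as_array()
    ah = np.array([t.a * t.h for t in traits])

    sum_np = float(n_p.sum())
    sum_nb = float(n_b.sum())
    patch_interaction = float(ah @ n_p)       # Σ a_j h_j N_pj
    background_interaction = float(ah @ n_b)  # Σ a_j h_j N_bj

    p_star = (sum_np / (1.0 + patch_interaction)) * (
        (1.0 + background_interaction) / sum_nb
    )
    a_vec = np.array([t.a for t in traits])
    rate_p = float(a_vec @ n_p) / (1.0 + patch_interaction)  # per unit root
    rate_b = float(a_vec @ n_b) / (1.0 + background_interaction)
    components = {
        "sum_patch": sum_np,
        "sum_background": sum_nb,
        "patch_interaction": patch_interaction,
        "background_interaction": background_interaction,
        "per_root_rate_patch": rate_p,
        "per_root_rate_background": rate_b,
        "equal_rate_ratio": rate_b / rate_p if rate_p > 0 else float("inf"),
    }
    return PrecisionResult(p_star=p_star, components=components)


def allocate_roots(s: PatchScenario, total_root: float) -> tuple[float, float]:
    """Split ``total_root`` grams between patch and background.

    Returns ``(r_p, r_b)`` with ``r_p/r_b`` equal to the predicted
    precision and ``r_p + r_b == total_root``.
    """
    total_root = float(total_root)
    if not np.isfinite(total_root) or total_root <= 0:
        raise DomainError(f"total_root must be positive and finite, got {total_root!r}")
    p = precision(s).p_star
    r_b = total_root / (1.0 + p)
    r_p = total_root - r_b
    return r_p, r_b


_SWEEPABLE = ("a", "h", "v_max", "k_m")


@dataclass(frozen=True)
class SweepSpec:
    """Specification of a one-parameter precision sweep.

    One of ``a``, ``h``, ``v_max`` or ``k_m`` is varied over ``grid``
    while its complement (``h`` for ``a`` and vice versa; ``k_m`` for
    ``v_max`` and vice versa) is held at ``held_value``.  Each grid point
    is evaluated at every patch concentration in ``patch_levels`` against
    the common ``background`` concentration.  Michaelis-Menten sweeps are
    translated to (a, h) before evaluating the precision model.
    """

    swept_parameter: str
    grid: tuple[float, ...]
    held_value: float | None = None
    patch_levels: tuple[float, ...] = (0.5, 1.0, 1.5, 2.0)
    background: float = 0.2

    def __post_init__(self) -> None:
        if self.swept_parameter not in _SWEEPABLE:
            raise DomainError(
                f"swept_parameter must be one of {_SWEEPABLE}, "
                f"got {self.swept_parameter!r}"
            )
        grid = tuple(float(g) for g in self.grid)
        if len(grid) == 0:
            raise DomainError("sweep grid is empty")
        if any((not np.isfinite(g)) or g <= 0 for g in grid):
            raise DomainError("sweep grid values must be positive and finite")
        if any(b >= a for b, a in zip(grid, grid[1:])):
            raise DomainError("sweep grid must be strictly increasing")
        object.__setattr__(self, "grid", grid)
        object.__setattr__(self, "patch_levels", tuple(float(p) for p in self.patch_levels))
        if self.background <= 0:
            raise DomainError("background concentration must be positive")
        if any(p < self.background for p in self.patch_levels):
            raise DomainError("patch levels must be >= the background concentration")
        held = self.held_value
        if held is None:
            held = {
                "a": DRY_NO3_MEANS["h"],
                "h": DRY_NO3_MEANS["a"],
                "v_max": DRY_NO3_MEANS["k_m"],
                "k_m": DRY_NO3_MEANS["v_max"],
            }[self.swept_parameter]
        if held <= 0 or not np.isfinite(held):
            raise DomainError(f"held_value must be positive and finite, got {held!r}")
        object.__setattr__(self, "held_value", float(held))

    def traits_at(self, value: float) -> ForagerTraits:
        """Forager traits at one grid point (translating MM sweeps)."""
        held = self.held_value
        if self.swept_parameter == "a":
            return ForagerTraits(a=value, h=held)
        if self.swept_parameter == "h":
            return ForagerTraits(a=held, h=value)
        if self.swept_parameter == "v_max":
            return mm_to_holling(UptakeKinetics(v_max=value, k_m=held))
        return mm_to_holling(UptakeKinetics(v_max=held, k_m=value))


def precision_sweep(spec: SweepSpec) -> pd.DataFrame:
    """Evaluate P* over a parameter grid at several patch qualities.

    Returns a tidy frame with one row per (grid point, patch level) and
    columns ``swept_param, value, patch_conc, background_conc, p_star``.
    """
    rows = []
    for value in spec.grid:
        traits = spec.traits_at(value)
        for n_p in spec.patch_levels:
            scen = PatchScenario.single(traits, n_patch=n_p, n_background=spec.background)
            rows.append(
                {
                    "swept_param": spec.swept_parameter,
                    "value": value,
                    "patch_conc": n_p,
                    "background_conc": spec.background,
                    "p_star": precision(scen).p_star,
                }
            )
    return pd.DataFrame(rows)
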