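"""Synthetic data emulating the statistical structure of the inputs.

Every analysis stage in the package can be exercised without external
downloads: this module generates literature-style trait tables, random
phylogenies and Brownian-motion tip traits, all as pure functions of a
specification plus a seed.

The default trait-table conditions mirror the literature compilation the
package's summaries are modelled on: 45 species drawn from 38 studies,
28 species with estimates for both nitrate and ammonium, 3 species
studied more than once, and log-uniform Vmax/Km marginals spanning the
observed envelope (so derived encounter rates span several orders of
magnitude).  Cross-nutrient dependence is imposed with a Gaussian
copula whose latent correlation is calibrated (via a Hermite-series
expansion of the marginal transform) so that the *population* Pearson
correlation of the ln(x+1)-transformed values equals the requested rho
— the scale on which the cross-nutrient regressions are run.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path

import dendropy
import numpy as np
from numpy.polynomial import hermite_e
from scipy.optimize import brentq
from scipy.stats import norm

from .exceptions import DomainError, StructuralError
from .trait_data import (
    CANONICAL_KM_UNIT,
    CANONICAL_VMAX_UNIT,
    TraitRecord,
    TraitTable,
)

__all__ = [
    "FixtureSpec",
    "gen_trait_table",
    "write_trait_csv",
    "gen_tree",
    "gen_bm_traits",
    "latent_copula_rho",
]


# --- copula calibration --------------------------------------------------

@lru_cache(maxsize=None)
def _hermite_coefficients(log10_lo: float, log10_hi: float, degree: int = 40
                          ) -> tuple[float, ...]:
    """Hermite-series coefficients of z -> ln(1 + 10**(lo+(hi-lo)*Phi(z)))."""
    z, w = hermite_e.hermegauss(120)
    w = w / math.sqrt(2.0 * math.pi)
    fz = np.log1p(10.0 ** (log10_lo + (log10_hi - log10_lo) * norm.cdf(z)))
    coefs = []
    fact = 1.0
    for k in range(degree + 1):
        if k > 0:
            fact *= k
        basis = hermite_e.hermeval(z, [0.0] * k + [1.0])
        coefs.append(float(np.sum(w * fz * basis)) / math.sqrt(fact))
    return tuple(coefs)


def latent_copula_rho(target_rho: float, log10_lo: float, log10_hi: float) -> float:
    """Latent Gaussian correlation yielding ``target_rho`` after transform.

    For a log-uniform marginal on [10**lo, 10**hi], the Pearson
    correlation of the ln(x+1)-transformed pair under a Gaussian copula
    with latent correlation r is ``sum_k c_k^2 r^k / sum_k c_k^2`` where
    c_k are the normalized Hermite coefficients of the marginal
    transform; this inverts that relation.
    """
    if not 0.0 <= target_rho <= 1.0:
        raise DomainError(f"rho must lie in [0, 1], got {target_rho!r}")
    if target_rho in (0.0, 1.0):
        return target_rho
    c = np.array(_hermite_coefficients(float(log10_lo), float(log10_hi)))[1:]
    weights = c**2 / np.sum(c**2)
    powers = np.arange(1, len(c) + 1)

    def achieved(r: float) -> float:
        return float(np.sum(weights * r**powers))

    return brentq(lambda r: achieved(r) - target_rho, 0.0, 1.0, xtol=1e-12)


# --- trait tables --------------------------------------------------------

@dataclass(frozen=True)
class FixtureSpec:
    """Conditions for a synthetic literature trait table.

    Defaults reproduce the structure of the literature compilation:
    ``n_species`` species across ``n_studies`` studies, ``n_both`` of
    them with estimates for both nutrient forms (the rest covered for
    one form only, split by ``p_no3_only``), ``n_multi_study`` species
    with a second independent estimate, a ``p_dry`` fraction of records
    on a dry-weight basis, log-uniform Vmax and Km marginals over
    ``v_max_log10_range`` / ``k_m_log10_range`` (canonical units), and
    cross-nutrient correlation ``rho`` on the ln(x+1) scale.
    """

    n_species: int = 45
    n_studies: int = 38
    n_both: int = 28
    n_multi_study: int = 3
    p_no3_only: float = 0.5
    p_dry: float = 0.5
    v_max_log10_range: tuple[float, float] = (math.log10(0.0183), math.log10(16.0))
    k_m_log10_range: tuple[float, float] = (math.log10(1.45), math.log10(2422.0))
    rho: float = math.sqrt(0.79)
    study_scatter_sd: float = 0.2  # ln-scale jitter of repeat estimates
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_species < 1:
            raise DomainError("n_species must be >= 1")
        if not 0 <= self.n_both <= self.n_species:
            raise DomainError("n_both must lie in [0, n_species]")
        if self.n_studies < 1 or self.n_studies > self.n_species:
            raise DomainError("need 1 <= n_studies <= n_species")
        if self.n_multi_study < 0 or self.n_multi_study > self.n_species:
            raise DomainError("n_multi_study must lie in [0, n_species]")
        for name in ("v_max_log10_range", "k_m_log10_range"):
            lo, hi = getattr(self, name)
            if not (math.isfinite(lo) and math.isfinite(hi) and lo < hi):
                raise DomainError(f"{name} must be a finite increasing pair")
        if not 0.0 <= self.rho <= 1.0:
            raise DomainError("rho must lie in [0, 1]")
        if not 0.0 <= self.p_no3_only <= 1.0 or not 0.0 <= self.p_dry <= 1.0:
            raise DomainError("probabilities must lie in [0, 1]")


def _correlated_loguniform(
    rng: np.random.Generator, n: int, log10_range: tuple[float, float], rho: float
) -> tuple[np.ndarray, np.ndarray]:
    """Paired log-uniform draws with calibrated ln(x+1)-scale correlation."""
    lo, hi = log10_range
    r_latent = latent_copula_rho(rho, lo, hi)
    z1 = rng.standard_normal(n)
    z2 = r_latent * z1 + math.sqrt(1.0 - r_latent**2) * rng.standard_normal(n)
    x1 = 10.0 ** (lo + (hi - lo) * norm.cdf(z1))
    x2 = 10.0 ** (lo + (hi - lo) * norm.cdf(z2))
    return x1, x2


def gen_trait_table(spec: FixtureSpec) -> TraitTable:
    """Generate a synthetic literature trait table.

    Deterministic under ``spec.seed``.  Raises
    :class:`~rootforage.exceptions.StructuralError` if the coverage
    specification leaves no species with both nutrients while pairs are
    implied (``n_both == 0`` with ``n_species >= 2`` is allowed; callers
    wanting pairs should request them).
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_species
    species = [f"sp{i + 1:03d}" for i in range(n)]

    v_no3, v_nh4 = _correlated_loguniform(rng, n, spec.v_max_log10_range, spec.rho)
    k_no3, k_nh4 = _correlated_loguniform(rng, n, spec.k_m_log10_range, spec.rho)

    # coverage: first n_both species have both nutrients (order is then
    # shuffled away by seeded permutation of species indices)
    order = rng.permutation(n)
    both = set(order[: spec.n_both])
    rest = order[spec.n_both:]
    no3_only = set(rest[rng.random(len(rest)) < spec.p_no3_only])
    nh4_only = set(rest) - no3_only

    basis = np.where(rng.random(n) < spec.p_dry, "dry", "fresh")
    study_of = {i: f"study{(i % spec.n_studies) + 1:02d}" for i in range(n)}
    multi = set(int(i) for i in rng.choice(n, size=spec.n_multi_study, replace=False))

    records: list[TraitRecord] = []

    def add(i: int, nutrient: str, v: float, k: float, study: str) -> None:
        records.append(
            TraitRecord(
                species=species[i],
                nutrient=nutrient,
                basis=str(basis[i]),
                v_max=float(v),
                v_max_units=CANONICAL_VMAX_UNIT,
                k_m=float(k),
                k_m_units=CANONICAL_KM_UNIT,
                study_id=study,
            )
        )

    for i in range(n):
        nutrients = []
        if i in both:
            nutrients = ["NO3", "NH4"]
        elif i in no3_only:
            nutrients = ["NO3"]
        elif i in nh4_only:
            nutrients = ["NH4"]
        for nut in nutrients:
            v = v_no3[i] if nut == "NO3" else v_nh4[i]
            k = k_no3[i] if nut == "NO3" else k_nh4[i]
            add(i, nut, v, k, study_of[i])
            if i in multi:
                # an independent re-estimate from a different study
                other = f"study{((i + 7) % spec.n_studies) + 1:02d}"
                if other == study_of[i]:
                    other = f"study{((i + 8) % spec.n_studies) + 1:02d}"
                jitter_v = math.exp(rng.normal(0.0, spec.study_scatter_sd))
                jitter_k = math.exp(rng.normal(0.0, spec.study_scatter_sd))
                add(i, nut, v * jitter_v, k * jitter_k, other)

    if not records:
        raise StructuralError("fixture spec produced an empty table")
    return TraitTable.from_records(records)


def write_trait_csv(table: TraitTable, path: str | Path,
                    spec: FixtureSpec | None = None) -> None:
    """Write a trait table as CSV with a provenance comment block."""
    path = Path(path)
    with open(path, "w", newline="") as fh:
        if spec is not None:
            fh.write(f"# generator: rootforage.fixtures.gen_trait_table\n# spec: {spec}\n")
        table.to_frame().to_csv(fh, index=False)


# --- phylogenies and Brownian traits -------------------------------------

def gen_tree(
    n_tips: int,
    seed: int | None = None,
    model: str = "yule",
    birth_rate: float = 1.0,
    labels: list[str] | None = None,
    ultrametric: bool = True,
) -> dendropy.Tree:
    """Simulate a rooted binary phylogeny with positive branch lengths.

    A Yule (pure-birth) tree with ``n_tips`` extant tips; with
    ``ultrametric=False`` branch lengths receive independent lognormal
    rate multipliers, breaking the equal root-to-tip depths.  Tip labels
    default to ``sp001, sp002, ...`` so trees pair naturally with
    :func:`gen_trait_table` output.
    """
    if n_tips < 4:
        raise DomainError(f"need n_tips >= 4, got {n_tips}")
    if model != "yule":
        raise DomainError(f"unsupported tree model {model!r}")
    if labels is None:
        labels = [f"sp{i + 1:03d}" for i in range(n_tips)]
    if len(labels) != n_tips or len(set(labels)) != n_tips:
        raise StructuralError("labels must be unique and match n_tips")
    pyrng = random.Random(None if seed is None else int(seed))
    from dendropy.simulate import treesim

    taxa = dendropy.TaxonNamespace(labels)
    tree = treesim.birth_death_tree(
        birth_rate=birth_rate,
        death_rate=0.0,
        num_extant_tips=n_tips,
        taxon_namespace=taxa,
        rng=pyrng,
    )
    tree.is_rooted = True
    # the simulator stops exactly at the n-th splitting event, leaving the
    # youngest cherry with zero-length tip edges; extend every leaf edge by
    # half the expected waiting time to the next event so all branches are
    # positive while the tree stays ultrametric
    extension = 0.5 / (birth_rate * n_tips)
    for leaf in tree.leaf_node_iter():
        leaf.edge.length = float(leaf.edge.length or 0.0) + extension
    if not ultrametric:
        rng = np.random.default_rng(None if seed is None else int(seed))
        for edge in tree.preorder_edge_iter():
            if edge.length is not None:
                edge.length = float(edge.length) * float(rng.lognormal(0.0, 0.5))
    return tree


def gen_bm_traits(
    tree: dendropy.Tree,
    sigma2: float,
    seed: int | None = None,
    root_value: float = 0.0,
) -> dict[str, float]:
    """Simulate a Brownian-motion trait along a tree.

    Starting at ``root_value``, each branch adds an independent normal
    increment with variance ``sigma2 * branch_length``; the returned
    mapping gives the trait value at every tip, keyed by taxon label.
    """
    if not (sigma2 > 0 and math.isfinite(sigma2)):
        raise DomainError(f"sigma2 must be positive and finite, got {sigma2!r}")
    rng = np.random.default_rng(seed)
    values: dict[int, float] = {id(tree.seed_node): float(root_value)}
    out: dict[str, float] = {}
    for node in tree.preorder_node_iter():
        if node is not tree.seed_node:
            bl = float(node.edge.length or 0.0)
            parent = values[id(node.parent_node)]
            values[id(node)] = parent + rng.normal(0.0, math.sqrt(sigma2 * bl))
        if node.is_leaf():
            out[node.taxon.label] = values[id(node)]
    return out
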