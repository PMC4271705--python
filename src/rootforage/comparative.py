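"""Comparative analyses of foraging traits.

Three analyses operate on translated literature trait tables:

* **Cross-nutrient regressions** — does a species' foraging ability for
  nitrate predict its ability for ammonium?  Species with estimates for
  both nutrient forms are paired, multi-study values averaged, traits
  ln(x+1)-transformed, fresh- and dry-weight points pooled, and an
  ordinary least-squares line fitted.
* **Phylogenetic signal** — Blomberg's K compares the fit of tip traits
  to the phylogeny against the Brownian-motion expectation (K = 1 under
  Brownian evolution; K << 1 indicates random/convergent trait values),
  with a permutation test shuffling trait values across tips.
* **Equivalence fit** — the Michaelis-Menten and disc-equation
  parameterizations are fitted by nonlinear least squares to the same
  simulated uptake data to demonstrate they describe one functional
  response: the optima coincide after parameter translation.
"""

from __future__ import annotations

import math
from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.optimize import curve_fit

from .exceptions import (
    DegenerateError,
    DomainError,
    InsufficientDataError,
    StructuralError,
)
from .kinetics import ForagerTraits, UptakeKinetics, holling_to_mm, mm_to_holling

__all__ = [
    "PairedTraitSet",
    "RegressionResult",
    "KResult",
    "pair_traits",
    "regress",
    "tree_covariance",
    "blomberg_k",
    "UptakeCurveModel",
    "UptakeCurveResults",
    "EquivalenceFit",
    "equivalence_fit",
]


# --- cross-nutrient pairing and regression -------------------------------

@dataclass(frozen=True)
class PairedTraitSet:
    """Species-level (NO3, NH4) trait pairs on the ln(x+1) scale."""

    trait: str
    species: tuple[str, ...]
    x: np.ndarray  # ln(trait_NO3 + 1)
    y: np.ndarray  # ln(trait_NH4 + 1)
    basis: tuple[str, ...]  # per-species basis tag ("dry"/"fresh"/"mixed")

    @property
    def n(self) -> int:
        return len(self.species)


def pair_traits(translated: pd.DataFrame, trait: str) -> PairedTraitSet:
    """Build NO3/NH4 trait pairs for species covered for both nutrients.

    Within-species multi-study values are averaged on the raw scale
    *before* the ln(x+1) transform; fresh- and dry-weight records are
    pooled (the transform is what makes the bases comparable), with the
    basis retained per point as a tag.  Species observed for only one
    nutrient form are excluded.
    """
    if trait not in ("a", "h", "v_max", "k_m"):
        raise DomainError(f"trait must be one of a/h/v_max/k_m, got {trait!r}")
    if trait not in translated.columns:
        raise StructuralError(f"column {trait!r} absent; run translate_table first")
    agg = (
        translated.groupby(["species", "nutrient"])
        .agg(value=(trait, "mean"), basis=("basis", lambda b: "/".join(sorted(set(b)))))
        .reset_index()
    )
    wide = agg.pivot(index="species", columns="nutrient", values="value")
    if "NO3" not in wide.columns or "NH4" not in wide.columns:
        raise InsufficientDataError("need records for both NO3 and NH4 to pair")
    wide = wide.dropna(subset=["NO3", "NH4"]).sort_index()
    if len(wide) < 3:
        raise InsufficientDataError(
            f"only {len(wide)} species have both NO3 and NH4 estimates; need >= 3"
        )
    basis_map = agg.groupby("species")["basis"].agg(
        lambda b: b.iloc[0] if len(set(b)) == 1 else "mixed"
    )
    species = tuple(wide.index)
    return PairedTraitSet(
        trait=trait,
        species=species,
        x=np.log1p(wide["NO3"].to_numpy(dtype=float)),
        y=np.log1p(wide["NH4"].to_numpy(dtype=float)),
        basis=tuple(basis_map.loc[list(species)]),
    )


@dataclass(frozen=True)
class RegressionResult:
    """Simple-regression fit of ammonium trait on nitrate trait."""

    slope: float
    intercept: float
    r_squared: float
    f_statistic: float
    df: tuple[int, int]
    p_value: float
    n: int

    def summary(self) -> str:
        return (
            f"OLS y ~ x, n={self.n}: slope={self.slope:.4f}, "
            f"intercept={self.intercept:.4f}, R^2={self.r_squared:.3f}, "
            f"F({self.df[0]},{self.df[1]})={self.f_statistic:.2f}, "
            f"p={self.p_value:.3g}"
        )


def regress(p: PairedTraitSet) -> RegressionResult:
    """Ordinary least squares of the NH4 trait on the NO3 trait."""
    if p.n < 3:
        raise InsufficientDataError(f"need >= 3 pairs, got {p.n}")
    if np.allclose(np.var(p.x), 0.0):
        raise DegenerateError("zero variance in x; regression is undefined")
    model = sm.OLS(p.y, sm.add_constant(p.x))
    fit = model.fit()
    return RegressionResult(
        slope=float(fit.params[1]),
        intercept=float(fit.params[0]),
        r_squared=float(fit.rsquared),
        f_statistic=float(fit.fvalue),
        df=(1, p.n - 2),
        p_value=float(fit.f_pvalue),
        n=p.n,
    )


# --- phylogenetic signal -------------------------------------------------

def tree_covariance(
    tree: dendropy.Tree,
    taxa: Sequence[str] | None = None,
    min_branch_length: float = 1e-8,
) -> tuple[np.ndarray, list[str]]:
    """Brownian-motion covariance matrix implied by a rooted tree.

    ``C[i, j]`` is the shared root-to-tip path length of tips i and j.
    Polytomies are resolved arbitrarily with zero-length internal edges
    and every branch length (missing ones count as zero) is floored at
    ``min_branch_length`` so the matrix is positive definite.  Tips are
    returned in canonical (sorted-label) order, restricted to ``taxa``
    when given.
    """
    tree = tree.clone(depth=1)
    tree.resolve_polytomies()
    for edge in tree.preorder_edge_iter():
        if edge.head_node is tree.seed_node:
            continue
        if edge.length is None or edge.length < min_branch_length:
            edge.length = min_branch_length

    depth = {tree.seed_node: 0.0}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        depth[node] = depth[node.parent_node] + node.edge.length

    leaves = {lf.taxon.label: lf for lf in tree.leaf_node_iter()}
    labels = sorted(leaves) if taxa is None else sorted(taxa)
    missing = [l for l in labels if l not in leaves]
    if missing:
        raise StructuralError(f"tips absent from tree: {missing}")

    # shared path length = depth of the MRCA
    n = len(labels)
    cov = np.zeros((n, n))
    # ancestors of each requested leaf, root-first
    anc: dict[str, list] = {}
    for lab in labels:
        chain = []
        node = leaves[lab]
        while node is not None:
            chain.append(node)
            node = node.parent_node
        anc[lab] = chain[::-1]
    for i, li in enumerate(labels):
        cov[i, i] = depth[leaves[li]]
        for j in range(i + 1, n):
            ci, cj = anc[li], anc[labels[j]]
            k = 0
            while k < min(len(ci), len(cj)) and ci[k] is cj[k]:
                k += 1
            mrca = ci[k - 1]
            cov[i, j] = cov[j, i] = depth[mrca]
    return cov, labels


@dataclass(frozen=True)
class KResult:
    """Blomberg's K with its permutation test."""

    k: float
    p_value: float
    n_perm: int
    seed: int | None
    n_tips: int
    unmatched_tips: tuple[str, ...] = ()
    unmatched_traits: tuple[str, ...] = ()

    def to_dict(self) -> dict:
        return {
            "k": self.k,
            "p_value": self.p_value,
            "n_perm": self.n_perm,
            "seed": self.seed,
            "n_tips": self.n_tips,
            "unmatched_tips": list(self.unmatched_tips),
            "unmatched_traits": list(self.unmatched_traits),
        }


def _k_statistic(x: np.ndarray, vinv: np.ndarray, trace_v: float, sum_vinv: float,
                 n: int, expected_ratio: float) -> tuple[float, float]:
    """Return (K, GLS mean-squared error) for one trait vector."""
    ones = np.ones(n)
    a_hat = (ones @ vinv @ x) / sum_vinv  # phylogenetically corrected mean
    dev = x - a_hat
    mse0 = float(dev @ dev) / (n - 1)
    mse = float(dev @ vinv @ dev) / (n - 1)
    if mse <= 0:
        raise DegenerateError("zero phylogenetically-corrected variance")
    return (mse0 / mse) / expected_ratio, mse


def blomberg_k(
    tree: dendropy.Tree,
    traits: Mapping[str, float],
    n_perm: int = 999,
    seed: int | None = None,
    min_branch_length: float = 1e-8,
) -> KResult:
    """Blomberg's K statistic and permutation p-value for tip traits.

    K is the ratio (MSE0/MSE) observed over its Brownian-motion
    expectation on the given tree, where MSE0 is the mean squared tip
    deviation from the phylogenetically corrected mean and MSE the
    generalized-least-squares error under the tree's Brownian covariance.
    The p-value shuffles trait values across tips and counts permutations
    whose phylogenetically corrected variance (MSE) is <= the observed
    one, with +1 smoothing: ``p = (1 + n_extreme) / (1 + n_perm)``.

    Tips and trait species are matched by label; the analysis runs on
    their intersection and reports the leftovers.  Requires >= 4 matched
    tips and a non-constant trait.
    """
    tip_labels = {lf.taxon.label for lf in tree.leaf_node_iter()}
    matched = sorted(tip_labels & set(traits))
    unmatched_tips = tuple(sorted(tip_labels - set(traits)))
    unmatched_traits = tuple(sorted(set(traits) - tip_labels))
    if len(matched) < 4:
        raise InsufficientDataError(
            f"only {len(matched)} species match between tree and traits; need >= 4"
        )
    x = np.array([float(traits[s]) for s in matched])
    if np.ptp(x) == 0:
        raise DegenerateError("trait is constant across all matched tips")

    cov, labels = tree_covariance(tree, taxa=matched, min_branch_length=min_branch_length)
    n = len(labels)
    vinv = np.linalg.inv(cov)
    sum_vinv = float(vinv.sum())
    trace_v = float(np.trace(cov))
    expected_ratio = (trace_v - n / sum_vinv) / (n - 1)

    k_obs, mse_obs = _k_statistic(x, vinv, trace_v, sum_vinv, n, expected_ratio)

    rng = np.random.default_rng(seed)
    n_extreme = 0
    for _ in range(n_perm):
        xp = rng.permutation(x)
        _, mse_p = _k_statistic(xp, vinv, trace_v, sum_vinv, n, expected_ratio)
        if mse_p <= mse_obs:
            n_extreme += 1
    p_value = (1 + n_extreme) / (1 + n_perm)
    return KResult(
        k=k_obs,
        p_value=p_value,
        n_perm=n_perm,
        seed=seed,
        n_tips=n,
        unmatched_tips=unmatched_tips,
        unmatched_traits=unmatched_traits,
    )


# --- equivalence of the two parameterizations ----------------------------

def _mm_curve(n, v_max, k_m):
    return v_max * n / (k_m + n)


def _holling_curve(n, a, h):
    return a * n / (1.0 + a * h * n)


class UptakeCurveModel:
    """Nonlinear least-squares model for a single uptake curve.

    Fits either the Michaelis-Menten (``parameterization="mm"``) or the
    disc-equation (``"holling"``) form of the Type II functional
    response to (concentration, rate) data, statsmodels-style: construct
    from data, call :meth:`fit`, inspect the returned results object.
    """

    def __init__(self, rates: np.ndarray, concentrations: np.ndarray,
                 parameterization: str = "mm"):
        self.rates = np.asarray(rates, dtype=float)
        self.conc = np.asarray(concentrations, dtype=float)
        if self.rates.shape != self.conc.shape or self.rates.ndim != 1:
            raise StructuralError("rates and concentrations must be equal-length 1-D")
        if len(self.rates) < 5:
            raise InsufficientDataError("need >= 5 points to fit two parameters")
        if np.any(self.conc < 0):
            raise DomainError("concentrations must be >= 0")
        if parameterization not in ("mm", "holling"):
            raise DomainError(f"unknown parameterization {parameterization!r}")
        self.parameterization = parameterization
        self._curve = _mm_curve if parameterization == "mm" else _holling_curve
        self.param_names = ("v_max", "k_m") if parameterization == "mm" else ("a", "h")

    def _start(self) -> tuple[float, float]:
        v0 = max(float(np.max(self.rates)), 1e-12)
        # concentration where the rate first exceeds half the apparent max
        half = self.conc[np.argmax(self.rates >= v0 / 2)]
        k0 = max(float(half), float(np.median(self.conc)), 1e-12)
        if self.parameterization == "mm":
            return v0, k0
        return v0 / k0, 1.0 / v0

    def fit(self, p0: tuple[float, float] | None = None,
            maxfev: int = 20000) -> "UptakeCurveResults":
        p0 = self._start() if p0 is None else p0
        converged = True
        message = "converged"
        try:
            params, pcov = curve_fit(
                self._curve, self.conc, self.rates, p0=p0, maxfev=maxfev,
                bounds=([1e-300, 1e-300], [np.inf, np.inf]),
                xtol=1e-14, ftol=1e-14, gtol=1e-14,
            )
        except RuntimeError as exc:  # non-convergence is a flagged result
            converged = False
            message = str(exc)
            params = np.array(p0, dtype=float)
            pcov = np.full((2, 2), np.nan)
        resid = self.rates - self._curve(self.conc, *params)
        return UptakeCurveResults(
            model=self,
            params=np.asarray(params, dtype=float),
            cov_params=np.asarray(pcov, dtype=float),
            rss=float(resid @ resid),
            converged=converged,
            message=message,
        )


@dataclass(frozen=True)
class UptakeCurveResults:
    """Fit results for one parameterization of the uptake curve."""

    model: UptakeCurveModel
    params: np.ndarray
    cov_params: np.ndarray
    rss: float
    converged: bool
    message: str = ""

    @property
    def bse(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov_params))

    def predict(self, concentrations: np.ndarray) -> np.ndarray:
        return self.model._curve(np.asarray(concentrations, dtype=float), *self.params)

    def as_traits(self) -> ForagerTraits:
        if self.model.parameterization == "holling":
            return ForagerTraits(a=self.params[0], h=self.params[1])
        return mm_to_holling(UptakeKinetics(v_max=self.params[0], k_m=self.params[1]))

    def as_kinetics(self) -> UptakeKinetics:
        if self.model.parameterization == "mm":
            return UptakeKinetics(v_max=self.params[0], k_m=self.params[1])
        return holling_to_mm(ForagerTraits(a=self.params[0], h=self.params[1]))

    def summary(self) -> str:
        lines = [
            f"Uptake curve fit ({self.model.parameterization} parameterization), "
            f"n={len(self.model.rates)}",
            f"  converged: {self.converged}",
        ]
        for name, value, se in zip(self.model.param_names, self.params, self.bse):
            lines.append(f"  {name} = {value:.6g} (se {se:.3g})")
        lines.append(f"  RSS = {self.rss:.6g}")
        return "\n".join(lines)


@dataclass(frozen=True)
class EquivalenceFit:
    """Both parameterizations fitted to the same data."""

    mm: UptakeCurveResults
    holling: UptakeCurveResults
    concentrations: np.ndarray = field(repr=False, default=None)
    rates: np.ndarray = field(repr=False, default=None)

    @property
    def converged(self) -> bool:
        return self.mm.converged and self.holling.converged

    @property
    def rss_rel_diff(self) -> float:
        denom = max(abs(self.mm.rss), abs(self.holling.rss), 1e-300)
        return abs(self.mm.rss - self.holling.rss) / denom

    @property
    def translation_rel_err(self) -> float:
        """Relative disagreement between fitted a,h and translated Vmax,Km."""
        t_direct = self.holling.as_traits()
        t_translated = self.mm.as_traits()
        return max(
            abs(t_direct.a - t_translated.a) / t_direct.a,
            abs(t_direct.h - t_translated.h) / t_direct.h,
        )

    def max_curve_rel_diff(self, concentrations: np.ndarray | None = None) -> float:
        c = self.concentrations if concentrations is None else np.asarray(concentrations)
        c = c[c > 0]
        y1, y2 = self.mm.predict(c), self.holling.predict(c)
        return float(np.max(np.abs(y1 - y2) / np.maximum(np.abs(y1), 1e-300)))


def equivalence_fit(
    n_points: int,
    true_kinetics: UptakeKinetics,
    noise: float = 0.0,
    seed: int | None = None,
) -> EquivalenceFit:
    """Fit both parameterizations to one simulated uptake data set.

    ``n_points`` concentrations are log-spaced from Km/10 to 10*Km; the
    per-gram uptake rate at each is the Michaelis-Menten value plus
    Gaussian noise with standard deviation ``noise * Vmax``.  Because the
    two forms draw the same curve, the fits share their optimum: the
    residual sums of squares coincide and the fitted (a, h) equals the
    translated fitted (Vmax, Km) up to optimizer tolerance.
    """
    if n_points < 5:
        raise InsufficientDataError("need n_points >= 5")
    if noise < 0 or not math.isfinite(noise):
        raise DomainError(f"noise must be >= 0, got {noise!r}")
    rng = np.random.default_rng(seed)
    conc = np.geomspace(true_kinetics.k_m / 10.0, true_kinetics.k_m * 10.0, n_points)
    rates = _mm_curve(conc, true_kinetics.v_max, true_kinetics.k_m)
    if noise > 0:
        rates = rates + rng.normal(0.0, noise * true_kinetics.v_max, size=n_points)
    mm_fit = UptakeCurveModel(rates, conc, "mm").fit()
    holling_fit = UptakeCurveModel(rates, conc, "holling").fit()
    return EquivalenceFit(mm=mm_fit, holling=holling_fit,
                          concentrations=conc, rates=rates)
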