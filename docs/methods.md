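# Methods

## The model

Both parameterizations of the Type II functional response are kept as
first-class objects. The Michaelis–Menten form
`dH/dt = r·Vmax·N/(Km+N)` and the disc-equation form
`dH/dt = r·a·N/(1+a·h·N)` are linked by the exact identities
`a = Vmax/Km`, `h = 1/Vmax` (and inversely `Vmax = 1/h`,
`Km = 1/(a·h)`); the translation carries units with it. Canonical
internal units are fixed throughout the package — µmol g⁻¹ min⁻¹
(V<sub>max</sub>), µM (K<sub>m</sub>, concentrations), L g⁻¹ min⁻¹
(*a*), min g µmol⁻¹ (*h*) — and every unit conversion happens once, at
ingest, using exact rational factors. Zero-valued parameters are
rejected rather than treated as limits; the h→0 and a→∞ limits are
exercised analytically in tests only, which keeps every denominator in
the model well defined.

For `j` substitutable nutrient forms the multi-resource disc equation
`dH/dt = r·Σaⱼ Nⱼ/(1+Σaⱼhⱼ Nⱼ)` applies. Note a real property of this
functional response asserted in the test suite: with heterogeneous
handling times the harvest rate is *not* monotone in every
concentration — `∂H/∂Nⱼ` has the sign of `1 + Σₖ aₖNₖ(hₖ−hⱼ)`, so
enriching a slow-to-handle form can depress total uptake. Monotonicity
holds for a single nutrient or equal handling times.

### Foraging precision

A plant faces one nutrient-rich patch (p) and nutrient-poor background
soil (b) of equal volume, with concentrations held constant (no
depletion, nitrogen limiting, uptake through roots only). The marginal
value theorem equalizes returns across locations; foraging precision is
the optimal root-production ratio

    P* = [Σ N_pj/(1+Σ aⱼhⱼN_pj)] · [(1+Σ aⱼhⱼN_bj)/Σ N_bj].

For a single nutrient with N_p ≥ N_b, P* lies in [1, N_p/N_b],
increases with patch quality, decreases in the product a·h, and tends
to the habitat-matching ratio N_p/N_b as a·h → 0 and to 1 (no
discrimination) as a·h → ∞. With several nutrients and heterogeneous
a·h the lower bound can fail even when the patch is elementwise richer;
the suite carries a counterexample. There is no upper cap: very large
P* is read downstream as "all roots in the patch".

A note on direction: literally equating the two per-unit-root uptake
rates gives a root ratio that is the *reciprocal* of the expression
above. The expression above is the model — it is the form whose
behaviour (precision rising with patch quality, falling with encounter
rate) matches the biological predictions the model exists to make. The
raw equal-rate ratio is kept as a diagnostic on `PrecisionResult`.

Parameter sweeps evaluate P* on a positive, strictly increasing grid of
one parameter (a, h, V<sub>max</sub> or K<sub>m</sub>; MM parameters
are translated before evaluation) against patch levels
{0.5, 1, 1.5, 2} µM over a 0.2 µM background by default, with the held
parameter defaulting to the mean dry-weight nitrate trait from the
literature compilation (a = 0.0511 L g⁻¹ min⁻¹, h = 11.241
min g µmol⁻¹; medians are also exposed). These defaults are
configurable.

## Trait tables

Literature records carry (species, nutrient ∈ {NO3, NH4}, weight basis
∈ {dry, fresh}, V<sub>max</sub>, K<sub>m</sub>, units, study id).
Validation is row-wise with line numbers; rows missing K<sub>m</sub>
(a common reporting gap) or duplicating a (species, nutrient, basis,
study) key are rejected and reported. Records are translated to (a, h)
*individually* before any summarizing — the median of per-record
V<sub>max</sub>/K<sub>m</sub> is not the ratio of medians — and
summaries (min/max/mean/median/CV/n) are grouped by nutrient × basis;
repeat estimates of one species from different studies remain separate
data points. The CV definition is pluggable (sample SD/mean by default,
SE/mean, or SD of ln(x+1) values) because published summaries of this
kind rarely state theirs; CV is excluded from the reproduced
quantities for that reason.

Fresh- and dry-weight bases are never pooled on the raw scale. For
cross-nutrient regressions, within-species multi-study values are
averaged on the raw scale first, then ln(x+1)-transformed (natural
log), and fresh/dry points are pooled on that transformed scale with
the basis kept as a per-point tag.

## Phylogenetic signal

Blomberg's K compares the observed ratio MSE₀/MSE — tip deviations from
the phylogenetically corrected mean over the generalized-least-squares
error under the tree's Brownian covariance — to its Brownian-motion
expectation `(tr(V) − n/Σ(V⁻¹))/(n−1)`. K = 1 is the Brownian
expectation; K ≪ 1 indicates random or convergent trait values. The
permutation test shuffles trait values across tips and counts
permutations with phylogenetically corrected variance ≤ observed, with
+1 smoothing: p = (1+k)/(1+n_perm), seeded, with the seed recorded in
the result. Polytomies are resolved arbitrarily with zero-length edges
and all branch lengths floored at a configurable ε (default 1e-8)
because source trees assembled from taxonomic backbones typically leave
genera and species as polytomies without usable branch lengths. The
implementation agrees with R's `picante::Kcalc` and
`phytools::phylosig` to 1e-10 on random instances (one live picante
cross-check is part of the suite), and direct multivariate-normal
simulation confirms the statistic is unbiased (mean K ≈ 1) under
Brownian traits.

## Equivalence fit

`equivalence_fit` draws log-spaced concentrations over
[K<sub>m</sub>/10, 10·K<sub>m</sub>], adds Gaussian noise with SD =
noise·V<sub>max</sub>, and fits both parameterizations by
Levenberg–Marquardt/TRF nonlinear least squares (scipy `curve_fit`,
tolerances 1e-14, self-starting values from the data). Because the two
forms draw the same curve, the fits share their optimum: residual sums
of squares agree to ~1e-15 relative and the directly fitted (a, h)
equals the translated fitted (V<sub>max</sub>, K<sub>m</sub>) within
optimizer tolerance. Non-convergence is returned as a flagged result
with diagnostics, never a silent failure.

## Synthetic data

The trait-table generator reproduces the *structure* of the literature
compilation, which is also the default condition for every structural
check: 45 species, 38 studies, 28 species with both nutrients, 3
species with a second independent estimate (ln-scale scatter SD 0.2),
half the records on each weight basis. Marginals for V<sub>max</sub>
and K<sub>m</sub> are log-uniform over the observed dry-weight
envelopes (0.0183–16.0 µmol g⁻¹ min⁻¹; 1.45–2422 µM), so derived
encounter rates span several orders of magnitude, as observed.

Cross-nutrient dependence uses a Gaussian copula. Because a monotone
transform attenuates Pearson correlation, the latent correlation is
calibrated so the *population* correlation of the ln(x+1)-transformed
values equals the requested ρ: the transform's normalized
Hermite-series coefficients c_k give the achieved correlation
Σc_k²r^k/Σc_k², which is inverted by root finding. Default
ρ = √0.79 ≈ 0.889, matching the strongest cross-nutrient relationship
reported for these traits; at n = 28 pairs the mean realized sample R²
is ≈ 0.78 (sample correlation of heavy-tailed data is slightly
attenuated at small n — a property of sampling, not of the generator).

Trees are Yule (pure birth) with all leaf edges extended by
`0.5/(birth_rate·n_tips)` — half the expected waiting time to the next
speciation — because the simulator stops exactly at the n-th split and
would otherwise leave the youngest cherry with zero-length tips. Trees
are ultrametric by default; a lognormal rate-jitter option breaks that.
Brownian traits accumulate independent normal increments with variance
σ²·branch length; tip covariances were checked against the analytic
shared-path-length form.

What the generator does *not* emulate: real measurement-protocol
heterogeneity between studies (temperature, solution chemistry,
starvation status), correlated coverage (which species get studied is
not random), taxonomic structure in trait values (species are
exchangeable here), or any phylogenetic signal in the trait table
itself. Passing tests therefore demonstrate the pipeline's correctness
and calibration, not field-data conclusions.

## Problem sizes and numerics

The test suite and the reproduction script use 1000-draw translation
checks, 40-point curve fits, 200 Brownian replicates on 64-tip trees
for the K calibration, 99–199 permutations inside p-value checks and
500 seeds for the regression calibration; these sizes give Monte-Carlo
error comfortably inside the asserted bands while keeping a full run in
tens of seconds. Permutation p-values are discrete on k/(n_perm+1), so
the uniformity check de-discretizes them with the randomized
probability integral transform before the Kolmogorov–Smirnov test.
Ties in permuted GLS errors have probability zero for continuous
traits and are not specially handled. Matrix work uses dense inverses
(trees here are ≤ a few hundred tips); for much larger trees a
pruning-based contrasts algorithm would be the right replacement.

## Known limitations

- The precision model is a point prediction at the root-allocation
  optimum; it says nothing about the growth dynamics that reach it, and
  alternative precision definitions used by empiricists (percent of
  total root system in the patch, patch-minus-background fractions)
  are not derivable from it without explicit spatial treatment.
- Nutrient depletion, carbon limitation / root:shoot allocation,
  mycorrhizal uptake and multi-essential-resource (Liebig) foraging are
  out of scope.
- Blomberg's K inherits whatever the branch lengths mean; on
  backbone-style trees with arbitrary polytomy resolution its p-values
  depend on the ε/unit-branch-length choice, so they should be read as
  descriptive, not inferential.
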