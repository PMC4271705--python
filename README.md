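# rootforage

Plant nutrient uptake, rethought as foraging behaviour.

Plant physiologists describe root nutrient uptake with the
Michaelis–Menten equation, whose parameters (V<sub>max</sub>,
K<sub>m</sub>) describe the *shape* of the uptake curve. Foraging
ecologists describe resource capture with Holling's disc equation, whose
parameters describe the *forager*: an encounter rate (search
efficiency) *a* and a handling time *h*. The two equations are
rearrangements of the same Type II functional response, and their
parameters translate exactly:

```
dH/dt = r·Vmax·N/(Km + N)  =  r·a·N/(1 + a·h·N)

a = Vmax/Km        Vmax = 1/h
h = 1/Vmax         Km   = 1/(a·h)
```

with a unit of root *r* (g) standing in for the individual forager, *N*
the nutrient concentration (µmol L⁻¹), V<sub>max</sub> in
µmol g⁻¹ min⁻¹, K<sub>m</sub> in µM, *a* in L g⁻¹ min⁻¹ and *h* in
min g µmol⁻¹.

`rootforage` is a toolkit for ecologists who want to move between these
two views. It provides:

- **kinetics** — the two parameterizations, their exact translation,
  and single- and multi-nutrient harvest rates
  (`dH/dt = r·Σaⱼ Nⱼ/(1 + Σaⱼhⱼ Nⱼ)` for substitutable forms such as
  nitrate and ammonium);
- **foraging** — a marginal-value-theorem model of *root foraging
  precision*: the optimal ratio `P* = r_p*/r_b*` of root production in
  a nutrient-rich patch to that in equal-volume background soil,
  `P* = [ΣN_pj/(1+Σaⱼhⱼ N_pj)]·[(1+Σaⱼhⱼ N_bj)/ΣN_bj]`, with
  parameter sweeps over the observed trait ranges;
- **trait_data** — ingest of literature trait tables (CSV) with exact
  unit normalization, per-record translation and grouped summaries by
  nutrient form and fresh/dry weight basis;
- **comparative** — cross-nutrient OLS regressions of ln(x+1) traits,
  Blomberg's K phylogenetic-signal statistic with a permutation test
  (verified against R's picante), and a nonlinear least-squares
  demonstration that both parameterizations share their optimum
  (`UptakeCurveModel.fit()` → results with estimates, standard errors
  and a `summary()`);
- **fixtures** — seeded generators for literature-style trait tables
  (including calibrated cross-nutrient correlation), Yule trees and
  Brownian-motion tip traits;
- a `rootforage` **CLI** (`translate`, `summarize`, `precision`,
  `sweep`, `compare`, `simulate`) that writes run manifests for
  reproducibility.

## Worked example

```python
from rootforage import (UptakeKinetics, mm_to_holling, ForagerTraits,
                        PatchScenario, precision, allocate_roots,
                        equivalence_fit)

# a barley-like nitrate uptake curve, translated into foraging traits
k = UptakeKinetics(v_max=0.5, k_m=50.0)
t = mm_to_holling(k)
print(f"a = {t.a:.4f} L/g/min, h = {t.h:.1f} min*g/umol")

# precision at the mean dry-weight nitrate traits from the literature,
# for a 2 µM patch in 0.2 µM background soil
scen = PatchScenario.single(ForagerTraits(a=0.0511, h=11.241),
                            n_patch=2.0, n_background=0.2)
print(f"P* = {precision(scen).p_star:.3f}")
r_p, r_b = allocate_roots(scen, 1.0)
print(f"allocation of 1 g of root: patch {r_p:.3f} g, background {r_b:.3f} g")

# both parameterizations fitted to the same noisy uptake data
fit = equivalence_fit(40, k, noise=0.05, seed=0)
print(fit.mm.summary())
print(f"RSS relative difference: {fit.rss_rel_diff:.2e}")
```

prints

```
a = 0.0100 L/g/min, h = 2.0 min*g/umol
P* = 5.188
allocation of 1 g of root: patch 0.838 g, background 0.162 g
Uptake curve fit (mm parameterization), n=40
  converged: True
  v_max = 0.512736 (se 0.0105)
  k_m = 54.8987 (se 3.39)
  RSS = 0.0146966
RSS relative difference: 5.90e-16
```

Read: this plant's roots "encounter" 0.01 L of solution per gram per
minute and need 2 min·g per µmol captured. At the literature-average
trait values, the marginal value theorem predicts 5.2× more root
production inside the rich patch than in the same volume of background
soil — about 84 % of new root mass in the patch. The two curve fits land
on the same optimum, as the algebra says they must.

The same analyses from the shell:

```sh
rootforage simulate --what trait-table --seed 1 --out traits.csv
rootforage translate traits.csv translated.csv
rootforage summarize traits.csv summary.csv
rootforage sweep --param a --grid-min 7.6e-6 --grid-max 0.36 \
    --out sweep.csv --plot sweep.png
```

## Layout

```
src/rootforage/
  kinetics.py      functional responses and parameter translation
  foraging.py      precision model, root allocation, parameter sweeps
  trait_data.py    trait-table ingest, unit registry, summaries
  comparative.py   regressions, Blomberg's K, equivalence fits
  fixtures.py      seeded synthetic data generators
  plotting.py      sweep panels
  cli.py           command-line interface
docs/methods.md    model assumptions, numerical choices, limitations
```
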