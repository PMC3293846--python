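# Methods

This note documents the models, algorithms and numerical choices behind
`kindisc`, in the package's own terms.

## Kinetic models

Units are fixed package-wide: concentrations mM, time min, `kcat` min⁻¹,
`Km` mM, `kf` mM⁻¹min⁻¹, `kr` min⁻¹.

Both glyoxalase candidates share four dynamic species (GSH, MGO, HTA,
SDLGS), two constant enzyme concentrations (E_GLOI, E_GLOII) and three
reactions:

* non-enzymatic hemithioacetal formation, reversible mass action:
  `v_ne = kf·[GSH]·[MGO] − kr·[HTA]`;
* glyoxalase I — the step the models disagree on;
* glyoxalase II, irreversible one-substrate Michaelis-Menten on SDLGS.

Model 1 gives glyoxalase I one-substrate Michaelis-Menten kinetics on HTA.
Model 2 binds GSH and MGO sequentially with a simplified two-substrate
Michaelis-Menten rate law in which the constant denominator term is the
product of the two Michaelis constants:

```
v = kcat·E·[GSH]·[MGO] / (Km_GSH·Km_MGO + Km_MGO·[GSH] + Km_GSH·[MGO] + [GSH]·[MGO])
```

This algebra is a reconstruction from the mechanism's textual description
(sequential two-substrate mechanism with the constant term replaced by the
product of the Michaelis constants); it is the only form consistent with
that description, but users extending the package should be aware it was
not transcribed from typeset equations.

Design choices:

* **Enzymes are constants, not species.** The rate laws are aggregate
  (no enzyme-intermediate states), so enzyme totals enter as fixed
  parameters; experiments may override them per assay.
* **D-lactate is not tracked.** It appears in no rate law; it is a pure
  sink and its omission changes nothing observable.
* **Shipped parameters.** The default kinetic constants are the
  collective-fit estimates for *S. cerevisiae* glyoxalase I and bovine
  liver glyoxalase II (model 1: kcat = 8×10⁴ min⁻¹, Km_HTA = 0.2 mM;
  model 2: kcat = 1.7×10⁵ min⁻¹, Km_GSH = 0.87 mM, Km_MGO = 1.2 mM;
  glyoxalase II: kcat = 3×10² min⁻¹, Km_SDLGS = 3 mM; kf = 0.34,
  kr = 1.01). Their reported standard errors are shipped alongside for
  testing. The default glyoxalase II concentration in the design problem
  is 4.0×10⁻⁴ mM (the documented upper bound of the assay); one source
  figure caption cites 4.0×10⁻³ mM, which is inconsistent with that bound
  and is treated as a typo.

### Simulation

With kcat up to 1.7×10⁵ min⁻¹ against mM concentrations the systems are
stiff. Integration uses LSODA (scipy's `odeint`) with an **analytic
Jacobian** assembled from per-reaction closed-form derivatives, at default
tolerances rtol = 1e-8, atol = 1e-12 mM. Trajectories may carry
integrator-level negatives of order ≤1e-11 mM; downstream code treats
anything above −1e-8 mM as numerically zero. Solutions are
grid-independent: halving the output step changes nothing beyond 10× the
tolerance (asserted in tests against a fixed-step RK4 oracle).

## Divergence measures

The extended Kullback-Leibler distance between predicted time courses is an
**un-normalized discrete sum** (no Δt factor) over grid points and
observables — only relative comparison between designs matters, so the
scale is irrelevant. Both arguments are clipped below at `eps = 1e-12` mM
before the logarithm, because the observable (reaction product SDLGS) is
exactly zero at t = 0. Consequences, both tested:

* refining the grid approximately scales the sum by the refinement factor
  (it is a Riemann sum without the Δt);
* as a quadrature of the continuous integrand the default 1-min design
  grid is accurate to ~5% at the discriminatory conditions (model 2 has a
  fast SDLGS transient in the first minute); a 0.1-min grid agrees with a
  10⁴-point quadrature within 1%.

The weighted L2 norm divides each observable's squared-difference sum by
the squared time-mean of the **first** argument. The convention (first
argument, second, or both) could not be pinned down from available
descriptions; the first-argument convention makes the asymmetry explicit
and is documented here as the package's choice.

## GDE3

Maximization is the native sense. Per generation, each target vector
produces one DE/rand/1/bin trial (three distinct random donors, weight
F = 0.5, binomial crossover CR = 0.7 with one guaranteed crossed
coordinate), resampled in full until inside the box (cap 100, then an
error). Selection: a dominating trial replaces its target; a dominated
trial is dropped; mutually non-dominated pairs are both kept. The grown
population is restored to NP by dominance-tree non-dominated sorting and
iterative removal of the most crowded member of the last retained front.

* **Dominance-tree sorting.** The population is recursively halved; each
  half becomes a tree whose sibling roots are mutually non-dominated and
  whose subtrees hold dominated solutions; halves merge by pairwise root
  comparison. Fronts are read off the successive root layers. The sort is
  cross-checked against a naive repeated-extraction O(n²) oracle on
  thousands of random populations.
* **Crowding.** Euclidean distance in raw (un-normalized) objective space
  to the k-th nearest neighbor, k = 3, recomputed after each removal,
  ties broken toward the lowest index; k is clamped to front-size − 1 as
  the front shrinks. Objective values here are same-scale directed KL
  values, so normalization would add nothing.
* **Improvement & termination.** An "improvement" is a replacement by a
  dominating trial or an insertion of a non-dominated trial — both change
  the approximation set. The run stops when the improvement fraction
  stays ≤ 5% for 20 consecutive generations, or at 200 generations. On
  the glyoxalase problem the non-dominated insertion rate stays high, so
  runs terminate by the generation cap, matching how the shipped design
  run is described to have ended.
* **Defaults.** NP = 40 and the reuse of F = 0.5 / CR = 0.7 for the
  multi-objective runs are package choices (the source states those F/CR
  values for the estimation DE; NP is unstated).
* **Reproducibility.** One seeded `numpy` Generator is threaded through
  the whole run; identical seeds give bitwise-identical histories.

## The shipped design problem and what it yields

Decision variables: initial GSH and MGO in [0, 1] mM (the documented
spectrophotometric feasibility bound). Fixed: HTA = SDLGS = 0,
E_GLOI = 2.0×10⁻³ mM, E_GLOII = 4.0×10⁻⁴ mM. Observable: SDLGS. Grid:
0–120 min, 121 points (1-min step; the sampling density of the design sum
is not documented in the source and 1 min is the package default).

Under these conditions the front concentrates near GSH ≈ 0.22 mM and
MGO ≈ 0.38 mM. An exhaustive 81×81 lattice scan (independent of the
optimizer) puts the true Pareto set at GSH ∈ [0.21, 0.24] (mean 0.221) and
MGO ∈ [0.35, 0.43] (mean 0.38): GDE3 lands exactly on it. The
published design point is (0.221, 0.441) mM; the GSH coordinate matches to
three digits, while the MGO coordinate of this reconstruction sits ~14%
lower, at the lower edge of the published cluster. The residual gap is
sensitive to the undocumented sampling density of the divergence sum
(denser grids weight the early transient more and pull MGO upward), so the
front's MGO statistics should be read with that caveat. Likewise the
reconstructed Pareto set is intrinsically wider (~19% relative MGO range,
~12% GSH) than the published cluster (10% and 6%).

At the discriminatory point the mechanistic reason for divergence is
visible in the reaction rates (tested): in model 1 the non-enzymatic HTA
step limits the pathway (its net rate tracks the glyoxalase I rate within
0.02% while flux is active), whereas in model 2 the HTA step idles at
quasi-equilibrium (net rate < 0.5% of the glyoxalase I rate) and turnover
is limited by glutathione regeneration. The plain and weighted L2 norms
place their maxima on the design-box boundary or against the
zero-concentration axes, making them unusable for this problem — the
package reproduces that failure mode in a 50×50 landscape scan.

## Parameter estimation

The collective fit minimizes the non-weighted SSQ over all experiments
simultaneously; model predictions are dense LSODA output evaluated at the
experimental time points (no grid interpolation). Because kinetic
constants span decades, the search runs in **log10 space** inside bounds
that bracket the shipped values by ≥ 2 orders of magnitude (kcat ∈
[10², 10⁷] min⁻¹, Km ∈ [10⁻³, 10²] mM — package defaults; the original
fitting boxes are not documented). The global stage is scipy's
differential evolution restricted to the classic rand/1/bin scheme
(mutation 0.5, recombination 0.7, uniformly sampled initial population,
no polishing), followed by Nelder-Mead; the refined point is only accepted
if it does not degrade the DE optimum. A failed simulation inside the
objective returns a 1e15 mM² sentinel instead of raising, so the
population can step over infeasible parameter vectors. The non-enzymatic
constants kf, kr are never fitted (literature values).

**Fisher information.** Sensitivities S = ∂x/∂p obey
dS/dt = (∂f/∂x)S + ∂f/∂p with S(0) = 0 (initial conditions are not
fitted); both Jacobians are derived symbolically with sympy and the
augmented system is integrated per experiment. The FIM accumulates
Sᵀ V⁻¹ S over measured points, with V = σ²I diagonal; when not supplied,
σ is the RMS residual at the optimum. Standard errors are the Cramér-Rao
bounds √diag(F⁻¹). When cond(F) > 10¹², errors are withheld and a
`SloppinessWarning` is raised — large standard errors with preserved
predictive power are expected in time-course collective fits, and the
shipped glyoxalase estimates themselves carry relative errors up to ~70%.

## Synthetic data

`make_glyoxalase_suite` emulates the structure of the original estimation
dataset: four glyoxalase-I-only assays (E_GLOII = 0; GSH/MGO between 0.15
and 1 mM; enzyme 2–8×10⁻⁷ mM; sampled every 10 min to 540 min, ~4.5-fold
longer than the 120-min design) and four glyoxalase-II-only hydrolysis
assays (SDLGS 0.5–6 mM straddling Km_SDLGS = 3 mM; enzyme 1–4×10⁻⁴ mM;
every 5 min to 240 min), all observing SDLGS only. The sub-nM
glyoxalase I levels are what the 10⁴–10⁵ min⁻¹ turnover numbers require
for an enzyme-limited multi-hour course. Noise is additive Gaussian,
default SD 0.005 mM (≈ 0.014 absorbance units through
ε = 2.86 mM⁻¹cm⁻¹), clipped at zero.

These suites *emulate* the original assays (whose exact initial
concentrations live only in the undistributed supplementary data); tests
built on them demonstrate self-consistency of the machinery — recovery of
generating parameters, correct model ranking at the design point,
shrinking error with shrinking noise — not agreement with the original
laboratory measurements. What they do not emulate: absorbance drift,
instrument artifacts, pipetting error in initial conditions.

## Problem sizes used in the shipped checks

The automated checks run the full design problem at NP = 40; the
multi-seed reproduction check uses 120 generations per seed (front
statistics are stationary from ~generation 80 on this problem; the
single-run acceptance script uses the full 200-generation budget).
Landscape scans use a 50×50 lattice; sorting equivalence uses 1000 random
populations of 2–100 solutions with 2–6 objectives; estimation checks use
DE populations of 10–15 over 25–40 generations, which recover noise-free
parameters to ~1e-8 relative.

## Known limitations

* Only the three shipped rate-law forms are supported; arbitrary symbolic
  laws are an extension point (`RateLaw`/`_compile_reactions`,
  `_symbolic_rate`) but untested.
* No SBML import/export; model configs are flat INI files.
* The divergence module compares exactly the model-predicted trajectories;
  probability-density KL between fitted error distributions and
  information-criterion model selection are out of scope.
* Box bounds only in GDE3 (no nonlinear constraint handling).
* Weighted/extended least squares and Bayesian posterior sampling are not
  implemented; identifiability analysis stops at FIM condition reporting.
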