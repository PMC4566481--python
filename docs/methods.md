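# Methods

## Model family

The package simulates an extended two-lesion kinetic (TLK) family for
radiation-induced DNA double-strand-break (DSB) foci.  Six pools are
tracked, all in foci per cell: initial simple (`Si`) and complex (`Ci`)
DSBs, protein-bound simple/complex breaks (`S`, `C`), the free
repair-protein pool (`P`, focus equivalents), and persistent
telomere-associated foci (`TAF`).  The observable total focus count is
`Ft = B + TAF + Si + Ci + S + C`, where `B` is a constant basal background
(γH2AX signal not caused by DSBs).  TAF are treated as unrepairable on the
months-long time scales modelled: `dTAF/dt = 0` between dose fractions.
Mechanistic repair-pathway detail (NHEJ/HR, cell cycle), ROS feedbacks, and
cell death/proliferation are deliberately lumped into the rate constants;
the parameters are phenomenological.

Twenty structural variants arise from four switches (protein binding
none/fixed/free pool, second-order channel on/off, backward dissociation
on/off — only meaningful with protein binding — and a linear vs square-root
dose map), giving free-parameter counts between 7 and 13.  The base
parameters are `kDSB`, `c`, `k1`, `k3`, `kTAF`, `T0`, `B`; options add
`kcross`, (`kf`, `ks`), (`k2`, `k4`) and `P_total`.

One genuinely open structural question is where the second-order
"binary-misrepair" term enters.  We apply `kcross (Si + Ci)` as an additive
modifier of the same channel as `k1`/`k3` — i.e. it accelerates the
binding step in protein variants and the direct repair step otherwise, for
both the simple and the complex pool, with a single shared coefficient.
This choice reproduces the published per-variant parameter counts with one
`kcross`; a parallel direct-repair channel would too, but would change the
protein-bound flux balance.  The right-hand sides live in one place
(`simulate._make_rhs`) should a user want the alternative coupling.

## Units, dosing, integration

Time is measured in days (the data designs span 1 hour to 4 months), all
rates in day⁻¹ (per-focus·day⁻¹ for the binding and cross coefficients).
Irradiation at the experimental dose rate (~2.5 Gy/min) is orders of
magnitude faster than any repair rate, so each dose fraction is an
instantaneous state increment: `Si += kDSB (1-c) f(D)`,
`Ci += kDSB c f(D)`, `TAF += kTAF f(D)`; at a stored time equal to a
fraction time the state is post-irradiation.  The fixed protein pool is 20
focus-equivalents.

Integration uses LSODA with `rtol=1e-8`, `atol=1e-10` for reporting-grade
simulation; the fitting path defaults to `rtol=1e-6`, `atol=1e-9` (the
objective is dominated by measurement noise well above this level).
Negative excursions within ~10·atol are clipped to zero; anything larger
raises.  The repair time τ (first time `Ft` falls to 150% of the floor
`B + TAF`) is interpolated linearly between grid points and reported as
NaN when the threshold is not reached in the simulated horizon.

## Synthetic data generator

The raw per-cell counts behind the published figures are not available as
numbers, so the generator emulates the study design rather than any
specific dataset.  Per design point it computes the model mean (of `Ft` or
`TAF`), draws `n_cells` independent Poisson counts with that mean, and
records the sample mean and SEM.  The default design has 49 fitted points
over seven experiments — γH2AX time courses at 2.5 and 10 Gy (8 points
each, 1 h–14 d), at 20 Gy (12 points, 1 h–120 d), γH2AX dose–responses at
1 d (5 doses) and 3 d (4 doses), a TAF dose–response at 1 d (5 doses) and
a TAF time course at 20 Gy (7 points) — plus a prediction-only %TAF series
at 20 Gy, which is never fitted.  Exact sampling times are published only
graphically; the defaults above are our one-time choice of a realistic
grid and are overridable per design.  Default `n_cells` is 50; counts can
optionally be right-censored to mimic focus-counting saturation (off by
default).  A linear dose-interpolation utility is provided for filling an
unmeasured dose from two neighbours (off by default).

The canonical ground truth (`default_ground_truth`) is the best-supported
structure (fixed protein pool, second-order channel, square-root dose
maps) with parameters chosen once from qualitative anchors reported for
primary human fibroblasts: complex fraction `c = 0.02`, background
`B = 1` focus, background TAF `T0 = 0.5`, induction `kDSB = 25` foci/√Gy,
effective simple-repair half-life of ~2 h (`k1 = 0.4` per-focus/day against
the pool of 20, `kf = 12`/day), complex repair about tenfold slower
(`k3 = 0.07`, `ks = 1`/day), a small cross term (`kcross = 0.002`), and
`kTAF = 0.8` TAF/√Gy so that the ERR predictor's zero crossing
`(B/kTAF)² ≈ 1.6 Gy` sits where an elevated risk becomes measurable.

What passing tests on these data do and do not show: the generator
reproduces the counting statistics (Poisson dispersion, SEM ~ √(mean/n)),
the design geometry and the dose maps, but not inter-experiment scaling
offsets, digitization error, microscope saturation, or any deviation of
real foci counts from Poisson.  Parameter- and model-recovery results are
therefore statements about the inference machinery under the model's own
assumptions, not about the original biological measurements.

## Fitting

The objective is the weighted SSR `Σ_i w_i Σ_j (ŷ_ij − y_ij)²` with
`w_i = 1/mean(series i)`, recomputed from whatever data are being fitted
(so Poisson-resampled replicates get their own weights; a flag restores
fixed weights).  γH2AX-type series are compared against `Ft`, TAF series
against `TAF`; %TAF series are prediction-only by construction and are
rejected if given the fit role.

The global optimizer is a (μ+λ) self-adaptive evolutionary search without
recombination: individuals live in a unit cube mapped log-uniformly onto
the bounds, carry per-coordinate mutation scales updated by the standard
log-normal rule, and compete jointly with their offspring.  The default
budget is population `10k` and generations `10×population`; a
`budget_scale` knob shrinks both for desk-scale studies.  The best distinct
survivors (2 by default) are polished with restarted Nelder–Mead
simplexes.  Warm-start vectors can be injected into the initial
population; the Monte-Carlo selection uses this to seed every replicate
refit with the fit to the unresampled data, keeping per-replicate budgets
small without changing the estimator.

Default search bounds are deliberately wide (1e-6…1e3, `c` in [1e-4, 1]).
All synthetic studies use the narrower `study_bounds` box set once from
the data scales (counts of order 1–100 foci, half-lives of hours to days);
with 7–13 free parameters and desk-scale budgets, a search box spanning
nine decades per parameter is a statement about ignorance the synthetic
data do not have.

## Selection, validation, risk

AICc uses the full Gaussian form including constants,
`n ln(SSR/n) + n ln 2π + n + 2k + 2k(k+1)/(n−k−1)`; the common
constant-free form does not reproduce the published reference ranking and
is not offered.  Weights are computed from unrounded AICc; ties break
parsimony-first (lower k, then lower variant id).  The evidence cutoff is
0.125.  Resampling reports accumulate rank frequencies and weight
histograms with 0.1-wide bins on [0, 1].

Cross-validation holds out each fitted non-TAF experiment once (TAF series
are always trained on — they are the only constraint on `kTAF`, `T0`);
the run error is the held-out series' inverse-mean-weighted SSR and the
report averages over runs.

Profile likelihood re-optimizes all other parameters at each of 41
log-spaced scan values spanning ±2 decades (both configurable), marching
outward from the fit with warm starts, and compares against the pointwise
1-degree-of-freedom F-ratio threshold
`SSR* = SSR_min (1 + F(0.95; 1, n−k)/(n−k))`; the simultaneous k-df
variant is available by flag.  Classification: *practical* (threshold
crossed on both sides), *one-sided*, *structural* (bounded but uncrossed),
*non-identifiable* (flat within `1e-6·SSR_min`).  Confidence-interval
crossings are interpolated linearly in log-parameter space.

Latin-hypercube robustness perturbs every free parameter uniformly within
±20% of its fitted value (1000 draws by default).  Since initial
conditions are parameter-derived, perturbing the induction parameters
(`kDSB`, `c`, `kTAF`, `T0`, `B`, `P_total`) perturbs the initial values,
as intended.  Reported are 5–95% quantile bands per dose, the relative
standard deviation `σ_sim(t)` around the unperturbed optimum, and the τ
distribution.

The risk predictor is `ERR(D) = T_AF+(D) − B` with
`T_AF+ = kTAF·f(ΣD)` under the default *cumulative* rule (risk curves are
plotted against cumulative dose as a single smooth function) or
`Σ_i kTAF·f(D_i)` under the *per-fraction* rule; for the square-root map
the per-fraction rule always dominates.  Which rule the original analysis
used for fractionated schedules is not documented; both are implemented
and every output records the rule.  The 95% band propagates `kTAF` and `B`
sampled independently and uniformly within supplied intervals (e.g.
profile-likelihood CIs).

## Problem sizes used in the shipped studies

The test suite runs the recovery studies at deliberately reduced scale,
chosen once as the smallest sizes at which the statistical questions are
still meaningful: parameter recovery fits the generating structure to a
49-point suite with 200 cells per point at `budget_scale=0.2` and profiles
`c` and `kTAF` on 11-point, ±1-decade grids; model recovery uses 20
Poisson resamples over the {7, 8, 9, 10} sub-ensemble with warm-started
replicate refits; robustness ordering uses 100 LHS draws.  Full-scale runs
(20 variants, 200 replicates, 1000 draws, default budgets) use the same
code paths through the CLI.

## Known limitations

* The exact published ODE right-hand sides and fitted parameter values are
  in unavailable supplementary material; the reconstruction here matches
  the published structure counts and conservation laws, but numeric
  trajectory or parameter comparisons with the original fits are not
  possible, and the published σ_sim maxima (13/19.9/41%), τ spread, and
  ERR R² = 0.475 (which needs externally digitized registry data) are not
  reproduced — only their qualitative/structural counterparts are tested.
* The evolutionary-programming dialect of the original fitting tool is
  implementation-specific; only its population/generation budget is
  honoured.
* Printed reference SSR values are rounded to three significant figures,
  which propagates up to ~0.06 into recomputed AICc for two of the twenty
  models.
* Poisson resampling acts on the reported means (one draw per point), not
  on re-simulated per-cell counts; the latter is available as an option.
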