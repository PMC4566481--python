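# focikit

Kinetic modelling of radiation-induced DNA damage foci: an extended
two-lesion kinetic (TLK) model family with persistent telomere-associated
damage, AICc-based model selection, identifiability and robustness
analysis, and a simple predictor for excess relative risk (ERR) of
secondary leukemia after radiotherapy.

## The scientific problem

Ionizing radiation induces DNA double-strand breaks (DSBs), routinely
counted per cell as γH2AX immunofluorescence foci.  The classical TLK
picture distinguishes *simple* DSBs (repaired fast) from *complex* DSBs
(repaired slowly).  Two further damage categories are needed to describe
long time courses: *persistent telomere-associated foci* (TAF), which are
effectively never repaired, and a constant *background* signal `B` from
non-DSB sources.  focikit implements a 20-member family of ODE models built
from four structural options:

* repair-protein binding: none / a fixed pool of 20 focus-equivalents / a
  fitted pool `P_total`;
* an optional second-order "binary misrepair" channel
  `k_cross (S_i + C_i)` added to the first-order rates;
* optional backward dissociation of protein-bound breaks (`k_2`, `k_4`);
* a linear or square-root mapping from dose `D` (Gy) to induced damage.

For the fullest model the dynamics are

```
dSi/dt = -(k1 + kcross (Si+Ci)) Si P + k2 S
dCi/dt = -(k3 + kcross (Si+Ci)) Ci P + k4 C
dS/dt  = +binding(S) - (k2 + kf) S
dC/dt  = +binding(C) - (k4 + ks) C
dP/dt  = -(bindings) + (k2 + kf) S + (k4 + ks) C
TAF    = const between dose fractions
```

with initial damage `Si = kDSB (1-c) f(D)`, `Ci = kDSB c f(D)`,
`TAF = T0 + kTAF f(D)` (`f(D) = D` or `√D`), and observable
`Ft = B + TAF + Si + Ci + S + C`.

Candidate models are fitted to mean±SEM foci time series by minimizing the
weighted sum of squared residuals (each experiment weighted by the inverse
of its mean) with a self-adaptive evolutionary-programming search, and
ranked by the small-sample-corrected Akaike criterion

```
AICc = n ln(SSR/n) + n ln(2π) + n + 2k + 2k(k+1)/(n-k-1)
```

with Akaike weights `w_i = exp(-Δ_i/2) / Σ_j exp(-Δ_j/2)` and an evidence
cutoff of 0.125.  Selection robustness is assessed by refitting the whole
ensemble on Poisson-resampled replicates of the data; parameters are probed
by profile-likelihood identifiability and ±20% Latin-hypercube robustness
analysis.  Finally, the fitted persistent-damage parameters give a
two-parameter risk predictor, `ERR(D) = T_AF+(D) - B`, for secondary
leukemia after fractionated radiotherapy.

Because the underlying experimental foci counts are published only in
figure form, the package ships a synthetic-data generator that emulates the
study design: Poisson-distributed per-cell counts whose means follow the
ODE model, summarized as mean ± SEM over a chosen number of cells, with 49
fitted data points across seven experiments.

## Worked example

```python
import numpy as np
from focikit import (DoseProtocol, OptimizerConfig, TLKRegressor,
                     default_design, default_ground_truth, generate_suite,
                     simulate, study_bounds, suite_to_xy, get_variant)

variant, params = default_ground_truth()           # model 10 ground truth
suite = generate_suite(variant, params,
                       default_design(n_cells=50), seed=1)
print(suite.n_fit_points)                          # 49

sim = simulate(variant, params, DoseProtocol.acute(10.0),
               np.array([1/24, 1.0, 7.0, 120.0]))
print(np.round(sim.Ft, 2))                         # [78.69  5.83  4.04  4.03]
print(np.round(sim.percent_taf, 1))                # [ 3.9 52.  75.1 75.2]

est = TLKRegressor(variant_id=7, bounds=study_bounds(get_variant(7)),
                   population=5, generations=10, polish=False,
                   random_state=0)
X, y = suite_to_xy(suite)
est.fit(X, y)
print(est.k_, est.n_, round(est.ssr_, 1))          # 7 49 255.6
```

The simulated 10 Gy time course drops from ~79 foci at 1 h towards the
unrepairable floor `B + TAF ≈ 4.0`, while the TAF share of the remaining
signal climbs to ~75% — persistent damage dominates late time points.  The
deliberately misspecified linear-dose variant 7 fit leaves a large weighted
SSR, which is what the AICc ranking penalizes.

The `focikit` command line exposes the pipeline stages
(`generate`, `fit`, `select`, `resample-select`, `crossval`, `profile`,
`robustness`, `err`); see `focikit --help`.

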