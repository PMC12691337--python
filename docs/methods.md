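# Methods

## Problem and models

Cumulative in vitro gas production tracks the fermentation of a feed
substrate incubated in buffered rumen fluid: gas volume, normalized per
100 mg of incubated dry matter (DM), rises from zero toward a plateau
that reflects the potentially degradable fraction. The package fits five
nonlinear families P(t), t in hours from inoculation:

| id | P(t) | parameters |
|---|---|---|
| `gompertz` | A·exp(−B·exp(−Ct)) | 3 |
| `orskov_mcdonald` | A + B·(1 − exp(−Ct)) | 3 |
| `brody` | A·(1 − B·exp(−Ct)) | 3 |
| `richards` | A·(1 − B·exp(−Ct))^D | 4 |
| `dual_pool_logistic` | A/(1+exp(2−4B(t−C))) + D/(1+exp(2−4E(t−C))) | 5 |

A is the asymptotic gas volume (mL/100 mg DM); for `orskov_mcdonald` the
soluble-fraction gas (possibly slightly negative) with A + B the total
potential; for the dual-pool model A and D are the non-fiber and fiber
pool volumes (total A + D) with rates B and E (h⁻¹) and a shared lag C
(hours). C is a fractional rate per hour elsewhere, and D in the
Richards family is the dimensionless inflection exponent: D = 1 recovers
Brody exactly, so the three-parameter monomolecular curve is a nested
special case.

B in the sigmoid families is a dimensionless shape term related to, but
not identical to, the microbial colonization lag. The package stores B
as estimated and derives no lag formula. For Brody/Richards with B > 1
the base 1 − B·exp(−Ct) is negative before t* = ln(B)/C; a non-integer
power of a negative base is undefined over the reals, so evaluation
clamps the base at zero: P(t) = 0 for t ≤ t*, an explicit lag phase.
This clamping is required even just to evaluate treatment-level
estimates with B ≈ 1.04–1.09 on a grid containing t = 0. Inside the
clamped window all parameter sensitivities are zero; the remaining ~97%
of the 24 h window identifies the parameters in practice. Exponent
arguments are clipped at ±700 before exponentiation so wandering
optimizer trial points return finite limit values instead of overflow.

## Estimation

Both solvers are damped least-squares iterations on the analytic
Jacobian (verified against central finite differences):

* **Modified Gauss–Newton** (default for all families except Richards):
  full GN step from the normal equations with step-halving line search
  (≤ 20 halvings), cap 100 iterations. A singular system or an exhausted
  line search returns a non-converged result rather than raising.
* **Levenberg–Marquardt** (always used for Richards, and the fallback
  when Gauss–Newton fails): Marquardt diagonal scaling, λ starting at
  1e−3, ×10 on a rejected step, ÷10 on acceptance, cap 300 iterations.

Convergence for both is *relative SSE decrease < 1e−8* on an accepted
step. Accepted-step SSE traces are recorded and are non-increasing by
construction (a property the tests assert). Trial steps are projected
onto per-model bounds: rates and shape terms ≥ ~1e−8 (the
`orskov_mcdonald` intercept is sign-free), and the Richards exponent is
capped at D ≤ 50. The cap matters: as D → ∞ with B → 0 the Richards
family degenerates into its Gompertz limit along a ridge with no finite
minimizer, and on noisy data LM can crawl there indefinitely —
exponents reported for fermentation curves are O(1), so the cap is far
outside the biologically plausible region.

Starting values are data-driven: A₀ = 1.05·max(gas), C₀ = 0.1 h⁻¹,
B₀ = 1 (Brody/Richards) or 2 (Gompertz), D₀ = 1.5 (Richards);
`orskov_mcdonald` starts at the first reading with B₀ the remaining
span; the dual-pool start splits A₀ 30/70 between pools with rates
0.2/0.05 h⁻¹ and lag 2 h. From these starts, noiseless curves generated
by any of the five families are recovered to machine precision on the
5-min/24-h grid.

Standard errors use the Gauss–Newton covariance approximation
(JᵀJ)⁻¹·SSE/(n − p) at the optimum. RMSE is reported as √(SSE/n)
(denominator n, not n − p) — one convention, stated so treatment-level
tables are reproducible.

## Adequacy criteria and model ranking

* **AIC** = n·ln(SSE/n) + 2(p + 1), the Gaussian profile form counting
  the residual variance as a parameter. The additive constant differs
  across software, so only ΔAIC — and hence the **evidence ratio**
  exp(ΔAIC/2) against the lowest-AIC model — is transportable. Ratios
  beyond the float range are reported as infinite.
* **R²** of the linear regression of predicted on observed values
  (= squared Pearson correlation).
* **CCC**, Lin's concordance correlation, with population (1/n)
  moments: 2·cov/(var_p + var_o + (mean difference)²).
* **MSPE** = mean((o − p)²), decomposed exactly into mean bias
  (ō − p̄)², systematic (slope) bias (s_p − r·s_o)², and random error
  (1 − r²)·s_o² — the three components are non-negative and conserve
  the total by identity.
* **Paired-MSPE accuracy test**: for two models predicting the same
  observations, a two-sided paired t-test on the per-observation squared
  errors d_i = e²_a,i − e²_b,i. With all d_i = 0 the p-value is 1.
  P-values are reported raw (no multiplicity correction), significance
  judged at α = 0.05.

Non-converged fits appear in the ranking table flagged, but are excluded
from best-model selection.

## Identity of curves across treatments

Whether inclusion levels share one degradation curve is tested by the
extra-sum-of-squares construction for nested nonlinear models: the full
model fits each group separately (equivalent to a dummy-variable
parameterization — the stacked least-squares problem is block-diagonal,
an equivalence the tests verify against an independent stacked solve),
the reduced model fits the pooled observations once, and

F = [(SSE_r − SSE_f)/(df_r − df_f)] / (SSE_f/df_f),  df = (df_r − df_f, df_f).

Pairwise comparisons refit full and reduced models on each pair's pooled
data (rather than taking contrasts inside one four-group fit — the two
constructions differ numerically; the pairwise-refit choice is this
package's, documented rather than asserted as anyone else's). Replicate
flasks enter as independent observations within their group. Under iid
Gaussian observation noise the test's type-I error is at the nominal 5%
(±2 points over 1000 seeded replicates in the test suite).

## Synthetic experiments

The generator emulates a wireless pressure-sensor incubation: 4
treatments × 6 flasks + 3 blanks, readings every 5 min for 24 h (289
points including t = 0), 500 mg substrate per flask. Default truths are
the four treatment-level Richards equations (asymptotes 4.87–6.18
mL/100 mg DM, rates 0.10–0.17 h⁻¹, exponents 1.99–2.50).

Because the raw signal is cumulative and physically non-decreasing,
noise is applied to per-interval increments: Gaussian steps with
standard deviation noise_sd/√(n_intervals), so the accumulated deviation
at 24 h has scale `noise_sd` (default 0.1 mL/100 mg DM, the magnitude of
treatment-level fit RMSEs for curves of this kind). A transiently
negative increment carries its deficit forward — the series is the
running maximum of truth + random walk, floored at zero — which keeps
every flask monotone while staying near-unbiased (mean deviation < 0.02
mL/100 mg DM over 100 seeds in the tests). Blanks follow the same
construction around a zero truth (scale `blank_drift_sd`, default 0.05
mL per flask); sample flasks add an independent background of the same
distribution, so subtracting the mean blank is unbiased in expectation.
Correction divides by mass/100 mg (factor 5 at the 500 mg load) to yield
mL/100 mg DM.

What the generator does *not* emulate: pressure→volume sensor physics,
venting events, temperature drift, heteroscedastic or serially dependent
sensor error beyond the random-walk increments, or between-run inoculum
variability. Passing tests therefore show the pipeline recovers kinetics
under the stated design and noise model, not that any particular real
incubation satisfies that model. Note the two noise regimes used
deliberately: generator curves carry random-walk (serially correlated)
deviations, while the F-test and paired-test calibration simulations add
iid Gaussian noise to truth curves — the sampling model under which
those tests are exact.

## Numerical and design choices

* Averaging: the "average gas production curve" is the pointwise mean
  across all flasks of all treatments; treatment-level fits use
  per-treatment pointwise means. Fitting itself is agnostic — it takes
  whatever curve (or pooled observation set) it is given.
* On data simulated from a Richards truth, Richards attains the lowest
  AIC essentially always, and with near-noiseless average curves its
  evidence ratios against the others saturate to infinity; real curves,
  with model misspecification and correlated errors, give the finite
  ratios in the hundreds-to-thousands range.
* Determinism: one `numpy` Generator seeded from the config drives a
  whole simulated experiment; equal seeds give byte-identical CSVs.
* Degenerate inputs: all-zero curves refuse to fit; curves shorter than
  p + 1 points are rejected; identical groups give F ≈ 0, p ≈ 1;
  perfect fits (SSE = 0) return an AIC of −∞ with a warning.
* p-values below 1e−4 are displayed as "<0.0001" in formatted tables;
  raw values are always written alongside.

## Problem sizes

Defaults mirror the study design (289 readings per flask, 27 flasks).
Calibration simulations in the test suite use 1000 replicates for
type-I error (two single-flask groups on the 5-min grid) and 500 for
power; the brute-force optimizer oracle uses 21³ grids on ≤ 20-point
curves. The full test suite runs in well under a minute on one CPU.

## Known limitations

* Absolute AIC values are convention-dependent; compare only
  differences/evidence ratios across software.
* The F test assumes iid Gaussian errors; with serially correlated
  flask noise (as the generator itself produces) it over-rejects, which
  is the textbook caveat for repeated-measures gas curves.
* No mixed-effects or multi-start estimation; the Richards D-cap is a
  pragmatic identifiability guard, not a biological claim.
* The paired-MSPE test is a plain paired t-test on squared errors;
  heavy-tailed errors would call for a permutation variant.
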