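# Methods

## Structural model

The kinetic model is a directed graph of well-mixed compartments with
first-order transfer. The full topology (preset `mtl3`) has nine
compartments: a latent central compartment C (dose and elimination), a
three-compartment muscle chain C↔M1↔M2↔M3, a three-compartment liver chain
C↔L1↔L2↔L3, and a two-compartment tumor chain attached to the first liver
compartment, L1↔T2↔T3 — the tumor is perfused through the liver, not
directly from the central space. M2, T2 and L2 are observed (they correspond
to the imaged muscle, tumor and liver ROIs); the other six are latent.
Reduced presets (`minimal`, `no_m3`, `no_t3`, `no_l3`, `tumor_on_central`)
express the structural-evaluation family; arbitrary topologies load from
YAML — topologies are data, not code.

Units are fixed throughout: seconds, millilitres, micromoles, millimolar
(µmol/ml ≡ mM). The dose is 0.2 mmol/kg × body weight; the default simulated
body weight of 0.3 kg gives 60 µmol. Plasma clearance is fixed at
Cl = 0.04 ml·s⁻¹ (literature rat value) and never estimated.

With amounts A(t) obeying dA/dt = K·A and a bolus at the injection lag, the
solution is A(t) = expm(K·(t−lag))·A₀. The propagator diagonalizes K once
per parameter set and evaluates all time points with one small matrix
product; if the eigenbasis is ill-conditioned (near-defective K) it falls
back to scaling-and-squaring matrix exponentials per time point. This is
the only numerically sane route: the published rates span 2.3·10⁻⁵ to
300 s⁻¹ and defeat fixed-step integration. The analytic path agrees with an
adaptive implicit (Radau) integrator to better than 10⁻¹³ of the dose on the
full model; the test suite enforces 10⁻⁸.

Concentration scaling uses apparent distribution volumes derived by flow
balance: V_c = Cl/k_C0 anchors the central volume and every bidirectional
exchange propagates Q = k_ij·V_i = k_ji·V_j outward. The observed
concentration is C_j = A_j/V_j. The derivation is exact and self-inverse
(k = Q/V round-trips to machine precision); it requires every edge to have a
return edge, which holds for all presets. This flow-balance chain is the
package's amount→concentration convention — the one self-consistent choice
compatible with the fixed clearance.

## Population layer

Each dataset (one animal at one measurement day) is an independent
individual; inter-occasional variability is absorbed into inter-individual
variability rather than modelled as a separate term. Individual rates are
log-normal around covariate-adjusted typical values:

    k_i = θ · exp(β·x_i) · exp(η_i),   η_i ~ N(0, ω²),

with one η per transfer constant and a diagonal Ω (no correlation structure).
Log-normality is the standard positivity-preserving choice. Covariate
effects are multiplicative log-linear: the binary anesthesia covariate
(`anest`) contributes exp(β·x); the ordered four-level tumor-vitality
covariate (`vti`, level 1 = pre-treatment reference) contributes exp(β_level)
with the reference fixed at factor one (three free coefficients).

Residual error is mixed additive + proportional,
y = f·(1+ε_prop) + ε_add with Var(y) = σ_add² + (σ_prop·f)², which keeps a
floor at low concentrations and a constant CV at high ones. The injection
lag is a per-dataset nuisance with a Normal(10 s, 5 s) prior truncated at
zero (configurable); one lag is shared by a dataset's three tissue curves —
the three ROIs are imaged simultaneously, so a per-tissue lag would have no
physical counterpart.

## Estimation

Fitting is two-stage, mirroring standard pharmacometric practice for this
model family.

**Initial estimates.** The model object passed to the fitter carries the
initial typical values. The defaults are the published population estimates
for this model in rat — exactly what a practitioner refitting a published
model starts from; structural variants fall back to 0.1 s⁻¹ for rates with
no literature value. Initial ω² is 0.1, initial σ_add/σ_prop are
0.01 mM/0.1.

**SAEM.** 120 iterations (default) of stochastic-approximation EM:
each iteration refreshes every dataset's η and lag with a few
componentwise Metropolis sweeps, then updates θ (and β, by per-rate linear
regression of the smoothed individual log-rates on the covariate design),
ω² and the residual SDs through stochastically smoothed sufficient
statistics. Step sizes are 1 for the first half of the iterations
(exploration) and 1/iter afterwards (averaging). Two stabilizers matter in
practice and are defaults: during the exploratory phase the residual SDs are
frozen (otherwise the error model absorbs early structural misfit, deadens
the likelihood signal, and the run parks in a large-noise local optimum),
and ω² may shrink by at most 10% per exploratory iteration (keeping the
random effects mobile). A naive-pooled Nelder-Mead pre-fit of the typical
values is available (`prefit_evals_per_rate`) but off by default: it helps
identifiable models started far from the optimum, yet on this model family
it lets the simplex drift along flat ridges (below) away from the supplied
initial values.

**MCMC.** Adaptive Metropolis-within-Gibbs over log-transfer-constants,
covariate coefficients, per-dataset η and lag, log-variances and log-residual
SDs; clearance is never sampled. Defaults follow the protocol: 3000 burn-in
plus 3000 retained samples; the `fast` profile (500/500) is the desk-scale
setting used by the test suite and acceptance script, `smoke` (40 SAEM,
120/120) drives replicate experiments. Priors are weakly informative —
log-uniform on [10⁻⁷, 10⁴] s⁻¹ for rates, half-Cauchy(1) for ω and σ,
Normal(0, 2²) for β. Proposal scales adapt toward 44% acceptance in batches
during burn-in only, and are capped at 0.5 natural-log units: in practically
non-identified directions acceptance-driven adaptation would otherwise grow
the step without bound and spend the run on excursions along flat ridges.
Acceptance rates outside [0.05, 0.95] are reported as warnings on the fit.

Randomness is organized as one substream per update block per sweep with a
fixed number of variates consumed per block (common random numbers). Chains
are bit-reproducible given the seed, and two nested models run from the same
seed share their innovations in every common block, so their OFV difference
reflects the model change rather than independent sampler noise. For the
same reason, covariate models are best compared against the base model from
a shared SAEM initialization (`run_mcmc` accepts the base init and fills the
missing coefficients from the model's initial values).

One non-obvious move: a covariate-recentering interweaving step. Each sweep,
β_b and the target-rate η of the affected datasets are shifted oppositely by
an exact Gaussian conditional draw — individual rates, and hence the
likelihood, are untouched. Without it the coefficient only creeps by random
walk while the etas absorb the group contrast, which cripples covariate
detection and produces spuriously tight intervals. The analogous move for
the typical values themselves is deliberately *not* used; see
identifiability below.

## Objective values, DIC, diagnostics

The per-dataset objective is

    OFV_i = posterior mean of [ −2 log p(y_i | k_i, lag_i)
                                −2 log p(η_i | Ω) ],

i.e. the conditional data deviance plus the random-effect term — the
analogue of the per-subject objective that mixed-effects tools report. The
random-effect term is what lets a covariate model that explains a group
shift show a lower OFV (it recenters the etas); on the pure data deviance
the base model's etas would absorb the effect and ΔOFV would be noise. The
lag prior term is omitted: it is common to all models on the same data and
cancels from every comparison.

DIC uses the Spiegelhalter form on the same deviance: D̄ is the mean of the
per-sweep total, D̂ evaluates the deviance at the posterior means of all
parameters (population, η, lag, σ), pD = D̄ − D̂, DIC = D̄ + pD. The
preferred model in a comparison is the lowest-DIC one; ΔOFV is reported
relative to a named reference.

CWRES conditions on the empirical-Bayes (posterior-mean) η and lag per
dataset and standardizes by the model-implied observation SD
√(σ_add² + (σ_prop f)²); conditional on the individual parameters the
observation covariance is diagonal, so no whitening matrix is needed. On
data simulated from the fitted model CWRES are standard normal (the suite
checks mean within ±0.1, SD within [0.9, 1.1]).

Chain stability is a Geweke-style screen: per parameter, a z-statistic
comparing the mean of the first 10% of the chain against the last 50%
(|z| > 2 flags instability), plus the total drift of the chain in SD units
from a linear fit. The model-level verdict is unstable if any parameter is
flagged. On white noise the flag stays silent in ≥95% of trials; a 3-SD
injected trend fires it.

The covariate scan replaces a GAM pre-screen with an exhaustive scan over
the physiologically admissible pairs — `anest` × muscle/liver rates,
`vti` × {k_T2T3, k_T3T2} — and the retention rule keeps a model only when
every coefficient's SE% stays at or below 55 (anest) / 30 (vti). Applying
covariates to several rates simultaneously over-parameterizes the model;
the suite checks that this trips the instability flag or blows up the
coefficient SE%.

## Identifiability — what the data can and cannot pin down

Profiling the likelihood of the full model around the published values
shows two kinds of practically flat directions at the 6 s sampling
resolution:

* **Central transit scale.** Jointly scaling (k_C0, k_CM1, k_CL1) leaves
  every observed curve essentially unchanged: the central compartment's
  residence time (≈0.3 s at the published values) is far below the sampling
  interval, and V_c = Cl/k_C0 co-varies so all concentration scales are
  preserved. Only the ratios among these rates, and a lower bound on the
  scale, are data-determined.
* **Fast-exchange pairs.** Jointly scaling (k_M1M2, k_M2M1) — equilibration
  time ≈3 ms — changes the total deviance by well under one unit across a
  four-fold range. The tumor pair (k_T2T3, k_T3T2) is a weaker version of
  the same ridge.

Consequently, point estimates of the individual rates in these directions
are anchored by the initial estimates and the finite sampling protocol, not
by the data; the identified quantities are the rate ratios, the derived
volumes and flows, the slow rates, and the observed-curve predictions. This
is a property of the design (three observed tissues, 6 s resolution), not of
the sampler: the very small reported SEs on the fastest rates in analyses of
this model family are the signature of the same anchoring. The package
keeps the finite protocol (SAEM from the supplied initials, then a fixed
MCMC budget) as the method, reports SE% as computed, and leaves the drift
diagnostics (chain stability) as the tool that exposes non-converged
directions — a deliberately pragmatic stance that reproduces how such
models are fitted in practice. A recentering (interweaving) move on the
typical values would be the "fully mixing" alternative; it was implemented,
explored, and rejected as a default because it turns the flat directions
into unbounded random walks under the uninformative priors.

The recovery experiments should be read with this in mind: they demonstrate
that the identified directions are recovered from data and that the
protocol-anchored directions stay at their initial values — which, in the
simulate-then-refit setting where truth equals the published values, also
lie at the truth.

## Synthetic-study generator

`generate_study` emulates the original design: 33 datasets by default —
17 pre-treatment (vti level 1) plus treated groups of 5/6/5 (vti levels
2–4, decreasing residual vital tumor tissue), a binary anesthesia flag on a
configurable fraction (default half) of post-treatment datasets, a shared
sampling schedule of 6 s spacing to 180 s then 24 s spacing to 900 s
(60 points per tissue curve; the alternative per-curve count statement in
the source material conflicts with these spacings, and the spacings govern),
a 0.2 mmol/kg bolus at 0.3 kg body weight, truncated-normal injection lag,
log-normal IIV and mixed noise. Defaults: truth θ = the published population
estimates; ω² = 0.09 on every rate (≈30% CV, the magnitude implied by the
published inter-individual variability); σ_prop = 0.05, σ_add = 0.005 mM
(only SEs, not magnitudes, of the error components are published; these are
realistic DCE-MRI values). For detection-power experiments the documented
covariate truths are β_anest = −0.3 on k_M1C and vti level effects
(0, −0.4, −0.8, −1.2) on k_T3T2 — generator conventions, not literature
claims. The generating η, lag and individual rates of every dataset are
recorded in a truth ledger for recovery scoring.

What the generator does **not** emulate: signal-to-concentration conversion
(curves are generated directly in mM, so converter bias/nonlinearity is out
of scope), ROI heterogeneity, a separate inter-occasional variability term,
schedule jitter, or non-Gaussian noise. Passing recovery tests therefore
demonstrates correctness of the estimation machinery under the model's own
assumptions — not robustness to the ways real DCE-MRI data violate them.

## Problem sizes and numerical choices

The test suite and acceptance script run desk-scale versions of each
experiment, chosen as the smallest sizes at which the scientific effect is
clearly resolved: parameter recovery uses 15 datasets with the full
schedule and the 500/500 sampler profile; DIC structural recovery uses 10
replicates of 6 datasets on a 3× thinned schedule with the smoke profile;
covariate power/calibration uses 5 replicates of 10 datasets on a 2×
thinned schedule. The full published protocol (33 datasets, 3000/3000) runs
in well under half an hour on one CPU.

Numerical details: amounts are clipped of round-off negatives below
10⁻¹⁰ × dose; ω² is floored at 10⁻⁴; rate proposals outside the prior box
are rejected without evaluation; the truncated-normal lag draws by
rejection; eigen-propagation clips decaying exponents at e⁻⁷⁴⁵ to avoid
spurious underflow warnings; dataset likelihoods evaluate on the union grid
of a dataset's observation times and index per-tissue.

## Known limitations

* OFV and DIC are conditional-deviance quantities (plus the η term), not
  marginal-likelihood approximations; comparisons are meaningful between
  models fitted to identical data with the same focus, which is how they
  are used here.
* SE% and CI understate uncertainty in the flat directions (see
  identifiability); they are faithful summaries of the finite protocol, not
  of the ideal posterior.
* The covariate scan fits one pair at a time; interactions between
  covariates are only assessed by explicitly composing specs.
* No correlated Ω blocks, no time-varying covariates, no saturable
  kinetics.
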