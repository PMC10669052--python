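# Methods

`rabepkpd` implements a population pharmacokinetic–pharmacodynamic (PK–PD)
analysis of single-dose oral rabeprazole (10 mg enteric-coated tablet) in
healthy adults, built so that every stage — non-compartmental analysis,
nonlinear mixed-effects (NLME) estimation, covariate selection, model
qualification and effect simulation — runs end to end on synthetic cohorts.

## Structural PK model

Disposition is two-compartment; oral input passes through an absorption lag
time `Tlag` and a chain of three sequential first-order depots:

    dA0/dt = -Ka1*A0                      (dosing depot)
    dA1/dt =  Ka1*A0 - Ka2*A1             (depot 1)
    dA2/dt =  Ka2*A1 - Ka3*A2             (depot 2)
    dAc/dt =  Ka3*A2 - (k10 + k12)*Ac + k21*Ap
    dAp/dt =  k12*Ac - k21*Ap

with `k10 = CLc/Vc`, `k12 = CLp/Vc`, `k21 = CLp/Vp` and plasma
concentration `C = Ac/(1000*Vc)` (amounts ng, volumes L, so C is ng/mL).
All clearances and volumes are apparent (/F): the dose is treated as fully
delivered into the chain. Doses in mg convert at 1 mg = 1e6 ng.

Because the system is linear, the central amount after the lag is a sum of
five exponentials whose rates are the three chain constants plus the
disposition hybrid constants (alpha, beta). The default solver evaluates
the closed-form partial-fraction (residue) expansion, vectorized over
subjects, parameter batches and times; when two rates (nearly) coincide the
expansion is ill-conditioned and the solver falls back to the exact matrix
exponential (`method="analytic"`). An LSODA integration (`method="ode"`)
is kept as an independent numerical route; the two agree to 1e-6 relative
to the profile maximum. Inside the NLME hot path the fallback is replaced
by a relative 1e-6 jitter of coincident rates — a perturbation far below
what the likelihood can resolve — so that batched evaluation never drops
into a per-element loop.

### Transit-chain symmetry and identifiability

The chain transfer function `prod_i Ka_i/(s + Ka_i)` is symmetric under
permutation of the three rate constants, so the individual `Ka`s are
identified only as a set unless the random-effect/covariate structure
breaks the tie. Moreover the published parameter regime is near flip-flop
(`k10 = 2.49/h` exceeds every `Ka`), with four of the five exponential
rates packed into 1.9–3.1/h. The profile likelihood therefore has a long,
nearly flat ridge linking (`Vc`, `Ka2`, `Ka3`): maximum-likelihood
refits of data simulated from the published values can sit 10–100% away
from the generating values of those coordinates at a genuinely better
likelihood, while `CLc`, `CLp`, `Vp`, `Ka1`, `Tlag` and the residual SD
are recovered tightly. This matches the published bootstrap, where the
`Ka2` resampling median sits 16% from its point estimate. Recovery tests
in this package report the full picture rather than hiding the ridge.

## Individual parameters, covariates, variability

Inter-individual variability (IIV) is log-normal, `P_i = tvP * exp(eta_P)`,
with diagonal variances `omega^2` on `Vc`, `CLc`, `Ka3`, `Tlag` (the
published `omega^2` for `Ka1`/`Ka2` is 0.00 and is treated as exactly
zero by default, with a config override for simulation studies; the
peripheral parameters carry no IIV). The final covariate model places
gender on the lag time and body-surface area (BSA) on the last absorption
rate constant, by default in the multiplicative-exponential form

    Tlag_i = tvTlag * exp(dTlagdGender * g + eta)     g: male 0, female 1
    Ka3_i  = tvKa3  * exp(dKa3dBSA * (BSA - 1.73) + eta)

An additive-shift form (`(tvP + coef*x) * exp(eta)`) is selectable because
the source analysis never prints its covariate equation; the multiplicative
default is retained since `exp(0.73) = 2.08` matches the observed
female/male lag-time ratio. BSA is centred at 1.73 m^2, the midpoint of
the reported gender medians (1.87/1.58), configurable. Residual error is
log-additive, `C_obs = C_pred * exp(eps)`, `eps ~ N(0, sigma^2)` with
`sigma = 0.37` interpreted as the log-scale SD. Predictions that are
structurally zero (samples at or before the lag) stay exactly zero.

## NCA

AUC/AUMC use the linear-up/log-down trapezoid (log branch only between two
positive declining samples). The terminal slope is chosen among suffixes of
the post-Tmax points (3–8 points) by best adjusted R^2, ties to more
points; windows under adjusted R^2 0.80 leave the slope-dependent outputs
missing rather than failing. Lag time is the last below-LLOQ time before
the first quantifiable sample. Weight-normalized NCA divides the profile
(and the LLOQ) by body weight first. Gender comparisons use Welch's
two-tailed t-test at alpha 0.05; the covariate screen computes Pearson r
for every covariate-parameter pair (overall and per gender), flags
|r| >= 0.3, and re-examines flagged pairs by OLS slope p-values.
Under the published IIV magnitudes the model-implied BSA–Cmax correlation
within a gender stratum is only about −0.05 to −0.10, so the screen's
flag threshold is reachable only through body-size effects that the final
model does not itself encode; the simulation tests assert the sign, not
the flag.

## NLME estimation

The marginal likelihood is approximated by Laplace expansion about the
conditional mode of the etas; observations below the LLOQ are excluded
(M1). Each subject contributes

    -2 log L_i = 2 g(eta*) + log|H| + log|Omega| + n_i log 2pi
                 + 2 n_i log sigma + 2 sum_j log DV_ij

where `g` is the penalized log-scale residual sum of squares and `H` its
curvature at the mode. `H` uses the first-order (FOCE-style) Gauss–Newton
form `J'J/sigma^2 + Omega^{-1}` with `J = d log f / d eta` by central
differences: it is positive definite by construction, which keeps both the
inner Newton iteration and the log-determinant numerically stable — the
exact second-order curvature is indefinite near the absorption onset,
where predictions vanish like `tau^3` and higher derivatives blow up. `J`
for the determinant uses a wider secant (0.1 on the eta scale) than the
Newton steps (0.01) for the same reason. A tiny smooth ramp
(`1e-12 * exp(8*min(tau,0))` ng/mL) below the lag keeps the log-likelihood
finite and informative about `Tlag` when an observed sample falls before
the current lag estimate.

The conditional-mode search is a damped Gauss–Newton iteration vectorized
across all subjects at once with a shrinking active set. The eta landscape
of lag-time models is multimodal, so the search is seeded from a
deterministic candidate set — a feasible cold start (lag pulled below the
first quantifiable sample), zero, the cached modes of the previous
objective evaluation, and on "global" evaluations a factorial grid at
±1.5 and ±3 omega-SD — taking Newton from the three best starts. The
outer problem maximizes over (log typical values, covariate coefficients,
log omega^2, log sigma) by alternating L-BFGS-B passes (coarse then fine
finite-difference steps) with global mode refreshes, followed by a
trust-region polish; on non-convergence up to three jittered restarts
(typical values scaled by U[0.5, 2], seed-controlled) are attempted.
Standard errors come from a central finite-difference Hessian of the OFV
on the natural scale (`Cov = 2 H^{-1}`), CV% = 100*SE/estimate.

Correctness of the Laplace machinery is pinned by two oracles: the
closed-form marginal likelihood of a linear-Gaussian toy model (agreement
to 1e-6) and 64-node adaptive Gauss–Hermite quadrature on a one-eta
nonlinear toy (agreement to 0.1).

## Covariate selection

Forward inclusion at chi-square p < 0.05 (dOFV > 3.84 per df), best
candidate first, then backward elimination at p < 0.01 (retained only if
removal worsens the OFV by > 6.63). Candidate screening uses restricted
refits: only the new coefficient, the IIV variance of its parameter and
sigma are re-estimated, everything else staying at the current model's
values, with the coefficient initialized from the regression of the
empirical-Bayes etas on the covariate — the likelihood is nearly flat at
coefficient zero because the base-model etas have already absorbed the
effect, and the eta-regression start (standard eta-screening practice)
lands the optimizer inside the informative basin. The screened dOFV is a
lower bound on the full-refit improvement, so selection is conservative;
the winning candidate is confirmed by a full refit before being added
(and dropped if the full refit does not reproduce the improvement), and
backward elimination always uses full refits. Every attempted step is
logged. Note an intrinsic power limit of the
published regime: the BSA->Ka3 effect moves `Ka3` by far less than its own
IIV (|coef|*sd(BSA) ≈ 0.2 versus omega_Ka3 ≈ 1.3), so on data simulated
from the final model that term carries only a few OFV units of information
even at hundreds of subjects, whereas the gender->Tlag term is reliably
recoverable.

## Qualification

*Bootstrap*: subjects resampled with replacement within gender strata
(every replicate keeps the 24/21 split), each replicate refitted
warm-started from the original estimates; medians and percentile 95% CIs
reported, >50% failures flags the table unreliable. *VPC*: replicate
datasets simulated at the observed design; 5th/50th/95th percentile bands
with 95% CIs per time bin (bins merged under 3 observations), coverage =
fraction of quantifiable observations inside the simulated 5–95% envelope
widened to the CI bounds of the outer percentiles (the fraction "within
the 95% CIs" of the predictions; the raw 5–95 band would cover exactly
90% in expectation for self-simulated data), gender stratification
optional. *GOF*: population and
individual predictions on the log scale and conditional weighted residuals
from the standard FOCE linearization `V = G Omega G' + sigma^2 I` about
the conditional modes, with a 500-replicate simulation fallback when `V`
is singular.

## PD model and effect metrics

Gastric pH follows a direct-response sigmoid Emax with baseline,
`E = E0 + Emax*C^gamma/(EC50^gamma + C^gamma)` (published values E0 2.50,
Emax 4.72, EC50 51.58 ng/mL, gamma 5.04), linked pointwise to the
central-compartment concentration; no effect-compartment delay and no PD
random effects. Effect metrics over a 0–10 h window: trapezoidal AUEC,
maximum pH, and onset/offset/total duration above pH 4 with
linear-interpolated crossings on a 0.01 h grid. The 10 h window is chosen
because the published total 5th-percentile AUEC (25.90) is consistent with
a 10 h baseline contribution (25.0) and impossible under 12 h; it is
configurable. PD fitting offers linear, hyperbolic-Emax and sigmoid-Emax
candidates by unweighted least squares, ranked by AIC, with Jacobian-based
SEs, RSE% and 95% CIs.

## Synthetic cohorts

The generator emulates the study design: 24 male / 21 female, single
10 mg dose. BSA is log-normal around the gender medians (1.87/1.58 m^2)
with 8% CV; height is normal per gender (174/161 cm, SD 5); weight is
back-derived from BSA and height through the DuBois relation so weight and
BSA stay coherent. The sampling schedule (not printed by the source) is
15 points over 12 h, dense across the 0–5 h absorption window; LLOQ is
1 ng/mL, with values below it recorded as zero. Everything is seeded;
identical spec + seed gives byte-identical CSV output.

What the generator does not emulate: the joint distribution of the
biochemical covariate panel, any body-size dependence of the distribution
volume (only the modelled BSA->Ka3 route exists), correlated etas, and
assay-level heteroscedasticity. Passing tests therefore demonstrate
internal consistency of the pipeline under the published model, not
robustness to real-data features outside it.

## Population effect simulation

Gender-stratified simulations fix each stratum's covariates at the
reported medians (male BSA 1.87, female 1.58), draw PK etas, convert each
concentration curve to pH and summarize the pointwise-median pH profile —
the analogue of a median population prediction. 5%/95% analogues come
from the median profiles of replicate 45-subject cohorts resampled from
the simulated pool. A stratum whose median profile never crosses pH 4
reports duration 0 and no onset. With the default multiplicative covariate
form this reproduces the published male onset (≈2.1 vs 2.02 h), male
duration (≈2.7 vs 2.79 h) and female duration (≈2.0 vs 2.09 h); the
female onset comes out later (≈3.9 vs 3.20 h), pushing the onset-delay
ratio to ≈1.86 versus the reported 1.58 — the expected signature of the
unresolved covariate-form question, since the reported female onset almost
equals the multiplicative female typical lag itself.

## Problem sizes used in the test suite

Test and acceptance runs are sized for a single CPU: parameter-recovery
fits use 200-subject trials over 3 seeds (median); the covariate-search
replicates use 40-subject trials, 5 planted and 5 null; the VPC uses 200
simulated replicates and the PD-effect simulations 1500 subjects per
stratum. The bootstrap default in the pipeline is 50 replicates (1000 in
the source analysis; the machinery is identical).
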