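# Methods

## Structural model

Disposition follows the mammillary three-compartment IV-bolus model
parameterized in clearances: central volume V1, peripheral volumes V2
(superficial) and V3 (deep) in mL/kg; plasma clearance Cl and
intercompartmental clearances Cl2, Cl3 in mL/kg/h.  The closed-form
tri-exponential solution is primary — the characteristic cubic of the
micro-constant matrix is solved numerically (`numpy.roots` on the companion
matrix) and the bolus coefficients follow from the spectral decomposition;
a matrix-exponential integration of the same linear system serves as the
independent oracle in the tests (adaptive ODE steppers lose relative
accuracy over the ~16 decades the late curve spans, so `scipy.linalg.expm`
is the right arbiter).  Closed form was chosen over repeated numerical
integration because the Monte Carlo study evaluates millions of curve
points.

Degenerate inputs collapse analytically: Cl2 = 0 and/or Cl3 = 0 drop the
corresponding exponential (two- or one-compartment limits) rather than
perturbing parameters by an epsilon, so the curves stay exact and the
two-compartment comparison model is the same code path.

Multiple dosing is superposition of shifted bolus solutions.  Doses are kept
internally in ng/kg (mg/horse arms convert through each horse's body
weight); concentrations are ng/mL throughout.

## Urine channel

Urine concentration is modeled as proportional to plasma,
C_u(t) = Rss · C_p(t), with Rss the pseudo-equilibrium urine-to-plasma
ratio.  The proportionality is only physically meaningful once
distribution equilibrium is reached; urine values earlier than 24 h after
the first dose are returned with a validity flag set false, and the fitting
and detection-time routines ignore flagged records.  Each simulated or
estimated horse uses its own Rss (with its random effect), not the typical
value; only the IUC derivation uses tvRss.

## Population model and residual error

Between-subject variability is log-normal on all seven structural
parameters, θ_i = θ_tv·exp(η_i), η ~ MVN(0, Ω) with Ω a full 7×7
covariance, reported as CV% = 100·√(exp(ω²)−1).  Residual error is
combined proportional + additive per matrix (plasma: 15% CV + 0.12 ng/mL;
urine: 42% CV + 0.11 ng/mL at the packaged published values); simulated
negative observations are clamped at zero with a logged count.  A non-PSD
covariance supplied by a user is projected to the PSD cone by eigenvalue
clipping with a warning.

## Synthetic cohorts — what they do and do not emulate

The generator reproduces the six study arms of the international dataset:
group sizes (10+10+16+11+6+12 = 65 horses), doses (1.1 mg/kg or
500 mg/horse IV, single or five daily boluses), per-country quantification
limits, and demographic ranges (age, body weight, sex, breed), with
covariates drawn independently and uniformly within their ranges.  Sampling
schedules were not published; the default plasma schedule
(0.083–168 h post last dose) and urine schedule (24–168 h) were chosen so
that the granularity of reported cohort detection times is representable,
and both are configurable per arm.  Scenario thinning (rich: plasma at
9/24/48 h + urine at 48 h; sparse: plasma at 24 h post last dose) requires
schedules containing those times.

Consequences: passing recovery tests show the estimation machinery is
consistent with its own generative model — they cannot certify behavior on
features real data would add (between-study schedule differences, assay
batch effects, covariate correlation structure, dropout, non-log-normal
tails).  Below-LOQ handling follows the sparse-censoring rule: when under
5% of a matrix's observations are below the LOQ they are excluded,
otherwise they are retained flagged (and always excluded from likelihoods
rather than integrated M3-style).

## Estimation

No nonlinear mixed-effects engine is available as a library dependency
here, so the fit is authored in-package as a **Laplace-EM**:

* **E-step** — per horse, the conditional mode of η (quasi-Newton L-BFGS-B
  from the previous iterate, bounded at |η| ≤ 10 to keep exp(η) finite) and
  a Laplace posterior covariance from the finite-difference Hessian.
* **M-step** — typical values and covariate coefficients update by
  closed-form log-scale least squares (log θ_i = log tv + covariate terms
  + η_i); Ω updates from posterior second moments (mean of m mᵀ + S,
  projected PSD); the four residual sigmas update by direct Nelder-Mead
  maximization of the observation likelihood at the conditional modes,
  floored at 10⁻³ (the floor keeps the inner problem well-conditioned in
  noise-free limits; an exactly-zero sigma makes the landscape pathologically
  stiff).
* The marginal log-likelihood is the Laplace approximation, from which
  BIC = −2 ln L + k ln n (n = observations, k = fixed effects + free Ω
  terms + sigmas) and likelihood-ratio tests are formed.

Initialization: typical values from per-horse noncompartmental analysis
(linear trapezoidal AUC with log back-extrapolation to the dose instant,
terminal slope from the last three positive points, Cl = dose/AUC∞,
Vss = Cl·MRT), Ω diagonal at 0.1, sigmas at NCA-agnostic defaults.
Convergence: maximum relative θ change below 10⁻⁴ with a stable penalized
objective, default cap 40–60 outer iterations.  Mode-based EM slightly
understates residual variances and Ω with modest per-horse information;
the recovery contract (typical values within 15%, BSV(Cl) within 10
points on 65-horse cohorts) holds with margin in the tests.

Conditional weighted residuals use the first-order conditional
linearization (V = FΩFᵀ + diag of residual variance at the individual
prediction, residuals whitened by its Cholesky factor); the visual
predictive check simulates 200–500 replicate datasets at the observed
design and reports 10/50/90 bands.

### Covariate search and its power ceiling

Covariate effects enter as power terms on continuous covariates
(tv·(x/ref)^b, ref = cohort median) or categorical shifts; both have
closed-form M-step updates, so a candidate model costs one extra fit.
Stepwise selection adds the best candidate when it improves BIC by more
than 6.635, deletes effects whose removal costs less than 10.823, and only
retains a final model that beats the covariate-free BIC by at least 10.
Candidate fits are initialized from the same starting values as the base
fit — initializing from the base fit's own estimates was observed to land
covariate models in inferior likelihood modes.

A practical note on power: an allometric body-weight effect on clearance of
exponent ~0.75 explains only (0.75·sd(log BW))² ≈ 0.01–0.02 of the 0.085
log-variance of clearance at realistic body-weight spreads, giving
2·ΔlnL well below the add threshold at 16–65 horses.  Selection of such an
effect is therefore *expected* to fail at this scale — consistent with the
finding that weight and age looked influential but were not retained in
the final published model — and the tests exercise selection with an
unambiguously strong injected effect instead, alongside exponent-recovery
and confounding-detection (perfectly nested categorical pairs, e.g. breed
within country) checks.

## Detection times

DT is measured from the last administration.  Three estimators:

* **model** — Brent root-finding (tolerance 0.01 h) on the noise-free
  individual curve after the final dose, which is strictly decreasing, so
  the crossing is unique; a curve never exceeding the SL reports DT 0 with
  a censoring flag;
* **interpolated** — log-linear interpolation between the last observation
  at/above the SL and the next below it (last crossing if several; linear
  fallback for non-positive brackets; censored-low/high flags mirror
  non-calculable cells);
* **cohort** — the earliest scheduled sampling time from which every
  horse's remaining observations are below the SL; always an element of
  the schedule, hence never below any horse's interpolated DT snapped up
  to the grid.

The Monte Carlo study samples 5000 η vectors from MVN(0, Ω), builds each
horse's parameters, and computes continuous model DTs per screening-limit
pair and matrix (quantiles by linear interpolation of order statistics,
type 7).  Plasma–urine agreement is summarized by difference quantiles and
Bland–Altman limits (mean ± 1.96·SD).

### The multiple-dose reconstruction gap

From the published *rounded* typical values and covariance, the single-dose
study reproduces the published quantiles closely (median 51.9–52.3 h,
95th 85.5–86.7 vs 84.4 h at SL 1 ng/mL; urine median 38.7–38.8 vs 38.5 h),
but the five-daily-dose plasma median lands at ~72 h against a reported
76 h (95th ~138 vs 157 h) while the corresponding urine quantiles match
(44.6/90.8 vs 45/88 h).  The multiple-dose plasma crossing sits deep in the
terminal phase, where accumulated concentration is maximally sensitive to
the unrounded internal estimates (and to whether the virtual population was
drawn from the covariance or resampled from estimated individual effects),
neither of which is recoverable from the published rounded values.  No
alternative dosing count (6, 10, or steady-state dosing) reconciles plasma
and urine simultaneously, so the faithful design — five boluses at
0/24/48/72/96 h, DT from the last dose — is retained and the residual
gap (~5% at the median) documented rather than tuned away.

## Regulatory limits

EPC = (dose per 24 h)/(Cl·24); IPC = EPC/500; IUC = IPC·tvRss, all
computed unrounded; rounding to whole ng/mL happens only when proposing
candidate screening limits (2/70 ng/mL at the packaged values).  Bootstrap
confidence intervals for the chain propagate per-replicate typical values
through the same equations.  The IUC's published point values are mutually
inconsistent at the first decimal, so its checks use the published 95%
interval (57.4–83.6 ng/mL) rather than a point.

## Bayesian individualization

A new horse's parameters are the posterior mode of η given its observations
under the population prior (the same penalized objective as the E-step;
residual sigmas fixed at population values, the conventional post-hoc
choice).  Zero observations return the prior mode — the typical horse — and
censored-only observation sets are rejected.  IBWT applies the model DT to
the posterior-mode curves at a screening-limit pair.

Identifiability caveats, quantified in the tests: four samples cannot pin
seven random effects, so even noise-free rich-scenario estimates carry a
~3 h average DT error from the prior-determined terminal phase (the <1 h
perfect-data limit requires the full curve); and with 15%/42% CV residual
noise the posterior SD of η_Cl caps the fraction of horses whose clearance
estimate improves on the prior mode at roughly 85%.

## Problem sizes and seeds

Tests run the full 65-horse recovery at three seeds, the Monte Carlo study
at its native n = 5000, and scale auxiliary experiments (bootstrap n = 3–5
on 3–4 horses, covariate experiments at 16 horses, VPC at 50–200
replicates) to keep the suite's fit count modest.  Every stochastic routine
takes an explicit seed; identical seeds give byte-identical datasets and DT
tables.

## Known limitations

* Mode-based (Laplace/EM) estimation, not stochastic-integration EM;
  sigma and Ω carry the usual small downward mode bias.
* The bootstrap refits with the same settings as the point fit; refit
  failures are dropped (aborting below 80% success).
* Urine is a pure proportional channel — no urine-flow or pH model, no
  metabolite kinetics, no oral/IM absorption, no saturable clearance.
* Covariate forms are power and categorical-shift only.
* The cohort generator draws covariates independently; real demographic
  structure (and its confounding with country) is only emulated in the
  aliasing tests.
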