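# Methods

## Pharmacokinetic model

Concentrations follow the one-compartment model with first-order
absorption and first-order elimination after a single oral dose,
parameterized with micro constants:

    dA_GI/dt = -ka·A_GI        dA1/dt = ka·A_GI - ke·A1        C = A1/V

whose closed-form (Bateman) solution is

    C(t) = F·D·ka / (V·(ka - ke)) · (e^(-ke·t) - e^(-ka·t)),

with the analytic limit `C(t) = F·D·ka·t·e^(-ka·t)/V` when ka = ke
(flip-flop degeneracy; the implementation branches rather than divides
by zero). The closed form is used everywhere for speed; a stiff ODE
integration of the same system is kept in the test suite as an
independent oracle (agreement to rtol 1e-6, and mass balance
A_GI + A1 + eliminated = F·D to 1e-8 relative).

Default population parameters: ka 1.22 h⁻¹, V 58.8 L, ke 0.150 h⁻¹,
F 0.90, dose 50 mg. Doses are converted mg → µg so concentrations are in
µg/L. The sampling schedule is fixed at 20 points: 0, 0.25, 0.50, 0.75,
1.00, 1.50, 1.75, 2.00, 2.25, 2.50, 2.75, 3.00, 3.25, 3.50, 3.75, 4.00,
6.00, 8.00, 12.00, 24.00 h (note there is no 1.25 h sample).

## Stochastic model

Random effects are log-normal and applied to **one** structural
parameter at a time (`varying_parameter`):

    P_ij = P_mean · exp(eta_i + kappa_ij),
    eta_i ~ N(0, omega²) per subject,  kappa_ij ~ N(0, gamma²) per
    subject-occasion (occasion = period).

Bioavailability F never varies. Sampled concentrations carry a
multiplicative log-normal residual error `Y = C·exp(eps)`,
eps ~ N(0, sigma²), drawn independently per sample; the pre-dose sample
is exactly zero and stays zero (multiplicative model). Default residual
CV is 10%.

**CV → log-SD convention.** For the simulation random effects the
stated CV% is taken directly as the log-scale SD (omega = CV/100), the
convention of ODE-based mixed-effects simulation engines; the
moment-exact mapping `omega = sqrt(ln(1+CV²))` is available via
`PopulationModel(exact_cv_mapping=True)`. The two differ by <1% at
CV 10% and ~4.5% at CV 45%. The default convention is corroborated by
the baseline observed-Cmax level it produces: the noise-free grid peak
is 570.4 µg/L, and the max-over-noisy-samples bias under sigma = 0.10
lifts the geometric mean to ≈642 µg/L, which matches the documented
simulated value; the package's acceptance script recomputes this.

A truly bioinequivalent test product is emulated by scaling the test
product's *mean* ka by `test_ka_multiplier` (0.3 by convention); F, V
and ke are untouched, so the extent of exposure AUC(0,∞) = F·D/(V·ke)
is identical for both products and only the rate (Cmax, tmax) differs.

Trials are 2×2×2 crossovers: sequence TR receives test in period 1,
reference in period 2; RT the reverse. Randomization is balanced
block-wise with block size 2 (the smallest balanced block; the exact
block size is a free design choice here). Washout is recorded as
metadata only — the model carries no carryover, sequence or period
effects, so a washout parameter would have nothing to act on.

## Non-compartmental analysis

Cmax is the maximum *observed* concentration; tmax the earliest time
achieving it. AUC runs from pre-dose to the last sampling time with the
linear-up/log-down trapezoid: linear when C2 ≥ C1 or either endpoint is
zero, logarithmic `(C1-C2)·dt/ln(C1/C2)` on strictly declining positive
segments. The log-down rule is exact on mono-exponential declines and
is what reproduces the documented baseline AUC0–24 of ≈4950 µg·h/L on
the sparse 8 → 12 → 24 h tail; the pure linear rule (available via
`auc_last(..., method="linear")`) inflates that tail by ≈4%. No
extrapolation to infinity is performed. Bioequivalence decisions use
Cmax only; AUC is computed as a descriptive summary.

## Average bioequivalence and centrality

The ANOVA on ln(Cmax) uses sequence, subject-within-sequence, period
and treatment as fixed effects. Because subject indicators absorb the
sequence contrast, the fitted design matrix is intercept + period +
treatment + subject dummies; treatment/period estimates and the residual
df (n − 2 for complete balanced data) are unchanged by this
reparameterization. For balanced complete data the fit reduces to the
classical paired contrast — half the difference between the two
sequences' mean period differences, with MSE half the pooled variance of
the period differences — and that closed form is used; unbalanced or
subject-depleted data fall back to a full least-squares fit (statsmodels
OLS). Both paths agree to rtol 1e-10 with a brute-force normal-equations
oracle in the tests. Subjects missing a period are excluded with a
warning; fewer than 3 complete subjects is an error.

Decisions: TOST concludes bioequivalence when the 90% CI
`exp(lsm_diff ∓ t(0.95, n−2)·se)·100` lies within [80.00, 125.00]%
(bounds inclusive, compared at full floating precision); centrality when
the point estimate lies within [90.00, 111.11]% (the printed upper bound
is used as-is rather than 1/0.9). The intra-subject CV is
`ISCV% = 100·sqrt(exp(MSE) − 1)`.

## Exact TOST power and sample size

Power of the two one-sided tests in a 2×2×2 crossover is computed
exactly by integrating the joint rejection probability over the chi
distribution of the variance estimate (equivalent to the difference of
Owen's Q functions), with `se = sigma_w·sqrt(2/n)` and df = n − 2. The
integration is truncated at min(R, chi quantile at 1−1e-14), where R is
the largest scaled SD at which the two one-sided rejection regions are
still compatible; without the truncation the quadrature can miss the
integrand's support when CV → 0. A noncentral-t difference
approximation (`method="nct"`) is retained and cross-validated: it
agrees with the exact path at moderate n but is conservative at small
n / high CV where the interval-width constraint binds; the exact path
matches a 200,000-replicate Monte-Carlo simulation of the t-statistics
within Monte-Carlo error in the tests.

Here the CV → sigma_w mapping is the exact `sqrt(ln(1+CV²))` — the
inverse of the ISCV formula — so that sizing from an estimated ISCV
round-trips. Sample-size search returns the smallest even n ≥ 4 meeting
the target power (doubling then bisection; power is monotone in n). No
12-subject pilot floor is applied at this layer; experiment-level
reporting applies the grid minimum instead.

## Bootstrap bioequivalence

Resample size = exact TOST sample size at the trial's estimated ISCV,
assumed true GMR 90%, power 80%, alpha 0.05 (forced even, minimum 4,
deliberately not capped at the original n). Resampling draws
resample_n/2 subjects with replacement from each sequence pool; a drawn
subject contributes both periods and receives a fresh pseudo-subject id
so repeated draws remain distinct ANOVA levels (the only full-rank
choice). 100 resamples are drawn; the 95% CI is the empirical 2.5th and
97.5th percentile of the resample GMRs using linear interpolation
between order statistics (numpy's default; at b = 100 competing
percentile definitions differ negligibly, but the rule is pinned for
reproducibility). The bootstrap SE of the GMR is reported but plays no
part in the decision, which is containment of the percentile CI in
[80.00, 125.00]%.

Internally the resample GMRs are computed from precomputed per-profile
NCA rows rather than by rebuilding concentration records — algebraically
identical, since NCA is profile-wise and every resample is balanced and
complete so its ANOVA reduces to the closed-form contrast; equality with
the full resample-then-analyze path is asserted in the tests.

## f2 on mean concentration profiles

Mean test and reference profiles (arithmetic, or geometric with the
convention that any zero contribution makes the geometric mean zero —
in practice only at t = 0) pool subjects from both sequences. Both
profiles are normalized to the *reference* mean profile's Cmax
(`100·Cbar(t)/CmaxR`), truncated to grid points with 0 ≤ t ≤ tmaxR
(ties at the peak broken to the earliest time), and compared with

    f2 = 50·log10(100·(1 + (1/n)·sum (R_t − T_t)²)^(−1/2)).

The t = 0 point — where both normalized values are exactly 0 — is
included in n by default, following the truncation rule's closed lower
bound; this slightly raises f2 and a switch (`include_t0=False`) is
provided since the convention is a genuine ambiguity. Each mean type
determines its own tmaxR (the two f2 variants are computed
independently). Similarity is declared when f2 ≥ cutoff, with cut-offs
35 / 41 / 50 corresponding to constant profile differences of 20 / 15 /
10 percentage points. No early-point-variability applicability guard is
imposed.

## Performance measurement

Truly bioequivalent trials are the positive class. From (TP, FN, FP,
TN): sensitivity (power), specificity (1 − type I error), precision,
NPV, accuracy, F1, Matthews correlation coefficient, and Cohen's kappa
in its standard two-class form `2(TP·TN − FP·FN) / ((TP+FP)(FP+TN) +
(TP+FN)(FN+TN))`. Zero-denominator statistics are reported as NaN with
an `undefined` flag rather than silently zeroed.

## Experiment orchestration and seeding

The default plan crosses 16 scenarios (baseline plus IIV/IOV levels
30/0, 30/10, 30/20, 30/30, 0/45 applied separately to ka, V and ke),
two truth groups (ka multiplier 1.0 and 0.3), sample sizes 12–30 step
2, and 100 replicate trials — 32,000 trials in total, reproducible in
roughly an hour on one CPU. Every method analyses the same simulated
trials within a cell. Per-trial seeds derive from the master seed as
`SeedSequence(master, spawn_key=(scenario, truth, n, rep))`, so any
subset of cells is bit-reproducible in any execution order; each trial
additionally spawns an analysis substream for the bootstrap's
resampling RNG. The truth groups use independent draws.

Empirical sample-size reporting returns the smallest grid n whose
empirical sensitivity reaches the target, with a `">30"`-style sentinel
when the grid never reaches it.

## What the simulator does and does not emulate

It emulates: balanced randomized 2×2×2 pilot trials, log-normal
IIV/IOV on a single PK parameter, log-normal assay error, a rate-only
(ka) true difference between products, and a fixed rich-then-sparse
sampling schedule. It does **not** emulate sequence/period/carryover
effects, dropout or missing samples, below-quantification-limit
censoring, multi-compartment or nonlinear kinetics, lag times, or
simultaneous variability on several parameters. Passing tests therefore
demonstrate the decision methods' behaviour under idealized trial
execution where the only disturbances are biological variability and
assay noise — not robustness to protocol deviations or model
misspecification.

## Test and acceptance problem sizes

The acceptance-level checks use desk-scale versions of the full grid:
2,000 simulated profiles for the NCA geometric means (Monte-Carlo SE
≈0.15%), 100 trials per operating-characteristic cell (binomial SE ≈5
percentage points, so comparisons use 3-SE bands), and a 3-point sample
size sweep (n = 12, 20, 30 at 60 trials each) for the
sensitivity-monotonicity property. Specificity checks compare against a
3-binomial-SE band around near-perfect specificity rather than a hard
cut, since a 100-trial estimate of a 99% specificity fluctuates by ±1–2
trials.

## Known limitations

* The CV → log-SD convention for the simulator is not uniquely
  determined by the problem statement; both conventions are implemented
  and the default is documented above.
* The bootstrap resample size can greatly exceed the pilot's n at high
  ISCV (it routinely reaches ~170 subjects at 45% IOV); this is the
  method as specified, and is the mechanism behind both its higher
  sensitivity and its type-I inflation.
* Cohen's kappa uses the standard two-class formula; alternative
  typesettings of the chance-agreement denominator that do not reduce
  to it are not supported.
* `empirical_sample_size` interpolates nothing: it reports grid values
  only.
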