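# Methods

## The identifiability metric

For a first-order model of a measured species X whose two free parameters
a and b enter separably,

    dX/dt = a·f(X, Y, t) + b·g(X, Y, t) + (known terms),

the integral form between t = 0 and each sample time tᵢ turns the
identification into a linear system: each parameter's column is the
cumulative integral of its coefficient, evaluated on an *assumed* response
to the test stimulus (a noiseless simulation under a-priori parameter
values — the metric is a design-stage tool applied before any data
exist).  Each column, evaluated at every sample time after the first, is
divided by its own mean; the 2-norm of the difference of the two
normalised curves, ‖Δ‖₂, measures how distinguishably the two parameters
bend the measured curve *at the chosen sample times*.  ‖Δ‖₂ = 0 means the
columns are collinear and the pair is unidentifiable no matter how good
the assay; in between, the coefficient of variation of each identified
parameter under fractional assay error ε follows the noise law

    CV ≈ μ · ε / ‖Δ‖₂,

with μ an empirical, parameter-specific proportionality factor fitted by
through-origin least squares of observed CV on ε/‖Δ‖₂ (the intercept is
pinned at zero because noiseless identification is exact).  μ has no
closed form — it absorbs the relative contribution of the parameter to
the derivative and the noise magnitude at the sampled times — so the
metric's quantitative use is *ratios*: between two designs, the predicted
ratio of parameter variability is the inverse ratio of their ‖Δ‖₂ values.

Normalisation and the norm use only the sample times after the first
(every integral is zero at t = 0, which would otherwise dilute the mean).
A consequence worth knowing: dense schedules accumulate many late,
near-proportional points, which drags both normalised curves toward each
other and biases ‖Δ‖₂ low relative to sparse schedules — so cross-design
μ values are not perfectly transferable, while the scaling of CV with ε
at a fixed design is tight.  `fit_mu` accepts points pooled however the
caller wishes; the scenario runner reports both the per-design fits and
the pooled one.

## The physiological models

Insulin pharmacokinetics (plasma I, interstitial Q, both mU/L):

    dI/dt = −nK·I − nL·I/(1 + αI·I) − (nI/VP)(I − Q) + (1 − xL)·uN(t) + uX(t)/VP
    dQ/dt = (nI/VQ)(I − Q) − nC·Q

Glucose pharmacodynamics (G, mmol/L):

    dG/dt = −pG·(G − Gb) − SI·(G·Q − Gb·Qb) + pX(t)/VG

Endogenous secretion uN is a three-stage step profile (basal; first phase
for 5 min from the glucose bolus; second phase) expressed as a
*concentration* rate (mU/L/min), the form in which it is reconstructed
from C-peptide — it therefore carries no 1/VP factor, and in the
identification it belongs to the known remainder rather than to the 1/VP
coefficient.  Exogenous boluses are impulses: instantaneous concentration
jumps of dose/VP (insulin, 1 U = 1000 mU) and dose/VG (glucose,
1 g = 5.551 mmol at 180.16 g/mol).  The 1/VP coefficient in the (nT, VP)
and five-parameter identifications is consequently the exogenous-input
step plus the exchange flux, which is what makes sample placement around
the insulin bolus decisive for VP.

Simulations start at the basal steady state (Ib solved by bracketing +
Brent on the scalar basal balance; Qb = nI·Ib/(nI + nC·VQ); G = Gb) and
integrate with fixed-step classical RK4 at 0.1 min on segments split at
every input discontinuity, storing both one-sided values at each bolus
time so the jump is represented exactly.  Insulin is solved first (it
does not depend on glucose), then glucose is driven by the stored Q(t).

### Parameters and defaults

Per-participant values (secretion rates, nL, xL, VG, SI) come from the
two built-in virtual participants (one normal glucose tolerant, one
insulin resistant); see `practident.participants`.  SI is on the
10⁻⁴ L/mU/min scale standard for this model family.  The remaining
kinetic parameters are population defaults, config-overridable, logged by
every experiment:

| parameter | default | units | meaning |
|-----------|---------|-------|---------|
| nK | 0.054 | 1/min | renal clearance (GFR scale) |
| nC | 0.03 | 1/min | interstitial clearance to cells |
| nI | 0.3 | L/min | plasma–interstitium exchange |
| VP | 4.0 | L | plasma insulin volume |
| VQ | 8.0 | L | interstitial insulin volume |
| αI | 0.001 | L/mU | hepatic saturation (accepted value) |
| pG | 0.02 | 1/min | glucose-dependent glucose clearance |
| Gb | 5.0 / 6.0 | mmol/L | basal glucose, NGT / IGT |

These sit inside textbook physiological ranges and were fixed once so
that the simulated responses reproduce the qualitative regime the
analyses require (NGT glucose dips below basal under the standard test;
the IR participant's does not, and needs ≈3 U extra insulin to get
0.5 mmol/L below basal) together with the scale of the deterministic
‖Δ‖₂ anchors; they are not re-derived per analysis.  All identifiability
conclusions that depend on them are ratio-based and proved insensitive
across the plausible ranges; absolute ‖Δ‖₂ and μ values inherit perhaps
±25% from this choice.

## The iterative integral identification

Each update simulates the model under the current estimates, assembles
the linear system, and solves it by least squares (minimum-norm via
`numpy.linalg.lstsq` when rank-deficient; cond(A) > 10¹² flags the case
non-identifiable rather than raising).  Three numerical choices matter:

1. **Quadrature consistency.** Coefficient and remainder integrals are
   accumulated *inside* the RK4 integration as auxiliary quadrature
   states advanced through the same stages as the trajectory.  The
   integral identity X(tᵢ) − X(0) = Σθⱼ Cⱼ(tᵢ) + F(tᵢ) then holds to
   machine precision on the grid, so with noise-free data the true
   parameters are an exact fixed point and zero-noise identification is
   exact — trapezoid integrals of the same trajectory would leave an
   O(h²) inconsistency that near-collinear columns amplify by 10³–10⁵.

2. **Data anchoring.** The measured species between samples is
   represented as the current simulation plus the piecewise-linear
   interpolation of the sample residuals; every data-dependent integral
   is the simulation quadrature plus a trapezoid-exact correction that
   vanishes when the simulation passes through the samples.  Assay noise
   thus enters the coefficient matrix (as it does when integrals are
   built from measured data), and the update map becomes strongly
   contracting.  For the five-parameter insulin case the interstitial
   compartment is likewise rebuilt each update from the data-anchored
   plasma profile under the current nI, replaying the stored RK4 stage
   values so the reconstruction is bitwise-exact at the fixed point;
   re-simulating Q from the coupled model feeds clearance errors back
   into the exchange column and diverges.

3. **Driving the update to its fixed point.** Plain successive updates
   contract slowly for poorly separated pairs (spectral radius ≈ 0.9).
   The default solver caps each step at 0.9× the parameter's starting
   scale and, if plain iteration has not converged, hands the same update
   to a quasi-Newton root solve (Powell hybrid); every function
   evaluation is exactly one integral-method update.  Convergence: max
   relative parameter change over one further update < 10⁻⁶ (default),
   max 100 plain iterations.  Under very sparse sampling the update map
   can possess spurious fixed points whose trajectories miss the data; if
   the returned root misfits the samples beyond the assay-noise floor
   (relative RMS > max(4ε, 10⁻⁷)), the solve restarts once from the
   a-priori parameter values and keeps the better-fitting root.
   Estimates may leave the physiological range — with noisy data that is
   the parameter trade-off the method exposes — so the fitting path
   bypasses the strict parameter-validation of the public constructors.

Initial estimates default to 50% of the true values, probing convexity
rather than starting at the answer.  Identified (nT, VP)-type cases are
solved in the linear parameterisation (nT, 1/VP) and mapped back.

## Monte Carlo noise analysis

Per iterate: sample the noiseless profiles at the protocol times, apply
multiplicative truncated-Gaussian noise v → v(1 + εz), z ~ N(0,1)
truncated to |z| ≤ 3 (resampled; the truncation shrinks the effective SD
to 0.98664ε), re-identify, collect estimates.  Per-iterate RNG streams
are spawned from a master `SeedSequence`, so runs are reproducible and
iterates independent.  Analyses use 100 iterates.  Summaries report, per
parameter, the mean of the estimates normalised by the true value and
CV = SD/mean of the estimates (the trade-off indicator); non-converged
iterates are excluded but counted, and a summary with over 50% failures
is flagged unreliable.  Glucose-side analyses simulate insulin once,
noise-free, and perturb glucose only.

## What the synthetic data does and does not emulate

The virtual participants are simulated by exactly the model that is then
identified, so zero-noise identification is exact by construction and the
Monte Carlo isolates assay error as the only corruption.  Real data add
model mismatch the metric cannot see: incomplete early mixing (the t = 10
glucose sample), non-impulsive boluses, secretion profiles that are not
three-stage steps, and within-test parameter drift.  Passing tests
therefore validate the *method* — that ‖Δ‖₂ ranks designs and
participants as a Monte Carlo does — not clinical error magnitudes; the
glucose CVs especially use 1%/3.5% noise for cross-case comparability
rather than the ~2% of a blood-gas analyser.

## Degenerate inputs and edge cases

αI = 0 makes the renal/hepatic columns identical: ‖Δ‖₂ = 0 and the fit
flags ill-conditioning (minimum-norm solution returned).  Protocols
reject unsorted or duplicated sample times and samples outside the test.
Zero secretion yields the zero basal state.  The metric refuses cases
with more than two free parameters — ranking parameter *pairs* is its
defined scope; the five-parameter case is reached only by the fitter.

## Problem sizes

Defaults throughout: 60 min tests on a 0.1 min grid (halving the step
changes sampled values by < 10⁻⁴ relative), 100 Monte Carlo iterates per
analysis, scenario suite ≈ 3 min on one core.
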