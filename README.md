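# practident

Practical identifiability analysis for two-parameter PK/PD ODE models,
with the DISST insulin-kinetics and glucose-pharmacodynamics models built
in.

## The problem

Classical structural identifiability analysis answers a binary question —
are two model parameters mathematically distinct given perfect,
continuous data? — and routinely says *yes* for parameter pairs that then
trade off hopelessly when identified from a handful of noisy clinical
samples.  `practident` implements a graphical, integral-based metric that
treats identifiability as continuous and asks the question that matters
at study-design time: *given this test protocol, these sample times and
this assay, how much will the two parameters interfere?*

For a separable first-order model of a measured species, each parameter's
coefficient is integrated over an assumed response from 0 to every
proposed sample time, each curve is normalised by its mean, and the
2-norm of their difference, ‖Δ‖₂, scores the design.  Parameter
variability under fractional assay error ε follows

    CV ≈ μ · ε / ‖Δ‖₂

with μ an empirical, parameter-specific factor — so the *ratio* of ‖Δ‖₂
between two designs predicts the ratio of Monte Carlo CVs without running
the Monte Carlo.  The package ships everything needed to verify that
claim in silico: the dynamic insulin sensitivity and secretion test
(DISST) models, two virtual participants (normal glucose tolerant and
insulin resistant), an iterative integral parameter-identification
method with exact zero-noise recovery, and truncated-Gaussian assay-noise
Monte Carlo analyses.

Typical uses: ranking sampling schedules before a clinical study,
explaining why glucose-effectiveness (pG) is practically unidentifiable
in insulin-resistant participants, and sizing protocol changes (an extra
insulin bolus) by their predicted variability reduction.

## Worked example

Rank three sampling schedules for identifying the combined insulin
clearance nT and plasma volume VP from plasma-insulin samples
(`examples/02_identifiability_curves.py`):

```python
from practident import NGT, build_case, case_delta_norm, disst_protocol

for label, times in {
    "P1 (5-minutely, 13 samples)": tuple(range(0, 61, 5)),
    "P2 (0, 15, 20, 60)": (0, 15, 20, 60),
    "P3 (0, 5, 45, 60)": (0, 5, 45, 60),
}.items():
    case = build_case("nT_VP", NGT, disst_protocol(sample_times=times))
    print(f"{label:32s} ||Delta||_2 = {case_delta_norm(case).delta_norm:.3f}")
```

```
P1 (5-minutely, 13 samples)      ||Delta||_2 = 0.718
P2 (0, 15, 20, 60)               ||Delta||_2 = 0.797
P3 (0, 5, 45, 60)                ||Delta||_2 = 0.041
```

Four well-placed samples (P2, bracketing the insulin bolus at t = 17.5)
carry as much identifying information as thirteen 5-minutely ones — while
four badly placed samples (P3) are ~18× worse and the pair is effectively
unidentifiable under realistic assay noise.  The prediction is borne out
by Monte Carlo (`examples/04_monte_carlo.py`, renal vs hepatic clearance
under two hepatic-saturation values):

```
||Delta||_2: alphaI=0.001 -> 0.031,  alphaI=0.05 -> 0.446
predicted variability ratio (0.001 vs 0.05): 14.4x
alphaI=0.001: nK: mean 0.848, CV 0.977  nL: mean 1.039, CV 0.211
alphaI=0.05:  nK: mean 0.991, CV 0.039  nL: mean 1.007, CV 0.034
observed CV ratio at 1% noise: 15.6x
```

At the accepted saturation the clearances trade off wildly (CVs up to
~1.0 at 1% assay error despite proven structural identifiability); the
metric predicted the ~15× contrast before any Monte Carlo ran.

The other examples simulate a full test (`01`), identify SI and VG from
noisy glucose samples (`03`), and design an improved protocol for an
insulin-resistant participant (`05`).  The full scenario battery —
coefficient-curve CSVs, Monte Carlo summary tables, predicted-vs-observed
ratio JSON, a run manifest — is available from Python
(`practident.run_all`) or the thin CLI:

```bash
practident all --out-dir out --seed 0          # every scenario, ~3 min
practident delta --case SI_pG --participant IGT --spacing 10
practident mc --case SI_VG --eps 0.01 --eps 0.035 --n-iter 100 --out-dir out
```

## Documentation

`docs/methods.md` describes the metric, the model equations and units,
the population parameter defaults, the numerical design of the iterative
integral solver (RK4-consistent quadratures, data anchoring, fixed-point
acceleration), and what the synthetic validation does and does not show
about real clinical data.
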