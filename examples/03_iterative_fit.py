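"""Identify insulin sensitivity and glucose volume from noisy samples.

Glucose samples (5-minutely) from a simulated test are perturbed with 1%
truncated-Gaussian assay noise and the iterative integral method is run
from initial guesses at 50% of the true values.  The printed estimates
sit within a few percent of the truth: with this protocol the (SI, VG)
pair is practically identifiable.  On the noise-free samples the method
recovers the simulation values exactly.
"""

from practident import NGT, add_noise, build_case, disst_protocol, iterative_fit

case = build_case("SI_VG", NGT, disst_protocol(5.0))
clean = case.noiseless_samples()

fit0 = iterative_fit(case, clean)
print("noise-free recovery:")
for s in case.free_params:
    print(f"  {s}: {fit0.estimates[s]:.6g}  (true {case.true_values[s]:.6g})")

noisy = add_noise(clean, eps=0.01, rng=12345)
fit = iterative_fit(case, noisy)
print(f"\n1% assay noise ({fit.iterations} integral-method updates, "
      f"converged={fit.converged}):")
for s in case.free_params:
    rel = 100 * (fit.estimates[s] / case.true_values[s] - 1)
    print(f"  {s}: {fit.estimates[s]:.6g}  ({rel:+.1f}% vs truth)")
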