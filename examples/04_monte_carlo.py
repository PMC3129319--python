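"""Predict, then observe, the effect of hepatic saturation on clearance
identifiability.

Renal (nK) and hepatic (nL) insulin clearance act almost identically on
plasma insulin when the hepatic saturation alphaI is small, so the pair
trades off badly under assay noise.  The metric predicts the improvement
from a larger saturation as the inverse ratio of the ||Delta||_2 values;
a 100-iterate Monte Carlo at 1% noise then shows the realised CVs.  The
observed CV ratio is of the same magnitude as the prediction — the
design-stage metric anticipates the Monte Carlo outcome without running
it.  (n = 25 here to keep the example fast; analyses use n = 100.)
"""

import numpy as np

from practident import (
    MCConfig,
    NGT,
    build_case,
    case_delta_norm,
    cv_ratio,
    disst_protocol,
    run_mc,
)

protocol = disst_protocol(5.0)
cases = {
    alpha: build_case("nK_nL", NGT.with_overrides(alphaI=alpha), protocol)
    for alpha in (0.001, 0.05)
}

d = {a: case_delta_norm(c).delta_norm for a, c in cases.items()}
print(f"||Delta||_2: alphaI=0.001 -> {d[0.001]:.3f},  alphaI=0.05 -> {d[0.05]:.3f}")
print(f"predicted variability ratio (0.001 vs 0.05): {d[0.05]/d[0.001]:.1f}x")

summaries = {
    a: run_mc(MCConfig(case=c, eps=0.01, n_iter=25, seed=0)) for a, c in cases.items()
}
for a, s in summaries.items():
    line = "  ".join(f"{p}: mean {s.mean_normalized[p]:.3f}, CV {s.cv[p]:.3f}"
                     for p in s.cv)
    print(f"alphaI={a}: {line}")
ratios, mean = cv_ratio(summaries[0.001], summaries[0.05])
print(f"observed CV ratio at 1% noise: {mean:.1f}x")
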