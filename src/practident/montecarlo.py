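"""Monte Carlo assay-noise analysis of integral identification.

Each iterate samples the noiseless simulated response at the protocol
times, perturbs the measured species with truncated-Gaussian assay noise,
and re-identifies the free parameters with the iterative integral method.
The summary reports, per parameter, the mean of the identified values
normalised by the true value and the coefficient of variation (SD/mean of
the estimates) — the paper-standard indicator of parameter trade-off.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .identify import ModelCase, iterative_fit
from .protocols import add_noise

__all__ = ["MCConfig", "MCSummary", "run_mc", "cv_ratio"]


@dataclass
class MCConfig:
    """Configuration of one Monte Carlo analysis.

    ``noisy_species`` lists which measured species receive assay error; for
    the glucose analyses insulin is simulated once, noise-free, so only
    glucose is noised there.
    """

    case: ModelCase
    eps: float
    n_iter: int = 100
    seed: int = 0
    noisy_species: tuple[str, ...] | None = None
    tol: float = 1e-6
    max_iter: int = 100

    def __post_init__(self) -> None:
        if self.n_iter < 2:
            raise ValueError("n_iter must be >= 2")
        if self.eps < 0:
            raise ValueError("eps must be >= 0")
        if self.noisy_species is None:
            self.noisy_species = (self.case.measured_species,)


@dataclass
class MCSummary:
    """Per-parameter normalised mean and CV over converged iterates."""

    case_name: str
    eps: float
    n_iter: int
    n_converged: int
    mean_normalized: dict[str, float]
    cv: dict[str, float]
    unreliable: bool
    estimates: dict[str, np.ndarray] = field(repr=False, default_factory=dict)

    def to_rows(self, protocol_label: str = "") -> list[dict]:
        """CSV-ready rows (case, protocol, eps, parameter, mean_norm, cv)."""
        return [
            {
                "case": self.case_name,
                "protocol": protocol_label,
                "eps": self.eps,
                "parameter": p,
                "mean_norm": self.mean_normalized[p],
                "cv": self.cv[p],
                "n_converged": self.n_converged,
            }
            for p in self.mean_normalized
        ]


def run_mc(config: MCConfig) -> MCSummary:
    """Run one Monte Carlo analysis and summarise it.

    Per-iterate RNG streams are spawned from the master seed so results are
    reproducible and iterates independent.  Non-converged iterates are
    excluded from the summary but counted; a summary with more than 50%
    failures is flagged unreliable.
    """
    case = config.case
    clean = case.noiseless_samples()
    noise_this = case.measured_species in (config.noisy_species or ())
    streams = np.random.SeedSequence(config.seed).spawn(config.n_iter)

    collected: dict[str, list[float]] = {s: [] for s in case.free_params}
    n_converged = 0
    for k in range(config.n_iter):
        if noise_this and config.eps > 0:
            rng = np.random.default_rng(streams[k])
            noisy = add_noise(clean, config.eps, rng)
        else:
            noisy = clean
        fit = iterative_fit(case, noisy, tol=config.tol, max_iter=config.max_iter)
        if fit.converged:
            n_converged += 1
            for s in case.free_params:
                collected[s].append(fit.estimates[s])

    mean_norm: dict[str, float] = {}
    cv: dict[str, float] = {}
    estimates: dict[str, np.ndarray] = {}
    for s in case.free_params:
        arr = np.asarray(collected[s])
        estimates[s] = arr
        if len(arr) == 0:
            mean_norm[s] = float("nan")
            cv[s] = float("nan")
            continue
        m = arr.mean()
        mean_norm[s] = float(m / case.true_values[s])
        cv[s] = float(arr.std(ddof=1) / m) if len(arr) > 1 and m != 0 else 0.0
    return MCSummary(
        case_name=case.name,
        eps=config.eps,
        n_iter=config.n_iter,
        n_converged=n_converged,
        mean_normalized=mean_norm,
        cv=cv,
        unreliable=n_converged < config.n_iter / 2,
        estimates=estimates,
    )


def cv_ratio(summary_a: MCSummary, summary_b: MCSummary) -> tuple[dict[str, float], float]:
    """Elementwise CV(a)/CV(b) per shared parameter, and their mean.

    A zero denominator yields ``inf`` for that parameter and is excluded
    from the mean.
    """
    params = [p for p in summary_a.cv if p in summary_b.cv]
    if not params:
        raise ValueError("summaries share no parameters")
    ratios: dict[str, float] = {}
    finite: list[float] = []
    for p in params:
        denom = summary_b.cv[p]
        if denom == 0.0:
            ratios[p] = float("inf")
        else:
            r = summary_a.cv[p] / denom
            ratios[p] = r
            finite.append(r)
    mean = float(np.mean(finite)) if finite else float("inf")
    return ratios, mean
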