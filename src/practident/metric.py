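"""Integral-coefficient identifiability metric for two-parameter models.

For a separable two-parameter first-order model, the integral of each
parameter's coefficient is evaluated on an *assumed* (noiseless, a-priori)
response at each proposed sample time after the first, each curve is
normalised by its own mean, and the 2-norm of the difference,
``||Delta||_2``, quantifies how distinguishable the two parameters are
under that protocol.  The coefficient of variation a Monte Carlo analysis
will find for each parameter scales as::

    CV = mu * eps / ||Delta||_2                                (noise law)

with ``eps`` the fractional assay error and ``mu`` an empirical,
parameter-specific proportionality factor obtained by through-origin
regression of observed CV on ``eps / ||Delta||_2``.  Ratios of
``||Delta||_2`` between two designs therefore predict the ratio of
parameter variability without running the Monte Carlo — the design-stage
use of the method.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .identify import ModelCase
from .protocols import SimProfiles

__all__ = [
    "CoefficientCurves",
    "DeltaResult",
    "MuFit",
    "coefficient_curves",
    "delta_norm",
    "case_delta_norm",
    "predicted_cv_ratio",
    "fit_mu",
]


@dataclass
class CoefficientCurves:
    """Raw and mean-normalised integral-coefficient curves of a two-free-
    parameter case, evaluated at each sample time after the first."""

    sample_times: np.ndarray
    param_names: tuple[str, str]
    c1: np.ndarray
    c2: np.ndarray
    n1: np.ndarray
    n2: np.ndarray

    def to_frame(self):
        """Plot-ready tidy table (time, raw and normalised curves)."""
        import pandas as pd

        return pd.DataFrame(
            {
                "time_min": self.sample_times,
                "raw_c1": self.c1,
                "raw_c2": self.c2,
                "norm_c1": self.n1,
                "norm_c2": self.n2,
            }
        )


@dataclass
class DeltaResult:
    """Pointwise difference of the normalised curves and its 2-norm."""

    delta: np.ndarray
    delta_norm: float


@dataclass
class MuFit:
    """Through-origin regression CV = mu * (eps/||Delta||_2) per parameter."""

    mu: dict[str, float]
    points: dict[str, list[tuple[float, float]]]
    max_rel_residual: dict[str, float]


def coefficient_curves(
    case: ModelCase,
    assumed_profiles: SimProfiles | None = None,
    sample_times: Sequence[float] | None = None,
) -> CoefficientCurves:
    """Normalised integral-coefficient curves for a two-parameter case.

    The integrals are evaluated on the dense noiseless assumed response
    (never on noisy samples: the metric is a design-stage tool applied
    before any data exist), at each sample time after the first, then each
    curve is divided by its own mean.
    """
    if len(case.free_params) != 2:
        raise ValueError(
            "the identifiability metric applies to two-free-parameter cases only; "
            f"case {case.name!r} has {len(case.free_params)}"
        )
    if assumed_profiles is None:
        assumed_profiles = case.assumed_profiles()
    if sample_times is None:
        sample_times = case.protocol.sample_times
    times = np.asarray(sample_times, dtype=float)
    A = case.columns_fn(assumed_profiles, times)
    c1, c2 = A[:, 0], A[:, 1]
    m1, m2 = c1.mean(), c2.mean()
    if m1 == 0.0 or m2 == 0.0:
        raise ValueError("coefficient curve has zero mean; cannot normalise")
    return CoefficientCurves(
        sample_times=times[1:],
        param_names=(case.free_params[0], case.free_params[1]),
        c1=c1,
        c2=c2,
        n1=c1 / m1,
        n2=c2 / m2,
    )


def delta_norm(curves: CoefficientCurves) -> DeltaResult:
    """2-norm of the difference between the normalised coefficient curves."""
    delta = curves.n1 - curves.n2
    return DeltaResult(delta=delta, delta_norm=float(np.linalg.norm(delta)))


def case_delta_norm(case: ModelCase, sample_times: Sequence[float] | None = None) -> DeltaResult:
    """Convenience: ``delta_norm(coefficient_curves(case))``."""
    return delta_norm(coefficient_curves(case, sample_times=sample_times))


def predicted_cv_ratio(delta_a: DeltaResult, delta_b: DeltaResult) -> float:
    """Predicted CV(a)/CV(b) at equal assay error.

    By the noise law CV is inversely proportional to ||Delta||_2, so the
    ratio of variabilities is the inverse ratio of the norms.  A zero
    denominator (design *a* non-identifiable) returns ``inf``.
    """
    if delta_a.delta_norm == 0.0:
        return math.inf
    return delta_b.delta_norm / delta_a.delta_norm


def fit_mu(points: dict[str, Sequence[tuple[float, float, float]]]) -> MuFit:
    """Fit mu per parameter from (eps, ||Delta||_2, observed CV) triples.

    Noiseless identifiability pins the intercept at zero, so the estimator
    is the through-origin least-squares slope ``mu = sum(x*y)/sum(x*x)``
    with ``x = eps/||Delta||_2``.
    """
    mu: dict[str, float] = {}
    pts: dict[str, list[tuple[float, float]]] = {}
    resid: dict[str, float] = {}
    for name, triples in points.items():
        if len(triples) < 1:
            raise ValueError(f"no points for parameter {name!r}")
        x = np.array([eps / dn for eps, dn, _ in triples])
        y = np.array([cv for *_, cv in triples])
        sxx = float(np.dot(x, x))
        if sxx == 0.0:
            raise ValueError(f"all eps/||Delta|| values are zero for {name!r}")
        slope = float(np.dot(x, y) / sxx)
        fitted = slope * x
        with np.errstate(divide="ignore", invalid="ignore"):
            rr = np.abs(y - fitted) / np.abs(fitted)
        mu[name] = slope
        pts[name] = list(zip(x.tolist(), y.tolist()))
        resid[name] = float(np.nanmax(rr)) if len(rr) else 0.0
    return MuFit(mu=mu, points=pts, max_rel_residual=resid)
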