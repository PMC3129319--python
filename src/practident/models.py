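"""DISST insulin-kinetics and glucose-pharmacodynamics models.

The dynamic insulin sensitivity and secretion test (DISST) is a short
(~60 min) clinical test in which a glucose bolus and an insulin bolus are
given and plasma glucose and insulin are sampled frequently.  Two coupled
compartment models describe the response:

* insulin pharmacokinetics — plasma insulin ``I`` (mU/L) and interstitial
  insulin ``Q`` (mU/L)::

      dI/dt = -nK*I - nL*I/(1 + alphaI*I) - (nI/VP)*(I - Q)
              + (1 - xL)*uN(t) + uX(t)/VP
      dQ/dt = (nI/VQ)*(I - Q) - nC*Q

  with renal clearance ``nK`` (1/min), saturable hepatic clearance ``nL``
  (1/min, saturation constant ``alphaI`` in L/mU), plasma-interstitium
  exchange ``nI`` (L/min), clearance to cells ``nC`` (1/min), first-pass
  hepatic extraction ``xL`` of endogenous secretion ``uN`` — a
  concentration rate in mU/L/min, typically reconstructed from C-peptide
  in those units, so it carries no 1/VP factor — and exogenous input
  ``uX`` (mU/min).

* glucose pharmacodynamics — plasma glucose ``G`` (mmol/L)::

      dG/dt = -pG*(G - Gb) - SI*(G*Q - Gb*Qb) + pX(t)/VG

  with glucose-dependent clearance ``pG`` (1/min), insulin sensitivity
  ``SI`` (L/mU/min) acting through interstitial insulin, and glucose input
  ``pX`` (mmol/min) distributed in ``VG`` (L).

Boluses are treated as impulses (instantaneous concentration jumps); see
:mod:`practident.protocols`.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable

from scipy.optimize import brentq

__all__ = [
    "InsulinKineticParams",
    "GlucosePDParams",
    "SecretionProfile",
    "StateVector",
    "insulin_rhs",
    "glucose_rhs",
    "combined_clearance",
    "basal_steady_state",
]

InputFn = Callable[[float], float]


@dataclass(frozen=True)
class InsulinKineticParams:
    """Insulin pharmacokinetic parameters.

    Attributes
    ----------
    nK : float
        Renal clearance of plasma insulin, 1/min.
    nL : float
        Hepatic clearance of plasma insulin, 1/min.
    nC : float
        Insulin clearance to cells (from interstitium), 1/min.
    nI : float
        Plasma <-> interstitium insulin transfer, L/min.
    alphaI : float
        Saturation of hepatic clearance, L/mU.
    xL : float
        First-pass hepatic extraction of endogenous secretion, in [0, 1].
    VP : float
        Plasma insulin distribution volume, L.
    VQ : float
        Interstitial insulin distribution volume, L.
    """

    nK: float
    nL: float
    nC: float
    nI: float
    alphaI: float
    xL: float
    VP: float
    VQ: float

    def __post_init__(self) -> None:
        for name in ("nK", "nL", "nC", "nI", "alphaI"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")
        if self.VP <= 0 or self.VQ <= 0:
            raise ValueError("distribution volumes VP and VQ must be > 0")
        if not 0.0 <= self.xL <= 1.0:
            raise ValueError(f"xL must lie in [0, 1], got {self.xL}")

    def with_(self, **kwargs: float) -> "InsulinKineticParams":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)


@dataclass(frozen=True)
class GlucosePDParams:
    """Glucose pharmacodynamic parameters.

    Attributes
    ----------
    pG : float
        Glucose-dependent glucose clearance, 1/min.
    SI : float
        Insulin sensitivity, L/mU/min.
    VG : float
        Glucose distribution volume, L.
    Gb : float
        Basal glucose concentration, mmol/L.
    Qb : float
        Basal interstitial insulin concentration, mU/L.
    """

    pG: float
    SI: float
    VG: float
    Gb: float
    Qb: float

    def __post_init__(self) -> None:
        if self.pG < 0:
            raise ValueError(f"pG must be >= 0, got {self.pG}")
        if self.VG <= 0:
            raise ValueError(f"VG must be > 0, got {self.VG}")
        if self.Gb <= 0:
            raise ValueError(f"Gb must be > 0, got {self.Gb}")
        if self.Qb < 0:
            raise ValueError(f"Qb must be >= 0, got {self.Qb}")

    def with_(self, **kwargs: float) -> "GlucosePDParams":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)


@dataclass(frozen=True)
class SecretionProfile:
    """Three-stage step profile of endogenous insulin secretion uN(t).

    Rates are concentration rates in mU/L/min (mass rates divided by the
    plasma distribution volume): basal rate ``Ub`` before the first phase,
    first-phase rate ``U1`` for ``phase1_duration`` minutes starting at
    ``t_phase1_start`` (the glucose bolus time), second-phase rate ``U2``
    for the remainder of the test.
    """

    Ub: float
    U1: float
    U2: float
    t_phase1_start: float = 7.5
    phase1_duration: float = 5.0

    def __post_init__(self) -> None:
        if min(self.Ub, self.U1, self.U2) < 0:
            raise ValueError("secretion rates must be >= 0")
        if self.phase1_duration <= 0:
            raise ValueError("phase1_duration must be > 0")

    def rate(self, t: float) -> float:
        """Secretion rate uN(t) in mU/L/min (right-continuous at the steps)."""
        t0 = self.t_phase1_start
        if t < t0:
            return self.Ub
        if t < t0 + self.phase1_duration:
            return self.U1
        return self.U2

    def cumulative(self, t: float) -> float:
        """Integral of uN from 0 to ``t`` in mU/L (exact for the step profile)."""
        t0 = self.t_phase1_start
        t1 = t0 + self.phase1_duration
        if t <= t0:
            return self.Ub * t
        if t <= t1:
            return self.Ub * t0 + self.U1 * (t - t0)
        return self.Ub * t0 + self.U1 * self.phase1_duration + self.U2 * (t - t1)


@dataclass(frozen=True)
class StateVector:
    """Concentration state (I, Q, G) in (mU/L, mU/L, mmol/L)."""

    I: float
    Q: float
    G: float


def insulin_rhs(
    state: StateVector,
    t: float,
    kin: InsulinKineticParams,
    secretion: SecretionProfile,
    infusion: InputFn | None = None,
) -> tuple[float, float]:
    """Time derivatives (dI/dt, dQ/dt) of the insulin kinetic model.

    ``infusion`` is an optional exogenous insulin input rate uX(t) in mU/min
    (continuous infusions only; impulsive boluses are handled as state jumps
    by the simulator).
    """
    I, Q = state.I, state.Q
    uN = secretion.rate(t)
    uX = infusion(t) if infusion is not None else 0.0
    dI = (
        -kin.nK * I
        - kin.nL * I / (1.0 + kin.alphaI * I)
        - (kin.nI / kin.VP) * (I - Q)
        + (1.0 - kin.xL) * uN
        + uX / kin.VP
    )
    dQ = (kin.nI / kin.VQ) * (I - Q) - kin.nC * Q
    return dI, dQ


def glucose_rhs(
    state: StateVector,
    t: float,
    pd: GlucosePDParams,
    glucose_input: InputFn | None = None,
) -> float:
    """Time derivative dG/dt of the glucose pharmacodynamic model.

    The ``pG`` term changes sign exactly when G crosses its basal value, so
    its integral coefficient can become convex over a test in which glucose
    dips below basal — the feature that separates ``pG`` from ``SI``.
    """
    G, Q = state.G, state.Q
    pX = glucose_input(t) if glucose_input is not None else 0.0
    return -pd.pG * (G - pd.Gb) - pd.SI * (G * Q - pd.Gb * pd.Qb) + pX / pd.VG


def combined_clearance(kin: InsulinKineticParams) -> InsulinKineticParams:
    """Collapse renal and hepatic clearance into a single linear term.

    Returns a parameter set with ``nL`` replaced by ``nT = nK + nL`` (stored
    in ``nL``), ``nK = 0`` and ``alphaI = 0``.  At physiological insulin
    concentrations the hepatic saturation is negligible, so the two
    clearances act identically on ``I`` and only their sum is resolvable.
    """
    return kin.with_(nL=kin.nK + kin.nL, nK=0.0, alphaI=0.0)


def basal_steady_state(
    kin: InsulinKineticParams,
    secretion: SecretionProfile,
    pd: GlucosePDParams,
) -> StateVector:
    """Basal equilibrium (Ib, Qb, Gb) with uX = 0 and uN = Ub.

    Solves ``insulin_rhs = 0``; the glucose equation is at equilibrium by
    construction when ``pd.Qb`` equals the returned Qb and G = Gb.

    Raises
    ------
    RuntimeError
        If the scalar root solve does not converge.
    """
    Ub = secretion.Ub
    if Ub == 0.0:
        return StateVector(0.0, 0.0, pd.Gb)

    # At steady state of the Q equation: Qb = nI*Ib / (nI + nC*VQ).
    q_frac = kin.nI / (kin.nI + kin.nC * kin.VQ) if kin.nI > 0 else 0.0

    def residual(Ib: float) -> float:
        Qb = q_frac * Ib
        dI, _ = insulin_rhs(StateVector(Ib, Qb, pd.Gb), 0.0, kin, secretion)
        return dI

    # residual(0) = (1-xL)*Ub/VP > 0 and residual is eventually negative
    # (clearance grows at least linearly via nK or the nI exchange).
    if residual(0.0) < 0.0:
        raise RuntimeError("no basal steady state for these parameters")
    hi = 1.0
    while residual(hi) > 0.0:
        hi *= 2.0
        if hi > 1e12:
            raise RuntimeError("basal steady-state solve failed to bracket a root")
    try:
        Ib = brentq(residual, 0.0, hi, xtol=1e-14, rtol=1e-15)
    except ValueError as exc:  # pragma: no cover - defensive
        raise RuntimeError(f"basal steady-state solve failed: {exc}") from exc
    Qb = q_frac * Ib
    if abs(residual(Ib)) > 1e-10:
        raise RuntimeError("basal steady-state residual did not converge below 1e-10")
    return StateVector(Ib, Qb, pd.Gb)
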