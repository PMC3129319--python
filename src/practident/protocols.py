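"""Test protocols, trajectory simulation, sampling and assay noise.

A :class:`TestProtocol` is a test duration, a list of impulsive boluses and
a sampling schedule.  :func:`simulate` produces dense (0.1 min) insulin and
glucose trajectories starting from the basal steady state, with boluses
applied as instantaneous concentration jumps of ``dose / V`` at the bolus
time; :func:`sample_profile` reads the profile at the scheduled times and
:func:`add_noise` applies multiplicative truncated-Gaussian assay error.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

from .models import (
    GlucosePDParams,
    InsulinKineticParams,
    SecretionProfile,
    StateVector,
    basal_steady_state,
)

__all__ = [
    "BolusEvent",
    "TestProtocol",
    "SimProfiles",
    "SampleSet",
    "MU_PER_UNIT",
    "MMOL_PER_GRAM",
    "disst_protocol",
    "simulate",
    "sample_profile",
    "add_noise",
]

#: mU of insulin per international unit.
MU_PER_UNIT = 1000.0
#: mmol of glucose per gram (molar mass 180.16 g/mol).
MMOL_PER_GRAM = 1000.0 / 180.16


@dataclass(frozen=True)
class BolusEvent:
    """An impulsive bolus: ``species`` is ``"insulin"`` (dose in U) or
    ``"glucose"`` (dose in g); ``time`` in minutes."""

    species: str
    time: float
    dose: float

    def __post_init__(self) -> None:
        if self.species not in ("insulin", "glucose"):
            raise ValueError(f"unknown bolus species {self.species!r}")
        if self.dose <= 0:
            raise ValueError("bolus dose must be > 0")

    def dose_model_units(self) -> float:
        """Dose in model units: mU for insulin, mmol for glucose."""
        if self.species == "insulin":
            return self.dose * MU_PER_UNIT
        return self.dose * MMOL_PER_GRAM


@dataclass(frozen=True)
class TestProtocol:
    """Bolus schedule plus sampling schedule for one test."""

    duration: float
    boluses: tuple[BolusEvent, ...]
    sample_times: tuple[float, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "boluses", tuple(self.boluses))
        object.__setattr__(self, "sample_times", tuple(self.sample_times))
        st = self.sample_times
        if not st or st[0] != 0.0:
            raise ValueError("sample_times must start at t = 0")
        if any(b <= a for a, b in zip(st, st[1:])):
            raise ValueError("sample_times must be strictly increasing")
        if st[-1] > self.duration:
            raise ValueError("sample_times must not exceed the test duration")
        for b in self.boluses:
            if not 0.0 <= b.time <= self.duration:
                raise ValueError(f"bolus at t={b.time} outside [0, {self.duration}]")

    def with_samples(self, sample_times: Iterable[float]) -> "TestProtocol":
        """Same boluses/duration with a different sampling schedule."""
        return replace(self, sample_times=tuple(sample_times))

    def with_extra_bolus(self, bolus: BolusEvent) -> "TestProtocol":
        """Add one bolus, keeping schedule and duration unchanged."""
        boluses = tuple(sorted(self.boluses + (bolus,), key=lambda b: b.time))
        return replace(self, boluses=boluses)

    def bolus_cumulative(self, species: str, times: np.ndarray) -> np.ndarray:
        """Cumulative bolus input of ``species`` (mU or mmol) up to each time.

        The input is a sum of steps ``dose * H(t - t_bolus)``; at exactly the
        bolus time the dose is counted as delivered.
        """
        out = np.zeros_like(np.asarray(times, dtype=float))
        for b in self.boluses:
            if b.species == species:
                out = out + b.dose_model_units() * (np.asarray(times) >= b.time)
        return out


def disst_protocol(
    sample_spacing: float = 5.0,
    duration: float = 60.0,
    sample_times: Sequence[float] | None = None,
) -> TestProtocol:
    """The standard DISST-like protocol: 10 g glucose at t = 7.5 min and
    1 U insulin at t = 17.5 min over a 60 min test.

    By default samples are taken every ``sample_spacing`` minutes from 0;
    pass ``sample_times`` to use an explicit schedule instead.
    """
    if sample_times is None:
        n = int(round(duration / sample_spacing))
        sample_times = tuple(i * sample_spacing for i in range(n + 1))
    return TestProtocol(
        duration=duration,
        boluses=(
            BolusEvent("glucose", 7.5, 10.0),
            BolusEvent("insulin", 17.5, 1.0),
        ),
        sample_times=tuple(sample_times),
    )


@dataclass
class SimProfiles:
    """Dense simulated trajectories on a shared grid.

    The grid duplicates each bolus time so that the instantaneous jump is
    represented exactly (pre-bolus value, then post-bolus value at the same
    abscissa); trapezoidal integrals over the grid therefore treat the jump
    exactly, contributing zero width at the discontinuity.
    """

    grid: np.ndarray
    I: np.ndarray
    Q: np.ndarray
    G: np.ndarray
    protocol: TestProtocol
    basal: StateVector
    quad: dict[str, np.ndarray] = field(default_factory=dict)
    #: RK4 stage values of I per grid interval (zero rows at the zero-width
    #: bolus intervals); lets Q be rebuilt stage-consistently
    stage_I: np.ndarray | None = None
    #: parameter values the profile was simulated under, when produced
    #: inside an identification loop
    params: dict[str, float] | None = None

    def cum(self, name: str, times: np.ndarray) -> np.ndarray:
        """Cumulative quadrature ``name`` at ``times`` (RK4-consistent)."""
        return np.interp(np.asarray(times, dtype=float), self.grid, self.quad[name])

    def interp(self, species: str, times: np.ndarray) -> np.ndarray:
        """Profile values at ``times`` by linear interpolation on the grid."""
        times = np.asarray(times, dtype=float)
        if times.min() < self.grid[0] or times.max() > self.grid[-1]:
            raise ValueError("requested times fall outside the simulated grid")
        return np.interp(times, self.grid, getattr(self, _SPECIES_ATTR[species]))

    def to_frame(self):
        """Tidy DataFrame (time_min, species, value) of the dense profiles."""
        import pandas as pd

        frames = []
        for species, attr in _SPECIES_ATTR.items():
            frames.append(
                pd.DataFrame(
                    {
                        "time_min": self.grid,
                        "species": species,
                        "value": getattr(self, attr),
                        "noise_cv": 0.0,
                        "replicate": 0,
                    }
                )
            )
        return pd.concat(frames, ignore_index=True)


_SPECIES_ATTR = {"insulin": "I", "interstitial": "Q", "glucose": "G"}


@dataclass
class SampleSet:
    """Discrete samples of one species, with the fractional assay CV used."""

    times: np.ndarray
    values: np.ndarray
    species: str
    noise_cv: float = 0.0

    def to_frame(self, replicate: int = 0):
        import pandas as pd

        return pd.DataFrame(
            {
                "time_min": self.times,
                "species": self.species,
                "value": self.values,
                "noise_cv": self.noise_cv,
                "replicate": replicate,
            }
        )


def _segment_boundaries(protocol: TestProtocol, secretion: SecretionProfile) -> list[float]:
    pts = {0.0, protocol.duration}
    pts.add(secretion.t_phase1_start)
    pts.add(secretion.t_phase1_start + secretion.phase1_duration)
    for b in protocol.boluses:
        pts.add(b.time)
    return sorted(p for p in pts if 0.0 <= p <= protocol.duration)


#: cumulative quadratures carried through the insulin integration
INSULIN_QUADS = ("int_I", "int_I_sat", "int_I_minus_Q")
#: cumulative quadratures carried through the glucose integration
GLUCOSE_QUADS = ("int_GQ_excess", "int_G_excess")


def _rk4_insulin(
    I0: float,
    Q0: float,
    q0: tuple[float, float, float],
    t0: float,
    t1: float,
    n_steps: int,
    kin: InsulinKineticParams,
    uN: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Fixed-step RK4 for the (I, Q) subsystem with constant secretion uN.

    Alongside the states, the cumulative integrals int I dt,
    int I/(1+alphaI*I) dt and int (I-Q) dt are advanced as quadrature
    states through the *same* RK4 stages, so that the integral form of the
    governing equation holds to machine precision on the returned grid —
    the property the iterative integral identification relies on for exact
    noiseless recovery.  The per-step plasma-insulin stage values are also
    returned so an interstitial trajectory can later be rebuilt with
    bitwise-identical arithmetic.
    """
    h = (t1 - t0) / n_steps
    nK, nL, aI = kin.nK, kin.nL, kin.alphaI
    kIV, kQV = kin.nI / kin.VP, kin.nI / kin.VQ
    nC = kin.nC
    src = (1.0 - kin.xL) * uN

    def f(I: float, Q: float) -> tuple[float, float, float, float, float]:
        dI = -nK * I - nL * I / (1.0 + aI * I) - kIV * (I - Q) + src
        dQ = kQV * (I - Q) - nC * Q
        return dI, dQ, I, I / (1.0 + aI * I), I - Q

    ts = np.linspace(t0, t1, n_steps + 1)
    out = np.empty((n_steps + 1, 5))
    stages = np.empty((n_steps, 4))
    state = [I0, Q0, q0[0], q0[1], q0[2]]
    out[0] = state
    for i in range(n_steps):
        I, Q = state[0], state[1]
        k1 = f(I, Q)
        I2, Q2 = I + 0.5 * h * k1[0], Q + 0.5 * h * k1[1]
        k2 = f(I2, Q2)
        I3, Q3 = I + 0.5 * h * k2[0], Q + 0.5 * h * k2[1]
        k3 = f(I3, Q3)
        I4, Q4 = I + h * k3[0], Q + h * k3[1]
        k4 = f(I4, Q4)
        stages[i] = (I, I2, I3, I4)
        for j in range(5):
            state[j] += h * (k1[j] + 2 * k2[j] + 2 * k3[j] + k4[j]) / 6.0
        out[i + 1] = state
    return ts, out[:, 0], out[:, 1], out[:, 2:], stages


def _rk4_glucose(
    G0: float,
    quad0: tuple[float, float],
    ts: np.ndarray,
    Q: np.ndarray,
    pd_params: GlucosePDParams,
) -> tuple[np.ndarray, np.ndarray]:
    """Fixed-step RK4 for G on an existing uniform segment grid.

    The glucose ODE is linear in G given Q(t); Q at half steps is taken as
    the midpoint average.  The cumulative integrals int (G*Q - Gb*Qb) dt
    and int (G - Gb) dt are advanced through the same stages (see
    :func:`_rk4_insulin`).
    """
    n = len(ts) - 1
    Gs = np.empty(n + 1)
    quads = np.empty((n + 1, 2))
    pG, SI, Gb, Qb = pd_params.pG, pd_params.SI, pd_params.Gb, pd_params.Qb
    const = pG * Gb + SI * Gb * Qb
    G, c1, c2 = G0, quad0[0], quad0[1]
    Gs[0] = G
    quads[0] = (c1, c2)

    def f(g: float, q: float) -> tuple[float, float, float]:
        return -(pG + SI * q) * g + const, g * q - Gb * Qb, g - Gb

    for i in range(n):
        h = ts[i + 1] - ts[i]
        q0, q1 = Q[i], Q[i + 1]
        qm = 0.5 * (q0 + q1)
        k1 = f(G, q0)
        k2 = f(G + 0.5 * h * k1[0], qm)
        k3 = f(G + 0.5 * h * k2[0], qm)
        k4 = f(G + h * k3[0], q1)
        G += h * (k1[0] + 2 * k2[0] + 2 * k3[0] + k4[0]) / 6.0
        c1 += h * (k1[1] + 2 * k2[1] + 2 * k3[1] + k4[1]) / 6.0
        c2 += h * (k1[2] + 2 * k2[2] + 2 * k3[2] + k4[2]) / 6.0
        Gs[i + 1] = G
        quads[i + 1] = (c1, c2)
    return Gs, quads


def simulate(
    kin: InsulinKineticParams,
    secretion: SecretionProfile,
    pd_params: GlucosePDParams,
    protocol: TestProtocol,
    grid_step: float = 0.1,
) -> SimProfiles:
    """Simulate (I, Q, G) over the protocol from the basal steady state.

    Insulin is solved first (it does not depend on glucose), then glucose is
    driven by the resulting interstitial profile Q(t).  Boluses enter as
    concentration jumps ``dose/VP`` (insulin, 1 U = 1000 mU) and ``dose/VG``
    (glucose, 1 g = 5.551 mmol); the grid stores both the pre- and
    post-bolus value at the bolus time.
    """
    if grid_step <= 0:
        raise ValueError("grid_step must be > 0")
    basal = basal_steady_state(kin, secretion, pd_params)

    boundaries = _segment_boundaries(protocol, secretion)
    bolus_at = {}
    for b in protocol.boluses:
        bolus_at.setdefault(b.time, []).append(b)

    grid_parts: list[np.ndarray] = []
    I_parts: list[np.ndarray] = []
    Q_parts: list[np.ndarray] = []
    G_parts: list[np.ndarray] = []
    iq_parts: list[np.ndarray] = []
    gq_parts: list[np.ndarray] = []
    stage_parts: list[np.ndarray] = []

    I, Q, G = basal.I, basal.Q, basal.G
    iq = (0.0, 0.0, 0.0)
    gq = (0.0, 0.0)
    for t0, t1 in zip(boundaries, boundaries[1:]):
        if t0 in bolus_at:
            if not grid_parts:
                # bolus at t = 0: record the pre-bolus point explicitly
                grid_parts.append(np.array([t0]))
                I_parts.append(np.array([I]))
                Q_parts.append(np.array([Q]))
                G_parts.append(np.array([G]))
                iq_parts.append(np.array([iq]))
                gq_parts.append(np.array([gq]))
            # the previous segment already ends at t0 with the pre-bolus
            # value; the post-bolus value re-uses the same abscissa below
            for b in bolus_at[t0]:
                if b.species == "insulin":
                    I += b.dose_model_units() / kin.VP
                else:
                    G += b.dose_model_units() / pd_params.VG
        n_steps = max(1, int(math.ceil((t1 - t0) / grid_step - 1e-9)))
        uN = secretion.rate(0.5 * (t0 + t1))
        try:
            ts, Is, Qs, iqs, stages = _rk4_insulin(I, Q, iq, t0, t1, n_steps, kin, uN)
        except (OverflowError, FloatingPointError) as exc:  # pragma: no cover
            raise RuntimeError(f"integration failed on [{t0}, {t1}] min: {exc}") from exc
        Gs, gqs = _rk4_glucose(G, gq, ts, Qs, pd_params)
        if grid_parts:
            # joining (possibly zero-width) interval between parts
            stage_parts.append(np.zeros((1, 4)))
        stage_parts.append(stages)
        grid_parts.append(ts)
        I_parts.append(Is)
        Q_parts.append(Qs)
        G_parts.append(Gs)
        iq_parts.append(iqs)
        gq_parts.append(gqs)
        I, Q, G = Is[-1], Qs[-1], Gs[-1]
        iq = tuple(iqs[-1])
        gq = tuple(gqs[-1])

    grid = np.concatenate(grid_parts)
    stage_I = np.concatenate(stage_parts)
    iq_all = np.concatenate(iq_parts)
    gq_all = np.concatenate(gq_parts)
    quad = {name: iq_all[:, j] for j, name in enumerate(INSULIN_QUADS)}
    quad.update({name: gq_all[:, j] for j, name in enumerate(GLUCOSE_QUADS)})
    profiles = SimProfiles(
        grid=grid,
        I=np.concatenate(I_parts),
        Q=np.concatenate(Q_parts),
        G=np.concatenate(G_parts),
        protocol=protocol,
        basal=basal,
        quad=quad,
        stage_I=stage_I,
    )
    if not np.all(np.isfinite(profiles.I)) or not np.all(np.isfinite(profiles.G)):
        raise RuntimeError("integration produced non-finite values")
    return profiles


def sample_profile(profiles: SimProfiles, times: Sequence[float], species: str = "insulin") -> SampleSet:
    """Noise-free samples of one species at ``times`` (linear interpolation)."""
    times = np.asarray(times, dtype=float)
    return SampleSet(times=times, values=profiles.interp(species, times), species=species, noise_cv=0.0)


def add_noise(samples: SampleSet, eps: float, rng: np.random.Generator | int) -> SampleSet:
    """Apply multiplicative truncated-Gaussian assay noise.

    Each value v becomes ``v * (1 + eps * z)`` with z standard normal
    truncated to |z| <= 3 (resampled beyond 3 SD).  Deterministic for a
    fixed generator state or integer seed.
    """
    if eps < 0:
        raise ValueError("noise CV eps must be >= 0")
    if eps == 0:
        return SampleSet(samples.times.copy(), samples.values.copy(), samples.species, 0.0)
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    n = len(samples.values)
    z = rng.standard_normal(n)
    bad = np.abs(z) > 3.0
    while np.any(bad):
        z[bad] = rng.standard_normal(int(bad.sum()))
        bad = np.abs(z) > 3.0
    return SampleSet(
        times=samples.times.copy(),
        values=samples.values * (1.0 + eps * z),
        species=samples.species,
        noise_cv=eps,
    )
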