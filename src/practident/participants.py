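"""Built-in virtual participants and population-default kinetic parameters.

Two pilot-study participants — one with normal glucose tolerance (NGT) and
one with impaired glucose tolerance / insulin resistance (IGT, also
referred to as IR) — span the realistic identifiability range for dynamic
insulin sensitivity tests.  Their individually identified values are:

==========  =====  =====  =====  =====  =====  =====  ==========
participant  Ub     U1     U2     nL     xL     VG    SI
             mU/m   mU/m   mU/m   1/min  --     L     L/mU/min
==========  =====  =====  =====  =====  =====  =====  ==========
NGT          26.6  487.7    9.7  0.218  0.797   9.75  20.95e-4
IGT         115.5  233.6  150.7  0.064  0.822  13.35  2.236e-4
==========  =====  =====  =====  =====  =====  =====  ==========

Kinetic parameters not identified per participant (nK, nC, nI, VP, VQ), the
hepatic saturation alphaI, glucose clearance pG and basal glucose Gb use
population-typical defaults below; every value is overridable through the
config layer, and experiments record the values actually used.
"""

from __future__ import annotations

from dataclasses import dataclass

from .models import (
    GlucosePDParams,
    InsulinKineticParams,
    SecretionProfile,
    basal_steady_state,
)

__all__ = ["Participant", "DEFAULT_KINETICS", "NGT", "IGT", "participant"]

#: Population-default insulin kinetics for an adult (alphaI = 0.001 L/mU is
#: the accepted physiological saturation; nL and xL are per-participant).
DEFAULT_KINETICS: dict[str, float] = {
    "nK": 0.054,  # 1/min, renal clearance (GFR-scale)
    "nC": 0.03,  # 1/min, clearance to cells from the interstitium
    "nI": 0.3,  # L/min, plasma<->interstitium exchange
    "VP": 4.0,  # L, plasma volume
    "VQ": 8.0,  # L, interstitial (insulin-accessible) volume
    "alphaI": 0.001,  # L/mU, hepatic saturation
}

#: Population-default glucose-dependent clearance, 1/min.
DEFAULT_PG = 0.02


@dataclass(frozen=True)
class Participant:
    """A virtual participant: kinetics + secretion + pharmacodynamics.

    ``pd.Qb`` is consistent with the basal steady state of the insulin
    model, so simulations started at basal remain at basal.
    """

    name: str
    kin: InsulinKineticParams
    secretion: SecretionProfile
    pd: GlucosePDParams

    def with_overrides(self, **overrides: float) -> "Participant":
        """New participant with kinetic/PD fields replaced (basal Qb is
        re-derived from the updated insulin model)."""
        kin_fields = {"nK", "nL", "nC", "nI", "alphaI", "xL", "VP", "VQ"}
        pd_fields = {"pG", "SI", "VG", "Gb"}
        sec_fields = {"Ub", "U1", "U2", "t_phase1_start", "phase1_duration"}
        kin_kw = {k: v for k, v in overrides.items() if k in kin_fields}
        pd_kw = {k: v for k, v in overrides.items() if k in pd_fields}
        sec_kw = {k: v for k, v in overrides.items() if k in sec_fields}
        unknown = set(overrides) - kin_fields - pd_fields - sec_fields
        if unknown:
            raise ValueError(f"unknown parameter overrides: {sorted(unknown)}")
        kin = self.kin.with_(**kin_kw) if kin_kw else self.kin
        sec = self.secretion
        if sec_kw:
            from dataclasses import replace

            sec = replace(sec, **sec_kw)
        pd = self.pd.with_(**pd_kw) if pd_kw else self.pd
        basal = basal_steady_state(kin, sec, pd)
        return Participant(self.name, kin, sec, pd.with_(Qb=basal.Q))


def _build(
    name: str,
    Ub: float,
    U1: float,
    U2: float,
    nL: float,
    xL: float,
    VG: float,
    SI: float,
    Gb: float,
    pG: float = DEFAULT_PG,
) -> Participant:
    kin = InsulinKineticParams(nL=nL, xL=xL, **DEFAULT_KINETICS)
    # printed secretion values are mass rates (mU/min); the model input is
    # a concentration rate, so divide by the population plasma volume once
    VP = DEFAULT_KINETICS["VP"]
    sec = SecretionProfile(Ub=Ub / VP, U1=U1 / VP, U2=U2 / VP)
    pd = GlucosePDParams(pG=pG, SI=SI, VG=VG, Gb=Gb, Qb=0.0)
    basal = basal_steady_state(kin, sec, pd)
    return Participant(name, kin, sec, pd.with_(Qb=basal.Q))


def participant(name: str) -> Participant:
    """Return a built-in participant by name ('NGT' or 'IGT'/'IR')."""
    key = name.upper()
    if key == "NGT":
        return NGT
    if key in ("IGT", "IR"):
        return IGT
    raise KeyError(f"unknown participant {name!r}; expected 'NGT' or 'IGT'")


# SI values are in units of 1e-4 L/mU/min as printed for this model family.
NGT = _build("NGT", Ub=26.6, U1=487.7, U2=9.7, nL=0.218, xL=0.797, VG=9.75, SI=20.95e-4, Gb=5.0)
IGT = _build("IGT", Ub=115.5, U1=233.6, U2=150.7, nL=0.064, xL=0.822, VG=13.35, SI=2.236e-4, Gb=6.0)
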