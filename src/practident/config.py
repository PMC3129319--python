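"""Flat YAML/JSON configuration for parameter sets and protocols.

Parameter keys follow the model nomenclature exactly (nK, nL, nC, nI,
alphaI, xL, VP, VQ, pG, SI, VG, Gb, Qb, Ub, U1, U2).  Secretion rates Ub,
U1, U2 are the model's concentration rates (mU/L/min); SI is in L/mU/min
on its natural scale (e.g. 20.95e-4).  Protocols use ``duration``,
``sample_times`` and a ``boluses`` list of ``{species, time, dose}``
entries (dose in U for insulin, g for glucose).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any, Mapping

import yaml

from .models import (
    GlucosePDParams,
    InsulinKineticParams,
    SecretionProfile,
    basal_steady_state,
)
from .participants import Participant, participant
from .protocols import BolusEvent, TestProtocol

__all__ = [
    "participant_to_config",
    "participant_from_config",
    "protocol_to_config",
    "protocol_from_config",
    "load_config",
    "save_config",
]

_KIN_KEYS = ("nK", "nL", "nC", "nI", "alphaI", "xL", "VP", "VQ")
_PD_KEYS = ("pG", "SI", "VG", "Gb", "Qb")
_SEC_KEYS = ("Ub", "U1", "U2")


def participant_to_config(part: Participant) -> dict[str, Any]:
    """Flatten a participant to a plain key-value mapping."""
    cfg: dict[str, Any] = {"name": part.name}
    for k in _KIN_KEYS:
        cfg[k] = float(getattr(part.kin, k))
    for k in _PD_KEYS:
        cfg[k] = float(getattr(part.pd, k))
    for k in _SEC_KEYS:
        cfg[k] = float(getattr(part.secretion, k))
    cfg["t_phase1_start"] = float(part.secretion.t_phase1_start)
    cfg["phase1_duration"] = float(part.secretion.phase1_duration)
    return cfg


def participant_from_config(cfg: Mapping[str, Any]) -> Participant:
    """Build a participant from a flat mapping.

    Either give the full parameter set, or a ``base`` key naming a built-in
    participant ('NGT'/'IGT') plus any overrides.  ``Qb`` is always
    re-derived from the basal steady state of the insulin model.
    """
    cfg = dict(cfg)
    if "base" in cfg:
        base = participant(str(cfg.pop("base")))
        name = str(cfg.pop("name", base.name))
        overrides = {k: float(v) for k, v in cfg.items() if k != "Qb"}
        part = base.with_overrides(**overrides) if overrides else base
        return Participant(name, part.kin, part.secretion, part.pd)
    name = str(cfg.pop("name", "custom"))
    kin = InsulinKineticParams(**{k: float(cfg[k]) for k in _KIN_KEYS})
    sec = SecretionProfile(
        Ub=float(cfg["Ub"]),
        U1=float(cfg["U1"]),
        U2=float(cfg["U2"]),
        t_phase1_start=float(cfg.get("t_phase1_start", 7.5)),
        phase1_duration=float(cfg.get("phase1_duration", 5.0)),
    )
    pd = GlucosePDParams(
        pG=float(cfg["pG"]),
        SI=float(cfg["SI"]),
        VG=float(cfg["VG"]),
        Gb=float(cfg["Gb"]),
        Qb=0.0,
    )
    basal = basal_steady_state(kin, sec, pd)
    return Participant(name, kin, sec, pd.with_(Qb=basal.Q))


def protocol_to_config(protocol: TestProtocol) -> dict[str, Any]:
    return {
        "duration": float(protocol.duration),
        "sample_times": [float(t) for t in protocol.sample_times],
        "boluses": [
            {"species": b.species, "time": float(b.time), "dose": float(b.dose)}
            for b in protocol.boluses
        ],
    }


def protocol_from_config(cfg: Mapping[str, Any]) -> TestProtocol:
    return TestProtocol(
        duration=float(cfg["duration"]),
        boluses=tuple(
            BolusEvent(str(b["species"]), float(b["time"]), float(b["dose"]))
            for b in cfg.get("boluses", [])
        ),
        sample_times=tuple(float(t) for t in cfg["sample_times"]),
    )


def load_config(path: str | Path) -> dict[str, Any]:
    """Load a YAML (or JSON) config file into a dict."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        return json.loads(text)
    return yaml.safe_load(text)


def save_config(obj: Mapping[str, Any], path: str | Path) -> None:
    path = Path(path)
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(obj, indent=2, sort_keys=True))
    else:
        path.write_text(yaml.safe_dump(dict(obj), sort_keys=True))
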