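"""Bundled voltage-clamp protocol definitions and their YAML serialization.

Six drug-free protocols (SSA, ACT, RFI, RUDB, TAU50, MOT) and five drug
protocols (SSA_DRUG, TB, UDB, RUDB_DRUG, FDUDB).  The printed anchors are
honored (recovery from inactivation at -100 mV, mean open time at -30 mV,
use-dependent block trains at 10 Hz); remaining pulse durations and sweep
grids are declared assumptions, editable through the YAML representation.
"""

from __future__ import annotations

from dataclasses import asdict
from typing import Dict, Iterable

import yaml

from .clamp_engine import Readout, Segment, VoltageProtocol
from .errors import ProtocolDefinitionError


_SEGMENT_DEFAULTS = {"record": False, "tag": None, "repeat": 1, "period": None,
                     "record_pulses": ()}


def protocol_to_dict(p: VoltageProtocol) -> dict:
    d = asdict(p)
    segments = []
    for s in d["segments"]:
        out = {"level": s["level"], "duration": s["duration"]}
        for k, default in _SEGMENT_DEFAULTS.items():
            if s[k] != default or type(s[k]) is not type(default):
                out[k] = list(s[k]) if k == "record_pulses" else s[k]
        segments.append(out)
    d["segments"] = segments
    d["sweep"] = list(d["sweep"])
    d["readout"] = {k: v for k, v in d["readout"].items() if v is not None}
    return d


def protocol_from_dict(d: dict) -> VoltageProtocol:
    try:
        segments = tuple(
            Segment(
                level=s["level"],
                duration=s["duration"],
                record=s.get("record", False),
                tag=s.get("tag"),
                repeat=s.get("repeat", 1),
                period=s.get("period"),
                record_pulses=tuple(s.get("record_pulses", ())),
            )
            for s in d["segments"]
        )
        readout = Readout(**d["readout"])
        return VoltageProtocol(
            name=d["name"],
            holding=float(d["holding"]),
            segments=segments,
            sweep=tuple(float(v) for v in d["sweep"]),
            readout=readout,
            sweep_unit=d.get("sweep_unit", "mV"),
            sweep_kind=d.get("sweep_kind", "segment"),
            drug_start=d.get("drug_start", "equilibrated"),
        )
    except KeyError as exc:
        raise ProtocolDefinitionError(f"protocol definition missing key {exc}") from exc


def protocols_to_yaml(protocols: Iterable[VoltageProtocol]) -> str:
    return yaml.safe_dump(
        [protocol_to_dict(p) for p in protocols], sort_keys=False, default_flow_style=None
    )


def protocols_from_yaml(text: str) -> Dict[str, VoltageProtocol]:
    raw = yaml.safe_load(text)
    if not isinstance(raw, list):
        raise ProtocolDefinitionError("protocol YAML must be a list of protocols")
    out = {}
    for entry in raw:
        p = protocol_from_dict(entry)
        if p.name in out:
            raise ProtocolDefinitionError(f"duplicate protocol name {p.name!r}")
        out[p.name] = p
    return out


def drug_free_protocols() -> Dict[str, VoltageProtocol]:
    """The six drug-free protocols used to constrain the wild-type model."""
    ps = [
        # steady-state availability: long conditioning prepulse, fixed test pulse
        VoltageProtocol(
            name="SSA",
            holding=-100.0,
            segments=(
                Segment(level="sweep", duration=500.0),
                Segment(level=-20.0, duration=25.0, record=True, tag="test"),
            ),
            sweep=(-140.0, -120.0, -110.0, -100.0, -90.0, -80.0, -70.0, -60.0, -40.0),
            readout=Readout(statistic="availability", test="test", normalize="max"),
        ),
        # steady-state activation: peak open occupancy vs test voltage
        VoltageProtocol(
            name="ACT",
            holding=-100.0,
            segments=(Segment(level="sweep", duration=25.0, record=True, tag="test"),),
            sweep=(-60.0, -50.0, -40.0, -30.0, -20.0, -10.0, 0.0, 10.0),
            readout=Readout(statistic="activation", test="test", normalize="max"),
        ),
        # recovery from 1-pulse inactivation at -100 mV
        VoltageProtocol(
            name="RFI",
            holding=-100.0,
            segments=(
                Segment(level=-20.0, duration=100.0, record=True, tag="ref"),
                Segment(level=-100.0, duration="sweep"),
                Segment(level=-20.0, duration=25.0, record=True, tag="test"),
            ),
            sweep=(1.0, 3.0, 10.0, 30.0, 100.0, 300.0, 1000.0),
            sweep_unit="ms",
            readout=Readout(statistic="recovery_fraction", test="test", reference="ref"),
        ),
        # recovery after a conditioning pulse train (multiple-pulse inactivation)
        VoltageProtocol(
            name="RUDB",
            holding=-100.0,
            segments=(
                Segment(
                    level=-20.0, duration=25.0, repeat=20, period=40.0,
                    record_pulses=(1,),
                ),
                Segment(level=-100.0, duration="sweep"),
                Segment(level=-20.0, duration=25.0, record=True, tag="test"),
            ),
            sweep=(1.0, 10.0, 100.0, 1000.0, 10000.0),
            sweep_unit="ms",
            readout=Readout(statistic="recovery_fraction", test="test", reference="P1"),
        ),
        # time to 50% decay of the open-state transient
        VoltageProtocol(
            name="TAU50",
            holding=-100.0,
            segments=(Segment(level="sweep", duration=25.0, record=True, tag="test"),),
            sweep=(-30.0, -20.0, -10.0, 0.0, 10.0),
            readout=Readout(statistic="tau50", test="test"),
        ),
        # mean open time at -30 mV (single-point analytic readout)
        VoltageProtocol(
            name="MOT",
            holding=-100.0,
            segments=(Segment(level="sweep", duration=1.0),),
            sweep=(-30.0,),
            readout=Readout(statistic="mot"),
        ),
    ]
    return {p.name: p for p in ps}


def drug_protocols() -> Dict[str, VoltageProtocol]:
    """The five drug protocols (run on a drug-extended model)."""
    ps = [
        VoltageProtocol(
            name="SSA_DRUG",
            holding=-100.0,
            segments=(
                Segment(level="sweep", duration=500.0),
                Segment(level=-20.0, duration=25.0, record=True, tag="test"),
            ),
            sweep=(-140.0, -120.0, -110.0, -100.0, -90.0, -80.0, -70.0, -60.0, -40.0),
            readout=Readout(statistic="availability", test="test", normalize="max"),
        ),
        # tonic (first-pulse) block after rest-state drug equilibration
        VoltageProtocol(
            name="TB",
            holding=-100.0,
            segments=(Segment(level="sweep", duration=25.0, record=True, tag="test"),),
            sweep=(-20.0,),
            readout=Readout(statistic="peak", test="test", normalize="drug_free"),
        ),
        # use-dependent block: peak current rundown along a 10 Hz train
        VoltageProtocol(
            name="UDB",
            holding=-100.0,
            segments=(
                Segment(level=-20.0, duration=25.0, repeat=30, period=100.0),
            ),
            sweep=(2.0, 5.0, 10.0, 20.0, 30.0),
            sweep_unit="pulse",
            sweep_kind="pulse_index",
            readout=Readout(statistic="pulse_ratio", test="P30", reference="P1"),
        ),
        # recovery from use-dependent block
        VoltageProtocol(
            name="RUDB_DRUG",
            holding=-100.0,
            segments=(
                Segment(
                    level=-20.0, duration=25.0, repeat=30, period=100.0,
                    record_pulses=(1,),
                ),
                Segment(level=-100.0, duration="sweep"),
                Segment(level=-20.0, duration=25.0, record=True, tag="test"),
            ),
            sweep=(10.0, 100.0, 1000.0, 5000.0, 20000.0),
            sweep_unit="ms",
            readout=Readout(statistic="recovery_fraction", test="test", reference="P1"),
        ),
        # frequency dependence of use-dependent block (last/first pulse ratio)
        VoltageProtocol(
            name="FDUDB",
            holding=-100.0,
            segments=(
                Segment(
                    level=-20.0, duration=25.0, repeat=30, period="sweep_period",
                    record_pulses=(1, 30),
                ),
            ),
            sweep=(2.0, 5.0, 10.0, 20.0),
            sweep_unit="Hz",
            readout=Readout(statistic="pulse_ratio", test="P30", reference="P1"),
        ),
    ]
    return {p.name: p for p in ps}


def default_protocols() -> Dict[str, VoltageProtocol]:
    out = dict(drug_free_protocols())
    out.update(drug_protocols())
    return out
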