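"""Synthetic dataset generation and file input/output.

The experimental summary curves the optimizer fits are published only as
figure points, so the primary test surface is parameter recovery on
*synthetic* datasets: a known "true" model is simulated under the same
protocols and optionally corrupted with additive Gaussian noise on the
normalized readouts.  The generating parameters travel with the fixture so
recovery can be scored.

File formats: parameter/drug/protocol files are YAML or JSON key-value
documents with strict key checking; datasets are comma-separated tables with
a header row (columns ``protocol,x,y[,sd[,concentration,neutral_analog]]``)
and '.' decimals, written and read bit-identically.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
import yaml

from .clamp_engine import ChannelModel, VoltageProtocol, run_protocol
from .core_model import RateParams
from .drug_extension import (
    CHARGED_SCALAR_NAMES,
    NEUTRAL_SCALAR_NAMES,
    DrugScalars,
    DrugSpec,
)
from .errors import DatasetFormatError, NavfitError, ParameterDomainError
from .objective_optimizer import ExperimentDataset
from .protocols import default_protocols, protocols_from_yaml, protocols_to_yaml

# ---------------------------------------------------------------------------
# reference "true" model

#: Default generating parameters of the synthetic-data model.  Chosen (and
#: frozen) to give physiological wild-type Na+ channel kinetics: availability
#: midpoint near -85 mV, activation between -60 and +10 mV, sub-millisecond
#: mean open time at -30 mV, and fast+slow recovery from inactivation.
DEFAULT_TRUE_PARAMS: Dict[str, float] = {
    "a11_v1": 0.1,
    "a11_v2": 17.0,
    "a12": 1.0,
    "a13": 1.0,
    "b11_v1": 5.0,
    "b11_v2": 22.0,
    "b12": 1.0,
    "b13": 1.0,
    "a3_v1": 3.8e-7,
    "a3_v2": 7.7,
    "b3_v1": 0.20,
    "b3_v2": 40.0,
    "a2_v1": 3.0,
    "a2_v2": 30.0,
    "ax": 0.05,
    "bx": 1.0 / 45.0,
}


def default_true_params() -> RateParams:
    return RateParams.from_dict(DEFAULT_TRUE_PARAMS)


# ---------------------------------------------------------------------------
# fixture specification and generation

@dataclass(frozen=True)
class ProtocolCondition:
    """One protocol run condition: which protocol, at which drug condition."""

    protocol: str
    concentration: float = 0.0
    neutral_analog: bool = False

    @property
    def dataset_name(self) -> str:
        if self.concentration <= 0:
            return self.protocol
        tag = f"{self.concentration * 1e6:g}uM"
        if self.neutral_analog:
            tag += "N"
        return f"{self.protocol}:{tag}"


@dataclass
class FixtureSpec:
    """Recipe for a synthetic multi-protocol dataset.

    ``noise_sd`` is the absolute SD of additive Gaussian noise on the
    (normalized, dimensionless or ms) readouts; 0 gives noise-free data whose
    cost at the generating parameters is exactly zero.  All randomness flows
    from ``seed``.
    """

    params: RateParams = field(default_factory=default_true_params)
    conditions: Tuple[ProtocolCondition, ...] = tuple(
        ProtocolCondition(p) for p in ("SSA", "ACT", "RFI", "RUDB", "TAU50", "MOT")
    )
    scalars: Optional[DrugScalars] = None
    drug: Optional[DrugSpec] = None
    noise_sd: float = 0.0
    seed: int = 0
    sample_dt: float = 0.05

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ParameterDomainError("noise SD must be >= 0")


def add_noise(values: np.ndarray, sd: float, rng: np.random.Generator) -> np.ndarray:
    """Additive Gaussian noise with absolute SD ``sd`` on each readout."""
    if sd == 0:
        return np.asarray(values, dtype=float).copy()
    return np.asarray(values, dtype=float) + rng.normal(0.0, sd, size=len(values))


def generate_datasets(
    spec: FixtureSpec,
    protocols: Optional[Dict[str, VoltageProtocol]] = None,
) -> List[ExperimentDataset]:
    """Simulate the generating model under each condition and emit datasets.

    Deterministic for a given seed; the generating parameters are attached to
    every dataset's ``meta`` under ``"true_params"`` for recovery scoring.
    """
    registry = protocols if protocols is not None else default_protocols()
    rng = np.random.default_rng(spec.seed)
    out: List[ExperimentDataset] = []
    for cond in spec.conditions:
        if cond.protocol not in registry:
            raise NavfitError(f"fixture generation failed: unknown protocol {cond.protocol!r}")
        proto = registry[cond.protocol]
        if cond.concentration > 0:
            template = spec.drug if spec.drug is not None else DrugSpec()
            drug = replace(
                template,
                concentration=cond.concentration,
                charged_fraction_override=0.0 if cond.neutral_analog else
                template.charged_fraction_override,
            )
            model = ChannelModel(spec.params, drug=drug, scalars=spec.scalars)
        else:
            model = ChannelModel(spec.params)
        try:
            results = run_protocol(model, proto, sample_dt=spec.sample_dt)
        except NavfitError as exc:
            raise NavfitError(
                f"fixture generation failed for protocol {cond.protocol!r}: {exc}"
            ) from exc
        x = np.array([r.sweep_value for r in results])
        clean = np.array([r.value for r in results])
        y = add_noise(clean, spec.noise_sd, rng)
        meta: Dict[str, object] = {
            "base_protocol": cond.protocol,
            "true_params": spec.params.to_dict(),
            "noise_sd": spec.noise_sd,
        }
        if cond.concentration > 0:
            meta["concentration"] = cond.concentration
            meta["neutral_analog"] = cond.neutral_analog
        out.append(
            ExperimentDataset(protocol=cond.dataset_name, x=x, y=y, meta=meta)
        )
    return out


# ---------------------------------------------------------------------------
# delimited dataset IO

def write_datasets(datasets: Sequence[ExperimentDataset], path: Union[str, Path]) -> None:
    """Write datasets as one comma-separated table (full float precision)."""
    rows = []
    any_sd = any(ds.sd is not None for ds in datasets)
    any_drug = any("concentration" in ds.meta for ds in datasets)
    for ds in datasets:
        for i in range(ds.n_points):
            row = {
                "protocol": ds.protocol,
                "x": repr(float(ds.x[i])),
                "y": repr(float(ds.y[i])),
            }
            if any_sd:
                row["sd"] = "" if ds.sd is None else repr(float(ds.sd[i]))
            if any_drug:
                row["concentration"] = repr(float(ds.meta.get("concentration", 0.0)))
                row["neutral_analog"] = int(bool(ds.meta.get("neutral_analog", False)))
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_datasets(path: Union[str, Path]) -> List[ExperimentDataset]:
    """Read a comma-separated dataset table; errors cite the offending row."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep=",", float_precision="round_trip")
    except pd.errors.ParserError as exc:
        raise DatasetFormatError(f"{path}: {exc}") from exc
    required = {"protocol", "x", "y"}
    missing = required - set(df.columns)
    if missing:
        raise DatasetFormatError(f"{path}: missing columns {sorted(missing)}")
    allowed = required | {"sd", "concentration", "neutral_analog"}
    unknown = set(df.columns) - allowed
    if unknown:
        raise DatasetFormatError(f"{path}: unknown columns {sorted(unknown)}")
    for col in ("x", "y"):
        bad = df.index[pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()]
        if len(bad):
            # +2: header line plus 1-based numbering
            raise DatasetFormatError(
                f"{path}: non-numeric value in column {col!r} on row {bad[0] + 2}"
            )
        nan = df.index[df[col].isna()]
        if len(nan):
            raise DatasetFormatError(
                f"{path}: missing value in column {col!r} on row {nan[0] + 2}"
            )
    out = []
    for name, grp in df.groupby("protocol", sort=False):
        sd = None
        if "sd" in grp.columns and grp["sd"].notna().any():
            sd = grp["sd"].to_numpy(dtype=float)
        meta: Dict[str, object] = {"base_protocol": str(name).split(":")[0]}
        if "concentration" in grp.columns:
            conc = float(grp["concentration"].iloc[0])
            if conc > 0:
                meta["concentration"] = conc
                meta["neutral_analog"] = bool(int(grp["neutral_analog"].iloc[0])) if (
                    "neutral_analog" in grp.columns
                ) else False
        out.append(
            ExperimentDataset(
                protocol=str(name),
                x=grp["x"].to_numpy(dtype=float),
                y=grp["y"].to_numpy(dtype=float),
                sd=sd,
                meta=meta,
            )
        )
    return out


# ---------------------------------------------------------------------------
# parameter / drug / protocol file IO

def _load_mapping(path: Path) -> dict:
    text = path.read_text()
    if path.suffix in (".yaml", ".yml"):
        data = yaml.safe_load(text)
    elif path.suffix == ".json":
        data = json.loads(text)
    else:
        raise DatasetFormatError(f"{path}: unsupported extension {path.suffix!r}")
    if not isinstance(data, dict):
        raise DatasetFormatError(f"{path}: expected a key->value mapping")
    return data


def _dump_mapping(data: dict, path: Path) -> None:
    if path.suffix in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(data, sort_keys=False))
    elif path.suffix == ".json":
        path.write_text(json.dumps(data, indent=2) + "\n")
    else:
        raise DatasetFormatError(f"{path}: unsupported extension {path.suffix!r}")


def read_params(path: Union[str, Path]) -> RateParams:
    """Read the 16 rate parameters; unknown or missing keys are rejected."""
    data = _load_mapping(Path(path))
    try:
        return RateParams.from_dict(data)
    except ParameterDomainError as exc:
        raise DatasetFormatError(f"{path}: {exc}") from exc


def write_params(params: RateParams, path: Union[str, Path]) -> None:
    _dump_mapping(params.to_dict(), Path(path))


def read_drug(path: Union[str, Path]) -> Tuple[DrugSpec, DrugScalars]:
    """Read a drug file: DrugSpec fields plus the 16 scalar entries."""
    data = _load_mapping(Path(path))
    scalar_keys = set(CHARGED_SCALAR_NAMES) | set(NEUTRAL_SCALAR_NAMES)
    scalars = {k: v for k, v in data.items() if k in scalar_keys}
    spec_fields = {k: v for k, v in data.items() if k not in scalar_keys}
    try:
        spec = DrugSpec(**spec_fields)
    except (TypeError, ParameterDomainError) as exc:
        raise DatasetFormatError(f"{path}: {exc}") from exc
    return spec, DrugScalars.from_dict(scalars)


def write_drug(spec: DrugSpec, scalars: DrugScalars, path: Union[str, Path]) -> None:
    data = {
        "pKa": spec.pKa,
        "pH": spec.pH,
        "diffusion": spec.diffusion,
        "concentration": spec.concentration,
        "d": spec.d,
        "T": spec.T,
        "kd0_charged_open": spec.kd0_charged_open,
        "kd_neutral_open": spec.kd_neutral_open,
        "kd_neutral_closed": spec.kd_neutral_closed,
        "kd_neutral_inactivated": spec.kd_neutral_inactivated,
        "closed_ref_voltage": spec.closed_ref_voltage,
    }
    data.update(scalars.to_dict())
    _dump_mapping(data, Path(path))


def read_scheme(path: Union[str, Path]):
    """Read a scheme override file: states, conducting states and edges."""
    from .core_model import ChannelScheme

    data = _load_mapping(Path(path))
    unknown = set(data) - {"states", "conducting_states", "edges"}
    if unknown:
        raise DatasetFormatError(f"{path}: unknown keys {sorted(unknown)}")
    try:
        return ChannelScheme(
            states=tuple(data["states"]),
            edges=tuple((f, t, l) for f, t, l in data["edges"]),
            conducting_states=tuple(data.get("conducting_states", ("O",))),
        )
    except (KeyError, ValueError, TypeError) as exc:
        raise DatasetFormatError(f"{path}: malformed scheme file ({exc})") from exc


def write_scheme(scheme, path: Union[str, Path]) -> None:
    _dump_mapping(
        {
            "states": list(scheme.states),
            "conducting_states": list(scheme.conducting_states),
            "edges": [list(e) for e in scheme.edges],
        },
        Path(path),
    )


def read_fixture_spec(
    path: Union[str, Path],
    params: Optional[RateParams] = None,
    scalars: Optional[DrugScalars] = None,
    drug: Optional[DrugSpec] = None,
) -> FixtureSpec:
    """Read a fixture recipe (protocol conditions, noise SD, seed).

    Generating parameters default to the bundled wild-type set; drug
    constants/scalars may be supplied when the recipe includes drug
    conditions.
    """
    data = _load_mapping(Path(path))
    unknown = set(data) - {"noise_sd", "seed", "protocols", "sample_dt"}
    if unknown:
        raise DatasetFormatError(f"{path}: unknown keys {sorted(unknown)}")
    try:
        conditions = tuple(
            ProtocolCondition(
                protocol=entry["protocol"],
                concentration=float(entry.get("concentration", 0.0)),
                neutral_analog=bool(entry.get("neutral_analog", False)),
            )
            for entry in data["protocols"]
        )
    except (KeyError, TypeError) as exc:
        raise DatasetFormatError(f"{path}: malformed protocol entry ({exc})") from exc
    return FixtureSpec(
        params=params if params is not None else bundled_wt_params(),
        conditions=conditions,
        scalars=scalars,
        drug=drug,
        noise_sd=float(data.get("noise_sd", 0.0)),
        seed=int(data.get("seed", 0)),
        sample_dt=float(data.get("sample_dt", 0.05)),
    )


def read_protocols(path: Union[str, Path]) -> Dict[str, VoltageProtocol]:
    return protocols_from_yaml(Path(path).read_text())


def write_protocols(protocols: Dict[str, VoltageProtocol], path: Union[str, Path]) -> None:
    Path(path).write_text(protocols_to_yaml(protocols.values()))


def bundled_flecainide() -> Tuple[DrugSpec, DrugScalars]:
    """The bundled flecainide constants (pKa 9.3, Kd0 11.2 uM, D 5500 ...)."""
    with resources.as_file(resources.files("navfit") / "data" / "flecainide.yaml") as p:
        return read_drug(p)


def bundled_protocols() -> Dict[str, VoltageProtocol]:
    with resources.as_file(resources.files("navfit") / "data" / "protocols.yaml") as p:
        return read_protocols(p)


def bundled_wt_params() -> RateParams:
    with resources.as_file(resources.files("navfit") / "data" / "wt_params.yaml") as p:
        return read_params(p)


# ---------------------------------------------------------------------------
# run manifest

def write_manifest(
    path: Union[str, Path],
    command: str,
    seed: Optional[int],
    options: Optional[dict] = None,
    input_files: Sequence[Union[str, Path]] = (),
) -> dict:
    """Record seeds, options and input-file hashes for a CLI invocation."""
    manifest = {
        "command": command,
        "seed": seed,
        "options": options or {},
        "inputs": {},
    }
    for f in input_files:
        f = Path(f)
        if f.exists():
            manifest["inputs"][str(f)] = hashlib.sha256(f.read_bytes()).hexdigest()
    Path(path).write_text(json.dumps(manifest, indent=2, default=str) + "\n")
    return manifest
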