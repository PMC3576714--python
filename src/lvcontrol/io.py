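"""File formats: CSV event trains, JSON model files, YAML run configs."""

from __future__ import annotations

from dataclasses import dataclass, field
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import DataError
from .events import EventTrain
from .laguerre import LaguerreBasis
from .model import LVCoefficients

__all__ = ["read_event_trains", "write_event_trains", "save_model",
           "load_model", "RunConfig", "load_run_config"]

_UNITS_PREFIX = "# units:"


def write_event_trains(trains, path) -> None:
    """Write trains as CSV `train_id,time_s,amplitude[,output]`.

    A `# units:` comment line records amplitude/output units.
    """
    if isinstance(trains, EventTrain):
        trains = [trains]
    frames = []
    any_outputs = any(t.has_outputs for t in trains)
    for t in trains:
        d = {"train_id": t.train_id, "time_s": t.times, "amplitude": t.amplitudes}
        if any_outputs:
            d["output"] = t.outputs if t.has_outputs else np.nan
        frames.append(pd.DataFrame(d))
    df = pd.concat(frames, ignore_index=True)
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"{_UNITS_PREFIX} amplitude={trains[0].amplitude_unit} "
                 f"output={trains[0].output_unit}\n")
        df.to_csv(fh, index=False, float_format="%.17g")


def read_event_trains(path) -> list[EventTrain]:
    """Read trains from CSV, grouped by train_id, validated per train."""
    path = Path(path)
    units = {"amplitude": "uA", "output": "mV"}
    with path.open() as fh:
        first = fh.readline()
    if first.startswith(_UNITS_PREFIX):
        for tok in first[len(_UNITS_PREFIX):].split():
            if "=" in tok:
                k, v = tok.split("=", 1)
                units[k.strip()] = v.strip()
    try:
        df = pd.read_csv(path, comment="#", float_precision="round_trip")
    except (pd.errors.ParserError, ValueError) as err:
        raise DataError(f"cannot parse {path}: {err}") from err
    required = {"train_id", "time_s", "amplitude"}
    if not required.issubset(df.columns):
        raise DataError(f"{path}: missing required columns "
                        f"{sorted(required - set(df.columns))}")
    for col in ("time_s", "amplitude"):
        bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()
                       & df[col].notna()]
        if len(bad):
            # +2: one for the header row, one for 1-based line numbers
            raise DataError(f"{path}: malformed {col!r} value near line "
                            f"{int(bad[0]) + 2}")
    trains = []
    for tid, grp in df.groupby("train_id", sort=False):
        outputs = None
        if "output" in grp.columns and grp["output"].notna().all():
            outputs = grp["output"].to_numpy(dtype=float)
        trains.append(EventTrain(
            grp["time_s"].to_numpy(dtype=float),
            grp["amplitude"].to_numpy(dtype=float),
            outputs, train_id=str(tid),
            amplitude_unit=units["amplitude"], output_unit=units["output"]))
    return trains


def save_model(path, coefficients: LVCoefficients, basis: LaguerreBasis,
               metadata: dict | None = None) -> None:
    """Write a model file: JSON {basis, coefficients, metadata}.

    The basis is stored by its parameters only; the tabulated values are
    regenerated deterministically on load.
    """
    payload = {
        "basis": basis.to_spec(),
        "coefficients": {k: v for k, v in coefficients.to_dict().items()
                         if k != "basis_spec"},
        "metadata": metadata or {},
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def load_model(path) -> tuple[LVCoefficients, LaguerreBasis, dict]:
    payload = json.loads(Path(path).read_text())
    basis = LaguerreBasis.from_spec(payload["basis"])
    coeffs = LVCoefficients.from_dict(
        {**payload["coefficients"], "basis_spec": basis.to_spec()})
    return coeffs, basis, payload.get("metadata", {})


@dataclass
class RunConfig:
    """Bundle of end-to-end scenario settings loadable from YAML."""

    preset: str = "mixed"
    noise_sd: float = 0.05
    seed: int = 0
    n_trains: int = 4
    n_pulses: int = 300
    farit_amplitude: float = 200.0
    rarit_mean: float = 150.0
    rarit_sd: float = 45.0
    basis: dict = field(default_factory=dict)  # alpha/n_basis/n_lags/dt overrides


def load_run_config(path) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    known = {f for f in RunConfig.__dataclass_fields__}
    unknown = set(raw) - known
    if unknown:
        raise DataError(f"unknown run-config keys: {sorted(unknown)}")
    return RunConfig(**raw)
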