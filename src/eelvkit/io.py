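"""File exchange: waveform CSV, config YAML, paired/replicate CSV, JSON reports.

CSV dialect everywhere: comma-separated, '.' decimal, mandatory header,
UTF-8. Gas composition may be given as dry fractions (``f_o2``, ``f_co2``)
or as partial pressures (``p_o2_mmhg``, ``p_co2_mmhg``), converted with
``F = P / Pb`` at a configurable barometric pressure; no water-vapor or
BTPS/STPD correction is applied.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import DataError, InvalidConfigError
from .simkit import GasWaveform, LungConfig, PhantomConfig

DEFAULT_BAROMETRIC_MMHG = 760.0

_WAVEFORM_COLS = ("time_s", "flow_mls", "paw_cmh2o")


def write_waveform_csv(w: GasWaveform, path) -> None:
    pd.DataFrame(
        {
            "time_s": w.time_s,
            "flow_mls": w.flow_mls,
            "paw_cmh2o": w.paw_cmh2o,
            "f_o2": w.f_o2,
            "f_co2": w.f_co2,
        }
    ).to_csv(path, index=False)


def read_waveform_csv(
    path, barometric_mmhg: float = DEFAULT_BAROMETRIC_MMHG
) -> GasWaveform:
    """Read a waveform CSV with either fraction or partial-pressure columns."""
    df = pd.read_csv(path)
    if df.empty:
        raise DataError(f"{path}: no samples")
    for col in _WAVEFORM_COLS:
        if col not in df.columns:
            raise DataError(f"{path}: missing column '{col}'")
    if {"f_o2", "f_co2"} <= set(df.columns):
        f_o2 = df["f_o2"].to_numpy(dtype=float)
        f_co2 = df["f_co2"].to_numpy(dtype=float)
    elif {"p_o2_mmhg", "p_co2_mmhg"} <= set(df.columns):
        f_o2 = df["p_o2_mmhg"].to_numpy(dtype=float) / barometric_mmhg
        f_co2 = df["p_co2_mmhg"].to_numpy(dtype=float) / barometric_mmhg
    else:
        raise DataError(
            f"{path}: need f_o2/f_co2 or p_o2_mmhg/p_co2_mmhg columns"
        )
    t = df["time_s"].to_numpy(dtype=float)
    for name in ("time_s", "flow_mls", "paw_cmh2o"):
        arr = df[name].to_numpy(dtype=float)
        if not np.all(np.isfinite(arr)):
            bad = int(np.flatnonzero(~np.isfinite(arr))[0])
            raise DataError(f"{path}: non-finite value in '{name}' at row {bad}")
    if len(t) < 2:
        raise DataError(f"{path}: need at least two samples")
    dts = np.diff(t)
    if np.any(dts <= 0) or np.ptp(dts) > 1e-6 * np.mean(dts) + 1e-12:
        raise DataError(f"{path}: time_s must increase at a fixed sample rate")
    return GasWaveform(
        sample_rate_hz=1.0 / float(np.mean(dts)),
        flow_mls=df["flow_mls"].to_numpy(dtype=float),
        paw_cmh2o=df["paw_cmh2o"].to_numpy(dtype=float),
        f_o2=f_o2,
        f_co2=f_co2,
    )


def read_lung_config(path) -> LungConfig:
    """Load a LungConfig from YAML; unknown keys are rejected."""
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    known = set(LungConfig.__dataclass_fields__)
    unknown = set(raw) - known
    if unknown:
        raise InvalidConfigError(f"{path}: unknown keys {sorted(unknown)}")
    if "fio2_schedule" in raw:
        raw["fio2_schedule"] = [tuple(map(float, step)) for step in raw["fio2_schedule"]]
    cfg = LungConfig(**raw)
    cfg.validate()
    return cfg


def read_phantom_config(path) -> PhantomConfig:
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    known = set(PhantomConfig.__dataclass_fields__)
    unknown = set(raw) - known
    if unknown:
        raise InvalidConfigError(f"{path}: unknown keys {sorted(unknown)}")
    if "shape" in raw:
        raw["shape"] = tuple(int(s) for s in raw["shape"])
    if "voxel_dims_mm" in raw:
        raw["voxel_dims_mm"] = tuple(float(d) for d in raw["voxel_dims_mm"])
    if "regions" in raw:
        raw["regions"] = [tuple(map(float, r)) for r in raw["regions"]]
    cfg = PhantomConfig(**raw)
    cfg.validate()
    return cfg


def read_paired_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"subject", "value_test", "value_ref"}
    missing = required - set(df.columns)
    if missing:
        raise DataError(f"{path}: missing columns {sorted(missing)}")
    return df


def read_replicates_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = {"value_1", "value_2"} - set(df.columns)
    if missing:
        raise DataError(f"{path}: missing columns {sorted(missing)}")
    return df


def _jsonify(obj):
    if isinstance(obj, dict):
        return {k: _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [_jsonify(v) for v in obj.tolist()]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def write_report(payload: dict, path=None, *, provenance: dict | None = None) -> str:
    """Serialize a result dict to JSON (stable key order, no timestamps)."""
    out = dict(payload)
    if provenance is not None:
        out["provenance"] = provenance
    text = json.dumps(_jsonify(out), indent=2, sort_keys=True) + "\n"
    if path is not None:
        Path(path).write_text(text, encoding="utf-8")
    return text


def provenance_block(seed=None, **config_echo) -> dict:
    from . import __version__

    return {"package": "eelvkit", "version": __version__, "seed": seed,
            "config": _jsonify(config_echo)}
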