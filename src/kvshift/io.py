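"""Table and metadata I/O.

Delimited-text conventions: every column name carries its unit suffix
(``_mV``, ``_uA``, ``_ms``, ``_uM``, ``_nm``); delimiters are sniffed on read.
Fit results are written as JSON records with a metadata block (package
version, seed, parameters) so runs are reproducible and self-describing.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .gv import CurrentTraceFamily, VoltageProtocol
from .sites import ShiftDataset

__all__ = [
    "read_table",
    "family_to_frame",
    "frame_to_family",
    "read_current_family",
    "write_current_family",
    "read_shift_table",
    "write_fit_json",
    "read_fit_json",
]

TRACE_COLUMNS = ("sweep_voltage_mV", "time_ms", "current_uA")


def read_table(path: str | Path, required: tuple[str, ...] = ()) -> pd.DataFrame:
    """Read a delimited table (sniffed delimiter), checking required columns."""
    df = pd.read_csv(path, sep=None, engine="python")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s): {missing}")
    return df


def family_to_frame(family: CurrentTraceFamily) -> pd.DataFrame:
    """Long-format (sweep_voltage_mV, time_ms, current_uA) table of a family."""
    v = np.asarray(family.protocol.test_voltages)
    n_t = family.time_grid.size
    return pd.DataFrame(
        {
            "sweep_voltage_mV": np.repeat(v, n_t),
            "time_ms": np.tile(family.time_grid, v.size),
            "current_uA": family.currents.ravel(),
        }
    )


def frame_to_family(
    df: pd.DataFrame,
    reversal_potential: float = -80.0,
    steady_state_window: float = 10.0,
    holding_potential: float = -80.0,
    condition_label: str = "",
) -> CurrentTraceFamily:
    """Rebuild a current family from a long-format trace table.

    The voltage protocol is reconstructed from the data: test voltages from
    the distinct sweep voltages, sweep duration and sampling from the time
    grid; reversal potential and steady-state window are analysis settings
    supplied by the caller.
    """
    missing = [c for c in TRACE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trace table missing required column(s): {missing}")
    voltages = np.sort(df["sweep_voltage_mV"].unique())
    t = np.sort(df["time_ms"].unique())
    wide = df.pivot_table(
        index="sweep_voltage_mV", columns="time_ms", values="current_uA"
    ).loc[voltages, t]
    if wide.isna().any().any():
        raise ValueError("trace table is not a complete sweep x time grid")
    dt = float(np.median(np.diff(t))) if t.size > 1 else float(t[0])
    proto = VoltageProtocol(
        test_voltages=tuple(voltages),
        holding_potential=holding_potential,
        sweep_duration=float(t[-1]),
        steady_state_window=steady_state_window,
        reversal_potential=reversal_potential,
        sample_interval=dt,
    )
    return CurrentTraceFamily(proto, t, wide.to_numpy(), condition_label)


def write_current_family(family: CurrentTraceFamily, path: str | Path) -> None:
    family_to_frame(family).to_csv(path, index=False)


def read_current_family(path: str | Path, **kwargs) -> CurrentTraceFamily:
    return frame_to_family(read_table(path, required=TRACE_COLUMNS), **kwargs)


def read_shift_table(path: str | Path) -> ShiftDataset:
    """Read a per-mutant shift table; raises naming any missing column."""
    return ShiftDataset(read_table(path, required=ShiftDataset.REQUIRED))


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, float) and not np.isfinite(obj):
        return None if np.isnan(obj) else ("inf" if obj > 0 else "-inf")
    return obj


def write_fit_json(
    path: str | Path,
    result,
    seed: int | None = None,
    parameters: dict | None = None,
) -> None:
    """Write a fit record plus a reproducibility metadata block."""
    payload = {
        "metadata": {
            "package": "kvshift",
            "version": __version__,
            "seed": seed,
            "parameters": _jsonable(parameters or {}),
        },
        "result": _jsonable(result),
    }
    Path(path).write_text(json.dumps(payload, indent=2, allow_nan=False) + "\n")


def read_fit_json(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
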