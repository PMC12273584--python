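"""Typed CSV/JSON readers and writers shared by all modules.

Declared CSV schemas (header → meaning):

* ``acf``         — ``lag_s,G``: one autocorrelation curve per file
* ``profile``     — ``distance_um,value,unit``: radial profile samples
* ``titration``   — ``bulk_nM,response``: dose–response table
* ``simulation``  — ``time_s,distance_um,L_nM,LR_nM,R_nM``: long-format
  reaction–diffusion output

Schema errors (missing columns, non-numeric cells, unknown unit tags) are
raised before any computation, naming the offending column.  JSON writing
uses deterministic key ordering and no timestamps, so identical inputs
give byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .fcs import AutocorrelationCurve
from .steady_state import DEFAULT_CELL_RADIUS, RadialProfile
from .units import CONC_UNITS, DIFFUSIVITY_UNIT

__all__ = [
    "SchemaError",
    "SCHEMAS",
    "read_table",
    "read_acf_csv",
    "write_acf_csv",
    "read_profile_csv",
    "write_profile_csv",
    "read_titration_csv",
    "write_titration_csv",
    "write_simulation_csv",
    "read_simulation_csv",
    "write_result",
    "read_result",
]

SCHEMAS: dict[str, tuple[str, ...]] = {
    "acf": ("lag_s", "G"),
    "profile": ("distance_um", "value", "unit"),
    "titration": ("bulk_nM", "response"),
    "simulation": ("time_s", "distance_um", "L_nM", "LR_nM", "R_nM"),
}

_NUMERIC = {
    "acf": ("lag_s", "G"),
    "profile": ("distance_um", "value"),
    "titration": ("bulk_nM", "response"),
    "simulation": ("time_s", "distance_um", "L_nM", "LR_nM", "R_nM"),
}


class SchemaError(ValueError):
    """A table does not match its declared schema."""


def read_table(path, schema: str) -> pd.DataFrame:
    """Read and validate a CSV against one of the declared schemas."""
    if schema not in SCHEMAS:
        raise ValueError(f"unknown schema {schema!r}; known: {sorted(SCHEMAS)}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise SchemaError(f"{path}: empty file") from None
    expected = SCHEMAS[schema]
    missing = [c for c in expected if c not in df.columns]
    if missing:
        raise SchemaError(
            f"{path}: missing column(s) {missing} for schema {schema!r} "
            f"(found {list(df.columns)})"
        )
    if df.empty:
        raise SchemaError(f"{path}: no data rows")
    for col in _NUMERIC[schema]:
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            row = int(vals.isna().idxmax())
            raise SchemaError(f"{path}: non-numeric value in column {col!r}, row {row}")
        df[col] = vals
    if schema == "profile":
        bad = set(df["unit"].unique()) - set(CONC_UNITS) - {DIFFUSIVITY_UNIT}
        if bad:
            raise SchemaError(f"{path}: unknown unit tag(s) {sorted(bad)} in column 'unit'")
    return df[list(expected)]


def read_acf_csv(path) -> AutocorrelationCurve:
    df = read_table(path, "acf")
    return AutocorrelationCurve(lags=df["lag_s"].to_numpy(), values=df["G"].to_numpy())


def write_acf_csv(curve: AutocorrelationCurve, path) -> None:
    pd.DataFrame({"lag_s": curve.lags, "G": curve.values}).to_csv(path, index=False)


def read_profile_csv(path, a: float = DEFAULT_CELL_RADIUS) -> RadialProfile:
    df = read_table(path, "profile")
    units = df["unit"].unique()
    if len(units) != 1:
        raise SchemaError(f"{path}: mixed unit tags {sorted(units)} in one profile")
    return RadialProfile(
        radii=df["distance_um"].to_numpy() + a,
        values=df["value"].to_numpy(),
        unit=str(units[0]),
        a=a,
    )


def write_profile_csv(profile: RadialProfile, path) -> None:
    pd.DataFrame(
        {
            "distance_um": profile.distances,
            "value": profile.values,
            "unit": profile.unit,
        }
    ).to_csv(path, index=False)


def read_titration_csv(path) -> tuple[np.ndarray, np.ndarray]:
    df = read_table(path, "titration")
    return df["bulk_nM"].to_numpy(), df["response"].to_numpy()


def write_titration_csv(bulk, response, path) -> None:
    pd.DataFrame({"bulk_nM": bulk, "response": response}).to_csv(path, index=False)


def write_simulation_csv(states, grid, path) -> None:
    """Long-format reaction–diffusion output, one row per (time, cell)."""
    rows = []
    d = grid.centers - grid.a
    for st in states:
        rows.append(
            pd.DataFrame(
                {
                    "time_s": st.time,
                    "distance_um": d,
                    "L_nM": st.L,
                    "LR_nM": st.LR,
                    "R_nM": st.R,
                }
            )
        )
    pd.concat(rows, ignore_index=True).to_csv(path, index=False)


def read_simulation_csv(path) -> pd.DataFrame:
    return read_table(path, "simulation")


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _jsonable(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def write_result(obj, path) -> None:
    """Serialize a result object (dataclass/dict) to deterministic JSON."""
    payload = _jsonable(obj)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_result(path) -> dict:
    with open(path) as fh:
        return json.load(fh)
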