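"""Schema-validated CSV I/O.

Column names embed units (_ppmv, _permil, _ng_g_h, ...) so tables cannot
be combined with silent unit mistakes; every writer prepends ``# key = value``
comment headers (seed, config hash, package version) and every reader
skips them, so all outputs round-trip through their own validators.
"""

from __future__ import annotations

import hashlib
import json
import math
from pathlib import Path

import numpy as np
import pandas as pd

from .simulate import HeadspaceSeries, PlfaRecord, SedimentEndpoint
from .upscaling import HABITATS

__all__ = [
    "SchemaError",
    "SCHEMAS",
    "validate_table",
    "write_table",
    "read_table",
    "read_headspace",
    "read_endpoints",
    "read_plfa",
    "config_hash",
]


class SchemaError(ValueError):
    """Raised with file/row/column detail when a table violates its schema."""


_EVENTS = {"none", "replenish", "swap"}

# column -> (kind, min, max, allow_nan); kind in {str, int, float, cat:<name>}
SCHEMAS: dict[str, dict] = {
    "headspace": {
        "treatment_id": ("str", None, None, False),
        "replicate": ("int", 0, None, False),
        "time_h": ("float", 0.0, None, False),
        "ch4_ppmv": ("float", 0.0, None, False),
        "ch4_13f": ("float", 0.0, 1.0, True),
        "co2_ppmv": ("float", 0.0, None, False),
        "delta_co2_permil": ("float", -1000.0, None, True),
        "event": ("cat:event", None, None, False),
        "vented_13c_ug": ("float", 0.0, None, False),
    },
    "endpoints": {
        "treatment_id": ("str", None, None, False),
        "replicate": ("int", 0, None, False),
        "toc_pct": ("float", 0.0, None, False),
        "delta_toc_permil": ("float", -1000.0, None, False),
        "delta_methanol_permil": ("float", -1000.0, None, False),
    },
    "plfa": {
        "treatment_id": ("str", None, None, False),
        "replicate": ("int", 0, None, False),
        "compound": ("str", None, None, False),
        "n_carbons": ("int", 2, None, False),
        "conc_ng_per_g": ("float", 0.0, None, False),
        "delta_fame_permil": ("float", -1000.0, None, False),
    },
    "rates": {
        "treatment_id": ("str", None, None, False),
        "replicate": ("int", 0, None, False),
        "initial_ppm": ("float", 0.0, None, False),
        "rate_ng_g_h": ("float", None, None, False),
        "se": ("float", 0.0, None, True),
        "method": ("str", None, None, False),
        "window_start_h": ("float", 0.0, None, False),
        "window_end_h": ("float", 0.0, None, False),
    },
    "budget": {
        "treatment_id": ("str", None, None, False),
        "supplied_13c_ug": ("float", 0.0, None, False),
        "residual_13c_ug": ("float", None, None, False),
        "co2_13c_ug": ("float", None, None, True),
        "soc_13c_ug": ("float", None, None, False),
        "efficiency_pct": ("float", None, None, False),
        "partition_biomass_pct": ("float", None, None, False),
        "partition_co2_pct": ("float", None, None, True),
        "recovery_pct": ("float", None, None, False),
    },
    "habitat_rates": {
        "habitat": ("cat:habitat", None, None, False),
        "initial_ch4_ppm": ("float", 0.0, None, False),
        "rate_ng_g_h": ("float", 0.0, None, False),
        "source": ("str", None, None, True),
    },
    "plfa_corrected": {
        "treatment_id": ("str", None, None, False),
        "replicate": ("int", 0, None, False),
        "compound": ("str", None, None, False),
        "n_carbons": ("int", 2, None, False),
        "conc_ng_per_g": ("float", 0.0, None, False),
        "delta_fame_permil": ("float", -1000.0, None, False),
        "delta_plfa_permil": ("float", -1000.0, None, False),
    },
}

_CATS = {"event": _EVENTS, "habitat": set(HABITATS)}


def config_hash(obj) -> str:
    """Short stable hash of a pydantic model / dict for output provenance."""
    if hasattr(obj, "model_dump"):
        obj = obj.model_dump()
    blob = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def validate_table(table, schema: str, path: str = "<memory>") -> pd.DataFrame:
    """Validate a DataFrame (or CSV path) against a named schema.

    Returns the typed table; raises :class:`SchemaError` with file, row and
    column on the first violation.
    """
    if schema not in SCHEMAS:
        raise KeyError(f"unknown schema {schema!r}")
    if not isinstance(table, pd.DataFrame):
        path = str(table)
        table = pd.read_csv(table, comment="#")
    spec = SCHEMAS[schema]
    missing = set(spec) - set(table.columns)
    extra = set(table.columns) - set(spec)
    if missing or extra:
        raise SchemaError(
            f"{path}: column mismatch (missing={sorted(missing)}, "
            f"unexpected={sorted(extra)})"
        )
    df = table[list(spec)].copy()
    for col, (kind, lo, hi, allow_nan) in spec.items():
        s = df[col]
        if kind == "int":
            try:
                df[col] = s.astype(int)
            except (ValueError, TypeError) as exc:
                raise SchemaError(f"{path}: column {col}: not integer ({exc})")
            s = df[col]
        elif kind == "float":
            try:
                df[col] = s.astype(float)
            except (ValueError, TypeError) as exc:
                raise SchemaError(f"{path}: column {col}: not numeric ({exc})")
            s = df[col]
        elif kind.startswith("cat:"):
            allowed = _CATS[kind.split(":", 1)[1]]
            for i, v in enumerate(s):
                if v not in allowed:
                    raise SchemaError(
                        f"{path}: row {i}, column {col}: {v!r} not in {sorted(allowed)}"
                    )
            continue
        else:  # str
            if not allow_nan:
                for i, v in enumerate(s):
                    if v is None or (isinstance(v, float) and math.isnan(v)):
                        raise SchemaError(f"{path}: row {i}, column {col}: missing")
            continue
        vals = s.to_numpy(dtype=float)
        nan = np.isnan(vals)
        if nan.any() and not allow_nan:
            i = int(np.argmax(nan))
            raise SchemaError(f"{path}: row {i}, column {col}: NaN not allowed")
        ok = np.ones(len(vals), dtype=bool)
        if lo is not None:
            ok &= nan | (vals >= lo)
        if hi is not None:
            ok &= nan | (vals <= hi)
        if not ok.all():
            i = int(np.argmax(~ok))
            raise SchemaError(
                f"{path}: row {i}, column {col}: value {vals[i]} outside "
                f"[{lo}, {hi}]"
            )
    return df


def write_table(df: pd.DataFrame, path, schema: str,
                metadata: dict | None = None) -> Path:
    """Validate and write a table with ``# key = value`` comment headers."""
    df = validate_table(df, schema, path=str(path)) if len(df) else df
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="") as fh:
        fh.write(f"# schema = {schema}\n")
        for k, v in sorted((metadata or {}).items()):
            fh.write(f"# {k} = {v}\n")
        df.to_csv(fh, index=False)
    return path


def read_table(path, schema: str) -> pd.DataFrame:
    return validate_table(pd.read_csv(path, comment="#"), schema, path=str(path))


def read_headspace(path) -> list[HeadspaceSeries]:
    """Read headspace.csv back into per-bottle series objects."""
    df = read_table(path, "headspace")
    out = []
    for (tid, rep), g in df.groupby(["treatment_id", "replicate"], sort=False):
        g = g.sort_values("time_h")
        t = g["time_h"].to_numpy()
        if len(t) > 1 and not np.all(np.diff(t) > 0):
            raise SchemaError(f"{path}: {tid}/{rep}: time not strictly increasing")
        out.append(
            HeadspaceSeries(
                treatment_id=tid,
                replicate=int(rep),
                time=t,
                ch4=g["ch4_ppmv"].to_numpy(),
                ch4_13f=g["ch4_13f"].to_numpy(),
                co2=g["co2_ppmv"].to_numpy(),
                delta_co2=g["delta_co2_permil"].to_numpy(),
                event=list(g["event"]),
                vented_co2_13c=g["vented_13c_ug"].to_numpy(),
            )
        )
    return out


def read_endpoints(endpoints_path, plfa_path=None) -> list[SedimentEndpoint]:
    """Read endpoints.csv (and optionally plfa.csv) into endpoint objects."""
    df = read_table(endpoints_path, "endpoints")
    plfa: dict[tuple, list[PlfaRecord]] = {}
    if plfa_path is not None:
        pf = read_table(plfa_path, "plfa")
        for _, r in pf.iterrows():
            plfa.setdefault((r["treatment_id"], int(r["replicate"])), []).append(
                PlfaRecord(
                    compound=r["compound"],
                    n_carbons=int(r["n_carbons"]),
                    concentration=float(r["conc_ng_per_g"]),
                    delta_fame=float(r["delta_fame_permil"]),
                )
            )
    out = []
    for _, r in df.iterrows():
        key = (r["treatment_id"], int(r["replicate"]))
        out.append(
            SedimentEndpoint(
                treatment_id=r["treatment_id"],
                replicate=int(r["replicate"]),
                toc=float(r["toc_pct"]),
                delta_toc=float(r["delta_toc_permil"]),
                delta_methanol=float(r["delta_methanol_permil"]),
                plfa_records=plfa.get(key, []),
            )
        )
    return out


def read_plfa(path) -> pd.DataFrame:
    return read_table(path, "plfa")
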