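"""Plain-text instrument CSV schemas with provenance headers.

Every instrument file is a comma-separated table with a declared column
schema; writers can prepend ``# key: value`` provenance comment lines
(input hashes, config hash, package version) which readers skip.  Dates
are ISO-8601, water potentials MPa (<= 0), masses g.  Malformed numeric
cells (including comma decimal separators) are rejected with the first
offending row named, never silently coerced.
"""

from __future__ import annotations

import hashlib
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__

__all__ = ["SCHEMAS", "read_csv", "write_csv", "file_sha256",
           "SchemaError"]


class SchemaError(ValueError):
    """An instrument file violates its declared schema."""


#: column name -> kind ("num", "str", "date") per schema.
SCHEMAS: dict[str, dict[str, str]] = {
    "drying": {
        "branch_id": "str", "species": "str", "step": "num",
        "sm_g": "num", "dm_g": "num",
        "fm_before_cut_g": "num", "excised_leaf_mass_g": "num",
        "psi_leaf1_mpa": "num", "psi_leaf2_mpa": "num"},
    "pneumatron_trace": {
        "branch_id": "str", "step": "num", "time_s": "num",
        "pressure_kpa": "num"},
    "pneumatron_steps": {
        "branch_id": "str", "species": "str", "step": "num",
        "psi_mpa": "num"},
    "desiccation": {
        "leaf_id": "str", "species": "str", "time_s": "num", "mass_g": "num",
        "area_projected_m2": "num", "t_c": "num", "rh": "num",
        "p_amb_kpa": "num"},
    "osmometry": {
        "tree_id": "str", "species": "str", "osmolality_mmol_kg": "num"},
    "morphology": {
        "tree_id": "str", "species": "str", "leaf_id": "str",
        "area_cm2": "num", "dry_mass_g": "num"},
    "wood": {
        "branch_id": "str", "species": "str", "dry_mass_g": "num",
        "fresh_volume_cm3": "num"},
    "gas": {
        "curve_id": "str", "species": "str", "kind": "str", "driver": "num",
        "a_umol_m2_s": "num", "ci_ppm": "num"},
    "dendro": {
        "tree_id": "str", "species": "str", "date": "date",
        "circumference_mm": "num"},
    "water_potential": {
        "tree_id": "str", "species": "str", "date": "date",
        "psi_pd": "num", "psi_md": "num", "soil_psi_15cm": "num",
        "soil_psi_30cm": "num", "soil_psi_45cm": "num"},
}

#: schemas whose date column must increase strictly within each group.
_MONOTONE_DATES = {"dendro": "tree_id", "water_potential": "tree_id"}


def file_sha256(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


def read_csv(path, schema: str) -> pd.DataFrame:
    """Read and validate one instrument CSV."""
    if schema not in SCHEMAS:
        raise KeyError(f"unknown schema '{schema}'")
    spec = SCHEMAS[schema]
    df = pd.read_csv(path, comment="#", dtype=str,
                     skip_blank_lines=True)
    missing = set(spec) - set(df.columns)
    if missing:
        raise SchemaError(
            f"{path}: missing column(s) {sorted(missing)} for schema "
            f"'{schema}'")
    for col, kind in spec.items():
        if kind == "num":
            converted = pd.to_numeric(df[col], errors="coerce")
            bad = converted.isna() & df[col].notna()
            if bad.any():
                row = int(np.flatnonzero(bad)[0])
                raise SchemaError(
                    f"{path}: non-numeric value '{df[col].iloc[row]}' in "
                    f"column '{col}' at data row {row + 1}")
            df[col] = converted
        elif kind == "date":
            try:
                df[col] = pd.to_datetime(df[col], format="ISO8601")
            except ValueError as err:
                raise SchemaError(
                    f"{path}: unparseable ISO-8601 date in column "
                    f"'{col}': {err}") from err
    group = _MONOTONE_DATES.get(schema, "absent")
    if group != "absent":
        date_col = next(c for c, k in spec.items() if k == "date")
        groups = df.groupby(group) if group else [(None, df)]
        for gid, sub in groups:
            diffs = sub[date_col].diff().dropna()
            if (diffs <= pd.Timedelta(0)).any():
                row = int(sub.index[1:][diffs <= pd.Timedelta(0)][0])
                raise SchemaError(
                    f"{path}: dates not strictly increasing "
                    f"(group {gid!r}) at data row {row + 1}")
    return df


def write_csv(df: pd.DataFrame, path, schema: str | None = None,
              provenance: dict | None = None) -> None:
    """Write one CSV, optionally validated and with a provenance header."""
    if schema is not None:
        spec = SCHEMAS[schema]
        missing = set(spec) - set(df.columns)
        if missing:
            raise SchemaError(
                f"refusing to write {path}: missing column(s) "
                f"{sorted(missing)}")
        df = df[[c for c in spec] + [c for c in df.columns if c not in spec]]
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    header = {"writer": f"hydrotraits {__version__}"}
    header.update(provenance or {})
    lines = "".join(f"# {k}: {v}\n" for k, v in header.items())
    with open(path, "w") as fh:
        fh.write(lines)
        out = df.copy()
        for col in out.columns:
            if pd.api.types.is_datetime64_any_dtype(out[col]):
                out[col] = out[col].dt.strftime("%Y-%m-%d")
        out.to_csv(fh, index=False)
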