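"""Reading and writing of gas tables and result tables.

The pipeline's universal input is a long-format CSV with columns
``treatment, flask, is_blank, time_h, gas`` (raw mL per flask). Output
tables are CSV with leading ``#``-comment provenance lines (read them
back with ``pandas.read_csv(..., comment="#")``).
"""

from __future__ import annotations

import hashlib
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "read_gas_table",
    "write_gas_table",
    "curves_by_treatment",
    "format_pvalue",
    "write_result_table",
]

REQUIRED_COLUMNS = ("treatment", "flask", "is_blank", "time_h", "gas")


def read_gas_table(path: str | Path) -> pd.DataFrame:
    """Read and validate a long-format raw gas CSV.

    Checks the schema, numeric types, duplicate (flask, time) records
    and strictly increasing times per flask; validation errors carry the
    offending flask ids and 1-based data row numbers.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    table = pd.read_csv(path, comment="#", float_precision="round_trip")
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"{path.name}: missing required column(s) {missing}")
    for col in ("time_h", "gas"):
        coerced = pd.to_numeric(table[col], errors="coerce")
        bad = table.index[coerced.isna() & table[col].notna()]
        if len(bad):
            rows = [int(i) + 2 for i in bad[:5]]  # +2: header + 1-based
            raise ValueError(
                f"{path.name}: non-numeric {col!r} values at file line(s) {rows}"
            )
        if coerced.isna().any():
            rows = [int(i) + 2 for i in table.index[coerced.isna()][:5]]
            raise ValueError(f"{path.name}: missing {col!r} at file line(s) {rows}")
        table[col] = coerced
    table["is_blank"] = table["is_blank"].astype(bool)
    table["treatment"] = table["treatment"].astype(str)
    table["flask"] = table["flask"].astype(str)
    dupes = table.duplicated(subset=["flask", "time_h"])
    if dupes.any():
        rows = [int(i) + 2 for i in table.index[dupes][:5]]
        raise ValueError(
            f"{path.name}: duplicate (flask, time_h) records at file line(s) {rows}"
        )
    for flask, g in table.groupby("flask", sort=False):
        t = g.sort_index()["time_h"].to_numpy()
        if t.size and (t[0] < 0 or np.any(np.diff(t) <= 0)):
            raise ValueError(
                f"{path.name}: flask {flask!r} times must be non-negative and "
                "strictly increasing"
            )
    return table


def write_gas_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write a raw gas table as CSV plus a YAML provenance sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, index=False)
    provenance = table.attrs.get("provenance")
    if provenance is not None:
        sidecar = path.with_suffix(path.suffix + ".provenance.yaml")
        sidecar.write_text(yaml.safe_dump(provenance, sort_keys=True))


def curves_by_treatment(curves) -> dict[str, list]:
    """Group GasCurve objects by treatment label, preserving order."""
    groups: dict[str, list] = {}
    for c in curves:
        groups.setdefault(c.treatment_id, []).append(c)
    return groups


def format_pvalue(p: float, floor: float = 1e-4) -> str:
    """Display convention for p-values: below the floor print '<0.0001'."""
    if not np.isfinite(p):
        return "NA"
    if p < floor:
        return f"<{floor:.4f}"
    return f"{p:.4f}"


def provenance_header(meta: dict[str, object]) -> str:
    payload = yaml.safe_dump(meta, sort_keys=True).strip().splitlines()
    return "".join(f"# {line}\n" for line in payload)


def config_hash(obj: object) -> str:
    blob = yaml.safe_dump(obj, sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def write_result_table(
    table: pd.DataFrame, path: str | Path, meta: dict[str, object], index: bool = True
) -> None:
    """Write a result table with leading provenance comment lines."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(provenance_header(meta))
        table.to_csv(fh, index=index)
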