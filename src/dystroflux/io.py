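"""Tabular I/O with schema validation and provenance headers.

All pipeline tables are RFC-4180 CSV, UTF-8, one header row, units
encoded in column names (``vo2_ml_h``), timestamps ISO-8601 wall-clock
(the light-cycle logic needs clock time).  Output files carry ``#``
comment metadata lines (tool version, seed, config hash) that readers
skip.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd

__all__ = ["SchemaError", "validate_table", "read_table", "write_table", "SCHEMAS"]


class SchemaError(ValueError):
    """A table fails schema validation; the message lists every violation."""


def _nonneg(col: str) -> Callable[[pd.DataFrame], list[str]]:
    def check(df: pd.DataFrame) -> list[str]:
        bad = np.flatnonzero(pd.to_numeric(df[col], errors="coerce") < 0)
        return [f"{col} negative at row {i}" for i in bad[:5]]

    return check


def _positive(col: str) -> Callable[[pd.DataFrame], list[str]]:
    def check(df: pd.DataFrame) -> list[str]:
        bad = np.flatnonzero(~(pd.to_numeric(df[col], errors="coerce") > 0))
        return [f"{col} must be positive; offending row {i}" for i in bad[:5]]

    return check


def _in_set(col: str, allowed: tuple) -> Callable[[pd.DataFrame], list[str]]:
    def check(df: pd.DataFrame) -> list[str]:
        bad = df.index[~df[col].isin(allowed)]
        return [f"{col}={df[col].loc[i]!r} at row {i} not in {allowed}" for i in bad[:5]]

    return check


def _feeder_monotone(df: pd.DataFrame) -> list[str]:
    feeder = pd.to_numeric(df["feeder_g"]).to_numpy()
    refill = (
        df["refill"].astype(bool).to_numpy()
        if "refill" in df.columns
        else np.zeros(len(df), bool)
    )
    rises = np.flatnonzero(np.diff(feeder) > 1e-9) + 1
    out = []
    for i in rises:
        if not refill[i]:
            ts = df["timestamp"].iloc[i] if "timestamp" in df.columns else f"row {i}"
            out.append(f"feeder refill without flag at {ts}")
    return out[:5]


def _timestamps_uniform(df: pd.DataFrame) -> list[str]:
    ts = pd.to_datetime(df["timestamp"], errors="coerce")
    if ts.isna().any():
        return [f"unparseable timestamp at row {int(ts.isna().idxmax())}"]
    d = ts.diff().dropna().dt.total_seconds().to_numpy()
    if len(d) and (np.any(d <= 0) or not np.allclose(d, d[0])):
        return ["timestamps not strictly increasing and uniformly spaced"]
    return []


SCHEMAS: dict[str, dict] = {
    "cohort": {
        "required": ["animal_id", "genotype", "age_group", "weight_g", "ffm_g", "fat_g"],
        "checks": [
            _in_set("genotype", ("mdx", "control")),
            _in_set("age_group", ("juvenile", "adult")),
            _positive("weight_g"),
            _positive("ffm_g"),
            _nonneg("fat_g"),
        ],
    },
    "trace": {
        "required": [
            "timestamp", "vo2_ml_h", "vco2_ml_h", "x_counts", "z_counts",
            "feeder_g", "spill_g",
        ],
        "checks": [
            _timestamps_uniform,
            _nonneg("vo2_ml_h"),
            _nonneg("vco2_ml_h"),
            _nonneg("x_counts"),
            _nonneg("z_counts"),
            _nonneg("spill_g"),
            _feeder_monotone,
        ],
    },
    "enrichments": {
        "required": [
            "animal_id", "e_d5_phe_mpe", "e_d4_tyr_mpe", "e_d2_tyr_mpe",
            "i_phe", "i_tyr",
        ],
        "checks": [
            _positive("e_d5_phe_mpe"),
            _nonneg("e_d4_tyr_mpe"),
            _positive("e_d2_tyr_mpe"),
            _positive("i_phe"),
            _positive("i_tyr"),
        ],
    },
    "flooding": {
        "required": [
            "animal_id", "muscle", "s_a_blood", "s_a_tissue", "s_b_tp",
            "s_b_mp", "t_label_min",
        ],
        "checks": [
            _in_set(
                "muscle",
                ("gastrocnemius", "quadriceps", "soleus", "tibialis_anterior",
                 "diaphragm", "heart"),
            ),
            _positive("s_a_blood"),
            _positive("s_a_tissue"),
            _nonneg("s_b_tp"),
            _nonneg("s_b_mp"),
            _positive("t_label_min"),
        ],
    },
}


def validate_table(table: pd.DataFrame | str | Path, schema_name: str) -> pd.DataFrame:
    """Validate a table (or CSV path) against a named schema.

    Returns the validated DataFrame; raises :class:`SchemaError` listing
    missing columns and row-level violations (with row numbers).
    """
    if schema_name not in SCHEMAS:
        raise ValueError(f"unknown schema {schema_name!r}")
    df = read_table(table) if not isinstance(table, pd.DataFrame) else table
    schema = SCHEMAS[schema_name]
    problems = [f"missing column {c!r}" for c in schema["required"] if c not in df.columns]
    if not problems:
        for check in schema["checks"]:
            problems.extend(check(df))
    if problems:
        raise SchemaError(
            f"table failed {schema_name!r} schema: " + "; ".join(problems)
        )
    return df


def read_table(path: str | Path, **kwargs) -> pd.DataFrame:
    """Read a pipeline CSV, skipping ``#`` metadata lines."""
    return pd.read_csv(path, comment="#", **kwargs)


def _config_hash(meta: dict) -> str:
    return hashlib.sha1(
        json.dumps(meta, sort_keys=True, default=str).encode()
    ).hexdigest()[:12]


def write_table(
    df: pd.DataFrame, path: str | Path, seed: int | None = None, **meta
) -> Path:
    """Write a CSV with a provenance metadata header."""
    from . import __version__

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    header = [f"# dystroflux v{__version__}"]
    if seed is not None:
        header.append(f"# seed={seed}")
    if meta:
        header.append(f"# config_hash={_config_hash(meta)}")
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write("\n".join(header) + "\n")
        df.to_csv(fh, index=False)
    return path
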