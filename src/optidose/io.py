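"""Patient-table and configuration I/O.

Patient tables are plain CSV with header ``id, x1..xQ, dose, E, T``; E and
T are coded 0/1 and missing values are not allowed (imputation is out of
scope).  Doses are written with 6 significant digits, UTF-8, "." decimal.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .utility import UtilityConfig, UtilityMatrix

__all__ = [
    "read_patient_table",
    "write_patient_table",
    "load_yaml",
    "utility_config_from_dict",
]


def read_patient_table(path: str | Path) -> pd.DataFrame:
    """Read and validate a patient CSV (columns id, x1..xQ, dose, E, T)."""
    table = pd.read_csv(path)
    required = {"id", "dose", "E", "T"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"patient table missing columns: {sorted(missing)}")
    x_cols = [c for c in table.columns if c.startswith("x") and c[1:].isdigit()]
    if not x_cols:
        raise ValueError("patient table has no covariate columns x1..xQ")
    use = ["id"] + sorted(x_cols, key=lambda c: int(c[1:])) + ["dose", "E", "T"]
    table = table[use]
    if table.isna().any().any():
        bad = table.columns[table.isna().any()].tolist()
        raise ValueError(f"missing values in columns {bad}; imputation is out of scope")
    if not np.isin(table[["E", "T"]].to_numpy(), [0, 1]).all():
        raise ValueError("E and T must be coded 0/1")
    return table


def write_patient_table(table: pd.DataFrame, path: str | Path) -> None:
    table = table.copy()
    table["dose"] = table["dose"].map(lambda v: float(f"{v:.6g}"))
    x_cols = [c for c in table.columns if c.startswith("x")]
    for c in x_cols:
        table[c] = table[c].map(lambda v: float(f"{v:.6g}"))
    table.to_csv(path, index=False)


def load_yaml(path: str | Path) -> dict:
    with open(path, "r", encoding="utf-8") as fh:
        return yaml.safe_load(fh) or {}


def utility_config_from_dict(block: dict) -> UtilityConfig:
    """Build a UtilityConfig from a config block with keys
    {omega1, omega2, rule, tox_threshold, tox_multiplier, delta, d_fix}."""
    matrix = UtilityMatrix.from_omegas(
        float(block.get("omega1", 0.5)), float(block.get("omega2", 0.5))
    )
    return UtilityConfig(
        matrix=matrix,
        rule=block.get("rule", "base"),
        tox_threshold=float(block.get("tox_threshold", 0.3)),
        tox_multiplier=float(block.get("tox_multiplier", 2.0)),
        delta=float(block.get("delta", 0.1)),
        d_fix=(None if block.get("d_fix") is None else float(block["d_fix"])),
    )
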