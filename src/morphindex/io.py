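"""Delimited-text IO for morphometry tables and run artifacts.

Tables are TAB-separated with one row per subject-by-timepoint, matching
the layout of the standard segmentation-stats table exporters; columns are
canonicalised on read so files with shuffled column order parse
identically.
"""

from __future__ import annotations

import hashlib
import json
import platform
from pathlib import Path

import numpy as np
import pandas as pd

from .features import (
    ALL_FEATURES,
    DIAGNOSES,
    ICV_COLUMN,
    ID_COLUMN,
    META_COLUMNS,
    TIMEPOINT_COLUMN,
    TIMEPOINTS,
)
from .preprocessing import FeatureMismatchError, validate_morphometry

CANONICAL_COLUMNS = (
    [ID_COLUMN, TIMEPOINT_COLUMN]
    + list(META_COLUMNS)
    + [ICV_COLUMN]
    + list(ALL_FEATURES)
)


def write_morphometry(table: pd.DataFrame, path: str | Path) -> None:
    """Write a cohort table as TSV in canonical column order."""
    cols = [c for c in CANONICAL_COLUMNS if c in table.columns]
    extra = [c for c in table.columns if c not in cols]
    table[cols + extra].to_csv(path, sep="\t", index=False)


def read_morphometry(path: str | Path) -> pd.DataFrame:
    """Read and validate a cohort TSV; returns the canonically ordered table.

    Errors name missing feature columns, malformed numerics, duplicated
    subject-by-timepoint rows and unknown diagnosis or timepoint codes.
    """
    table = pd.read_csv(
        path, sep="\t", dtype={ID_COLUMN: str}, float_precision="round_trip"
    )
    if "mci_status" in table.columns:
        table["mci_status"] = table["mci_status"].fillna("").astype(str)
    missing_req = [c for c in (ID_COLUMN, TIMEPOINT_COLUMN, ICV_COLUMN) if c not in table.columns]
    if missing_req:
        raise FeatureMismatchError(f"missing required columns: {missing_req}")
    for col in list(ALL_FEATURES) + [ICV_COLUMN]:
        if col in table.columns and not np.issubdtype(table[col].dtype, np.number):
            raise ValueError(f"column {col!r} contains non-numeric values")
    validate_morphometry(table)
    bad_tp = set(table[TIMEPOINT_COLUMN].unique()) - set(TIMEPOINTS)
    if bad_tp:
        raise ValueError(f"unknown timepoint codes: {sorted(bad_tp)} (expected {TIMEPOINTS})")
    if "dx" in table.columns:
        bad_dx = set(table["dx"].dropna().unique()) - set(DIAGNOSES)
        if bad_dx:
            raise ValueError(f"unknown diagnosis codes: {sorted(bad_dx)} (expected {DIAGNOSES})")
    cols = [c for c in CANONICAL_COLUMNS if c in table.columns]
    extra = [c for c in table.columns if c not in cols]
    return table[cols + extra]


def config_hash(config: dict) -> str:
    """Stable short hash of a JSON-serialisable configuration."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_manifest(path: str | Path, config: dict, outputs: dict[str, str]) -> dict:
    """Write the machine-readable run manifest; returns the manifest dict."""
    manifest = {
        "config": config,
        "config_hash": config_hash(config),
        "outputs": outputs,
        "versions": {
            "python": platform.python_version(),
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }
    Path(path).write_text(json.dumps(manifest, indent=1, default=str))
    return manifest
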