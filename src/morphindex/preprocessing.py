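"""Morphometry preprocessing: hemisphere averaging, ICV normalisation and
frozen autoscaling.

The scaling statistics are estimated once on the training table and then
re-applied verbatim to any new table; transforming new data never mutates
the stored parameters.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .features import (
    ALL_FEATURES,
    ICV_COLUMN,
    ID_COLUMN,
    MIDLINE_FEATURES,
    PAIRED_FEATURES,
    TIMEPOINT_COLUMN,
    VOLUME_FEATURES,
)


class FeatureMismatchError(ValueError):
    """Raised when a table's feature columns do not match the canonical set."""


def validate_morphometry(table: pd.DataFrame, require_icv: bool = True) -> None:
    """Check a morphometry table against the canonical feature contract.

    Raises :class:`FeatureMismatchError` listing missing/extra features, and
    ``ValueError`` for duplicated subject-by-timepoint rows or non-positive
    ICV.
    """
    missing = [f for f in ALL_FEATURES if f not in table.columns]
    if missing:
        raise FeatureMismatchError(f"missing feature columns: {missing}")
    if require_icv:
        if ICV_COLUMN not in table.columns:
            raise FeatureMismatchError(f"missing required column: {ICV_COLUMN!r}")
        if (table[ICV_COLUMN] <= 0).any():
            bad = table.loc[table[ICV_COLUMN] <= 0, ID_COLUMN].tolist()
            raise ValueError(f"icv must be > 0; offending subjects: {bad}")
    if ID_COLUMN in table.columns and TIMEPOINT_COLUMN in table.columns:
        dups = table.duplicated([ID_COLUMN, TIMEPOINT_COLUMN])
        if dups.any():
            raise ValueError(
                "duplicated subject x timepoint rows: "
                f"{table.loc[dups, [ID_COLUMN, TIMEPOINT_COLUMN]].values.tolist()}"
            )
    feats = table[list(ALL_FEATURES)]
    if feats.isna().any().any():
        bad = feats.columns[feats.isna().any()].tolist()
        raise ValueError(f"missing values are not supported (no imputation): {bad}")


def average_hemispheres(raw_table: pd.DataFrame) -> pd.DataFrame:
    """Collapse per-hemisphere columns (``lh_*``/``rh_*``) to their mean.

    Paired structures must be present for both hemispheres; midline
    structures are passed through unchanged under their plain name.
    Non-feature columns (ids, metadata, ``icv``) are preserved.
    """
    out = raw_table.copy()
    for feat in PAIRED_FEATURES:
        left, right = f"lh_{feat}", f"rh_{feat}"
        has_l, has_r = left in out.columns, right in out.columns
        if has_l != has_r:
            missing = right if has_l else left
            raise FeatureMismatchError(
                f"feature {feat!r}: missing hemisphere partner column {missing!r}"
            )
        if has_l:
            out[feat] = (out[left] + out[right]) / 2.0
            out = out.drop(columns=[left, right])
        elif feat not in out.columns:
            raise FeatureMismatchError(f"feature {feat!r} absent from raw table")
    for feat in MIDLINE_FEATURES:
        if feat not in out.columns:
            raise FeatureMismatchError(f"midline feature {feat!r} absent from raw table")
    return out


def normalize_icv(table: pd.DataFrame) -> pd.DataFrame:
    """Divide every volume feature by the subject's intracranial volume.

    Thickness features are left untouched.  The ``icv`` column is retained
    so the operation is idempotent only by convention: apply it exactly once.
    """
    if ICV_COLUMN not in table.columns:
        raise FeatureMismatchError(f"missing required column: {ICV_COLUMN!r}")
    icv = table[ICV_COLUMN].to_numpy(dtype=float)
    if (icv <= 0).any():
        raise ValueError("icv must be strictly positive for every row")
    out = table.copy()
    vols = list(VOLUME_FEATURES)
    out[vols] = out[vols].to_numpy(dtype=float) / icv[:, None]
    return out


@dataclass(frozen=True)
class ScalingParams:
    """Frozen per-feature centring/scaling statistics from a training table."""

    features: tuple[str, ...]
    mean: np.ndarray
    sd: np.ndarray
    icv_normalized: tuple[str, ...] = tuple(VOLUME_FEATURES)
    provenance: str = "unspecified"

    def __post_init__(self) -> None:
        if len(self.features) != len(self.mean) or len(self.features) != len(self.sd):
            raise ValueError("features, mean and sd must have equal length")
        if (self.sd <= 0).any():
            bad = [f for f, s in zip(self.features, self.sd) if s <= 0]
            raise ValueError(f"non-positive SD for features: {bad}")

    def to_dict(self) -> dict:
        return {
            "features": list(self.features),
            "mean": self.mean.tolist(),
            "sd": self.sd.tolist(),
            "icv_normalized": list(self.icv_normalized),
            "provenance": self.provenance,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ScalingParams":
        return cls(
            features=tuple(d["features"]),
            mean=np.asarray(d["mean"], dtype=float),
            sd=np.asarray(d["sd"], dtype=float),
            icv_normalized=tuple(d["icv_normalized"]),
            provenance=d.get("provenance", "unspecified"),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "ScalingParams":
        return cls.from_dict(json.loads(Path(path).read_text()))


def fit_scaler(
    train: pd.DataFrame,
    features: tuple[str, ...] | list[str] = ALL_FEATURES,
    provenance: str = "unspecified",
) -> ScalingParams:
    """Estimate per-feature mean and sample SD (n-1 denominator).

    ``train`` must already be ICV-normalised when volume features are
    included.  Constant features are rejected by name.
    """
    feats = tuple(features)
    missing = [f for f in feats if f not in train.columns]
    if missing:
        raise FeatureMismatchError(f"missing feature columns: {missing}")
    X = train[list(feats)].to_numpy(dtype=float)
    if X.shape[0] < 2:
        raise ValueError("need at least 2 rows to estimate scaling")
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    if (sd == 0).any():
        bad = [f for f, s in zip(feats, sd) if s == 0]
        raise ValueError(f"constant features cannot be autoscaled: {bad}")
    icv_norm = tuple(f for f in feats if f in set(VOLUME_FEATURES))
    return ScalingParams(
        features=feats, mean=mean, sd=sd, icv_normalized=icv_norm, provenance=provenance
    )


def apply_scaler(params: ScalingParams, table: pd.DataFrame) -> np.ndarray:
    """Autoscale a table with *training* statistics; returns an (n, p) array.

    The table must carry exactly the training feature set (extra non-feature
    columns are ignored); any symmetric difference is reported.
    """
    have = set(c for c in table.columns if c in set(params.features))
    want = set(params.features)
    if have != want:
        raise FeatureMismatchError(
            f"feature-set mismatch; missing={sorted(want - have)} "
            f"(table also lacks nothing else relevant)"
        )
    X = table[list(params.features)].to_numpy(dtype=float)
    return (X - params.mean) / params.sd


def invert_scaler(params: ScalingParams, X_scaled: np.ndarray) -> pd.DataFrame:
    """Undo :func:`apply_scaler`; returns a DataFrame in feature units."""
    X = np.asarray(X_scaled, dtype=float) * params.sd + params.mean
    return pd.DataFrame(X, columns=list(params.features))
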