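"""Two-block hierarchical severity-index model.

Cortical thickness and (ICV-normalised) subcortical volumes are modelled
by separate OPLS block models; their latent scores are pooled, autoscaled
and fed to a top-level OPLS whose predicted class value is the per-subject
index.  The index tends towards 1 for target-class-like morphometry and 0
for reference-class-like morphometry; values strictly above 0.5 label a
subject AD-like, everything else CTL-like.  The index is the raw top-model
prediction and is deliberately not clipped to [0, 1].
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import opls
from .features import (
    ALL_FEATURES,
    ID_COLUMN,
    THICKNESS_FEATURES,
    TIMEPOINT_COLUMN,
    VOLUME_FEATURES,
)
from .preprocessing import (
    ScalingParams,
    apply_scaler,
    fit_scaler,
    normalize_icv,
    validate_morphometry,
)

AD_LIKE_THRESHOLD = 0.5
AD_LIKE = "AD-like"
CTL_LIKE = "CTL-like"


def pattern_label(index: np.ndarray | float) -> np.ndarray | str:
    """AD-like strictly above the 0.5 cut; ties are CTL-like."""
    arr = np.asarray(index, dtype=float)
    labels = np.where(arr > AD_LIKE_THRESHOLD, AD_LIKE, CTL_LIKE)
    return labels if arr.ndim else str(labels)


@dataclass
class HierarchicalConfig:
    """Fitting configuration for the hierarchical model."""

    n_ortho_thickness: int | None = None   # None -> select by CV on training data
    n_ortho_volume: int | None = None
    n_ortho_top: int = 0
    max_ortho: int = 3
    block_scores: str = "all"              # "all" | "predictive"
    k_folds: int = 7
    seed: int = 0

    def to_dict(self) -> dict:
        return dict(self.__dict__)

    @classmethod
    def from_dict(cls, d: dict) -> "HierarchicalConfig":
        return cls(**d)


@dataclass
class HierarchicalIndexModel:
    """Fitted two-block hierarchy with every scaler frozen from training."""

    thickness_block: opls.OPLSModel
    volume_block: opls.OPLSModel
    thickness_scaler: ScalingParams
    volume_scaler: ScalingParams
    block_score_scaler: ScalingParams
    top_model: opls.OPLSModel
    config: HierarchicalConfig
    partition: dict = field(
        default_factory=lambda: {
            "thickness": list(THICKNESS_FEATURES),
            "volume": list(VOLUME_FEATURES),
        }
    )

    def to_dict(self) -> dict:
        return {
            "thickness_block": self.thickness_block.to_dict(),
            "volume_block": self.volume_block.to_dict(),
            "thickness_scaler": self.thickness_scaler.to_dict(),
            "volume_scaler": self.volume_scaler.to_dict(),
            "block_score_scaler": self.block_score_scaler.to_dict(),
            "top_model": self.top_model.to_dict(),
            "config": self.config.to_dict(),
            "partition": self.partition,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "HierarchicalIndexModel":
        return cls(
            thickness_block=opls.OPLSModel.from_dict(d["thickness_block"]),
            volume_block=opls.OPLSModel.from_dict(d["volume_block"]),
            thickness_scaler=ScalingParams.from_dict(d["thickness_scaler"]),
            volume_scaler=ScalingParams.from_dict(d["volume_scaler"]),
            block_score_scaler=ScalingParams.from_dict(d["block_score_scaler"]),
            top_model=opls.OPLSModel.from_dict(d["top_model"]),
            config=HierarchicalConfig.from_dict(d["config"]),
            partition=d["partition"],
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict()))

    @classmethod
    def load(cls, path: str | Path) -> "HierarchicalIndexModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


def _block_score_matrix(
    model: opls.OPLSModel, X_scaled: np.ndarray, which: str, prefix: str
) -> tuple[np.ndarray, list[str]]:
    t_pred = model.predictive_score(X_scaled)
    cols = [t_pred[:, None]]
    names = [f"{prefix}_t_pred"]
    if which == "all" and model.n_ortho:
        t_o = model.orthogonal_scores(X_scaled)
        cols.append(t_o)
        names += [f"{prefix}_t_ortho{k + 1}" for k in range(model.n_ortho)]
    return np.hstack(cols), names


def _fit_block(
    table_norm: pd.DataFrame,
    y: np.ndarray,
    features: tuple[str, ...],
    n_ortho: int | None,
    config: HierarchicalConfig,
    provenance: str,
) -> tuple[opls.OPLSModel, ScalingParams]:
    scaler = fit_scaler(table_norm, features=features, provenance=provenance)
    X = apply_scaler(scaler, table_norm)
    if n_ortho is None:
        n_ortho, _ = opls.select_n_ortho(
            table_norm[list(features)].to_numpy(dtype=float),
            y,
            k_folds=config.k_folds,
            seed=config.seed,
            max_ortho=config.max_ortho,
        )
    model = opls.fit_opls(X, y, n_ortho=n_ortho, feature_names=features)
    return model, scaler


def fit_hierarchical(
    train: pd.DataFrame, y: np.ndarray, config: HierarchicalConfig | None = None
) -> HierarchicalIndexModel:
    """Fit the full hierarchy on baseline target/reference training rows.

    ``train`` is a raw morphometry table (feature units, with ``icv``);
    ICV normalisation, both block scalers, the block-score scaler and all
    three OPLS models are estimated here and frozen.
    """
    config = config or HierarchicalConfig()
    validate_morphometry(train)
    y = np.asarray(y, dtype=float).ravel()
    if len(y) != len(train):
        raise ValueError("y length must match training rows")
    norm = normalize_icv(train)

    thickness_block, thickness_scaler = _fit_block(
        norm, y, THICKNESS_FEATURES, config.n_ortho_thickness, config, "train:thickness"
    )
    volume_block, volume_scaler = _fit_block(
        norm, y, VOLUME_FEATURES, config.n_ortho_volume, config, "train:volume"
    )

    S_thk, names_thk = _block_score_matrix(
        thickness_block, apply_scaler(thickness_scaler, norm), config.block_scores, "thk"
    )
    S_vol, names_vol = _block_score_matrix(
        volume_block, apply_scaler(volume_scaler, norm), config.block_scores, "vol"
    )
    scores = pd.DataFrame(
        np.hstack([S_thk, S_vol]), columns=names_thk + names_vol
    )
    score_scaler = fit_scaler(
        scores, features=tuple(scores.columns), provenance="train:block_scores"
    )
    top = opls.fit_opls(
        apply_scaler(score_scaler, scores),
        y,
        n_ortho=config.n_ortho_top,
        feature_names=tuple(scores.columns),
    )
    return HierarchicalIndexModel(
        thickness_block=thickness_block,
        volume_block=volume_block,
        thickness_scaler=thickness_scaler,
        volume_scaler=volume_scaler,
        block_score_scaler=score_scaler,
        top_model=top,
        config=config,
    )


def _index_values(model: HierarchicalIndexModel, table: pd.DataFrame) -> np.ndarray:
    norm = normalize_icv(table)
    S_thk, names_thk = _block_score_matrix(
        model.thickness_block,
        apply_scaler(model.thickness_scaler, norm),
        model.config.block_scores,
        "thk",
    )
    S_vol, names_vol = _block_score_matrix(
        model.volume_block,
        apply_scaler(model.volume_scaler, norm),
        model.config.block_scores,
        "vol",
    )
    scores = pd.DataFrame(np.hstack([S_thk, S_vol]), columns=names_thk + names_vol)
    return opls.predict_y(model.top_model, apply_scaler(model.block_score_scaler, scores))


def compute_index(model: HierarchicalIndexModel, table: pd.DataFrame) -> pd.DataFrame:
    """Per-row severity index with the AD-like/CTL-like pattern label.

    Accepts any diagnosis and timepoint; the table must carry all 57
    features plus ``icv`` in raw units.
    """
    validate_morphometry(table)
    index = _index_values(model, table)
    out = pd.DataFrame(
        {
            ID_COLUMN: table[ID_COLUMN].to_numpy()
            if ID_COLUMN in table.columns
            else np.arange(len(table)),
            TIMEPOINT_COLUMN: table[TIMEPOINT_COLUMN].to_numpy()
            if TIMEPOINT_COLUMN in table.columns
            else "baseline",
            "index": index,
            "pattern": pattern_label(index),
        }
    )
    return out


def cross_validate_hierarchical(
    train: pd.DataFrame,
    y: np.ndarray,
    config: HierarchicalConfig | None = None,
) -> opls.CVResult:
    """Stratified K-fold CV refitting the *entire* hierarchy per fold.

    Every scaler and every block/top model is re-estimated on each training
    split, so out-of-fold indices carry no leakage from the held-out rows.
    """
    config = config or HierarchicalConfig()
    y = np.asarray(y, dtype=float).ravel()
    folds = opls.stratified_folds(y, config.k_folds, config.seed)
    y_pred = np.empty(len(y))
    for f in range(config.k_folds):
        test = folds == f
        train_rows = train[~test].reset_index(drop=True)
        test_rows = train[test].reset_index(drop=True)
        if np.unique(y[~test]).size < 2:
            raise ValueError(f"fold {f}: training split lacks both classes")
        sub = fit_hierarchical(train_rows, y[~test], config)
        y_pred[test] = _index_values(sub, test_rows)
    return opls.CVResult.from_predictions(y, y_pred, folds)
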