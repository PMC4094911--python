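"""Two-class orthogonal projections to latent structures (single-y OPLS).

Algorithm (single response): the predictive weight is ``w = X'y/||X'y||``.
Each orthogonal component is extracted from the current residual matrix as
the part of the loading ``p = X't/(t't)`` (with ``t = Xw``) that is
orthogonal to ``w``, renormalised; its score/loading pair is deflated from
X and the recursion repeats.  Because ``w`` is proportional to ``X'y`` and
every orthogonal weight is orthogonal to ``w``, every orthogonal score
vector has exactly zero covariance with y, and ``X'y`` is unchanged by the
deflation, so ``w`` is fixed throughout.  After removing ``n_ortho``
components, a single predictive component is fit on the filtered matrix
with an inner univariate regression onto y.

For a single response, training predictions of OPLS with k orthogonal
components coincide with those of a (k+1)-component PLS1 model; the test
suite asserts this against an independent NIPALS oracle.

Model quality is summarised by cross-validated Q2(Y) = 1 - PRESS/SSY with
PRESS the out-of-fold squared prediction error and SSY the total centred
variation of the class-code vector; Q2 above 0.05 is treated as a
significant model.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

Q2_SIGNIFICANCE_THRESHOLD = 0.05


@dataclass
class OPLSModel:
    """Fitted single-y OPLS discriminant model."""

    w: np.ndarray          # predictive weight, unit norm
    p: np.ndarray          # predictive loading
    b: float               # inner regression: y_hat = b * t + y_mean
    y_mean: float
    W_o: np.ndarray        # (n_ortho, p) orthogonal weights, unit norm rows
    P_o: np.ndarray        # (n_ortho, p) orthogonal loadings
    n_ortho: int
    r2y: float
    q2y: float | None = None
    feature_names: tuple[str, ...] | None = None

    def filter_orthogonal(self, X: np.ndarray) -> np.ndarray:
        """Remove the model's orthogonal variation from new scaled rows."""
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        if X.shape[1] != self.w.shape[0]:
            raise ValueError(
                f"column count mismatch: model has {self.w.shape[0]} features, "
                f"input has {X.shape[1]}"
            )
        Xr = X.copy()
        for k in range(self.n_ortho):
            t_o = Xr @ self.W_o[k]
            Xr -= np.outer(t_o, self.P_o[k])
        return Xr

    def orthogonal_scores(self, X: np.ndarray) -> np.ndarray:
        """Sequential orthogonal scores, shape (n, n_ortho)."""
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        Xr = X.copy()
        scores = np.empty((Xr.shape[0], self.n_ortho))
        for k in range(self.n_ortho):
            t_o = Xr @ self.W_o[k]
            scores[:, k] = t_o
            Xr -= np.outer(t_o, self.P_o[k])
        return scores

    def predictive_score(self, X: np.ndarray) -> np.ndarray:
        return self.filter_orthogonal(X) @ self.w

    def to_dict(self) -> dict:
        return {
            "w": self.w.tolist(),
            "p": self.p.tolist(),
            "b": self.b,
            "y_mean": self.y_mean,
            "W_o": self.W_o.tolist(),
            "P_o": self.P_o.tolist(),
            "n_ortho": self.n_ortho,
            "r2y": self.r2y,
            "q2y": self.q2y,
            "feature_names": list(self.feature_names) if self.feature_names else None,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "OPLSModel":
        return cls(
            w=np.asarray(d["w"], dtype=float),
            p=np.asarray(d["p"], dtype=float),
            b=float(d["b"]),
            y_mean=float(d["y_mean"]),
            W_o=np.asarray(d["W_o"], dtype=float).reshape(d["n_ortho"], -1)
            if d["n_ortho"]
            else np.empty((0, len(d["w"]))),
            P_o=np.asarray(d["P_o"], dtype=float).reshape(d["n_ortho"], -1)
            if d["n_ortho"]
            else np.empty((0, len(d["w"]))),
            n_ortho=int(d["n_ortho"]),
            r2y=float(d["r2y"]),
            q2y=d.get("q2y"),
            feature_names=tuple(d["feature_names"]) if d.get("feature_names") else None,
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict()))

    @classmethod
    def load(cls, path: str | Path) -> "OPLSModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass
class CVResult:
    """Pooled out-of-fold predictions and the derived Q2(Y)."""

    fold_assignment: np.ndarray
    y_actual: np.ndarray
    y_predicted: np.ndarray
    press: float
    ssy: float
    q2y: float

    @classmethod
    def from_predictions(
        cls, y: np.ndarray, y_pred: np.ndarray, folds: np.ndarray | None = None
    ) -> "CVResult":
        y = np.asarray(y, dtype=float)
        y_pred = np.asarray(y_pred, dtype=float)
        if folds is None:
            folds = np.zeros(len(y), dtype=int)
        press = float(np.sum((y - y_pred) ** 2))
        ssy = float(np.sum((y - y.mean()) ** 2))
        if ssy <= 0:
            raise ValueError("SSY must be positive (y is constant)")
        return cls(
            fold_assignment=np.asarray(folds),
            y_actual=y,
            y_predicted=y_pred,
            press=press,
            ssy=ssy,
            q2y=1.0 - press / ssy,
        )


def _check_Xy(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.shape[0] != y.shape[0]:
        raise ValueError("X and y row counts differ")
    if np.unique(y).size < 2:
        raise ValueError("y must contain both classes")
    return X, y


def fit_opls(
    X: np.ndarray,
    y: np.ndarray,
    n_ortho: int = 0,
    feature_names: tuple[str, ...] | None = None,
) -> OPLSModel:
    """Fit the single-y OPLS model on a column-autoscaled matrix.

    ``y`` carries the class codes (0 for the reference class, 1 for the
    target class).  ``n_ortho`` orthogonal components are extracted before
    the single predictive component.
    """
    X, y = _check_Xy(X, y)
    n, p = X.shape
    if n_ortho < 0:
        raise ValueError("n_ortho must be >= 0")
    max_rank = min(n - 1, p)
    if n_ortho >= max_rank:
        raise ValueError(f"n_ortho={n_ortho} too large for matrix of rank <= {max_rank}")
    y_mean = float(y.mean())
    yc = y - y_mean

    w = X.T @ yc
    w_norm = np.linalg.norm(w)
    if w_norm <= 1e-12:
        raise ValueError("X carries no covariance with y; cannot fit")
    w = w / w_norm

    Xr = X.copy()
    W_o = np.empty((n_ortho, p))
    P_o = np.empty((n_ortho, p))
    for k in range(n_ortho):
        t = Xr @ w
        pk = Xr.T @ t / (t @ t)
        w_o = pk - (w @ pk) * w
        norm_o = np.linalg.norm(w_o)
        if norm_o <= 1e-10:
            raise ValueError(
                f"orthogonal component {k + 1} degenerate; reduce n_ortho"
            )
        w_o /= norm_o
        t_o = Xr @ w_o
        p_o = Xr.T @ t_o / (t_o @ t_o)
        Xr = Xr - np.outer(t_o, p_o)
        W_o[k] = w_o
        P_o[k] = p_o

    t = Xr @ w
    tt = float(t @ t)
    if tt <= 1e-12:
        raise ValueError("predictive score collapsed; reduce n_ortho")
    p_load = Xr.T @ t / tt
    b = float(t @ yc) / tt
    fitted = b * t + y_mean
    ssy = float(yc @ yc)
    r2y = 1.0 - float(np.sum((y - fitted) ** 2)) / ssy
    return OPLSModel(
        w=w,
        p=p_load,
        b=b,
        y_mean=y_mean,
        W_o=W_o,
        P_o=P_o,
        n_ortho=n_ortho,
        r2y=r2y,
        feature_names=tuple(feature_names) if feature_names is not None else None,
    )


def predict_y(model: OPLSModel, X_new: np.ndarray) -> np.ndarray:
    """Predict the continuous class value for scaled new rows.

    Rows must be scaled with the *training* scaling parameters.  Output is
    unbounded (values outside [0, 1] are legitimate).
    """
    t = model.predictive_score(X_new)
    return model.b * t + model.y_mean


def q2_significant(q2y: float) -> bool:
    """Strictly-greater-than-0.05 model significance convention."""
    return q2y > Q2_SIGNIFICANCE_THRESHOLD


def stratified_folds(y: np.ndarray, k_folds: int, seed: int) -> np.ndarray:
    """Seeded stratified fold assignment; returns fold index per row."""
    y = np.asarray(y)
    if k_folds < 2:
        raise ValueError("k_folds must be >= 2")
    skf = StratifiedKFold(n_splits=k_folds, shuffle=True, random_state=seed)
    folds = np.empty(len(y), dtype=int)
    for i, (_, test_idx) in enumerate(skf.split(np.zeros((len(y), 1)), y)):
        folds[test_idx] = i
    return folds


def cross_validate(
    X: np.ndarray,
    y: np.ndarray,
    n_ortho: int = 0,
    k_folds: int = 7,
    seed: int = 0,
    rescale_in_fold: bool = True,
) -> CVResult:
    """K-fold cross-validation of the OPLS fit with no leakage.

    When ``rescale_in_fold`` is set (the default), ``X`` is taken to be in
    raw (post-ICV-normalisation) units and the column autoscaling is
    re-estimated on each training split only; otherwise ``X`` is used as
    given.  Folds are stratified by class and deterministic given ``seed``.
    """
    X, y = _check_Xy(X, y)
    folds = stratified_folds(y, k_folds, seed)
    y_pred = np.empty(len(y))
    for f in range(k_folds):
        test = folds == f
        train = ~test
        if np.unique(y[train]).size < 2:
            raise ValueError(f"fold {f}: training split lacks both classes")
        X_tr, X_te = X[train], X[test]
        if rescale_in_fold:
            mu = X_tr.mean(axis=0)
            sd = X_tr.std(axis=0, ddof=1)
            if (sd == 0).any():
                raise ValueError(f"fold {f}: constant feature in training split")
            X_tr = (X_tr - mu) / sd
            X_te = (X_te - mu) / sd
        model = fit_opls(X_tr, y[train], n_ortho=n_ortho)
        y_pred[test] = predict_y(model, X_te)
    return CVResult.from_predictions(y, y_pred, folds)


def select_n_ortho(
    X: np.ndarray,
    y: np.ndarray,
    k_folds: int = 7,
    seed: int = 0,
    max_ortho: int = 5,
    rescale_in_fold: bool = True,
) -> tuple[int, list[float]]:
    """Greedy orthogonal-component count selection on the training set.

    Starting from zero, a further orthogonal component is accepted while it
    increases cross-validated Q2(Y).  Returns the chosen count and the Q2
    trajectory (index k = Q2 with k orthogonal components).
    """
    q2_path: list[float] = []
    best = 0
    for k in range(max_ortho + 1):
        try:
            cv = cross_validate(
                X, y, n_ortho=k, k_folds=k_folds, seed=seed,
                rescale_in_fold=rescale_in_fold,
            )
        except ValueError:
            break
        q2_path.append(cv.q2y)
        if k == 0:
            continue
        if cv.q2y > q2_path[best]:
            best = k
        else:
            break
    return best, q2_path


def variable_importance(model: OPLSModel) -> pd.DataFrame:
    """Rank features by the magnitude of the predictive loading.

    Returns the full ranking as a DataFrame with columns ``feature``,
    ``loading`` and ``rank`` (1 = most important).
    """
    names = (
        list(model.feature_names)
        if model.feature_names is not None
        else [f"x{i}" for i in range(len(model.p))]
    )
    order = np.argsort(-np.abs(model.p), kind="stable")
    return pd.DataFrame(
        {
            "feature": [names[i] for i in order],
            "loading": model.p[order],
            "rank": np.arange(1, len(order) + 1),
        }
    )
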