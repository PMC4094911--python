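"""Classification performance: confusion-count metrics, empirical ROC/AUC
and the combined classification/prediction report.

Sensitivity and specificity are reported as integer percents with half-up
rounding, always recomputed from raw counts.  The ROC is the empirical
curve over all distinct index thresholds with trapezoidal AUC and the
Hanley-McNeil standard error.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .features import BASELINE, FOLLOWUP, ID_COLUMN, TIMEPOINT_COLUMN
from .hierarchical import AD_LIKE, AD_LIKE_THRESHOLD


def _round_half_up(x: float) -> int:
    return int(Decimal(repr(x)).quantize(Decimal("1"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ConfusionCounts:
    """Counts of AD-like/CTL-like labels within the true-positive and
    true-negative groups of a two-group comparison."""

    ad_like_pos: int
    ctl_like_pos: int
    ad_like_neg: int
    ctl_like_neg: int

    def __post_init__(self) -> None:
        for name, v in self.__dict__.items():
            if v < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def n_pos(self) -> int:
        return self.ad_like_pos + self.ctl_like_pos

    @property
    def n_neg(self) -> int:
        return self.ad_like_neg + self.ctl_like_neg


def sensitivity(counts: ConfusionCounts) -> int:
    """Percent of the positive group labelled AD-like (half-up integer)."""
    if counts.n_pos == 0:
        raise ValueError("positive group is empty")
    return _round_half_up(100.0 * counts.ad_like_pos / counts.n_pos)

def specificity(counts: ConfusionCounts) -> int:
    """Percent of the negative group labelled CTL-like (half-up integer)."""
    if counts.n_neg == 0:
        raise ValueError("negative group is empty")
    return _round_half_up(100.0 * counts.ctl_like_neg / counts.n_neg)


@dataclass
class ROCResult:
    """Empirical ROC curve with trapezoidal AUC and Hanley-McNeil SE."""

    thresholds: np.ndarray
    fpr: np.ndarray            # 1 - specificity, non-decreasing
    tpr: np.ndarray            # sensitivity, non-decreasing
    auc: float
    auc_se: float


def _hanley_mcneil_se(auc: float, n_pos: int, n_neg: int) -> float:
    q1 = auc / (2 - auc)
    q2 = 2 * auc**2 / (1 + auc)
    var = (
        auc * (1 - auc)
        + (n_pos - 1) * (q1 - auc**2)
        + (n_neg - 1) * (q2 - auc**2)
    ) / (n_pos * n_neg)
    return float(np.sqrt(max(var, 0.0)))


def empirical_auc(values: np.ndarray, labels: np.ndarray) -> ROCResult:
    """Empirical ROC of a continuous score against binary labels.

    ``labels`` are truthy for the positive class.  Ties in the score are
    handled by sweeping only distinct thresholds, which makes the
    trapezoidal area equal to the tie-corrected pair-counting statistic
    U / (n_pos * n_neg).
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels).astype(bool)
    n_pos = int(labels.sum())
    n_neg = int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    order = np.argsort(-values, kind="stable")
    v_sorted = values[order]
    l_sorted = labels[order]
    # cumulative counts at each distinct threshold (score >= threshold -> positive call)
    distinct = np.r_[np.diff(v_sorted) != 0, True]
    tp = np.cumsum(l_sorted)[distinct]
    fp = np.cumsum(~l_sorted)[distinct]
    tpr = np.r_[0.0, tp / n_pos]
    fpr = np.r_[0.0, fp / n_neg]
    thresholds = np.r_[np.inf, v_sorted[distinct]]
    auc = float(np.trapezoid(tpr, fpr))
    return ROCResult(
        thresholds=thresholds,
        fpr=fpr,
        tpr=tpr,
        auc=auc,
        auc_se=_hanley_mcneil_se(auc, n_pos, n_neg),
    )


def counts_from_index(
    index: np.ndarray,
    is_positive: np.ndarray,
    threshold: float = AD_LIKE_THRESHOLD,
) -> ConfusionCounts:
    """Confusion counts at the (strictly-above) AD-like cut."""
    index = np.asarray(index, dtype=float)
    is_positive = np.asarray(is_positive).astype(bool)
    ad_like = index > threshold
    return ConfusionCounts(
        ad_like_pos=int((ad_like & is_positive).sum()),
        ctl_like_pos=int((~ad_like & is_positive).sum()),
        ad_like_neg=int((ad_like & ~is_positive).sum()),
        ctl_like_neg=int((~ad_like & ~is_positive).sum()),
    )


def _report_block(
    dataset: str,
    comparison: str,
    pos_name: str,
    neg_name: str,
    index: np.ndarray,
    is_positive: np.ndarray,
) -> list[dict]:
    counts = counts_from_index(index, is_positive)
    roc = empirical_auc(index, is_positive)
    shared = {
        "dataset": dataset,
        "comparison": comparison,
        "sensitivity": sensitivity(counts),
        "specificity": specificity(counts),
        "auc": round(roc.auc, 3),
        "auc_se": round(roc.auc_se, 3),
    }
    return [
        {
            **shared,
            "group": pos_name,
            "n": counts.n_pos,
            "ad_like": counts.ad_like_pos,
            "ctl_like": counts.ctl_like_pos,
        },
        {
            **shared,
            "group": neg_name,
            "n": counts.n_neg,
            "ad_like": counts.ad_like_neg,
            "ctl_like": counts.ctl_like_neg,
        },
    ]


def classification_report(
    indices: pd.DataFrame,
    meta: pd.DataFrame,
    cv_indices: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Build the combined classification/prediction table.

    ``indices`` holds direct model-application indices (columns
    ``subject_id``, ``timepoint``, ``index``); ``meta`` is per-subject with
    ``dx`` and, for MCI subjects, ``mci_status`` ('c'/'nc').  When
    ``cv_indices`` (out-of-fold training predictions at baseline) is given,
    a training-set block is emitted from those, mirroring the convention
    that baseline AD/CTL metrics come from cross-validation while follow-up
    and all MCI metrics come from direct application of the final model.
    """
    meta_cols = [ID_COLUMN, "dx"] + (["mci_status"] if "mci_status" in meta else [])
    meta_u = meta[meta_cols].drop_duplicates(ID_COLUMN)
    joined = indices.merge(meta_u, on=ID_COLUMN, how="left", validate="many_to_one")
    if joined["dx"].isna().any():
        bad = joined.loc[joined["dx"].isna(), ID_COLUMN].tolist()
        raise ValueError(f"subjects missing metadata: {bad}")

    rows: list[dict] = []
    if cv_indices is not None:
        cv = cv_indices.merge(meta_u, on=ID_COLUMN, how="left", validate="many_to_one")
        cv = cv[cv["dx"].isin(["AD", "CTL"])]
        rows += _report_block(
            "training (baseline, CV)",
            "AD vs CTL",
            "AD",
            "CTL",
            cv["index"].to_numpy(),
            (cv["dx"] == "AD").to_numpy(),
        )

    for tp, label in ((BASELINE, "longitudinal baseline"), (FOLLOWUP, "1-year")):
        sub = joined[joined[TIMEPOINT_COLUMN] == tp]
        adctl = sub[sub["dx"].isin(["AD", "CTL"])]
        if len(adctl) and adctl["dx"].nunique() == 2:
            rows += _report_block(
                label, "AD vs CTL", "AD", "CTL",
                adctl["index"].to_numpy(), (adctl["dx"] == "AD").to_numpy(),
            )
        if "mci_status" in sub.columns:
            mci = sub[(sub["dx"] == "MCI") & (sub["mci_status"].isin(["c", "nc"]))]
            if len(mci) and mci["mci_status"].nunique() == 2:
                rows += _report_block(
                    label, "MCI-c vs MCI-nc", "MCI-c", "MCI-nc",
                    mci["index"].to_numpy(), (mci["mci_status"] == "c").to_numpy(),
                )
    return pd.DataFrame(
        rows,
        columns=[
            "dataset", "comparison", "group", "n", "ad_like", "ctl_like",
            "sensitivity", "specificity", "auc", "auc_se",
        ],
    )
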