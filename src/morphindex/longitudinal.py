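"""Longitudinal index derivations and stratified statistical comparisons.

Annual rate of change is the raw 12-month difference of the index
(no per-subject interval scaling); the average index is the mean of the
baseline and 12-month values and drives the pattern-of-atrophy
stratification.  All p-values are reported raw, without multiplicity
correction.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .features import BASELINE, FOLLOWUP, ID_COLUMN, TIMEPOINT_COLUMN
from .hierarchical import AD_LIKE_THRESHOLD, pattern_label

logger = logging.getLogger(__name__)


def derive_longitudinal(indices: pd.DataFrame) -> pd.DataFrame:
    """Per-subject baseline/12-month index pairs with derived quantities.

    Subjects missing either timepoint are dropped (the count is logged);
    duplicate timepoint rows for a subject are an error.  Output columns:
    ``subject_id``, ``index_baseline``, ``index_m12``, ``annual_rate``,
    ``average_index``, ``pattern``.
    """
    if indices.duplicated([ID_COLUMN, TIMEPOINT_COLUMN]).any():
        dup = indices[indices.duplicated([ID_COLUMN, TIMEPOINT_COLUMN], keep=False)]
        raise ValueError(
            f"duplicate subject x timepoint rows: {dup[ID_COLUMN].unique().tolist()}"
        )
    wide = indices.pivot(index=ID_COLUMN, columns=TIMEPOINT_COLUMN, values="index")
    for tp in (BASELINE, FOLLOWUP):
        if tp not in wide.columns:
            wide[tp] = np.nan
    n_total = len(wide)
    wide = wide.dropna(subset=[BASELINE, FOLLOWUP])
    dropped = n_total - len(wide)
    if dropped:
        logger.info("derive_longitudinal: dropped %d subjects missing a timepoint", dropped)
    out = pd.DataFrame(
        {
            ID_COLUMN: wide.index.to_numpy(),
            "index_baseline": wide[BASELINE].to_numpy(),
            "index_m12": wide[FOLLOWUP].to_numpy(),
        }
    )
    out["annual_rate"] = out["index_m12"] - out["index_baseline"]
    out["average_index"] = (out["index_baseline"] + out["index_m12"]) / 2.0
    out["pattern"] = pattern_label(out["average_index"].to_numpy())
    return out.reset_index(drop=True)


def descriptive_summary(values: np.ndarray) -> dict:
    """Mean, SD, median, min, max, Q1, Q3 of one group's values.

    A single-value group reports SD 0 with ``sd_degenerate`` flagged.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("empty group")
    degenerate = v.size < 2
    return {
        "n": int(v.size),
        "mean": float(v.mean()),
        "sd": 0.0 if degenerate else float(v.std(ddof=1)),
        "sd_degenerate": degenerate,
        "median": float(np.median(v)),
        "min": float(v.min()),
        "max": float(v.max()),
        "q1": float(np.percentile(v, 25)),
        "q3": float(np.percentile(v, 75)),
    }


def summarize_groups(df: pd.DataFrame, value: str, by: list[str]) -> pd.DataFrame:
    """Tidy per-group descriptive summaries of one column."""
    rows = []
    for keys, sub in df.groupby(by, dropna=False):
        keys = keys if isinstance(keys, tuple) else (keys,)
        rows.append({**dict(zip(by, keys)), **descriptive_summary(sub[value].to_numpy())})
    return pd.DataFrame(rows)


@dataclass
class ComparisonResult:
    """One stratified statistical comparison."""

    test: str
    groups: tuple[str, str]
    n: tuple[int, int]
    statistic: float
    p_value: float
    sided: str

    def as_row(self) -> dict:
        return {
            "test": self.test,
            "group_a": self.groups[0],
            "group_b": self.groups[1],
            "n_a": self.n[0],
            "n_b": self.n[1],
            "statistic": self.statistic,
            "p_value": self.p_value,
            "sided": self.sided,
        }


def rank_sum_test(
    a: np.ndarray,
    b: np.ndarray,
    alternative: str = "two-sided",
    labels: tuple[str, str] = ("a", "b"),
) -> ComparisonResult:
    """Mann-Whitney U: exact enumeration for small tie-free samples,
    tie-corrected normal approximation otherwise."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    small = max(a.size, b.size) <= 20
    no_ties = np.unique(np.r_[a, b]).size == a.size + b.size
    method = "exact" if (small and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative=alternative, method=method)
    return ComparisonResult(
        test=f"mann-whitney ({method})",
        groups=labels,
        n=(a.size, b.size),
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        sided=alternative,
    )


def _exact_spearman_p(rx: np.ndarray, ry: np.ndarray) -> float:
    """Two-sided exact permutation p for Spearman rho (small n).

    Enumerates all n! pairings of the rank vectors in chunks; |rho| is
    monotone in |sum(cx * permuted(cy))| so only dot products are compared.
    """
    n = len(rx)
    cx = rx - rx.mean()
    cy = ry - ry.mean()
    obs = abs(np.dot(cx, cy))
    count = 0
    total = 0
    perms = itertools.permutations(range(n))
    while True:
        chunk = list(itertools.islice(perms, 100_000))
        if not chunk:
            break
        scores = np.abs(cy[np.array(chunk)] @ cx)
        count += int((scores >= obs - 1e-12).sum())
        total += len(chunk)
    return count / total


def rank_correlation(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Spearman rho (average ranks for ties) and its p-value.

    Exact permutation p for n <= 10; t approximation otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need paired samples with n >= 3")
    if np.unique(x).size < 2 or np.unique(y).size < 2:
        raise ValueError("constant input")
    rho, p_t = stats.spearmanr(x, y)
    if x.size <= 10:
        rx = stats.rankdata(x)
        ry = stats.rankdata(y)
        return float(rho), float(_exact_spearman_p(rx, ry))
    return float(rho), float(p_t)


def paired_change_test(
    baseline: np.ndarray,
    m12: np.ndarray,
    alternative: str = "two-sided",
) -> dict:
    """Paired t-test and Wilcoxon signed-rank on 12-month change.

    ``alternative='greater'`` tests for an increase at 12 months.  Both
    tests are reported because the source analyses mix parametric and
    non-parametric matched-pair tests.
    """
    baseline = np.asarray(baseline, dtype=float)
    m12 = np.asarray(m12, dtype=float)
    if baseline.size != m12.size:
        raise ValueError("paired samples must have equal length")
    if baseline.size < 2:
        raise ValueError("need n >= 2 pairs")
    diff = m12 - baseline
    t_res = stats.ttest_rel(m12, baseline, alternative=alternative)
    if np.allclose(diff, 0):
        w_stat, w_p = 0.0, 1.0
    else:
        mode = "exact" if baseline.size <= 25 else "approx"
        w_res = stats.wilcoxon(m12, baseline, alternative=alternative, mode=mode)
        w_stat, w_p = float(w_res.statistic), float(w_res.pvalue)
    return {
        "n": int(baseline.size),
        "mean_change": float(diff.mean()),
        "t_statistic": float(t_res.statistic),
        "t_p": float(t_res.pvalue),
        "wilcoxon_statistic": w_stat,
        "wilcoxon_p": w_p,
        "sided": alternative,
    }


def rate_anova(df: pd.DataFrame, value: str = "annual_rate", by: str = "dx") -> dict:
    """One-way ANOVA of annual rates across diagnostic groups."""
    groups = [sub[value].to_numpy() for _, sub in df.groupby(by)]
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    f, p = stats.f_oneway(*groups)
    return {"f_statistic": float(f), "p_value": float(p), "groups": int(len(groups))}


def zscore(values: np.ndarray) -> np.ndarray:
    """Sample z-score (mean 0, SD 1 with n-1 denominator)."""
    v = np.asarray(values, dtype=float)
    sd = v.std(ddof=1)
    if sd == 0:
        raise ValueError("cannot z-score a constant variable")
    return (v - v.mean()) / sd


def apoe_stratification(
    mci: pd.DataFrame,
    variables: tuple[str, ...] = ("index", "mmse", "cdr_sob", "adas1"),
) -> pd.DataFrame:
    """Carrier vs non-carrier comparison of z-scored timepoint averages.

    ``mci`` must hold MCI subjects with both timepoints and columns
    ``subject_id``, ``timepoint``, ``apoe_e4`` and the requested variables.
    Each variable is averaged over the two timepoints per subject,
    z-scored over the whole MCI sample, and compared between carriers and
    non-carriers with a rank-sum test.
    """
    required = {ID_COLUMN, TIMEPOINT_COLUMN, "apoe_e4"} | set(variables)
    missing = required - set(mci.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    carriers = mci[[ID_COLUMN, "apoe_e4"]].drop_duplicates(ID_COLUMN)
    rows = []
    for var in variables:
        wide = mci.pivot(index=ID_COLUMN, columns=TIMEPOINT_COLUMN, values=var)
        wide = wide.dropna(subset=[BASELINE, FOLLOWUP])
        avg = (wide[BASELINE] + wide[FOLLOWUP]) / 2.0
        z = pd.Series(zscore(avg.to_numpy()), index=avg.index, name="z")
        merged = z.reset_index().merge(carriers, on=ID_COLUMN)
        z_car = merged.loc[merged["apoe_e4"] == 1, "z"].to_numpy()
        z_non = merged.loc[merged["apoe_e4"] == 0, "z"].to_numpy()
        if z_car.size == 0 or z_non.size == 0:
            raise ValueError(f"{var}: one APOE stratum is empty")
        cmp = rank_sum_test(z_car, z_non, labels=("e4+", "e4-"))
        rows.append(
            {
                "variable": var,
                "n_carrier": z_car.size,
                "n_noncarrier": z_non.size,
                "median_z_carrier": float(np.median(z_car)),
                "median_z_noncarrier": float(np.median(z_non)),
                "statistic": cmp.statistic,
                "p_value": cmp.p_value,
                "test": cmp.test,
            }
        )
    return pd.DataFrame(rows)


def pattern_comparisons(longit: pd.DataFrame, meta: pd.DataFrame) -> pd.DataFrame:
    """Per-diagnosis AD-like vs CTL-like comparison of annual rates."""
    meta_u = meta[[ID_COLUMN, "dx"]].drop_duplicates(ID_COLUMN)
    df = longit.merge(meta_u, on=ID_COLUMN, validate="one_to_one")
    rows = []
    for dx, sub in df.groupby("dx"):
        ad_like = sub.loc[sub["pattern"] == "AD-like", "annual_rate"].to_numpy()
        ctl_like = sub.loc[sub["pattern"] == "CTL-like", "annual_rate"].to_numpy()
        if ad_like.size == 0 or ctl_like.size == 0:
            continue
        cmp = rank_sum_test(ad_like, ctl_like, labels=("AD-like", "CTL-like"))
        rows.append({"dx": dx, **cmp.as_row()})
    return pd.DataFrame(rows)
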