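"""Independent reference implementations used only to check the package.

These are written directly from textbook definitions and never share code
with the implementation under test.
"""

from __future__ import annotations

import itertools

import numpy as np


def pls1_nipals_fitted(X: np.ndarray, y: np.ndarray, n_components: int) -> np.ndarray:
    """Training fitted values of an A-component NIPALS PLS1 regression.

    X must be column-scaled already; y is centred internally.  Classic
    deflation recursion: w = X'y/||X'y||, t = Xw, p = X't/(t't),
    q = y't/(t't), deflate both X and y.
    """
    X = np.asarray(X, dtype=float).copy()
    y = np.asarray(y, dtype=float).ravel().copy()
    y_mean = y.mean()
    yr = y - y_mean
    fitted = np.full(len(y), y_mean)
    for _ in range(n_components):
        w = X.T @ yr
        w /= np.linalg.norm(w)
        t = X @ w
        tt = t @ t
        p = X.T @ t / tt
        q = (yr @ t) / tt
        fitted += q * t
        X = X - np.outer(t, p)
        yr = yr - q * t
    return fitted


def pair_counting_auc(values: np.ndarray, labels: np.ndarray) -> float:
    """Brute-force tie-corrected AUC: U/(n_pos * n_neg) over all pairs."""
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels).astype(bool)
    pos = values[labels]
    neg = values[~labels]
    u = 0.0
    for vp in pos:
        for vn in neg:
            if vp > vn:
                u += 1.0
            elif vp == vn:
                u += 0.5
    return u / (len(pos) * len(neg))


def exact_rank_sum_p_two_sided(a: np.ndarray, b: np.ndarray) -> float:
    """Exact two-sided Mann-Whitney p by enumerating all label assignments."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    pooled = np.r_[a, b]
    n_a = len(a)

    def u_stat(x, y):
        u = 0.0
        for vx in x:
            for vy in y:
                if vx > vy:
                    u += 1.0
                elif vx == vy:
                    u += 0.5
        return u

    obs = u_stat(a, b)
    centre = n_a * len(b) / 2.0
    obs_dev = abs(obs - centre)
    count = 0
    total = 0
    for comb in itertools.combinations(range(len(pooled)), n_a):
        mask = np.zeros(len(pooled), dtype=bool)
        mask[list(comb)] = True
        u = u_stat(pooled[mask], pooled[~mask])
        if abs(u - centre) >= obs_dev - 1e-12:
            count += 1
        total += 1
    return count / total


def spearman_no_ties(x: np.ndarray, y: np.ndarray) -> float:
    """Classic d-squared formula; valid only without ties."""
    from scipy.stats import rankdata

    rx = rankdata(x)
    ry = rankdata(y)
    n = len(x)
    d2 = float(np.sum((rx - ry) ** 2))
    return 1.0 - 6.0 * d2 / (n * (n**2 - 1))


def cohens_d(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sample standardized mean difference with pooled sample SD."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = len(a), len(b)
    pooled = np.sqrt(
        ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    )
    return (a.mean() - b.mean()) / pooled
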