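"""Two-group multivariate tests on reduced tangent coordinates.

Tangent coordinates of k 2-D landmarks are rank-deficient (rank at most
2k - 4), so covariance-based tests require a reduced orthonormal basis;
:func:`reduce_dimension` provides it.  The Box-M test gates the choice
between the unequal-covariance James resampling test and the classical
Hotelling T-squared.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "HomogeneityResult",
    "MeanShapeTestResult",
    "reduce_dimension",
    "box_m_test",
    "james_test",
    "hotelling_test",
    "t_test_from_summary",
]


@dataclass(frozen=True)
class HomogeneityResult:
    """Box-M covariance-homogeneity test outcome (F approximation)."""

    box_m: float
    f_stat: float
    df1: float
    df2: float
    p_value: float
    reduced_dim: int


@dataclass(frozen=True)
class MeanShapeTestResult:
    """Two-sample mean test outcome on reduced tangent scores."""

    statistic: float
    p_value: float
    method: str  # "james_resampling" or "hotelling"
    n_resamples: int
    seed: int | None
    reduced_dim: int


def reduce_dimension(
    group_a: np.ndarray,
    group_b: np.ndarray,
    target_dim: int | None = None,
) -> tuple[tuple[np.ndarray, np.ndarray], np.ndarray]:
    """Project two coordinate blocks onto a common principal-component basis.

    The basis is computed from the pooled, group-mean-centered data (so
    between-group mean differences do not inflate the retained subspace's
    variance ordering); both groups are then projected onto it.

    Parameters
    ----------
    group_a, group_b
        n_i x d coordinate blocks sharing the column count d.
    target_dim
        Number of components to retain; ``None`` ("auto") keeps the
        effective rank of the centered pooled data.

    Returns
    -------
    (scores_a, scores_b), basis
        Reduced blocks and the d x r orthonormal basis.
    """
    group_a = np.asarray(group_a, dtype=float)
    group_b = np.asarray(group_b, dtype=float)
    if group_a.shape[1] != group_b.shape[1]:
        raise ValueError("groups must share the same number of columns")
    n1, n2 = group_a.shape[0], group_b.shape[0]
    centered = np.vstack(
        [group_a - group_a.mean(axis=0), group_b - group_b.mean(axis=0)]
    )
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    tol = s.max(initial=0.0) * max(centered.shape) * np.finfo(float).eps
    eff_rank = int(np.sum(s > max(tol, 1e-10)))
    cap = min(eff_rank, n1 + n2 - 2)
    r = cap if target_dim is None else min(int(target_dim), cap)
    if r >= min(n1, n2) - 1:
        raise ValueError(
            f"retained dimension {r} >= min group size - 1 = {min(n1, n2) - 1}; "
            "group covariances would be singular — pass a smaller target_dim"
        )
    basis = vt[:r].T  # d x r, orthonormal columns
    return (group_a @ basis, group_b @ basis), basis


def _unbiased_cov(x: np.ndarray) -> np.ndarray:
    xc = x - x.mean(axis=0)
    return xc.T @ xc / (x.shape[0] - 1)


def box_m_test(group_a: np.ndarray, group_b: np.ndarray) -> HomogeneityResult:
    """Box's M test of covariance equality with the Box (1949) F approximation.

    M = (N - g) ln|S_pooled| - sum_i (n_i - 1) ln|S_i| with unbiased
    covariance estimates; the F approximation is reported because it is
    the form the downstream report prints.
    """
    groups = [np.asarray(g, dtype=float) for g in (group_a, group_b)]
    p = groups[0].shape[1]
    if groups[1].shape[1] != p:
        raise ValueError("groups must share dimensionality")
    ns = [g.shape[0] for g in groups]
    for i, (g, n) in enumerate(zip(groups, ns), start=1):
        if n <= p + 1:
            raise ValueError(f"group {i}: n={n} must exceed dim+1={p + 1}")
    g_count = len(groups)
    N = sum(ns)
    covs = [_unbiased_cov(g) for g in groups]
    pooled = sum((n - 1) * c for n, c in zip(ns, covs)) / (N - g_count)
    signs_logdets = [np.linalg.slogdet(c) for c in covs]
    for i, (sign, _) in enumerate(signs_logdets, start=1):
        if sign <= 0:
            raise np.linalg.LinAlgError(f"group {i}: singular within-group covariance")
    sign_p, logdet_p = np.linalg.slogdet(pooled)
    if sign_p <= 0:
        raise np.linalg.LinAlgError("singular pooled covariance")
    M = (N - g_count) * logdet_p - sum(
        (n - 1) * ld for n, (_, ld) in zip(ns, signs_logdets)
    )
    M = max(0.0, float(M))
    inv_terms = sum(1.0 / (n - 1) for n in ns) - 1.0 / (N - g_count)
    c1 = inv_terms * (2 * p**2 + 3 * p - 1) / (6.0 * (p + 1) * (g_count - 1))
    df1 = p * (p + 1) * (g_count - 1) / 2.0
    c2 = (
        (sum(1.0 / (n - 1) ** 2 for n in ns) - 1.0 / (N - g_count) ** 2)
        * (p - 1)
        * (p + 2)
        / (6.0 * (g_count - 1))
    )
    if c2 > c1**2:
        df2 = (df1 + 2) / (c2 - c1**2)
        b = df1 / (1 - c1 - df1 / df2)
        f_stat = M / b
    else:
        df2 = (df1 + 2) / (c1**2 - c2)
        b = df2 / (1 - c1 + 2 / df2)
        f_stat = df2 * M / (df1 * (b - M))
    p_value = float(stats.f.sf(f_stat, df1, df2)) if f_stat > 0 else 1.0
    return HomogeneityResult(
        box_m=M,
        f_stat=float(f_stat),
        df1=float(df1),
        df2=float(df2),
        p_value=p_value,
        reduced_dim=p,
    )


def _james_t2(group_a: np.ndarray, group_b: np.ndarray) -> float:
    n1, n2 = group_a.shape[0], group_b.shape[0]
    d = group_a.mean(axis=0) - group_b.mean(axis=0)
    w = _unbiased_cov(group_a) / n1 + _unbiased_cov(group_b) / n2
    try:
        sol = np.linalg.solve(w, d)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "singular S1/n1 + S2/n2 matrix in James statistic"
        ) from exc
    return float(d @ sol)


def james_test(
    group_a: np.ndarray,
    group_b: np.ndarray,
    n_resamples: int = 999,
    seed: int | None = None,
) -> MeanShapeTestResult:
    """James's unequal-covariance two-sample test with a bootstrap null.

    The statistic is T^2 = d' (S1/n1 + S2/n2)^{-1} d.  The null is built
    by centering each group at its own mean and resampling specimens with
    replacement within group; p = (1 + #{T2* >= T2_obs}) / (1 + B).
    """
    group_a = np.asarray(group_a, dtype=float)
    group_b = np.asarray(group_b, dtype=float)
    p = group_a.shape[1]
    for i, g in enumerate((group_a, group_b), start=1):
        if g.shape[0] <= p + 1:
            raise ValueError(f"group {i}: n={g.shape[0]} must exceed dim+1={p + 1}")
    if n_resamples < 99:
        warnings.warn(
            f"n_resamples={n_resamples} gives coarse p-value resolution",
            RuntimeWarning,
            stacklevel=2,
        )
    t2_obs = _james_t2(group_a, group_b)
    rng = np.random.default_rng(seed)
    ca = group_a - group_a.mean(axis=0)
    cb = group_b - group_b.mean(axis=0)
    n1, n2 = ca.shape[0], cb.shape[0]
    exceed = 0
    for _ in range(n_resamples):
        ia = rng.integers(0, n1, size=n1)
        ib = rng.integers(0, n2, size=n2)
        try:
            t2_star = _james_t2(ca[ia], cb[ib])
        except np.linalg.LinAlgError:
            t2_star = np.inf  # degenerate resample counts against rejection
        if t2_star >= t2_obs:
            exceed += 1
    p_value = (1 + exceed) / (1 + n_resamples)
    return MeanShapeTestResult(
        statistic=t2_obs,
        p_value=float(p_value),
        method="james_resampling",
        n_resamples=n_resamples,
        seed=seed,
        reduced_dim=p,
    )


def hotelling_test(group_a: np.ndarray, group_b: np.ndarray) -> MeanShapeTestResult:
    """Classical two-sample Hotelling T-squared with the exact F transform."""
    group_a = np.asarray(group_a, dtype=float)
    group_b = np.asarray(group_b, dtype=float)
    n1, n2 = group_a.shape[0], group_b.shape[0]
    p = group_a.shape[1]
    d = group_a.mean(axis=0) - group_b.mean(axis=0)
    pooled = (
        (n1 - 1) * _unbiased_cov(group_a) + (n2 - 1) * _unbiased_cov(group_b)
    ) / (n1 + n2 - 2)
    try:
        sol = np.linalg.solve(pooled, d)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError("singular pooled covariance") from exc
    t2 = float(n1 * n2 / (n1 + n2) * (d @ sol))
    df2 = n1 + n2 - p - 1
    if df2 <= 0:
        raise ValueError("not enough observations for the F transform")
    f_stat = t2 * df2 / ((n1 + n2 - 2) * p)
    p_value = float(stats.f.sf(f_stat, p, df2))
    return MeanShapeTestResult(
        statistic=t2,
        p_value=p_value,
        method="hotelling",
        n_resamples=0,
        seed=None,
        reduced_dim=p,
    )


def t_test_from_summary(
    n1: int, mean1: float, sd1: float, n2: int, mean2: float, sd2: float
) -> tuple[float, float, float]:
    """Pooled-variance two-sample t-test from summary statistics.

    Returns (t, df, two-sided p).
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs n >= 2")
    if sd1 <= 0 or sd2 <= 0:
        raise ValueError("standard deviations must be positive")
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / df
    se = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    t = (mean1 - mean2) / se
    p = 2.0 * float(stats.t.sf(abs(t), df))
    return float(t), float(df), p
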