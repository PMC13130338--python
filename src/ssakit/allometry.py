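"""Allometric regression: multivariate fit of tangent scores on centroid size.

Fits V = 1 a' + s b' + E by least squares on the reduced (full-rank)
tangent scores, tests the size effect with Wilks' lambda (exact F for a
single predictor), and summarizes fit with R^2 and MSE.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import stats

from .procrustes import preshape

__all__ = ["AllometryModel", "allometric_regression", "predict_shape_at_size"]


@dataclass(frozen=True)
class AllometryModel:
    """Fitted size-on-shape multivariate regression."""

    slope: np.ndarray  # d
    intercept: np.ndarray  # d
    wilks_lambda: float
    f_stat: float
    df1: int
    df2: int
    p_value: float
    r_squared: float
    mse: float
    use_log_cs: bool
    n: int = 0
    cs_mean: float = field(default=0.0)

    def to_dict(self) -> dict:
        return {
            "slope": self.slope.tolist(),
            "intercept": self.intercept.tolist(),
            "wilks_lambda": self.wilks_lambda,
            "f_stat": self.f_stat,
            "df1": self.df1,
            "df2": self.df2,
            "p_value": self.p_value,
            "r_squared": self.r_squared,
            "mse": self.mse,
            "use_log_cs": self.use_log_cs,
            "n": self.n,
            "cs_mean": self.cs_mean,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


def allometric_regression(
    tangent_scores: np.ndarray,
    cs: np.ndarray,
    use_log_cs: bool = False,
) -> AllometryModel:
    """Regress reduced tangent scores on centroid size.

    Parameters
    ----------
    tangent_scores
        n x d full-rank tangent scores (see ``shape_tests.reduce_dimension``).
    cs
        n positive centroid sizes; the predictor is CS or ln CS.
    use_log_cs
        Use ln CS as the predictor.

    Notes
    -----
    Wilks' lambda = |E'E| / |E'E + H|; with a single predictor the exact
    F transform is F = ((1 - L)/L) ((n - d - 1)/d) on (d, n - d - 1) df.
    R^2 = 1 - tr(E'E)/tr(T'T) against the intercept-only model and
    MSE = tr(E'E)/(n d).
    """
    V = np.asarray(tangent_scores, dtype=float)
    cs = np.asarray(cs, dtype=float)
    n, d = V.shape
    if cs.shape != (n,):
        raise ValueError("cs must be a length-n vector")
    if np.any(cs <= 0):
        raise ValueError("centroid sizes must be positive")
    if d >= n - 2:
        raise ValueError(f"d={d} too large for n={n}: need n > d + 2")
    s = np.log(cs) if use_log_cs else cs
    if np.ptp(s) == 0:
        raise ValueError("zero variance in the size predictor")
    sc = s - s.mean()
    Vc = V - V.mean(axis=0)
    sxx = float(sc @ sc)
    beta = (sc @ Vc) / sxx  # d
    alpha = V.mean(axis=0) - beta * s.mean()
    E = Vc - np.outer(sc, beta)
    EtE = E.T @ E
    TtT = Vc.T @ Vc
    # H is rank one for a single predictor, so |E'E|/|E'E + H| collapses to
    # 1/(1 + sxx b'(E'E)^{-1} b) — numerically stable even as E -> 0
    if np.allclose(beta, 0.0):
        lam = 1.0
    else:
        try:
            t_hl = sxx * float(beta @ np.linalg.solve(EtE, beta))
        except np.linalg.LinAlgError:
            t_hl = np.inf  # effect lies in the null space of a singular E'E
        lam = 0.0 if not np.isfinite(t_hl) else 1.0 / (1.0 + max(0.0, t_hl))
    lam = min(1.0, max(0.0, lam))
    df1 = d
    df2 = n - d - 1
    if lam > 0:
        f_stat = (1.0 - lam) / lam * df2 / df1
        p_value = float(stats.f.sf(f_stat, df1, df2))
    else:
        f_stat = np.inf
        p_value = 0.0
    tr_t = float(np.trace(TtT))
    r_squared = 1.0 - float(np.trace(EtE)) / tr_t if tr_t > 0 else 0.0
    r_squared = min(1.0, max(0.0, r_squared))
    mse = float(np.trace(EtE)) / (n * d)
    return AllometryModel(
        slope=beta,
        intercept=alpha,
        wilks_lambda=lam,
        f_stat=float(f_stat),
        df1=df1,
        df2=df2,
        p_value=p_value,
        r_squared=r_squared,
        mse=mse,
        use_log_cs=use_log_cs,
        n=n,
        cs_mean=float(s.mean()),
    )


def predict_shape_at_size(
    model: AllometryModel,
    cs_value: float,
    reference: np.ndarray,
    basis: np.ndarray,
) -> np.ndarray:
    """Reconstruct the fitted mean shape at a given centroid size.

    Maps the fitted tangent score at ``cs_value`` back through the
    reduction basis into 2k tangent coordinates, adds the reference
    preshape, and renormalizes to a unit-CS k x 2 shape.
    """
    if cs_value <= 0:
        raise ValueError("cs_value must be positive")
    reference = np.asarray(reference, dtype=float)
    basis = np.asarray(basis, dtype=float)
    s = np.log(cs_value) if model.use_log_cs else cs_value
    scores = model.intercept + model.slope * s  # d
    full = basis @ scores  # 2k tangent coordinates (x block then y block)
    k = reference.shape[0]
    tangent = np.stack([full[:k], full[k:]], axis=1)
    shape = reference + tangent
    return preshape(shape)
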