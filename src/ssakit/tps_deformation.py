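"""Thin-plate spline warps, expansion-factor grids, and landmark dissimilarity.

Kernel convention: U(r) = r^2 ln r with U(0) = 0.  The warp maps the
source configuration exactly onto the target; bending energy is the
quadratic form w' K w and vanishes iff the target is an affine image of
the source.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "TPSWarp",
    "DeformationGrid",
    "LandmarkDissimilarityTable",
    "fit_tps",
    "evaluate_warp",
    "expansion_grid",
    "landmark_dissimilarity",
    "per_specimen_dissimilarity",
    "warp_jacobian",
]

_MIN_SEPARATION = 1e-9


def _tps_kernel(r: np.ndarray) -> np.ndarray:
    """U(r) = r^2 ln r, with U(0) = 0."""
    out = np.zeros_like(r)
    nz = r > 0
    out[nz] = r[nz] ** 2 * np.log(r[nz])
    return out


@dataclass(frozen=True)
class TPSWarp:
    """A fitted thin-plate spline between two k x 2 configurations.

    ``affine`` is 2 x 3: the 2 x 2 linear part in columns 0-1 and the
    translation in column 2.  ``weights`` is the k x 2 matrix of
    non-affine kernel coefficients.
    """

    source: np.ndarray
    target: np.ndarray
    affine: np.ndarray
    weights: np.ndarray
    bending_energy: float

    @property
    def k(self) -> int:
        return self.source.shape[0]


def fit_tps(source: np.ndarray, target: np.ndarray) -> TPSWarp:
    """Fit the interpolating thin-plate spline mapping source onto target.

    Solves the standard augmented linear system; side conditions
    (sum of weights = 0, source' weights = 0) hold by construction.

    Raises
    ------
    ValueError
        If source landmarks coincide (naming the offending pair) or the
        source is collinear (rank-deficient affine block).
    """
    source = np.asarray(source, dtype=float)
    target = np.asarray(target, dtype=float)
    if source.shape != target.shape or source.ndim != 2 or source.shape[1] != 2:
        raise ValueError("source and target must be matching k x 2 matrices")
    k = source.shape[0]
    if k < 3:
        raise ValueError("need at least 3 landmarks")
    diff = source[:, None, :] - source[None, :, :]
    r = np.sqrt(np.sum(diff**2, axis=-1))
    close = np.argwhere((r < _MIN_SEPARATION) & ~np.eye(k, dtype=bool))
    if close.size:
        i, j = close[0]
        raise ValueError(f"coincident source landmarks {i + 1} and {j + 1} (1-based)")
    P = np.hstack([np.ones((k, 1)), source])  # k x 3
    if np.linalg.matrix_rank(P) < 3:
        raise ValueError("collinear source landmarks: TPS system is rank-deficient")
    K = _tps_kernel(r)
    L = np.zeros((k + 3, k + 3))
    L[:k, :k] = K
    L[:k, k:] = P
    L[k:, :k] = P.T
    rhs = np.zeros((k + 3, 2))
    rhs[:k] = target
    try:
        sol = np.linalg.solve(L, rhs)
    except np.linalg.LinAlgError as exc:
        raise ValueError("singular TPS system") from exc
    weights = sol[:k]  # k x 2
    a = sol[k:]  # 3 x 2: [const; x-coef; y-coef]
    affine = np.zeros((2, 3))
    affine[:, :2] = a[1:].T
    affine[:, 2] = a[0]
    be = float(np.trace(weights.T @ K @ weights))
    return TPSWarp(
        source=source,
        target=target,
        affine=affine,
        weights=weights,
        bending_energy=max(0.0, be),
    )


def evaluate_warp(warp: TPSWarp, points: np.ndarray) -> np.ndarray:
    """Apply the warp to a p x 2 matrix of points."""
    points = np.atleast_2d(np.asarray(points, dtype=float))
    diff = points[:, None, :] - warp.source[None, :, :]  # p x k x 2
    r = np.sqrt(np.sum(diff**2, axis=-1))
    u = _tps_kernel(r)  # p x k
    affine_part = points @ warp.affine[:, :2].T + warp.affine[:, 2]
    return affine_part + u @ warp.weights


def warp_jacobian(warp: TPSWarp, points: np.ndarray) -> np.ndarray:
    """Analytic 2 x 2 Jacobian of the warp at each of p points (p x 2 x 2).

    grad U(|p - s_i|) = (2 ln r + 1)(p - s_i); the gradient vanishes in
    the limit r -> 0, which is used at nodes that coincide with landmarks.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    diff = points[:, None, :] - warp.source[None, :, :]  # p x k x 2
    r = np.sqrt(np.sum(diff**2, axis=-1))  # p x k
    factor = np.zeros_like(r)
    nz = r > 0
    factor[nz] = 2.0 * np.log(r[nz]) + 1.0
    grad = factor[..., None] * diff  # p x k x 2 (d/dp of U)
    # J = A_lin + sum_i w_i outer grad_i
    jac = np.einsum("ic,pid->pcd", warp.weights, grad)
    jac += warp.affine[:, :2][None, :, :]
    return jac


@dataclass(frozen=True)
class DeformationGrid:
    """A lattice over the source plane with warped positions and expansion factors."""

    grid_points: np.ndarray  # g x g x 2
    warped_points: np.ndarray  # g x g x 2
    expansion: np.ndarray  # g x g, Jacobian determinants

    @property
    def log2_expansion(self) -> np.ndarray:
        """log2 of expansion factors (symmetric color scaling); NaN where folded."""
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(self.expansion > 0, np.log2(self.expansion), np.nan)

    def to_dict(self) -> dict:
        return {
            "grid_points": self.grid_points.tolist(),
            "warped_points": self.warped_points.tolist(),
            "expansion": self.expansion.tolist(),
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict()))


def expansion_grid(
    warp: TPSWarp, grid_size: int = 24, margin: float = 0.1
) -> DeformationGrid:
    """Evaluate the warp and its Jacobian determinant on a regular lattice.

    The lattice covers the source bounding box expanded by ``margin``
    (fraction of each side length) on every side.
    """
    if grid_size <= 0:
        raise ValueError("grid_size must be positive")
    lo = warp.source.min(axis=0)
    hi = warp.source.max(axis=0)
    span = hi - lo
    span = np.where(span == 0, 1.0, span)
    lo = lo - margin * span
    hi = hi + margin * span
    xs = np.linspace(lo[0], hi[0], grid_size)
    ys = np.linspace(lo[1], hi[1], grid_size)
    gx, gy = np.meshgrid(xs, ys, indexing="xy")
    pts = np.stack([gx.ravel(), gy.ravel()], axis=1)
    warped = evaluate_warp(warp, pts)
    jac = warp_jacobian(warp, pts)
    det = np.linalg.det(jac)
    return DeformationGrid(
        grid_points=pts.reshape(grid_size, grid_size, 2),
        warped_points=warped.reshape(grid_size, grid_size, 2),
        expansion=det.reshape(grid_size, grid_size),
    )


@dataclass(frozen=True)
class LandmarkDissimilarityTable:
    """Per-landmark dissimilarity between two aligned mean shapes, ranked.

    Rows are sorted descending by dissimilarity (ties broken by ascending
    1-based landmark index); contributions sum to 1.  When the two means
    are identical the contributions are uniform and ``degenerate`` is set.
    """

    landmark_index: np.ndarray  # 1-based, in rank order
    dissimilarity: np.ndarray
    contribution: np.ndarray
    degenerate: bool = False

    @property
    def k(self) -> int:
        return len(self.landmark_index)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "rank": np.arange(1, self.k + 1),
                "landmark_index": self.landmark_index,
                "dissimilarity": self.dissimilarity,
                "contribution": self.contribution,
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    def to_dict(self) -> dict:
        return {
            "landmark_index": self.landmark_index.tolist(),
            "dissimilarity": self.dissimilarity.tolist(),
            "contribution": self.contribution.tolist(),
            "degenerate": self.degenerate,
        }


def landmark_dissimilarity(
    mean_a: np.ndarray, mean_b: np.ndarray
) -> LandmarkDissimilarityTable:
    """Per-landmark Euclidean distance between two superimposed mean shapes.

    Both means must already be in a common Procrustes frame.  The
    contribution of landmark j is its distance divided by the total;
    identical means yield uniform contributions with the degenerate flag.
    """
    mean_a = np.asarray(mean_a, dtype=float)
    mean_b = np.asarray(mean_b, dtype=float)
    if mean_a.shape != mean_b.shape:
        raise ValueError(f"mismatched shapes {mean_a.shape} vs {mean_b.shape}")
    k = mean_a.shape[0]
    diss = np.sqrt(np.sum((mean_a - mean_b) ** 2, axis=1))
    total = diss.sum()
    # unit-CS frame: differences below 1e-10 are floating-point residue
    if diss.max(initial=0.0) < 1e-10:
        contrib = np.full(k, 1.0 / k)
        degenerate = True
    else:
        contrib = diss / total
        degenerate = False
    order = np.lexsort((np.arange(1, k + 1), -diss))
    return LandmarkDissimilarityTable(
        landmark_index=(order + 1).astype(int),
        dissimilarity=diss[order],
        contribution=contrib[order],
        degenerate=degenerate,
    )


def per_specimen_dissimilarity(
    aligned_a: np.ndarray, aligned_b: np.ndarray
) -> LandmarkDissimilarityTable:
    """Specimen-averaged variant of :func:`landmark_dissimilarity`.

    For each landmark, averages over specimens the distance between each
    specimen's landmark and the opposite group's mean landmark (both
    directions pooled).  Reported alongside the mean-to-mean table.
    """
    aligned_a = np.asarray(aligned_a, dtype=float)
    aligned_b = np.asarray(aligned_b, dtype=float)
    mean_a = aligned_a.mean(axis=0)
    mean_b = aligned_b.mean(axis=0)
    da = np.sqrt(np.sum((aligned_a - mean_b[None]) ** 2, axis=2)).mean(axis=0)
    db = np.sqrt(np.sum((aligned_b - mean_a[None]) ** 2, axis=2)).mean(axis=0)
    diss = 0.5 * (da + db)
    k = diss.shape[0]
    total = diss.sum()
    if total == 0:
        contrib = np.full(k, 1.0 / k)
        degenerate = True
    else:
        contrib = diss / total
        degenerate = False
    order = np.lexsort((np.arange(1, k + 1), -diss))
    return LandmarkDissimilarityTable(
        landmark_index=(order + 1).astype(int),
        dissimilarity=diss[order],
        contribution=contrib[order],
        degenerate=degenerate,
    )
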