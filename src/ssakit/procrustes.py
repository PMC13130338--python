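"""Procrustes superimposition and Kendall shape-space geometry for 2-D landmarks.

Planar configurations are handled in the complex representation
(each landmark x + iy), which gives the optimal rotation in closed form.
The full-Procrustes (scaled) fit is used throughout; reflections are
forbidden — which in 2-D is automatic, since complex multiplication can
only realise rotations (determinant +1 similarities).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .landmark_io import LandmarkConfiguration, LandmarkSample

logger = logging.getLogger(__name__)

__all__ = [
    "DegenerateShapeError",
    "ProcrustesFit",
    "TangentSample",
    "centroid_size",
    "preshape",
    "to_complex",
    "to_real",
    "opa_align",
    "gpa",
    "riemann_rho",
    "rms_rho",
    "tangent_coordinates",
]


class DegenerateShapeError(ValueError):
    """Raised when a configuration has zero centroid size."""


def _as_coords(config) -> np.ndarray:
    if isinstance(config, LandmarkConfiguration):
        return config.coords
    return np.asarray(config, dtype=float)


def to_complex(coords: np.ndarray) -> np.ndarray:
    """k x 2 real matrix -> complex k-vector."""
    coords = np.asarray(coords, dtype=float)
    return coords[..., 0] + 1j * coords[..., 1]


def to_real(z: np.ndarray) -> np.ndarray:
    """Complex k-vector -> k x 2 real matrix."""
    return np.stack([np.real(z), np.imag(z)], axis=-1)


def centroid_size(config) -> float:
    """Centroid size: sqrt of summed squared distances of landmarks to their centroid."""
    coords = _as_coords(config)
    centered = coords - coords.mean(axis=0)
    cs = float(np.sqrt(np.sum(centered**2)))
    if cs == 0.0:
        logger.warning("degenerate configuration: all landmarks coincide (CS = 0)")
    return cs


def preshape(config) -> np.ndarray:
    """Center and scale to unit centroid size (translation and size removed)."""
    coords = _as_coords(config)
    centered = coords - coords.mean(axis=0)
    cs = np.sqrt(np.sum(centered**2))
    if cs == 0.0:
        raise DegenerateShapeError("cannot form preshape: centroid size is 0")
    return centered / cs


def opa_align(config: np.ndarray, target: np.ndarray) -> tuple[np.ndarray, float]:
    """Ordinary Procrustes alignment of ``config`` onto ``target``.

    Both inputs must be centered with positive centroid size.  Returns the
    rotated-and-scaled copy of ``config`` minimising the summed squared
    distance to ``target``, plus the applied rotation angle (radians).
    Rotation only — no reflection.
    """
    z = to_complex(np.asarray(config, dtype=float))
    w = to_complex(np.asarray(target, dtype=float))
    inner = np.vdot(z, w)  # sum conj(z_i) * w_i
    zz = np.vdot(z, z).real
    if zz == 0.0:
        raise DegenerateShapeError("config has zero centroid size")
    mag = np.abs(inner)
    if mag == 0.0:
        warnings.warn(
            "shapes are orthogonal in preshape space: rotation is ambiguous, using angle 0",
            RuntimeWarning,
            stacklevel=2,
        )
        beta = np.sqrt(np.vdot(w, w).real / zz)
        return to_real(z * beta), 0.0
    # optimal similarity: z -> (inner / |z|^2) * z  (rotation e^{i theta}, scale |inner|/|z|^2)
    coef = inner / zz
    aligned = z * coef
    angle = float(np.angle(coef))
    return to_real(aligned), angle


def riemann_rho(shape1, shape2) -> float:
    """Kendall's Riemann (Procrustes geodesic) distance in [0, pi/2].

    Invariant to translation, scaling and rotation of either argument.
    """
    z1 = to_complex(preshape(shape1))
    z2 = to_complex(preshape(shape2))
    c = np.abs(np.vdot(z1, z2))
    return float(np.arccos(min(1.0, c)))


@dataclass(frozen=True)
class ProcrustesFit:
    """Result of generalized Procrustes analysis.

    ``aligned`` holds the superimposed configurations at unit centroid
    size (full-Procrustes fit); ``centroid_sizes`` are the raw sizes
    before normalization.
    """

    mean_shape: np.ndarray
    aligned: np.ndarray
    centroid_sizes: np.ndarray
    iterations: int
    converged: bool
    specimen_ids: tuple[str, ...] = ()

    @property
    def n(self) -> int:
        return self.aligned.shape[0]

    @property
    def k(self) -> int:
        return self.aligned.shape[1]


def gpa(sample: LandmarkSample, tol: float = 1e-10, max_iter: int = 100) -> ProcrustesFit:
    """Generalized Procrustes analysis of a landmark sample.

    Iteratively aligns every preshape to the current mean estimate and
    re-averages until the Riemann distance between successive means falls
    below ``tol``.  The mean is re-normalized to unit centroid size each
    round, so the fit is the full-Procrustes one.
    """
    if sample.n < 2:
        raise ValueError("GPA requires at least 2 configurations")
    coords = sample.coords_array()
    cs = np.array([centroid_size(c) for c in coords])
    if np.any(cs == 0):
        raise DegenerateShapeError("GPA input contains a degenerate configuration")
    pre = np.stack([preshape(c) for c in coords])
    z = to_complex(pre)  # n x k complex
    mean = z[0].copy()
    converged = False
    iterations = 0
    for iterations in range(1, max_iter + 1):
        inner = z @ np.conj(mean)  # <mean, z_i>* per row; rotation coef below
        coef = np.conj(inner)
        mags = np.abs(coef)
        safe = np.where(mags == 0, 1.0, mags)
        rot = np.where(mags == 0, 1.0, coef / safe)
        aligned = z * rot[:, None]  # rotation only; preshapes stay unit norm
        new_mean = aligned.mean(axis=0)
        new_mean = new_mean - new_mean.mean()
        norm = np.sqrt(np.vdot(new_mean, new_mean).real)
        if norm == 0:
            raise DegenerateShapeError("GPA mean collapsed to a point")
        new_mean = new_mean / norm
        # chordal step: full floating-point resolution where arccos saturates
        step = float(np.linalg.norm(new_mean - mean))
        mean = new_mean
        if step < tol:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"GPA did not converge in {max_iter} iterations", RuntimeWarning, stacklevel=2
        )
    # final alignment of all preshapes to the converged mean
    coef = np.conj(z @ np.conj(mean))
    mags = np.abs(coef)
    safe = np.where(mags == 0, 1.0, mags)
    rot = np.where(mags == 0, 1.0, coef / safe)
    aligned = z * rot[:, None]
    return ProcrustesFit(
        mean_shape=to_real(mean),
        aligned=to_real(aligned),
        centroid_sizes=cs,
        iterations=iterations,
        converged=converged,
        specimen_ids=tuple(c.specimen_id for c in sample),
    )


def rms_rho(configurations: np.ndarray, reference) -> float:
    """Root mean square Riemann distance of configurations to a reference shape."""
    configurations = np.asarray(configurations, dtype=float)
    if configurations.ndim == 2:
        configurations = configurations[None]
    if configurations.shape[0] == 0:
        raise ValueError("rms_rho of an empty set")
    rhos = np.array([riemann_rho(c, reference) for c in configurations])
    return float(np.sqrt(np.mean(rhos**2)))


@dataclass(frozen=True)
class TangentSample:
    """Tangent-space coordinates of a sample about a reference mean shape.

    ``coords`` rows are real 2k-vectors: the k real parts (x) followed by
    the k imaginary parts (y) of the projected complex tangent vectors.
    """

    reference: np.ndarray
    coords: np.ndarray
    effective_rank: int

    @property
    def n(self) -> int:
        return self.coords.shape[0]

    @property
    def k(self) -> int:
        return self.reference.shape[0]


def tangent_coordinates(fit: ProcrustesFit, reference=None) -> TangentSample:
    """Project aligned preshapes onto the tangent plane at ``reference``.

    Each aligned preshape is rotated to the reference pole and projected
    with ``v = (I - mu mu*) z``.  ``reference`` defaults to the fit's own
    mean shape and must be centered with unit centroid size.
    """
    if reference is None:
        reference = fit.mean_shape
    reference = np.asarray(reference, dtype=float)
    mu = to_complex(reference)
    if abs(np.abs(mu.mean()) * len(mu)) > 1e-8 or abs(np.vdot(mu, mu).real - 1.0) > 1e-8:
        raise ValueError("reference must be centered with unit centroid size")
    z = to_complex(fit.aligned)
    inner = np.conj(z @ np.conj(mu))  # <z_i, mu> with <a,b> = sum conj(a) b
    mags = np.abs(inner)
    safe = np.where(mags == 0, 1.0, mags)
    rot = np.where(mags == 0, 1.0, inner / safe)
    z_rot = z * rot[:, None]
    proj = z_rot - np.outer(z_rot @ np.conj(mu), mu)
    coords = np.concatenate([np.real(proj), np.imag(proj)], axis=1)
    if coords.shape[0] > 1:
        sv = np.linalg.svd(coords - coords.mean(axis=0), compute_uv=False)
    else:
        sv = np.linalg.svd(coords, compute_uv=False)
    effective_rank = int(np.sum(sv > 1e-10))
    return TangentSample(reference=reference, coords=coords, effective_rank=effective_rank)
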