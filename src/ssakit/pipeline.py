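"""End-to-end two-group shape comparison and report serialization.

Stages: pooled GPA -> tangent projection about the pooled mean ->
dimension reduction -> Box-M homogeneity gate -> James resampling test
(inhomogeneous covariances) or Hotelling T-squared (homogeneous) ->
RMS-rho summaries -> group-mean TPS warp with expansion grid ->
per-landmark dissimilarity ranking -> pooled allometric regression ->
per-landmark scatter, 95% concentration ellipses and convex hulls.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np
from scipy import stats
from scipy.spatial import ConvexHull

from . import allometry as _allometry
from . import shape_tests as _shape_tests
from . import tps_deformation as _tps
from .landmark_io import LandmarkSample
from .procrustes import gpa, preshape, rms_rho, tangent_coordinates

logger = logging.getLogger(__name__)

__all__ = ["AnalysisConfig", "AnalysisReport", "run_two_group_analysis", "write_report"]


@dataclass(frozen=True)
class AnalysisConfig:
    """Knobs for the two-group analysis."""

    n_resamples: int = 999
    seed: int = 0
    grid_size: int = 24
    warp_direction: Literal["b_to_a", "a_to_b"] = "b_to_a"
    use_log_cs: bool = False
    alpha: float = 0.05
    reduction_dim: int | None = None  # None = auto (effective rank)

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        if self.n_resamples < 99:
            raise ValueError("n_resamples must be at least 99")
        if self.grid_size <= 0:
            raise ValueError("grid_size must be positive")
        if self.warp_direction not in ("b_to_a", "a_to_b"):
            raise ValueError("warp_direction must be 'b_to_a' or 'a_to_b'")


@dataclass(frozen=True)
class AnalysisReport:
    """Complete two-group analysis result (JSON-serializable via to_dict)."""

    group_labels: tuple[str, str]
    group_sizes: tuple[int, int]
    homogeneity: _shape_tests.HomogeneityResult
    mean_shape_test: _shape_tests.MeanShapeTestResult
    rms_rho: dict
    dissimilarity_table: _tps.LandmarkDissimilarityTable
    dissimilarity_table_per_specimen: _tps.LandmarkDissimilarityTable
    warp: _tps.TPSWarp
    grid: _tps.DeformationGrid
    allometry: _allometry.AllometryModel
    mean_shapes: dict
    scatter: dict
    ellipses: dict
    hulls: dict
    provenance: dict

    def to_dict(self) -> dict:
        return {
            "group_labels": list(self.group_labels),
            "group_sizes": list(self.group_sizes),
            "homogeneity": asdict(self.homogeneity),
            "mean_shape_test": asdict(self.mean_shape_test),
            "rms_rho": self.rms_rho,
            "dissimilarity_table": self.dissimilarity_table.to_dict(),
            "dissimilarity_table_per_specimen": self.dissimilarity_table_per_specimen.to_dict(),
            "warp": {
                "direction": self.provenance["config"]["warp_direction"],
                "affine": self.warp.affine.tolist(),
                "bending_energy": self.warp.bending_energy,
            },
            "grid": self.grid.to_dict(),
            "allometry": self.allometry.to_dict(),
            "mean_shapes": self.mean_shapes,
            "scatter": self.scatter,
            "ellipses": self.ellipses,
            "hulls": self.hulls,
            "provenance": self.provenance,
        }


def _concentration_ellipses(aligned: np.ndarray, level: float = 0.95) -> list[dict]:
    """Per-landmark 95% concentration ellipse from the 2x2 coordinate covariance."""
    quantile = stats.chi2.ppf(level, df=2)
    out = []
    for j in range(aligned.shape[1]):
        cloud = aligned[:, j, :]
        center = cloud.mean(axis=0)
        cov = np.cov(cloud.T, ddof=1)
        evals, evecs = np.linalg.eigh(cov)
        evals = np.maximum(evals, 0.0)
        # eigh returns ascending order; major axis last
        angle = float(np.arctan2(evecs[1, 1], evecs[0, 1]))
        out.append(
            {
                "landmark_index": j + 1,
                "center": center.tolist(),
                "semi_major": float(np.sqrt(evals[1] * quantile)),
                "semi_minor": float(np.sqrt(evals[0] * quantile)),
                "angle": angle,
            }
        )
    return out


def _convex_hulls(aligned: np.ndarray) -> list[dict]:
    out = []
    for j in range(aligned.shape[1]):
        cloud = aligned[:, j, :]
        try:
            hull = ConvexHull(cloud)
            verts = cloud[hull.vertices].tolist()
        except Exception:  # degenerate (collinear) cloud
            verts = cloud.tolist()
        out.append({"landmark_index": j + 1, "vertices": verts})
    return out


def run_two_group_analysis(
    sample_a: LandmarkSample,
    sample_b: LandmarkSample,
    config: AnalysisConfig | None = None,
) -> AnalysisReport:
    """Run the full two-group landmark shape comparison.

    Both samples are superimposed in one pooled GPA so the two groups'
    tangent coordinates are commensurate; group means are computed from
    the pooled-aligned specimens.
    """
    if config is None:
        config = AnalysisConfig()
    if sample_a.k != sample_b.k:
        raise ValueError(f"samples disagree on k: {sample_a.k} vs {sample_b.k}")
    t0 = time.perf_counter()
    n1, n2 = sample_a.n, sample_b.n

    pooled = LandmarkSample(
        group_label="pooled",
        configurations=tuple(sample_a) + tuple(sample_b),
    )
    fit = gpa(pooled)
    logger.info("stage gpa: %d specimens, %d iterations, converged=%s (%.2fs)",
                pooled.n, fit.iterations, fit.converged, time.perf_counter() - t0)

    tangent = tangent_coordinates(fit, fit.mean_shape)
    coords_a = tangent.coords[:n1]
    coords_b = tangent.coords[n1:]

    try:
        (scores_a, scores_b), basis = _shape_tests.reduce_dimension(
            coords_a, coords_b, config.reduction_dim
        )
    except ValueError as exc:
        raise ValueError(f"stage reduce_dimension: {exc}") from exc

    homogeneity = _shape_tests.box_m_test(scores_a, scores_b)
    logger.info("stage box_m: F=%.4f p=%.4g", homogeneity.f_stat, homogeneity.p_value)

    if homogeneity.p_value < config.alpha:
        mean_test = _shape_tests.james_test(
            scores_a, scores_b, n_resamples=config.n_resamples, seed=config.seed
        )
    else:
        mean_test = _shape_tests.hotelling_test(scores_a, scores_b)
    logger.info("stage mean test (%s): T2=%.4f p=%.4g",
                mean_test.method, mean_test.statistic, mean_test.p_value)

    aligned_a = fit.aligned[:n1]
    aligned_b = fit.aligned[n1:]
    mean_a = preshape(aligned_a.mean(axis=0))
    mean_b = preshape(aligned_b.mean(axis=0))
    rho_summary = {
        "pooled_vs_pooled_mean": rms_rho(fit.aligned, fit.mean_shape),
        "group_a_vs_pooled_mean": rms_rho(aligned_a, fit.mean_shape),
        "group_b_vs_pooled_mean": rms_rho(aligned_b, fit.mean_shape),
        "group_a_vs_own_mean": rms_rho(aligned_a, mean_a),
        "group_b_vs_own_mean": rms_rho(aligned_b, mean_b),
    }

    if config.warp_direction == "b_to_a":
        warp = _tps.fit_tps(mean_b, mean_a)
    else:
        warp = _tps.fit_tps(mean_a, mean_b)
    grid = _tps.expansion_grid(warp, grid_size=config.grid_size)

    diss = _tps.landmark_dissimilarity(mean_a, mean_b)
    diss_per_spec = _tps.per_specimen_dissimilarity(aligned_a, aligned_b)

    allo = _allometry.allometric_regression(
        np.vstack([scores_a, scores_b]),
        fit.centroid_sizes,
        use_log_cs=config.use_log_cs,
    )

    scatter = {
        "group_a": aligned_a.tolist(),
        "group_b": aligned_b.tolist(),
    }
    ellipses = {
        "group_a": _concentration_ellipses(aligned_a),
        "group_b": _concentration_ellipses(aligned_b),
    }
    hulls = {
        "group_a": _convex_hulls(aligned_a),
        "group_b": _convex_hulls(aligned_b),
    }

    from . import __version__

    provenance = {
        "config": asdict(config),
        "seed": config.seed,
        "software_version": __version__,
        "gpa_iterations": fit.iterations,
        "gpa_converged": fit.converged,
        "reduced_dim": int(scores_a.shape[1]),
    }
    logger.info("analysis complete in %.2fs", time.perf_counter() - t0)
    return AnalysisReport(
        group_labels=(sample_a.group_label, sample_b.group_label),
        group_sizes=(n1, n2),
        homogeneity=homogeneity,
        mean_shape_test=mean_test,
        rms_rho=rho_summary,
        dissimilarity_table=diss,
        dissimilarity_table_per_specimen=diss_per_spec,
        warp=warp,
        grid=grid,
        allometry=allo,
        mean_shapes={
            "pooled": fit.mean_shape.tolist(),
            "group_a": mean_a.tolist(),
            "group_b": mean_b.tolist(),
        },
        scatter=scatter,
        ellipses=ellipses,
        hulls=hulls,
        provenance=provenance,
    )


def render_text_report(report: AnalysisReport) -> str:
    """Human-readable rendering with a ranked dissimilarity block."""
    lines = []
    la, lb = report.group_labels
    na, nb = report.group_sizes
    lines.append("Two-group landmark shape analysis")
    lines.append(f"  group A: {la} (n={na})   group B: {lb} (n={nb})")
    lines.append("")
    h = report.homogeneity
    lines.append(
        f"Box-M homogeneity: M={h.box_m:.4f}  F={h.f_stat:.4f} "
        f"(df {h.df1:.0f}, {h.df2:.1f})  p={h.p_value:.4g}"
    )
    m = report.mean_shape_test
    lines.append(
        f"Mean-shape test [{m.method}]: T2={m.statistic:.4f}  p={m.p_value:.4g}"
        + (f"  ({m.n_resamples} resamples, seed {m.seed})" if m.n_resamples else "")
    )
    lines.append("rho RMS:")
    for key, val in report.rms_rho.items():
        lines.append(f"  {key}: {val:.8f}")
    lines.append("")
    lines.append("Landmark dissimilarity (mean-to-mean):")
    if report.dissimilarity_table.degenerate:
        lines.append("  [DEGENERATE: group means identical; uniform contributions]")
    lines.append(f"  {'rank':>4} {'landmark':>8} {'dissimilarity':>14} {'contribution':>13}")
    t = report.dissimilarity_table
    for rank, (lm, d, c) in enumerate(
        zip(t.landmark_index, t.dissimilarity, t.contribution), start=1
    ):
        lines.append(f"  {rank:>4} {lm:>8} {d:>14.6f} {c:>13.6f}")
    lines.append("")
    a = report.allometry
    lines.append(
        f"Allometry: Wilks' lambda={a.wilks_lambda:.4g}  F={a.f_stat:.4f} "
        f"(df {a.df1}, {a.df2})  p={a.p_value:.4g}  R2={a.r_squared:.5f}  MSE={a.mse:.4g}"
    )
    lines.append(f"TPS bending energy: {report.warp.bending_energy:.6g}")
    return "\n".join(lines) + "\n"


def write_report(
    report: AnalysisReport, path: str | Path, format: Literal["json", "text"] = "json"
) -> None:
    """Serialize a report to JSON (stable key order) or text."""
    path = Path(path)
    if format == "json":
        path.write_text(json.dumps(report.to_dict(), indent=2, sort_keys=True))
    elif format == "text":
        path.write_text(render_text_report(report))
    else:
        raise ValueError(f"unknown format {format!r}")
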