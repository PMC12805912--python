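"""Bivariate-normal confidence ellipses and directional overlap proportions.

A coverage-p ellipse of a bivariate normal N2(c, S) is the set
{x : (x - c)' S^-1 (x - c) <= q} with q = -2 ln(1 - p), the chi-square
quantile with 2 degrees of freedom; its area is pi * q * sqrt(det S).
Ellipses are polygonised (default 360 vertices, <0.1% area error) and
overlap is the polygon-intersection area divided by the area of the first
ellipse — an asymmetric quantity by construction.

For posterior overlap between two independently fitted groups, the ellipse
of each draw uses the TOTAL niche covariance G + R and the draw's
campaign-averaged marginal mean; draws are paired across groups by retained
index.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from shapely.geometry import Polygon

from .errors import DegenerateEllipseError, PairingError
from .mixed_model import GroupPosterior


@dataclass(frozen=True)
class EllipseSpec:
    """Centroid + 2x2 covariance + coverage level defining one ellipse."""

    centroid: np.ndarray
    covariance: np.ndarray
    coverage: float = 0.67

    def __post_init__(self):
        if not (0.0 < self.coverage < 1.0):
            raise ValueError("coverage must lie in (0, 1)")


def mahalanobis_radius_sq(coverage: float) -> float:
    """Chi-square(2 df) quantile at ``coverage``: q = -2 ln(1 - coverage)."""
    return float(-2.0 * np.log1p(-coverage))


def ellipse_area(e: EllipseSpec) -> float:
    """Exact area pi * q * sqrt(det covariance)."""
    det = float(np.linalg.det(np.asarray(e.covariance, dtype=float)))
    if det <= 0:
        raise DegenerateEllipseError("singular covariance: ellipse has no area")
    return float(np.pi * mahalanobis_radius_sq(e.coverage) * np.sqrt(det))


def ellipse_polygon(e: EllipseSpec, n_vertices: int = 360) -> Polygon:
    """Polygonise the ellipse: centroid + sqrt(q) * L (cos t, sin t)."""
    if n_vertices < 16:
        raise ValueError("n_vertices must be >= 16")
    cov = np.asarray(e.covariance, dtype=float)
    if np.linalg.det(cov) <= 0:
        raise DegenerateEllipseError("singular covariance: cannot polygonise")
    L = np.linalg.cholesky(cov)
    theta = np.linspace(0.0, 2.0 * np.pi, n_vertices, endpoint=False)
    circle = np.stack([np.cos(theta), np.sin(theta)])
    pts = np.asarray(e.centroid, dtype=float)[:, None] + (
        np.sqrt(mahalanobis_radius_sq(e.coverage)) * (L @ circle)
    )
    return Polygon(pts.T)


def directional_overlap(
    a: EllipseSpec, b: EllipseSpec, n_vertices: int = 360
) -> float:
    """Proportion of ellipse ``a``'s area covered by ellipse ``b``, in [0, 1]."""
    pa = ellipse_polygon(a, n_vertices)
    pb = ellipse_polygon(b, n_vertices)
    return float(pa.intersection(pb).area / pa.area)


@dataclass(frozen=True)
class OverlapDraws:
    """Draw-wise directional overlap between two groups, plus labels."""

    label_a: str
    label_b: str
    a_in_b: np.ndarray  # proportion of a's ellipse covered by b, per draw
    b_in_a: np.ndarray

    @property
    def n_draws(self) -> int:
        return self.a_in_b.size

    def summary_percent(self) -> dict:
        """Mean and SD per direction, in percent."""
        return {
            f"{self.label_a}_in_{self.label_b}": {
                "mean": float(100.0 * np.mean(self.a_in_b)),
                "sd": float(100.0 * np.std(self.a_in_b, ddof=1)),
            },
            f"{self.label_b}_in_{self.label_a}": {
                "mean": float(100.0 * np.mean(self.b_in_a)),
                "sd": float(100.0 * np.std(self.b_in_a, ddof=1)),
            },
        }


def posterior_overlap(
    post_a: GroupPosterior,
    post_b: GroupPosterior,
    coverage: float = 0.67,
    n_vertices: int = 360,
    intercept_only: bool = False,
) -> OverlapDraws:
    """Directional overlap of total-niche ellipses at each paired MCMC draw.

    Draw j of group a is paired with draw j of group b (no resampling); a
    draw-count mismatch raises :class:`PairingError`.  Per draw the ellipse
    covariance is G + R and the centroid the marginal fixed-effect mean.
    """
    if post_a.n_effective_draws != post_b.n_effective_draws:
        raise PairingError(
            f"draw-count mismatch: {post_a.n_effective_draws} vs "
            f"{post_b.n_effective_draws}"
        )
    ca = post_a.marginal_mean(intercept_only)
    cb = post_b.marginal_mean(intercept_only)
    Sa = post_a.total_covariance()
    Sb = post_b.total_covariance()
    n = post_a.n_effective_draws
    a_in_b = np.empty(n)
    b_in_a = np.empty(n)
    for j in range(n):
        pa = ellipse_polygon(EllipseSpec(ca[j], Sa[j], coverage), n_vertices)
        pb = ellipse_polygon(EllipseSpec(cb[j], Sb[j], coverage), n_vertices)
        inter = pa.intersection(pb).area
        a_in_b[j] = inter / pa.area
        b_in_a[j] = inter / pb.area
    return OverlapDraws(
        label_a=post_a.species, label_b=post_b.species,
        a_in_b=a_in_b, b_in_a=b_in_a,
    )
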