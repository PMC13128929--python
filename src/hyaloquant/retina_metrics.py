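"""Retinal vascular expansion and density from collagen IV flatmount masks.

Radial vascular expansion is half of the mean axis length of the smallest
oval fully encompassing the vascular plexus; vascular density is the
collagen IV-positive area divided by the area of the disc of that radius,
``area / (expansion² · π)``.  The manually drawn oval of the original
workflow is replaced by the minimum-area enclosing ellipse of the positive
pixels, computed with Khachiyan's algorithm on the convex hull.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial import ConvexHull, QhullError

from .types import VesselMask

__all__ = [
    "RetinaMetrics",
    "minimum_enclosing_ellipse",
    "radial_expansion",
    "vascular_density",
    "retina_metrics",
]


@dataclass
class RetinaMetrics:
    """Vascular area (µm²), radial expansion (µm) and dimensionless density."""

    vascular_area_um2: float
    radial_expansion_um: float
    density: float
    density_exceeds_one: bool = False


def minimum_enclosing_ellipse(
    points: np.ndarray, tol: float = 1e-5, max_iter: int = 5000
) -> tuple[np.ndarray, np.ndarray]:
    """Minimum-area enclosing ellipse (MVEE) of a 2-D point set.

    Returns ``(center, A)`` such that every point satisfies
    ``(x - center)ᵀ A (x - center) <= 1`` and the ellipse area is minimal
    (to tolerance ``tol``).  Khachiyan's barycentric ascent is run on the
    convex-hull vertices only, which keeps the iteration cheap for large
    masks.
    """
    pts = np.asarray(points, float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be an (n, 2) array")
    if len(pts) < 3:
        raise ValueError("need at least 3 points for an enclosing ellipse")
    try:
        hull = ConvexHull(pts)
        pts = pts[hull.vertices]
    except QhullError as exc:
        raise ValueError("point set is degenerate (collinear)") from exc
    n, d = pts.shape
    Q = np.column_stack([pts, np.ones(n)]).T  # (3, n)
    u = np.full(n, 1.0 / n)
    for _ in range(max_iter):
        X = Q @ np.diag(u) @ Q.T
        M = np.einsum("ij,ji->i", Q.T @ np.linalg.inv(X), Q)
        j = int(np.argmax(M))
        maximum = M[j]
        step = (maximum - d - 1.0) / ((d + 1.0) * (maximum - 1.0))
        new_u = (1.0 - step) * u
        new_u[j] += step
        if np.linalg.norm(new_u - u) < tol:
            u = new_u
            break
        u = new_u
    center = pts.T @ u
    cov = (pts.T @ np.diag(u) @ pts) - np.outer(center, center)
    A = np.linalg.inv(cov) / d
    return center, A


def _ellipse_semiaxes(A: np.ndarray) -> tuple[float, float]:
    eigvals = np.linalg.eigvalsh(A)
    semi = 1.0 / np.sqrt(eigvals)
    return float(semi.max()), float(semi.min())


def radial_expansion(collagen_mask: VesselMask) -> float:
    """Radial vascular expansion in µm.

    Half of the mean axis length of the minimum-area ellipse enclosing the
    collagen IV-positive pixels: ``(major + minor) / 4`` in pixel units,
    scaled by the pixel size.
    """
    pts = np.argwhere(collagen_mask.mask)
    if len(pts) == 0:
        raise ValueError("collagen IV mask is empty; no vascular plexus to enclose")
    _, A = minimum_enclosing_ellipse(pts)
    semi_major, semi_minor = _ellipse_semiaxes(A)
    return (semi_major + semi_minor) / 2.0 * collagen_mask.pixel_size


def vascular_density(vascular_area_um2: float, radial_expansion_um: float) -> float:
    """Retinal vascular density: positive area over the enclosing-disc area.

    ``density = area / (expansion² · π)``; values above 1 indicate positive
    area outside the fitted disc and are flagged with a warning.
    """
    if radial_expansion_um <= 0:
        raise ValueError("radial expansion must be positive")
    density = vascular_area_um2 / (radial_expansion_um**2 * np.pi)
    if density > 1.0:
        warnings.warn(
            f"vascular density {density:.3f} exceeds 1: positive area extends "
            "beyond the disc of the fitted radial expansion",
            stacklevel=2,
        )
    return float(density)


def retina_metrics(collagen_mask: VesselMask) -> RetinaMetrics:
    """Compute the full retina metric triple from a collagen IV mask."""
    area = collagen_mask.area_um2
    expansion = radial_expansion(collagen_mask)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        density = vascular_density(area, expansion)
    return RetinaMetrics(
        vascular_area_um2=area,
        radial_expansion_um=expansion,
        density=density,
        density_exceeds_one=density > 1.0,
    )
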