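"""Feret-diameter morphometry: section length, mean thickness,
parakeratosis density, unit conversion, and per-subject summaries.

Mean thickness of a manually-outlined strip is its area divided by the
Feret (maximum caliper) diameter of the outline, which closely
approximates the strip's length when length ≫ thickness.  For a
w×h-pixel rectangle this gives w·h/√(w²+h²) → h as w/h → ∞ with
relative error ≤ h²/(2w²).

A mask is treated as a union of unit pixel squares, so the Feret
diameter is the maximum pairwise distance over the *corner* points of
its boundary pixels (computed exactly via the convex hull).  Under this
convention a single-pixel mask has Feret √2 · pixel size — its true
caliper diameter — and an axis-aligned w×h rectangle has exactly
√(w²+h²) pixels.
"""

from __future__ import annotations

import logging
import statistics
from collections import defaultdict
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial import ConvexHull, QhullError

from ._core import RegionMask, SectionMeasurement, SubjectSummary, ValidationError

logger = logging.getLogger(__name__)


def boundary_corner_points(mask: np.ndarray) -> np.ndarray:
    """Corner points (x, y) of the boundary pixels of a binary mask.

    Boundary pixels are mask pixels with at least one 4-neighbour outside
    the mask (or on the image edge); their corners span the convex hull
    of the full union-of-squares shape.
    """
    m = np.asarray(mask, dtype=bool)
    if not m.any():
        raise ValidationError("empty mask")
    interior = np.zeros_like(m)
    interior[1:-1, 1:-1] = m[1:-1, 1:-1] & m[:-2, 1:-1] & m[2:, 1:-1] & m[1:-1, :-2] & m[1:-1, 2:]
    rr, cc = np.nonzero(m & ~interior)
    corners = np.empty((4 * rr.size, 2), dtype=float)
    for i, (dr, dc) in enumerate(((0, 0), (0, 1), (1, 0), (1, 1))):
        corners[i * rr.size : (i + 1) * rr.size, 0] = cc + dc
        corners[i * rr.size : (i + 1) * rr.size, 1] = rr + dr
    return np.unique(corners, axis=0)


def _max_pairwise(points: np.ndarray) -> float:
    d2 = ((points[:, None, :] - points[None, :, :]) ** 2).sum(-1)
    return float(np.sqrt(d2.max()))


def feret_diameter(mask: RegionMask) -> float:
    """Maximum caliper distance of the mask outline, in µm.

    Computed as the exact maximum pairwise distance between convex-hull
    vertices of the boundary-pixel corner points.  Disconnected masks are
    allowed; the Feret is taken over the union's hull.
    """
    if mask.is_empty():
        raise ValidationError("feret_diameter: empty mask")
    pts = boundary_corner_points(mask.mask)
    if len(pts) > 4:
        try:
            hull = ConvexHull(pts)
            pts = pts[hull.vertices]
        except QhullError:  # pragma: no cover - degenerate, fall through
            pass
    return _max_pairwise(pts) * mask.pixel_size_um


def mean_thickness(mask: RegionMask) -> float:
    """Outline area / Feret diameter, in µm."""
    f = feret_diameter(mask)
    if f == 0:
        raise ValidationError("mean_thickness: zero Feret diameter")
    return mask.area_um2 / f


def parakeratosis_density(nuclei_count: int, sc_mask: RegionMask) -> float:
    """Retained SC nuclei per millimetre of SC length (Feret)."""
    if nuclei_count < 0:
        raise ValidationError("nuclei_count must be >= 0")
    f_mm = feret_diameter(sc_mask) / 1e3
    if f_mm == 0:
        raise ValidationError("parakeratosis_density: zero SC Feret diameter")
    return nuclei_count / f_mm


def convert_length(
    value_px: float,
    objective_magnification: float = 1.0,
    compression_factor: float = 1.0,
    camera_scale_um_per_px: float = 1.0,
) -> float:
    """Convert a length in image pixels to micrometers.

    µm = value_px · camera_scale / magnification / compression_factor.
    A composite compressed to 50% has ``compression_factor = 0.5``,
    doubling the effective µm per stored pixel.
    """
    for name, v in (
        ("objective_magnification", objective_magnification),
        ("compression_factor", compression_factor),
        ("camera_scale_um_per_px", camera_scale_um_per_px),
    ):
        if v <= 0:
            raise ValidationError(f"{name} must be > 0")
    return value_px * camera_scale_um_per_px / objective_magnification / compression_factor


def convert_length_inverse(
    value_um: float,
    objective_magnification: float = 1.0,
    compression_factor: float = 1.0,
    camera_scale_um_per_px: float = 1.0,
) -> float:
    """Inverse of :func:`convert_length` (µm back to pixels)."""
    return value_um / convert_length(
        1.0, objective_magnification, compression_factor, camera_scale_um_per_px
    )


def summarize_subject(measurements: Iterable[SectionMeasurement]) -> list[SubjectSummary]:
    """Median per (subject, site, metric) over its sections.

    Even-count medians are the mean of the two middle values.  A warning
    is logged when the section count falls outside the usual 3–5.
    """
    groups: dict[tuple, list[float]] = defaultdict(list)
    for m in measurements:
        groups[(m.subject_id, m.site, m.metric_name)].append(m.value)
    if not groups:
        raise ValidationError("summarize_subject: no measurements")
    out = []
    for (sid, site, metric), values in groups.items():
        n = len(values)
        if not 3 <= n <= 5:
            logger.warning(
                "%s/%s/%s summarised over %d section(s), outside the usual 3–5",
                sid, site, metric, n,
            )
        out.append(
            SubjectSummary(
                subject_id=sid,
                site=site,
                metric_name=metric,
                median=float(statistics.median(values)),
                n_sections=n,
            )
        )
    return out
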