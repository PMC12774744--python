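"""Shared raster/vector geometry helpers.

Coordinate convention (used package-wide): 0-based pixel indices, polygon
vertices in pixel units with x = column and y = row, pixel centers at integer
coordinates. Physical lengths are pixel lengths times ``pixel_size_um``.
"""
from __future__ import annotations

import numpy as np
import shapely
from shapely.geometry import Polygon


def polygon_to_mask(polygon: Polygon, shape: tuple[int, int]) -> np.ndarray:
    """Rasterize a polygon onto an H×W boolean grid.

    A pixel belongs to the polygon iff its center lies inside or on the
    boundary (even-odd rule, boundary ties resolved as inside).
    """
    h, w = shape
    mask = np.zeros((h, w), dtype=bool)
    minx, miny, maxx, maxy = polygon.bounds
    x0 = max(int(np.floor(minx)), 0)
    x1 = min(int(np.ceil(maxx)), w - 1)
    y0 = max(int(np.floor(miny)), 0)
    y1 = min(int(np.ceil(maxy)), h - 1)
    if x1 < x0 or y1 < y0:
        return mask
    xs, ys = np.meshgrid(np.arange(x0, x1 + 1), np.arange(y0, y1 + 1))
    inside = shapely.intersects_xy(polygon, xs.ravel(), ys.ravel())
    mask[y0:y1 + 1, x0:x1 + 1] = inside.reshape(ys.shape)
    return mask


def mask_to_polygon(mask: np.ndarray) -> Polygon:
    """Trace a pixel mask into a polygon running along pixel edges.

    Vertices sit on pixel corners (integer ± 0.5), so rasterizing the result
    with :func:`polygon_to_mask` reproduces the mask pixel-for-pixel.
    """
    ys, xs = np.nonzero(mask)
    if ys.size == 0:
        raise ValueError("cannot polygonize an empty mask")
    boxes = [shapely.box(x - 0.5, y - 0.5, x + 0.5, y + 0.5)
             for x, y in zip(xs, ys)]
    union = shapely.unary_union(boxes)
    if union.geom_type == "MultiPolygon":
        union = max(union.geoms, key=lambda g: g.area)
    return Polygon(union.exterior)


def regular_polygon(cx: float, cy: float, radius: float, n: int = 64,
                    phase: float = 0.0) -> Polygon:
    t = phase + np.linspace(0.0, 2 * np.pi, n, endpoint=False)
    return Polygon(np.column_stack([cx + radius * np.cos(t),
                                    cy + radius * np.sin(t)]))


def ellipse_polygon(cx: float, cy: float, a: float, b: float,
                    angle: float, n: int = 32) -> Polygon:
    """Polygon approximating an ellipse with semi-axes a, b rotated by angle."""
    t = np.linspace(0.0, 2 * np.pi, n, endpoint=False)
    x = a * np.cos(t)
    y = b * np.sin(t)
    c, s = np.cos(angle), np.sin(angle)
    return Polygon(np.column_stack([cx + c * x - s * y, cy + s * x + c * y]))


def resample_boundary(polygon: Polygon, n_points: int) -> np.ndarray:
    """n_points equally spaced points along the polygon exterior (pure numpy)."""
    coords = np.asarray(polygon.exterior.coords)
    seg = np.diff(coords, axis=0)
    seg_len = np.hypot(seg[:, 0], seg[:, 1])
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])
    total = cum[-1]
    s = np.linspace(0.0, total, n_points, endpoint=False)
    idx = np.searchsorted(cum, s, side="right") - 1
    idx = np.clip(idx, 0, len(seg_len) - 1)
    frac = (s - cum[idx]) / np.where(seg_len[idx] > 0, seg_len[idx], 1.0)
    return coords[idx] + seg[idx] * frac[:, None]


def polygon_second_moments(polygon: Polygon) -> tuple[float, float, float]:
    """Central second area moments (cov_xx, cov_yy, cov_xy) per unit area.

    Closed-form shoelace-type integrals over the polygon interior; returns the
    covariance matrix entries of the uniform density over the polygon.
    """
    coords = np.asarray(polygon.exterior.coords)
    x, y = coords[:-1, 0], coords[:-1, 1]
    x1, y1 = coords[1:, 0], coords[1:, 1]
    cross = x * y1 - x1 * y
    area = 0.5 * np.sum(cross)
    if abs(area) < 1e-300:
        raise ValueError("degenerate polygon with zero area")
    cx = np.sum((x + x1) * cross) / (6.0 * area)
    cy = np.sum((y + y1) * cross) / (6.0 * area)
    ixx = np.sum((y * y + y * y1 + y1 * y1) * cross) / 12.0
    iyy = np.sum((x * x + x * x1 + x1 * x1) * cross) / 12.0
    ixy = np.sum((x * y1 + 2 * x * y + 2 * x1 * y1 + x1 * y) * cross) / 24.0
    a = abs(area)
    sign = np.sign(area)
    cov_xx = sign * iyy / a - cx * cx
    cov_yy = sign * ixx / a - cy * cy
    cov_xy = sign * ixy / a - cx * cy
    return float(cov_xx), float(cov_yy), float(cov_xy)
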