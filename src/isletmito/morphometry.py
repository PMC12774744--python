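"""Mitochondrial morphometry and organelle distances from TEM annotations.

Shape descriptors per mitochondrion polygon:

* aspect ratio AR = length / width, with length and width the major and
  minor axis of the ellipse matching the polygon's second area moments
  (the common "fit ellipse" convention);
* form factor FF = perimeter² / (4π · area), a branching/complexity index;
* circularity = 4π · area / perimeter², the reciprocal of FF.

Distances are shortest Euclidean boundary-to-boundary distances between
polygons (zero when they touch or overlap); for a multi-component Golgi the
minimum over components is taken, and cells without any annotated Golgi get
a distinguished "absent" result rather than zero. Mitochondrial density is
total mitochondrial area over cell area.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import Polygon

from ._geometry import polygon_second_moments
from .io import ResultsTable, TemCellAnnotation, ValidationError


@dataclass
class MitoMorphology:
    """Shape and position metrics of one mitochondrion (µm / µm²)."""

    area_um2: float
    perimeter_um: float
    length_um: float
    width_um: float
    aspect_ratio: float
    form_factor: float
    circularity: float
    d_nucleus_um: float | None = None
    d_golgi_um: float | None = None


def shape_metrics(poly: Polygon, pixel_size_um: float = 1.0) -> MitoMorphology:
    """Compute area, perimeter, fitted-ellipse axes, AR, FF and circularity.

    Area comes from the shoelace formula, the perimeter from the vertex chain;
    length/width are the full axes (4·√eigenvalue) of the second-moment
    ellipse. FF and circularity are exact mutual reciprocals.
    """
    if poly.is_empty or len(poly.exterior.coords) < 4:
        raise ValidationError("polygon needs at least 3 vertices")
    area_px = poly.area
    if area_px <= 0:
        raise ValidationError("degenerate polygon with zero area")
    perim_px = poly.exterior.length
    cxx, cyy, cxy = polygon_second_moments(poly)
    cov = np.array([[cxx, cxy], [cxy, cyy]])
    eig = np.linalg.eigvalsh(cov)
    eig = np.clip(eig, 0.0, None)
    width_px = 4.0 * np.sqrt(eig[0])
    length_px = 4.0 * np.sqrt(eig[1])
    area = area_px * pixel_size_um ** 2
    perim = perim_px * pixel_size_um
    ff = perim ** 2 / (4.0 * np.pi * area)
    return MitoMorphology(
        area_um2=area, perimeter_um=perim,
        length_um=length_px * pixel_size_um,
        width_um=width_px * pixel_size_um,
        aspect_ratio=length_px / width_px if width_px > 0 else np.inf,
        form_factor=ff, circularity=1.0 / ff)


_ABSENT = object()


def min_distance(a: Polygon, b: Polygon | list[Polygon],
                 pixel_size_um: float = 1.0) -> float | None:
    """Shortest distance (µm) between polygon a and polygon(s) b.

    Returns 0.0 when they touch or overlap. For a list (e.g. a Golgi split
    into several components in the section) the minimum over components is
    returned; an empty list yields None — the organelle is absent from the
    section, which is distinct from a distance of zero.
    """
    if isinstance(b, (list, tuple)):
        if len(b) == 0:
            return None
        return min(min_distance(a, bi, pixel_size_um) for bi in b)
    if a.is_empty or b.is_empty:
        raise ValidationError("min_distance needs non-empty polygons")
    return float(shapely.distance(a, b)) * pixel_size_um


def mito_density(cell: TemCellAnnotation) -> float:
    """Total mitochondrial area over cell (plasma-membrane polygon) area.

    Overlapping mitochondrion annotations trigger a warning and the union
    area is used so the ratio stays a true area fraction.
    """
    cell_area = cell.plasma_membrane.area
    if cell_area <= 0:
        raise ValidationError(f"cell {cell.cell_id}: zero cell area")
    if not cell.mitochondria:
        return 0.0
    total = sum(m.area for m in cell.mitochondria)
    union = shapely.unary_union(cell.mitochondria).area
    if total - union > 1e-9 * max(total, 1.0):
        warnings.warn(f"cell {cell.cell_id}: overlapping mitochondrion "
                      "annotations; using union area", stacklevel=2)
        total = union
    return float(total / cell_area)


def distance_to_membrane(mito: Polygon, cell: TemCellAnnotation) -> float:
    """Shortest distance (µm) from a mitochondrion to the plasma membrane.

    2D-section caveat: in a single section this under- or over-states the
    true 3-D proximity to the membrane, so it is reported only as an
    auxiliary, explicitly caveated quantity, never as a headline metric.
    """
    d = mito.exterior.distance(cell.plasma_membrane.exterior)
    return float(d) * cell.pixel_size_um


def cell_morphometry(cell: TemCellAnnotation) -> ResultsTable:
    """Per-mitochondrion morphometry table plus one cell-level summary row.

    Mitochondrion rows carry all shape metrics, the shortest distances to the
    nucleus and (when annotated) Golgi, and the manual cristae count; the
    cell row carries cell area, mitochondrion count and density.
    """
    px = cell.pixel_size_um
    rows = []
    for i, (m, cc) in enumerate(zip(cell.mitochondria, cell.cristae_counts)):
        mm = shape_metrics(m, px)
        d_nuc = min_distance(m, cell.nucleus, px)
        d_gol = min_distance(m, cell.golgi, px)
        rows.append({
            "cell_id": cell.cell_id, "row_type": "mitochondrion",
            "mito_id": f"{cell.cell_id}_m{i:03d}",
            "cell_type": cell.cell_type,
            "area_um2": mm.area_um2, "perimeter_um": mm.perimeter_um,
            "length_um": mm.length_um, "width_um": mm.width_um,
            "aspect_ratio": mm.aspect_ratio, "form_factor": mm.form_factor,
            "circularity": mm.circularity,
            "d_nucleus_um": d_nuc,
            "d_golgi_um": d_gol if d_gol is not None else np.nan,
            "cristae_count": cc if cc is not None else np.nan,
        })
    rows.append({
        "cell_id": cell.cell_id, "row_type": "cell",
        "mito_id": "", "cell_type": cell.cell_type,
        "area_um2": cell.plasma_membrane.area * px ** 2,
        "n_mitochondria": len(cell.mitochondria),
        "mito_density": mito_density(cell),
    })
    return ResultsTable(df=pd.DataFrame(rows),
                        metadata={"operation": "tem_morphometry",
                                  "pixel_size_um": px,
                                  "golgi_annotated": bool(cell.golgi),
                                  "axis_convention": "moment_ellipse"})


def tem_morphometry(cells: list[TemCellAnnotation]) -> ResultsTable:
    """Concatenated :func:`cell_morphometry` over a set of TEM cells."""
    tables = [cell_morphometry(c) for c in cells]
    df = pd.concat([t.df for t in tables], ignore_index=True)
    meta = tables[0].metadata if tables else {}
    meta = dict(meta, n_cells=len(cells))
    return ResultsTable(df=df, metadata=meta)
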