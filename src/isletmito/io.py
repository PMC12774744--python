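"""Readers, writers and validated domain types for the imaging pipeline.

Formats: TIFF/OME-TIFF for time-lapse stacks, GeoJSON FeatureCollections for
polygon annotations (cell outlines, nuclei, TEM organelles), CSV plus a JSON
metadata sidecar for result tables.

Coordinate convention: 0-based pixel indices; polygon vertices in pixel units
with x = column, y = row; pixel centers at integer coordinates; physical
lengths are pixel lengths × ``pixel_size_um``.
"""
from __future__ import annotations

import json
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from shapely.geometry import Polygon

from ._geometry import mask_to_polygon, polygon_to_mask

CELL_CLASSES = ("alpha", "non_alpha", "unknown")
ANNOTATION_ROLES = ("cell", "nucleus", "golgi", "mitochondrion", "plasma_membrane")


class ValidationError(ValueError):
    """Raised when an input violates a domain-type invariant."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class TimeLapseStack:
    """A fluorescence time series: T×H×W or T×C×H×W intensities plus scale.

    Parameters
    ----------
    data:
        Non-negative, finite intensity array.
    pixel_size_um:
        Lateral pixel size in micrometres (> 0).
    frame_interval_s:
        Time between consecutive frames in seconds (> 0).
    channels:
        Ordered channel labels; length must match the C axis when present.
    """

    data: np.ndarray
    pixel_size_um: float
    frame_interval_s: float
    channels: tuple[str, ...] = ("ch0",)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.channels = tuple(self.channels)
        if self.data.ndim not in (3, 4):
            raise ValidationError(
                f"stack data must be T×H×W or T×C×H×W, got shape {self.data.shape}")
        if self.data.shape[0] < 1:
            raise ValidationError("stack must contain at least one frame")
        if not np.all(np.isfinite(self.data)):
            raise ValidationError("stack intensities must be finite (no NaN/Inf)")
        if np.any(self.data < 0):
            raise ValidationError("stack intensities must be non-negative")
        if not (self.pixel_size_um > 0):
            raise ValidationError("pixel_size_um must be strictly positive")
        if not (self.frame_interval_s > 0):
            raise ValidationError("frame_interval_s must be strictly positive")
        n_ch = self.data.shape[1] if self.data.ndim == 4 else 1
        if len(self.channels) != n_ch:
            raise ValidationError(
                f"{n_ch} channel axis entries but {len(self.channels)} labels")
        if len(set(self.channels)) != len(self.channels):
            raise ValidationError("channel labels must be unique")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.data.shape[-2], self.data.shape[-1]

    def channel(self, label: str) -> np.ndarray:
        """T×H×W view of one channel, by label."""
        if label not in self.channels:
            raise KeyError(f"channel {label!r} not in {self.channels}")
        if self.data.ndim == 3:
            return self.data
        return self.data[:, self.channels.index(label)]


@dataclass
class CellAnnotation:
    """One cell outline with optional nucleus and class call."""

    cell_id: str
    polygon: Polygon
    nucleus_polygon: Polygon | None = None
    cell_class: str = "unknown"
    nucleus_mask: np.ndarray | None = None
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.cell_class not in CELL_CLASSES:
            raise ValidationError(
                f"cell {self.cell_id}: class {self.cell_class!r} not in {CELL_CLASSES}")
        if not self.polygon.is_valid or self.polygon.is_empty:
            raise ValidationError(
                f"cell {self.cell_id}: polygon is not simple/valid")
        if self.nucleus_polygon is not None:
            if not self.nucleus_polygon.is_valid:
                raise ValidationError(
                    f"cell {self.cell_id}: nucleus polygon is not simple/valid")
            # boundary contact allowed; tiny buffer absorbs float round-off
            if not self.polygon.buffer(1e-9).covers(self.nucleus_polygon):
                raise ValidationError(
                    f"cell {self.cell_id}: nucleus polygon lies outside the cell")

    def cell_mask(self, shape: tuple[int, int]) -> np.ndarray:
        return polygon_to_mask(self.polygon, shape)


@dataclass
class AnnotationSet:
    """All cell annotations of one field of view."""

    cells: list[CellAnnotation]
    pixel_size_um: float
    image_shape: tuple[int, int]

    def __post_init__(self) -> None:
        if not (self.pixel_size_um > 0):
            raise ValidationError("pixel_size_um must be strictly positive")
        ids = [c.cell_id for c in self.cells]
        if len(set(ids)) != len(ids):
            raise ValidationError("cell ids must be unique")

    def __iter__(self):
        return iter(self.cells)

    def __len__(self) -> int:
        return len(self.cells)

    def get(self, cell_id: str) -> CellAnnotation:
        for c in self.cells:
            if c.cell_id == cell_id:
                return c
        raise KeyError(cell_id)


@dataclass
class TemCellAnnotation:
    """Manually annotated organelles of one TEM cell section."""

    cell_id: str
    plasma_membrane: Polygon
    nucleus: Polygon
    mitochondria: list[Polygon]
    golgi: list[Polygon] = field(default_factory=list)
    pixel_size_um: float = 1.0
    cell_type: str = "other"          # manual call: alpha / beta / other
    cristae_counts: list[int | None] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not (self.pixel_size_um > 0):
            raise ValidationError("pixel_size_um must be strictly positive")
        pm = self.plasma_membrane.buffer(1e-9)
        if not pm.covers(self.nucleus):
            raise ValidationError(
                f"cell {self.cell_id}: nucleus outside the plasma membrane")
        for i, m in enumerate(self.mitochondria):
            if not pm.covers(m):
                raise ValidationError(
                    f"cell {self.cell_id}: mitochondrion {i} outside the plasma membrane")
        for i, m in enumerate(self.mitochondria):
            for j in range(i + 1, len(self.mitochondria)):
                if m.equals(self.mitochondria[j]):
                    raise ValidationError(
                        f"cell {self.cell_id}: mitochondria {i} and {j} are identical")
        if not self.cristae_counts:
            self.cristae_counts = [None] * len(self.mitochondria)
        if len(self.cristae_counts) != len(self.mitochondria):
            raise ValidationError(
                f"cell {self.cell_id}: cristae_counts length mismatch")


@dataclass
class ResultsTable:
    """A results data frame plus the metadata needed to reproduce it."""

    df: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    def validate_against(self, annotations: AnnotationSet,
                         key: str = "cell_id") -> None:
        known = {c.cell_id for c in annotations}
        unknown = set(self.df[key].astype(str)) - known
        if unknown:
            raise ValidationError(f"rows reference unknown ids: {sorted(unknown)}")


# ---------------------------------------------------------------------------
# stacks
# ---------------------------------------------------------------------------

def write_stack(stack: TimeLapseStack, path: str | Path) -> Path:
    """Write a stack as OME-TIFF with pixel size, frame interval and channels."""
    path = Path(path)
    data = stack.data
    axes = "TYX" if data.ndim == 3 else "TCYX"
    metadata = {
        "axes": axes,
        "PhysicalSizeX": stack.pixel_size_um,
        "PhysicalSizeXUnit": "µm",
        "PhysicalSizeY": stack.pixel_size_um,
        "PhysicalSizeYUnit": "µm",
        "TimeIncrement": stack.frame_interval_s,
        "TimeIncrementUnit": "s",
        "Channel": {"Name": list(stack.channels)},
    }
    tifffile.imwrite(path, data, ome=True, metadata=metadata)
    return path


def _parse_ome(xml_str: str) -> dict:
    meta: dict = {}
    try:
        root = ET.fromstring(xml_str)
    except ET.ParseError:
        return meta
    for el in root.iter():
        tag = el.tag.rsplit("}", 1)[-1]
        if tag == "Pixels":
            for k in ("PhysicalSizeX", "TimeIncrement"):
                if k in el.attrib:
                    meta[k] = float(el.attrib[k])
        elif tag == "Channel" and "Name" in el.attrib:
            meta.setdefault("channels", []).append(el.attrib["Name"])
    return meta


def read_stack(path: str | Path,
               pixel_size_override: float | None = None,
               interval_override: float | None = None,
               channels: tuple[str, ...] | None = None) -> TimeLapseStack:
    """Read a TIFF/OME-TIFF into a validated :class:`TimeLapseStack`.

    OME tags supply pixel size, frame interval and channel names when present;
    explicit arguments override them. Axis order is normalized to T(×C)×H×W.
    """
    path = Path(path)
    for name, v in (("pixel_size_override", pixel_size_override),
                    ("interval_override", interval_override)):
        if v is not None and not (v > 0):
            raise ValidationError(f"{name} must be strictly positive")
    try:
        with tifffile.TiffFile(path) as tf:
            series = tf.series[0]
            data = series.asarray()
            axes = series.axes.upper()
            meta = _parse_ome(tf.ome_metadata) if tf.ome_metadata else {}
    except FileNotFoundError:
        raise
    except Exception as exc:  # noqa: BLE001 - surface the offending path
        raise OSError(f"cannot read TIFF stack from {path}: {exc}") from exc

    axes = axes.replace("S", "C").replace("Z", "T").replace("Q", "T")
    if data.ndim == 2:
        data = data[None]
        axes = "T" + axes
    order = [axes.index(a) for a in ("T", "C", "Y", "X") if a in axes]
    if len(order) != data.ndim or "Y" not in axes or "X" not in axes:
        raise ValidationError(f"unsupported TIFF axes {axes!r} in {path}")
    data = np.transpose(data, order)
    if "T" not in axes:
        data = data[None]

    pixel_size = pixel_size_override or meta.get("PhysicalSizeX")
    if pixel_size is None:
        raise ValidationError(
            f"{path}: no pixel size in metadata; pass pixel_size_override (µm)")
    interval = interval_override or meta.get("TimeIncrement", 1.0)
    n_ch = data.shape[1] if data.ndim == 4 else 1
    labels = channels or tuple(meta.get("channels", ())) or tuple(
        f"ch{i}" for i in range(n_ch))
    return TimeLapseStack(data=data, pixel_size_um=float(pixel_size),
                          frame_interval_s=float(interval), channels=labels)


# ---------------------------------------------------------------------------
# annotations (GeoJSON dialect)
# ---------------------------------------------------------------------------

def _poly_to_feature(poly: Polygon, props: dict) -> dict:
    coords = [list(map(list, np.asarray(poly.exterior.coords)))]
    return {"type": "Feature", "properties": props,
            "geometry": {"type": "Polygon", "coordinates": coords}}


def _feature_to_poly(feature: dict) -> Polygon:
    geom = feature.get("geometry") or {}
    if geom.get("type") != "Polygon":
        raise ValidationError(f"unsupported geometry type {geom.get('type')!r}")
    poly = Polygon(geom["coordinates"][0],
                   holes=geom["coordinates"][1:] or None)
    props = feature.get("properties") or {}
    if not poly.is_valid:
        raise ValidationError(
            f"self-intersecting polygon for cell {props.get('cell_id')!r}")
    return poly


def write_annotations(annotations: AnnotationSet, path: str | Path) -> Path:
    path = Path(path)
    features = []
    for cell in annotations:
        features.append(_poly_to_feature(cell.polygon, {
            "cell_id": cell.cell_id, "role": "cell", "class": cell.cell_class}))
        if cell.nucleus_polygon is not None:
            features.append(_poly_to_feature(cell.nucleus_polygon, {
                "cell_id": cell.cell_id, "role": "nucleus"}))
    doc = {"type": "FeatureCollection",
           "pixel_size_um": annotations.pixel_size_um,
           "image_shape": list(annotations.image_shape),
           "features": features}
    path.write_text(json.dumps(doc))
    return path


def read_annotations(path: str | Path,
                     pixel_size_um: float | None = None,
                     image_shape: tuple[int, int] | None = None) -> AnnotationSet:
    """Read a GeoJSON FeatureCollection of cell/nucleus polygons.

    Each feature carries properties ``cell_id``, ``role`` (cell or nucleus)
    and optionally ``class``. Polygons are grouped per cell id and validated.
    """
    path = Path(path)
    doc = json.loads(path.read_text())
    if doc.get("type") != "FeatureCollection":
        raise ValidationError(f"{path} is not a GeoJSON FeatureCollection")
    px = pixel_size_um or doc.get("pixel_size_um")
    if px is None:
        raise ValidationError(f"{path}: no pixel_size_um; pass it explicitly")
    shape = image_shape or tuple(doc.get("image_shape") or ())
    by_cell: dict[str, dict] = {}
    for feat in doc.get("features", []):
        props = feat.get("properties") or {}
        cid = str(props.get("cell_id"))
        role = props.get("role", "cell")
        poly = _feature_to_poly(feat)
        entry = by_cell.setdefault(cid, {"cell": None, "nucleus": None,
                                         "class": "unknown"})
        if role == "cell":
            entry["cell"] = poly
            entry["class"] = props.get("class", "unknown")
        elif role == "nucleus":
            entry["nucleus"] = poly
        else:
            raise ValidationError(
                f"{path}: role {role!r} not valid in a cell annotation file")
    cells = []
    for cid, entry in by_cell.items():
        if entry["cell"] is None:
            raise ValidationError(
                f"nucleus polygon for cell {cid} has no enclosing cell polygon")
        cells.append(CellAnnotation(cell_id=cid, polygon=entry["cell"],
                                    nucleus_polygon=entry["nucleus"],
                                    cell_class=entry["class"]))
    if not shape:
        maxx = max(c.polygon.bounds[2] for c in cells) if cells else 0
        maxy = max(c.polygon.bounds[3] for c in cells) if cells else 0
        shape = (int(np.ceil(maxy)) + 1, int(np.ceil(maxx)) + 1)
    return AnnotationSet(cells=cells, pixel_size_um=float(px),
                         image_shape=tuple(shape))


def annotations_from_labels(cell_labels: np.ndarray,
                            nucleus_labels: np.ndarray | None,
                            pixel_size_um: float) -> AnnotationSet:
    """Build an AnnotationSet from labeled masks (convenience ingestion).

    Outlines run along pixel edges, so rasterizing them back reproduces the
    label masks exactly. Nucleus labels are matched to cells by label value.
    """
    cells = []
    for lab in np.unique(cell_labels):
        if lab == 0:
            continue
        poly = mask_to_polygon(cell_labels == lab)
        nuc = None
        if nucleus_labels is not None and np.any(nucleus_labels == lab):
            nuc = mask_to_polygon(nucleus_labels == lab)
        cells.append(CellAnnotation(cell_id=str(int(lab)), polygon=poly,
                                    nucleus_polygon=nuc))
    return AnnotationSet(cells=cells, pixel_size_um=pixel_size_um,
                         image_shape=cell_labels.shape)


def write_tem_annotations(cells: list[TemCellAnnotation], path: str | Path) -> Path:
    path = Path(path)
    features = []
    for cell in cells:
        features.append(_poly_to_feature(cell.plasma_membrane, {
            "cell_id": cell.cell_id, "role": "plasma_membrane",
            "class": cell.cell_type}))
        features.append(_poly_to_feature(cell.nucleus, {
            "cell_id": cell.cell_id, "role": "nucleus"}))
        for g in cell.golgi:
            features.append(_poly_to_feature(g, {
                "cell_id": cell.cell_id, "role": "golgi"}))
        for m, cc in zip(cell.mitochondria, cell.cristae_counts):
            props = {"cell_id": cell.cell_id, "role": "mitochondrion"}
            if cc is not None:
                props["cristae_count"] = int(cc)
            features.append(_poly_to_feature(m, props))
    doc = {"type": "FeatureCollection",
           "pixel_size_um": cells[0].pixel_size_um if cells else 1.0,
           "features": features}
    path.write_text(json.dumps(doc))
    return path


def read_tem_annotations(path: str | Path,
                         pixel_size_um: float | None = None
                         ) -> list[TemCellAnnotation]:
    """Read TEM organelle annotations (plasma membrane, nucleus, Golgi,
    mitochondria per cell id) from a GeoJSON FeatureCollection."""
    path = Path(path)
    doc = json.loads(path.read_text())
    px = pixel_size_um or doc.get("pixel_size_um")
    if px is None:
        raise ValidationError(f"{path}: no pixel_size_um; pass it explicitly")
    by_cell: dict[str, dict] = {}
    for feat in doc.get("features", []):
        props = feat.get("properties") or {}
        cid = str(props.get("cell_id"))
        role = props.get("role")
        poly = _feature_to_poly(feat)
        entry = by_cell.setdefault(cid, {"pm": None, "nucleus": None,
                                         "golgi": [], "mito": [],
                                         "cristae": [], "type": "other"})
        if role == "plasma_membrane":
            entry["pm"] = poly
            entry["type"] = props.get("class", "other")
        elif role == "nucleus":
            entry["nucleus"] = poly
        elif role == "golgi":
            entry["golgi"].append(poly)
        elif role == "mitochondrion":
            entry["mito"].append(poly)
            cc = props.get("cristae_count")
            entry["cristae"].append(int(cc) if cc is not None else None)
        else:
            raise ValidationError(f"{path}: role {role!r} not a TEM role")
    cells = []
    for cid, e in by_cell.items():
        if e["pm"] is None or e["nucleus"] is None:
            raise ValidationError(
                f"cell {cid}: TEM annotation needs plasma membrane and nucleus")
        cells.append(TemCellAnnotation(
            cell_id=cid, plasma_membrane=e["pm"], nucleus=e["nucleus"],
            mitochondria=e["mito"], golgi=e["golgi"], pixel_size_um=float(px),
            cell_type=e["type"], cristae_counts=e["cristae"]))
    return cells


# ---------------------------------------------------------------------------
# result tables
# ---------------------------------------------------------------------------

def write_results(table: ResultsTable, path: str | Path) -> Path:
    """Write a results table as CSV plus a ``<name>.meta.json`` sidecar."""
    path = Path(path)
    table.df.to_csv(path, index=False, float_format="%.12g")
    sidecar = path.with_suffix(path.suffix + ".meta.json")
    sidecar.write_text(json.dumps(table.metadata, indent=2, sort_keys=True,
                                  default=str))
    return path


def read_results(path: str | Path) -> ResultsTable:
    path = Path(path)
    df = pd.read_csv(path)
    sidecar = path.with_suffix(path.suffix + ".meta.json")
    metadata = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    return ResultsTable(df=df, metadata=metadata)
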