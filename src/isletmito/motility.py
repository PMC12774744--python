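"""Mitochondrial motility quantification from time-lapse stacks.

The motility proxy is the per-pixel temporal standard deviation of the
mitochondrial channel: moving mitochondria sweep intensity through pixels
and inflate their SD over time, while stationary structures (and uniform
background) leave it low. Per cell, the SD image is normalized to the
maximal value observed in that cell, then sampled along radial line profiles
cast from the nucleus centroid every θ degrees; profiles start at the
nucleus periphery and cover a fixed cytosolic fraction (default 7 µm).
Per-cell motility is the mean of the normalized SD over all retained lines.

The temporal-mean image is kept alongside the SD image as a bleaching /
membrane-potential control; the correlation between the two over the cell is
reported as a QC statistic (high |r| suggests intensity-driven artefacts).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.filters import threshold_otsu

from ._geometry import polygon_to_mask
from .io import AnnotationSet, CellAnnotation, ResultsTable, TimeLapseStack, ValidationError


@dataclass
class MotilityMap:
    """Temporal SD and mean projections of one channel."""

    sd_image: np.ndarray
    mean_image: np.ndarray
    n_frames: int
    channel: str
    estimator: str = "sample_sd_ddof1"


@dataclass
class RadialProfileSet:
    """Sampled normalized-SD values along radial rays from the nucleus.

    ``values[i, j]`` is the normalized SD on ray i at ``distances_um[j]`` from
    the nucleus boundary; rows of non-retained rays are NaN.
    """

    angles_deg: np.ndarray
    distances_um: np.ndarray
    values: np.ndarray
    retained: np.ndarray
    theta_deg: float
    fraction_um: float
    flags: list[str] = field(default_factory=list)

    @property
    def n_candidate_lines(self) -> int:
        return len(self.angles_deg)

    @property
    def n_retained(self) -> int:
        return int(self.retained.sum())


@dataclass
class NormalizedCell:
    """Per-cell max-normalized SD image with its raw maximum."""

    norm_image: np.ndarray
    max_raw_sd: float
    cell_mask: np.ndarray
    degenerate: bool = False


@dataclass
class MotilityResult:
    cell_id: str
    cell_class: str
    bin_centers_um: np.ndarray
    profile: np.ndarray           # binned mean normalized SD per distance bin
    overall_mean: float
    max_raw_sd: float
    n_lines_retained: int
    qc_sd_mean_r: float
    degenerate: bool = False
    flags: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------

def temporal_sd_projection(stack: TimeLapseStack, channel: str) -> MotilityMap:
    """Collapse a time series into per-pixel temporal SD and mean images.

    The SD is the sample standard deviation (T−1 denominator) of each pixel
    over frames.
    """
    frames = stack.channel(channel).astype(float)
    if frames.shape[0] < 2:
        raise ValidationError("temporal SD needs at least 2 frames")
    sd = frames.std(axis=0, ddof=1)
    mean = frames.mean(axis=0)
    return MotilityMap(sd_image=sd, mean_image=mean,
                       n_frames=frames.shape[0], channel=channel)


def _largest_component(mask: np.ndarray) -> np.ndarray:
    labels, n = ndimage.label(mask)
    if n == 0:
        return mask
    sizes = ndimage.sum_labels(mask, labels, index=np.arange(1, n + 1))
    return labels == (1 + int(np.argmax(sizes)))


def segment_nucleus(stack: TimeLapseStack, cell: CellAnnotation,
                    mode: str = "gfp",
                    manual_threshold: float | None = None,
                    nuclear_channel: str = "nuclear",
                    mito_channel: str = "mito",
                    min_contrast: float = 5.0) -> np.ndarray:
    """Segment the nucleus of one cell by thresholding a temporal-mean image.

    mode="gfp": Otsu (or ``manual_threshold``) on the nuclear-marker channel;
    the nucleus is the largest bright component. mode="mito_inverse": the
    largest dark (below-Otsu) component of the mitochondrial channel, for
    marker-negative cells. The mask is stored on the annotation; a flag is
    added when more than half of the nucleus border hugs the cell border.
    """
    if mode not in ("gfp", "mito_inverse", "manual"):
        raise ValidationError(f"unknown segmentation mode {mode!r}")
    shape = stack.frame_shape
    cell_mask = cell.cell_mask(shape)
    if not cell_mask.any():
        raise ValidationError(f"cell {cell.cell_id}: degenerate cell polygon")
    ch = mito_channel if mode == "mito_inverse" else nuclear_channel
    img = stack.channel(ch).astype(float).mean(axis=0)
    vals = img[cell_mask]
    if manual_threshold is not None:
        if manual_threshold > vals.max():
            raise ValidationError(
                f"cell {cell.cell_id}: manual threshold above image maximum")
        thr = manual_threshold
    else:
        if np.ptp(vals) == 0:
            raise ValidationError(f"nucleus not found in cell {cell.cell_id}")
        thr = threshold_otsu(vals)
        if mode == "gfp":
            # with no real marker Otsu just splits read noise; demand a
            # bright class well separated from the dark one
            fg, bg = vals[vals > thr], vals[vals <= thr]
            if fg.size == 0 or bg.size == 0 or (
                    fg.mean() - bg.mean()) < min_contrast * max(bg.std(), 1e-12):
                raise ValidationError(
                    f"nucleus not found in cell {cell.cell_id} "
                    "(no marker contrast)")
    if mode == "mito_inverse":
        cand = (img < thr) & cell_mask
    else:
        cand = (img > thr) & cell_mask
    if not cand.any():
        raise ValidationError(f"nucleus not found in cell {cell.cell_id}")
    mask = ndimage.binary_fill_holes(_largest_component(cand))

    nuc_border = mask & ~ndimage.binary_erosion(mask)
    cell_border = cell_mask & ~ndimage.binary_erosion(cell_mask)
    near_cell_border = ndimage.binary_dilation(cell_border) & nuc_border
    if nuc_border.any() and near_cell_border.sum() > 0.5 * nuc_border.sum():
        cell.flags.append("implausible_nucleus_touches_cell_border")
        warnings.warn(f"cell {cell.cell_id}: nucleus hugs the cell border",
                      stacklevel=2)
    cell.nucleus_mask = mask
    return mask


def classify_cells(stack: TimeLapseStack, annotations: AnnotationSet,
                   nuclear_channel: str = "nuclear",
                   threshold_mode: str = "otsu_global",
                   fixed_threshold: float | None = None) -> AnnotationSet:
    """Call each cell alpha / non-alpha from nuclear-marker brightness.

    The per-cell statistic is the mean nuclear-channel intensity inside the
    nucleus mask (segmented beforehand, or rasterized from the annotated
    nucleus polygon). With ``otsu_global`` the alpha threshold is an Otsu
    split of the per-cell means; with ``fixed``, ``fixed_threshold`` is used
    (mean ≥ threshold → alpha).
    """
    img = stack.channel(nuclear_channel).astype(float).mean(axis=0)
    shape = stack.frame_shape
    means = []
    for cell in annotations:
        mask = cell.nucleus_mask
        if mask is None:
            if cell.nucleus_polygon is None:
                raise ValidationError(
                    f"cell {cell.cell_id}: no nucleus mask or polygon; "
                    "segment nuclei first")
            mask = polygon_to_mask(cell.nucleus_polygon, shape)
            cell.nucleus_mask = mask
        if not mask.any():
            raise ValidationError(f"cell {cell.cell_id}: empty nucleus mask")
        means.append(float(img[mask].mean()))
    means_arr = np.asarray(means)
    if threshold_mode == "fixed":
        if fixed_threshold is None:
            raise ValidationError("fixed threshold_mode needs fixed_threshold")
        alpha = means_arr >= fixed_threshold
    elif threshold_mode == "otsu_global":
        if len(means_arr) < 2:
            raise ValidationError(
                "otsu_global needs >= 2 cells; use threshold_mode='fixed'")
        if np.ptp(means_arr) == 0:
            raise ValidationError(
                "identical nuclear means; use threshold_mode='fixed'")
        thr = threshold_otsu(means_arr)
        alpha = means_arr > thr
    else:
        raise ValidationError(f"unknown threshold_mode {threshold_mode!r}")
    for cell, is_alpha in zip(annotations, alpha):
        cell.cell_class = "alpha" if is_alpha else "non_alpha"
    return annotations


def normalize_to_cell_max(mmap: MotilityMap,
                          cell: CellAnnotation) -> NormalizedCell:
    """Divide the SD image by its maximum inside the cell mask.

    The cell-wide maximum (nucleus included) is the "maximal motility" of the
    cell and is reported separately. A cell whose SD is identically zero is
    flagged degenerate and gets an all-zero normalized image.
    """
    mask = cell.cell_mask(mmap.sd_image.shape)
    if not mask.any():
        raise ValidationError(f"cell {cell.cell_id}: empty cell mask")
    max_raw = float(mmap.sd_image[mask].max())
    if max_raw <= 0:
        return NormalizedCell(norm_image=np.zeros_like(mmap.sd_image),
                              max_raw_sd=0.0, cell_mask=mask, degenerate=True)
    norm = np.clip(mmap.sd_image / max_raw, 0.0, 1.0)
    return NormalizedCell(norm_image=norm, max_raw_sd=max_raw, cell_mask=mask)


def _last_inside(mask: np.ndarray, origin: np.ndarray, direction: np.ndarray,
                 t_max: float, step: float = 0.25) -> float:
    """Largest ray parameter t (px) with the nearest pixel inside the mask."""
    ts = np.arange(0.0, t_max + step, step)
    xs = origin[0] + ts * direction[0]
    ys = origin[1] + ts * direction[1]
    xi = np.clip(np.round(xs).astype(int), 0, mask.shape[1] - 1)
    yi = np.clip(np.round(ys).astype(int), 0, mask.shape[0] - 1)
    inside = mask[yi, xi]
    inside &= (np.round(xs) >= 0) & (np.round(xs) < mask.shape[1]) \
        & (np.round(ys) >= 0) & (np.round(ys) < mask.shape[0])
    if not inside.any():
        return -1.0
    return float(ts[np.nonzero(inside)[0][-1]])


def radial_line_profiles(norm: NormalizedCell, cell: CellAnnotation,
                         pixel_size_um: float,
                         theta_deg: float = 10.0,
                         fraction_um: float = 7.0,
                         sample_step_um: float | None = None,
                         short_ray_mode: str = "exclude") -> RadialProfileSet:
    """Sample the normalized SD image along rays from the nucleus centroid.

    One candidate ray per ``theta_deg`` of angle (θ must divide 360). Each
    profile starts at the ray's last crossing of the nucleus boundary
    (distance 0 = nucleus periphery) and is sampled by bilinear interpolation
    every ``sample_step_um`` (default: one pixel) out to ``fraction_um``.
    A ray is retained only if the nucleus-boundary→cell-boundary span along
    it is at least ``fraction_um``; shorter rays are excluded, keeping all
    retained profiles the same fixed length (``short_ray_mode="truncate"``
    instead samples short rays out to the cell boundary).
    """
    if not float(360 / theta_deg).is_integer():
        raise ValidationError("theta_deg must divide 360")
    if short_ray_mode not in ("exclude", "truncate"):
        raise ValidationError(f"unknown short_ray_mode {short_ray_mode!r}")
    nuc_mask = cell.nucleus_mask
    if nuc_mask is None or not nuc_mask.any():
        raise ValidationError(f"cell {cell.cell_id}: nucleus mask required")
    step_um = sample_step_um or pixel_size_um
    flags: list[str] = []

    cy, cx = ndimage.center_of_mass(nuc_mask)
    if not nuc_mask[int(round(cy)), int(round(cx))]:
        # non-convex nucleus: fall back to the most interior point
        dt = ndimage.distance_transform_edt(nuc_mask)
        cy, cx = np.unravel_index(np.argmax(dt), dt.shape)
        flags.append("centroid_outside_nucleus_used_internal_pole")
        warnings.warn(f"cell {cell.cell_id}: nucleus centroid outside mask; "
                      "using internal pole", stacklevel=2)
    origin = np.array([cx, cy], dtype=float)

    cell_mask = norm.cell_mask
    n_lines = int(round(360 / theta_deg))
    angles = np.arange(n_lines) * theta_deg
    n_samples = int(round(fraction_um / step_um)) + 1
    distances = np.linspace(0.0, fraction_um, n_samples)
    values = np.full((n_lines, n_samples), np.nan)
    retained = np.zeros(n_lines, dtype=bool)
    t_max = float(np.hypot(*cell_mask.shape))

    for i, ang in enumerate(angles):
        rad = np.deg2rad(ang)
        direction = np.array([np.cos(rad), np.sin(rad)])
        t_nuc = _last_inside(nuc_mask, origin, direction, t_max)
        t_cell = _last_inside(cell_mask, origin, direction, t_max)
        if t_nuc < 0 or t_cell <= t_nuc:
            continue
        span_um = (t_cell - t_nuc) * pixel_size_um
        if span_um < fraction_um and short_ray_mode == "exclude":
            continue
        d = distances if span_um >= fraction_um else distances[
            distances <= span_um]
        ts = t_nuc + d / pixel_size_um
        xs = origin[0] + ts * direction[0]
        ys = origin[1] + ts * direction[1]
        vals = ndimage.map_coordinates(norm.norm_image, [ys, xs], order=1,
                                       mode="nearest")
        values[i, :len(d)] = vals
        retained[i] = True

    return RadialProfileSet(angles_deg=angles, distances_um=distances,
                            values=values, retained=retained,
                            theta_deg=theta_deg, fraction_um=fraction_um,
                            flags=flags)


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    den = np.sqrt((a * a).sum() * (b * b).sum())
    if den == 0:
        return 0.0
    return float((a * b).sum() / den)


def motility_result(profiles: RadialProfileSet, mmap: MotilityMap,
                    norm: NormalizedCell, cell: CellAnnotation,
                    bin_width_um: float = 0.5) -> MotilityResult:
    """Aggregate radial profiles into the per-cell motility summary.

    The distance profile is the bin-wise mean of normalized SD over all
    retained lines; the overall motility is the mean over every sample of
    every retained line. ``qc_sd_mean_r`` is the Pearson correlation between
    the SD and temporal-mean images over the cell (intensity-artefact QC).
    """
    if profiles.n_retained == 0:
        raise ValidationError(
            f"cell {cell.cell_id}: no line spans the {profiles.fraction_um} µm "
            "cytosolic fraction; cell too small for this fraction length")
    vals = profiles.values[profiles.retained]
    n_bins = int(np.ceil(profiles.fraction_um / bin_width_um))
    idx = np.minimum((profiles.distances_um / bin_width_um).astype(int),
                     n_bins - 1)
    profile = np.full(n_bins, np.nan)
    for b in range(n_bins):
        sel = vals[:, idx == b]
        if sel.size and np.isfinite(sel).any():
            profile[b] = np.nanmean(sel)
    overall = float(np.nanmean(vals))
    qc_r = _pearson(mmap.sd_image[norm.cell_mask],
                    mmap.mean_image[norm.cell_mask])
    centers = (np.arange(n_bins) + 0.5) * bin_width_um
    return MotilityResult(cell_id=cell.cell_id, cell_class=cell.cell_class,
                          bin_centers_um=centers, profile=profile,
                          overall_mean=overall, max_raw_sd=norm.max_raw_sd,
                          n_lines_retained=profiles.n_retained,
                          qc_sd_mean_r=qc_r, degenerate=norm.degenerate,
                          flags=list(cell.flags) + list(profiles.flags))


def qc_sd_vs_mean(results: list[MotilityResult],
                  cutoff: float = 0.7) -> dict:
    """Summarize SD-vs-mean correlations and flag suspect cells.

    Cells whose |r| exceeds ``cutoff`` are flagged as possibly contaminated
    by membrane-potential or quenching artefacts rather than motility.
    """
    if len(results) < 3:
        raise ValidationError("QC summary needs at least 3 cells")
    rs = np.array([r.qc_sd_mean_r for r in results])
    q1, med, q3 = np.percentile(rs, [25, 50, 75])
    flagged = [r.cell_id for r in results if abs(r.qc_sd_mean_r) > cutoff]
    return {"median_r": float(med), "iqr": float(q3 - q1),
            "flagged": flagged, "cutoff": cutoff, "n_cells": len(results)}


# ---------------------------------------------------------------------------

def analyze_movie(stack: TimeLapseStack, annotations: AnnotationSet,
                  mito_channel: str = "mito",
                  nuclear_channel: str = "nuclear",
                  theta_deg: float = 10.0,
                  fraction_um: float = 7.0,
                  bin_width_um: float = 0.5,
                  nucleus_source: str = "segment",
                  classify: bool = False,
                  fixed_threshold: float | None = None,
                  short_ray_mode: str = "exclude",
                  skip_failures: bool = False
                  ) -> tuple[list[MotilityResult], ResultsTable]:
    """Run the full motility pipeline over all annotated cells.

    ``nucleus_source="segment"`` thresholds the nuclear channel (falling back
    to the mitochondrial-channel dark region, then to the annotated nucleus
    polygon); ``"annotation"`` rasterizes annotated nucleus polygons directly.
    Returns per-cell results and a tidy table (one row per cell, one column
    per distance bin) with full parameter metadata.
    """
    mmap = temporal_sd_projection(stack, mito_channel)
    results: list[MotilityResult] = []
    for cell in annotations:
        try:
            if nucleus_source == "annotation" and cell.nucleus_polygon is not None:
                cell.nucleus_mask = polygon_to_mask(cell.nucleus_polygon,
                                                    stack.frame_shape)
            else:
                try:
                    segment_nucleus(stack, cell, mode="gfp",
                                    nuclear_channel=nuclear_channel,
                                    mito_channel=mito_channel)
                except ValidationError:
                    if cell.nucleus_polygon is not None:
                        cell.nucleus_mask = polygon_to_mask(
                            cell.nucleus_polygon, stack.frame_shape)
                    else:
                        segment_nucleus(stack, cell, mode="mito_inverse",
                                        mito_channel=mito_channel)
            norm = normalize_to_cell_max(mmap, cell)
            profiles = radial_line_profiles(
                norm, cell, stack.pixel_size_um, theta_deg=theta_deg,
                fraction_um=fraction_um, short_ray_mode=short_ray_mode)
            results.append(motility_result(profiles, mmap, norm, cell,
                                           bin_width_um=bin_width_um))
        except ValidationError:
            if not skip_failures:
                raise
    if classify:
        classify_cells(stack, annotations, nuclear_channel=nuclear_channel,
                       threshold_mode="fixed" if fixed_threshold is not None
                       else "otsu_global", fixed_threshold=fixed_threshold)
        by_id = {c.cell_id: c.cell_class for c in annotations}
        for r in results:
            r.cell_class = by_id.get(r.cell_id, r.cell_class)

    rows = []
    for r in results:
        row = {"cell_id": r.cell_id, "class": r.cell_class,
               "n_lines": r.n_lines_retained, "max_raw_sd": r.max_raw_sd,
               "mean_norm_motility": r.overall_mean, "qc_r": r.qc_sd_mean_r}
        for c, v in zip(r.bin_centers_um, r.profile):
            row[f"bin_{c:.2f}um"] = v
        rows.append(row)
    table = ResultsTable(
        df=pd.DataFrame(rows),
        metadata={"operation": "motility", "theta_deg": theta_deg,
                  "fraction_um": fraction_um, "bin_width_um": bin_width_um,
                  "mito_channel": mito_channel,
                  "nuclear_channel": nuclear_channel,
                  "short_ray_mode": short_ray_mode,
                  "nucleus_source": nucleus_source,
                  "sd_estimator": "sample_sd_ddof1",
                  "pixel_size_um": stack.pixel_size_um})
    return results, table
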