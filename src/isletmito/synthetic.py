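"""Ground-truth simulators for every stage of the pipeline.

Three generators emulate the data the analysis assumes, with known truth:

* :func:`simulate_movie` — whole-islet style time-lapse: cells containing
  elongated Gaussian "mitochondria" blobs, a fraction of which perform a
  reflected random walk in the cytosol, plus a nuclear marker channel present
  only in alpha cells. Defaults follow a typical confocal acquisition of
  18 frames at 5 s (≈1.5 min) with ~1 µm optical sections.
* :func:`simulate_ratio_movie` — dual-excitation biosensor stack whose pixel
  ratio is piecewise constant, with high-ratio microdomains planted just
  below the plasma membrane that vanish at a configured frame.
* :func:`simulate_tem_annotations` — TEM-style polygon annotations (plasma
  membrane, nucleus, Golgi components, mitochondria) with brute-force
  ground-truth organelle distances from dense boundary sampling.

All generators are bit-reproducible from their seed.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree
from shapely.geometry import Point, Polygon

from ._geometry import ellipse_polygon, regular_polygon, resample_boundary
from .io import AnnotationSet, CellAnnotation, TemCellAnnotation, TimeLapseStack, ValidationError


@dataclass
class MovieConfig:
    """Parameters of a simulated time-lapse movie.

    Length scales are in µm; the defaults emulate mouse islet cells large
    enough to carry the 7 µm cytosolic fraction used downstream.
    """

    n_cells: int = 4
    cell_radius_um: float = 11.0
    nucleus_radius_um: float = 3.5
    mito_per_cell: int = 40
    mito_length_um: float = 2.0
    mito_width_um: float = 0.4
    motile_fraction: float = 1.0
    step_sigma_um: float = 0.3      # per-frame random-walk step SD, per axis
    n_frames: int = 18
    frame_interval_s: float = 5.0
    pixel_size_um: float = 0.2
    gaussian_sigma: float = 0.5     # additive read noise SD (counts)
    poisson: bool = True
    bleach_rate_per_frame: float = 0.0
    alpha_fraction: float = 0.5
    blob_amplitude: float = 3000.0  # peak photon count of one blob
    nuclear_amplitude: float = 2000.0
    background: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        if not (0 < self.nucleus_radius_um < self.cell_radius_um):
            raise ValidationError(
                "need 0 < nucleus_radius_um < cell_radius_um")
        for name in ("cell_radius_um", "nucleus_radius_um", "mito_length_um",
                     "mito_width_um", "pixel_size_um", "frame_interval_s"):
            if not (getattr(self, name) > 0):
                raise ValidationError(f"{name} must be > 0")
        for name in ("motile_fraction", "alpha_fraction"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValidationError(f"{name} must be in [0, 1]")
        if not (0 <= self.bleach_rate_per_frame < 1):
            raise ValidationError("bleach_rate_per_frame must be in [0, 1)")
        if self.n_frames < 1 or self.n_cells < 1:
            raise ValidationError("n_frames and n_cells must be >= 1")
        if self.step_sigma_um < 0 or self.gaussian_sigma < 0:
            raise ValidationError("step_sigma_um and gaussian_sigma must be >= 0")


@dataclass
class GroundTruthCell:
    cell_id: str
    cell_class: str
    center_um: np.ndarray
    polygon: Polygon
    nucleus_polygon: Polygon
    trajectories_um: np.ndarray      # (n_blobs, n_frames, 2), absolute µm
    motile: np.ndarray               # (n_blobs,) bool
    microdomains: list[dict] = field(default_factory=list)


@dataclass
class GroundTruth:
    cells: list[GroundTruthCell]
    extras: dict = field(default_factory=dict)


@dataclass
class MicrodomainSpec:
    """Planted sub-plasma-membrane high-ratio domains."""

    count: int = 3
    radius_um: float = 1.0
    ratio_high: float = 2.0
    ratio_low: float = 1.0
    vanish_at_frame: int = 9
    shell_width_um: float = 4.0

    def validate(self) -> None:
        if not (self.ratio_high > self.ratio_low > 0):
            raise ValidationError("need ratio_high > ratio_low > 0")
        if self.radius_um > self.shell_width_um:
            raise ValidationError(
                "microdomain radius exceeds the sub-membrane shell width")
        if self.count < 0:
            raise ValidationError("count must be >= 0")


# ---------------------------------------------------------------------------
# layout helpers
# ---------------------------------------------------------------------------

def _cell_layout(config: MovieConfig) -> tuple[np.ndarray, tuple[int, int]]:
    """Cell centers (µm) on a square grid and the image shape (px)."""
    cols = int(np.ceil(np.sqrt(config.n_cells)))
    rows = int(np.ceil(config.n_cells / cols))
    # pitch leaves room for the full 7σ blob support so no flux leaves the frame
    pitch = 2 * config.cell_radius_um + 3.5 * config.mito_length_um + 1.0
    centers = np.array([
        [(i % cols + 0.5) * pitch, (i // cols + 0.5) * pitch]
        for i in range(config.n_cells)])
    w = int(np.ceil(cols * pitch / config.pixel_size_um))
    h = int(np.ceil(rows * pitch / config.pixel_size_um))
    return centers, (h, w)


def _add_gaussian_blob(frame: np.ndarray, cx: float, cy: float,
                       s_major: float, s_minor: float, angle: float,
                       amplitude: float) -> None:
    """Add an anisotropic Gaussian at (cx, cy) px in place (local patch only)."""
    # 7σ support keeps the sampled blob mass constant to ~1e-10 as it moves
    r = int(np.ceil(7.0 * s_major)) + 1
    h, w = frame.shape
    x0, x1 = max(int(cx) - r, 0), min(int(cx) + r + 1, w)
    y0, y1 = max(int(cy) - r, 0), min(int(cy) + r + 1, h)
    if x1 <= x0 or y1 <= y0:
        return
    xs, ys = np.meshgrid(np.arange(x0, x1) - cx, np.arange(y0, y1) - cy)
    c, s = np.cos(angle), np.sin(angle)
    u = c * xs + s * ys
    v = -s * xs + c * ys
    frame[y0:y1, x0:x1] += amplitude * np.exp(
        -0.5 * ((u / s_major) ** 2 + (v / s_minor) ** 2))


def _reflect_radial(pos: np.ndarray, inner: float, outer: float) -> np.ndarray:
    """Reflect a 2-D offset at concentric circular walls (nucleus, membrane)."""
    r = np.hypot(*pos)
    if r == 0:
        return pos
    r_new = r
    if r_new > outer:
        r_new = 2 * outer - r_new
    if r_new < inner:
        r_new = 2 * inner - r_new
    r_new = min(max(r_new, inner), outer)
    return pos * (r_new / r)


# ---------------------------------------------------------------------------
# fluorescence movie
# ---------------------------------------------------------------------------

def simulate_movie(config: MovieConfig
                   ) -> tuple[TimeLapseStack, AnnotationSet, GroundTruth]:
    """Simulate a two-channel ("mito", "nuclear") islet time-lapse.

    Motile blobs perform an isotropic Gaussian random walk (per-axis step SD
    ``step_sigma_um`` per frame) reflected at the nucleus and cell boundaries;
    stationary blobs never move. The nuclear channel is a bright uniform disk
    present only in alpha cells. Poisson shot noise is applied to the signal,
    then additive Gaussian read noise; bleaching is a per-frame geometric
    decay of the signal before noise.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    px = config.pixel_size_um
    centers, (h, w) = _cell_layout(config)

    n_alpha = int(round(config.alpha_fraction * config.n_cells))
    classes = np.array(["alpha"] * n_alpha
                       + ["non_alpha"] * (config.n_cells - n_alpha))
    rng.shuffle(classes)

    margin = max(config.mito_length_um / 2, 0.5)
    inner = config.nucleus_radius_um + margin
    outer = config.cell_radius_um - margin
    if inner >= outer:
        raise ValidationError("cell too small for the requested blob size")

    gt_cells: list[GroundTruthCell] = []
    annotations: list[CellAnnotation] = []
    signal = np.zeros((config.n_frames, 2, h, w))

    nuclear_plane = np.zeros((h, w))
    for ci, (center, cls) in enumerate(zip(centers, classes)):
        # nucleus offset kept small so every ray retains >= 7 µm of cytosol
        off = rng.uniform(-0.3, 0.3, size=2)
        nuc_center = center + off
        cell_poly = regular_polygon(*(center / px), config.cell_radius_um / px,
                                    n=96)
        nuc_poly = regular_polygon(*(nuc_center / px),
                                   config.nucleus_radius_um / px, n=64)

        # blob initial positions: uniform in the cytosolic annulus
        u = rng.uniform(size=config.mito_per_cell)
        radii = np.sqrt(u * (outer ** 2 - inner ** 2) + inner ** 2)
        theta = rng.uniform(0, 2 * np.pi, size=config.mito_per_cell)
        offsets = np.column_stack([radii * np.cos(theta),
                                   radii * np.sin(theta)])
        motile = rng.uniform(size=config.mito_per_cell) < config.motile_fraction
        angles = rng.uniform(0, np.pi, size=config.mito_per_cell)

        traj = np.empty((config.mito_per_cell, config.n_frames, 2))
        traj[:, 0] = offsets
        for t in range(1, config.n_frames):
            steps = rng.normal(0.0, config.step_sigma_um,
                               size=(config.mito_per_cell, 2))
            for b in range(config.mito_per_cell):
                if motile[b] and config.step_sigma_um > 0:
                    traj[b, t] = _reflect_radial(traj[b, t - 1] + steps[b],
                                                 inner, outer)
                else:
                    traj[b, t] = traj[b, t - 1]
        traj_abs = traj + center

        s_major = config.mito_length_um / 4 / px
        s_minor = config.mito_width_um / 4 / px
        for t in range(config.n_frames):
            for b in range(config.mito_per_cell):
                cx, cy = traj_abs[b, t] / px
                _add_gaussian_blob(signal[t, 0], cx, cy, s_major, s_minor,
                                   angles[b], config.blob_amplitude)
        if cls == "alpha":
            dist2 = ((np.arange(w) - nuc_center[0] / px)[None, :] ** 2
                     + (np.arange(h) - nuc_center[1] / px)[:, None] ** 2)
            nuclear_plane[dist2 <= (config.nucleus_radius_um / px) ** 2] = \
                config.nuclear_amplitude

        cid = f"cell_{ci:02d}"
        annotations.append(CellAnnotation(cell_id=cid, polygon=cell_poly,
                                          nucleus_polygon=nuc_poly,
                                          cell_class="unknown"))
        gt_cells.append(GroundTruthCell(
            cell_id=cid, cell_class=str(cls), center_um=center,
            polygon=cell_poly, nucleus_polygon=nuc_poly,
            trajectories_um=traj_abs, motile=motile))

    signal[:, 0] += config.background
    signal[:, 1] = nuclear_plane[None]
    if config.bleach_rate_per_frame > 0:
        decay = (1 - config.bleach_rate_per_frame) ** np.arange(config.n_frames)
        signal *= decay[:, None, None, None]

    data = signal
    if config.poisson:
        data = rng.poisson(data).astype(float)
    if config.gaussian_sigma > 0:
        data = data + rng.normal(0.0, config.gaussian_sigma, size=data.shape)
    data = np.clip(data, 0.0, None)

    stack = TimeLapseStack(data=data, pixel_size_um=px,
                           frame_interval_s=config.frame_interval_s,
                           channels=("mito", "nuclear"))
    ann = AnnotationSet(cells=annotations, pixel_size_um=px, image_shape=(h, w))
    return stack, ann, GroundTruth(cells=gt_cells)


# ---------------------------------------------------------------------------
# ratio movie
# ---------------------------------------------------------------------------

def simulate_ratio_movie(config: MovieConfig,
                         microdomains: MicrodomainSpec | None = None,
                         base_intensity: float = 100.0,
                         mult_sigma: float = 0.0
                         ) -> tuple[TimeLapseStack, AnnotationSet, GroundTruth]:
    """Simulate a dual-excitation ("ex476", "ex405") biosensor stack.

    The per-pixel intensity ratio ex476/ex405 equals ``ratio_low`` everywhere
    inside cells except inside planted sub-membrane microdomain disks, where
    it equals ``ratio_high`` until ``vanish_at_frame``. ``mult_sigma`` > 0
    applies independent multiplicative log-normal noise to both channels.
    """
    config.validate()
    spec = microdomains or MicrodomainSpec()
    spec.validate()
    rng = np.random.default_rng(config.seed)
    px = config.pixel_size_um
    centers, (h, w) = _cell_layout(config)
    xs, ys = np.meshgrid(np.arange(w) * px, np.arange(h) * px)

    ratio = np.full((config.n_frames, h, w), spec.ratio_low)
    ex405 = np.zeros((h, w))
    gt_cells: list[GroundTruthCell] = []
    annotations: list[CellAnnotation] = []
    R = config.cell_radius_um
    for ci, center in enumerate(centers):
        cell_poly = regular_polygon(*(center / px), R / px, n=96)
        nuc_poly = regular_polygon(*(center / px),
                                   config.nucleus_radius_um / px, n=64)
        dist2 = (xs - center[0]) ** 2 + (ys - center[1]) ** 2
        inside = dist2 <= R ** 2
        ex405[inside] = base_intensity

        domains = []
        margin = 0.05 * spec.radius_um + 1e-6
        lo = spec.radius_um + margin
        hi = max(spec.shell_width_um - spec.radius_um, lo)
        placed_angles: list[float] = []
        min_sep = 2.5 * spec.radius_um / max(R - spec.shell_width_um / 2, 1e-6)
        for _ in range(spec.count):
            for _try in range(200):
                ang = rng.uniform(0, 2 * np.pi)
                if all(min(abs(ang - a), 2 * np.pi - abs(ang - a)) > min_sep
                       for a in placed_angles):
                    break
            placed_angles.append(ang)
            d_boundary = rng.uniform(lo, hi)
            r_center = R - d_boundary
            dc = center + r_center * np.array([np.cos(ang), np.sin(ang)])
            dmask = (xs - dc[0]) ** 2 + (ys - dc[1]) ** 2 <= spec.radius_um ** 2
            dmask &= inside
            for t in range(min(spec.vanish_at_frame, config.n_frames)):
                ratio[t][dmask] = spec.ratio_high
            domains.append({"center_um": dc, "radius_um": spec.radius_um,
                            "vanish_at_frame": spec.vanish_at_frame,
                            "mask": dmask,
                            "ratio_high": spec.ratio_high,
                            "ratio_low": spec.ratio_low})

        cid = f"cell_{ci:02d}"
        annotations.append(CellAnnotation(cell_id=cid, polygon=cell_poly,
                                          nucleus_polygon=nuc_poly,
                                          cell_class="alpha"))
        gt_cells.append(GroundTruthCell(
            cell_id=cid, cell_class="alpha", center_um=center,
            polygon=cell_poly, nucleus_polygon=nuc_poly,
            trajectories_um=np.empty((0, config.n_frames, 2)),
            motile=np.empty(0, dtype=bool), microdomains=domains))

    data = np.stack([ratio * ex405[None], np.broadcast_to(
        ex405, ratio.shape).copy()], axis=1)
    if mult_sigma > 0:
        data = data * np.exp(rng.normal(0.0, mult_sigma, size=data.shape))
    stack = TimeLapseStack(data=data, pixel_size_um=px,
                           frame_interval_s=config.frame_interval_s,
                           channels=("ex476", "ex405"))
    ann = AnnotationSet(cells=annotations, pixel_size_um=px, image_shape=(h, w))
    return stack, ann, GroundTruth(cells=gt_cells,
                                   extras={"spec": spec,
                                           "base_intensity": base_intensity})


# ---------------------------------------------------------------------------
# TEM annotations
# ---------------------------------------------------------------------------

def boundary_sampling_distance(a: Polygon, b: Polygon,
                               n_points: int = 10_000) -> tuple[float, float]:
    """Brute-force min boundary distance by dense resampling.

    Returns ``(distance, step)`` where step is the larger of the two boundary
    sampling intervals; the true boundary-to-boundary distance lies within
    one step of the returned value. Used as the independent ground-truth
    oracle for polygon distance computations.
    """
    pa = resample_boundary(a, n_points)
    pb = resample_boundary(b, n_points)
    d = float(cKDTree(pb).query(pa, k=1)[0].min())
    step = max(a.exterior.length, b.exterior.length) / n_points
    return d, step


def _wobbly_polygon(rng: np.random.Generator, cx: float, cy: float,
                    radius: float, n: int = 72, wobble: float = 0.08) -> Polygon:
    """Convex-ish blob: radius modulated by two random low-frequency modes."""
    t = np.linspace(0, 2 * np.pi, n, endpoint=False)
    mod = np.ones(n)
    for k in (2, 3):
        mod += wobble * rng.uniform(0.3, 1.0) * np.sin(k * t + rng.uniform(0, 2 * np.pi))
    r = radius * mod
    return Polygon(np.column_stack([cx + r * np.cos(t), cy + r * np.sin(t)]))


def simulate_tem_annotations(n_cells: int = 5,
                             mitos_per_cell: int = 8,
                             golgi_components: int = 2,
                             pixel_size_um: float = 0.02,
                             seed: int = 0,
                             cell_radius_um: float = 9.0,
                             max_tries: int = 300
                             ) -> tuple[list[TemCellAnnotation], dict]:
    """Generate TEM-style organelle annotations with known distances.

    Each cell gets a convex-ish plasma-membrane polygon, an interior nucleus,
    ``golgi_components`` disjoint Golgi blobs near the nucleus and
    ``mitos_per_cell`` non-overlapping elliptical mitochondria. Ground-truth
    shortest distances (µm) from each mitochondrion to the nucleus and Golgi
    are computed by dense boundary sampling (10⁴ points per polygon).
    """
    if min(n_cells, mitos_per_cell, golgi_components) < 0:
        raise ValidationError("counts must be >= 0")
    rng = np.random.default_rng(seed)
    px = pixel_size_um
    R = cell_radius_um / px
    cells: list[TemCellAnnotation] = []
    truth: dict = {"cells": {}, "sampling_step_um": None}
    max_step = 0.0

    for ci in range(n_cells):
        c0 = np.array([(2 * ci + 1) * (R * 1.15), R * 1.15])
        pm = _wobbly_polygon(rng, *c0, R)
        nuc_r = rng.uniform(0.32, 0.42) * R
        nuc_off = rng.uniform(-0.15, 0.15, 2) * R
        nucleus = _wobbly_polygon(rng, *(c0 + nuc_off), nuc_r, wobble=0.05)

        interior = pm.buffer(-0.05 * R)
        blocked = [nucleus]
        golgi = []
        for _ in range(golgi_components):
            for _try in range(max_tries):
                ang = rng.uniform(0, 2 * np.pi)
                d = nuc_r + rng.uniform(0.3, 1.2) * 1.0 / px
                gc = np.asarray(nucleus.centroid.coords[0]) + d * np.array(
                    [np.cos(ang), np.sin(ang)])
                g = _wobbly_polygon(rng, *gc, rng.uniform(0.4, 0.8) / px,
                                    n=36, wobble=0.15)
                if interior.covers(g) and not any(g.intersects(b) for b in blocked):
                    golgi.append(g)
                    blocked.append(g)
                    break

        mitos = []
        for mi in range(mitos_per_cell):
            placed = False
            for _try in range(max_tries):
                a = rng.uniform(0.4, 1.0) / px
                b = rng.uniform(0.15, 0.35) / px
                ang = rng.uniform(0, np.pi)
                u = rng.uniform()
                rad = np.sqrt(u) * (R - 1.3 * a)
                th = rng.uniform(0, 2 * np.pi)
                mc = c0 + rad * np.array([np.cos(th), np.sin(th)])
                m = ellipse_polygon(*mc, a, b, ang, n=40)
                if interior.covers(m) and not any(m.intersects(bl) for bl in blocked):
                    mitos.append(m)
                    blocked.append(m)
                    placed = True
                    break
            if not placed:
                raise ValidationError(
                    "could not pack mitochondria; use fewer or smaller ones")

        cid = f"tem_{ci:02d}"
        d_nuc, d_gol = [], []
        for m in mitos:
            d, step = boundary_sampling_distance(m, nucleus)
            max_step = max(max_step, step)
            d_nuc.append(d * px)
            if golgi:
                dg = np.inf
                for g in golgi:
                    d2, step2 = boundary_sampling_distance(m, g)
                    max_step = max(max_step, step2)
                    dg = min(dg, d2)
                d_gol.append(dg * px)
            else:
                d_gol.append(None)
        cells.append(TemCellAnnotation(
            cell_id=cid, plasma_membrane=pm, nucleus=nucleus,
            mitochondria=mitos, golgi=golgi, pixel_size_um=px,
            cell_type="alpha"))
        truth["cells"][cid] = {"d_nucleus_um": d_nuc, "d_golgi_um": d_gol}
    truth["sampling_step_um"] = max_step * px
    return cells, truth
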