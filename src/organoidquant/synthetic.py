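"""Seeded synthetic fixtures with known ground truth for every pipeline stage.

The study's raw microscopy and video data are not available for desk
use, so each analysis stage is exercised on generated inputs whose true
answer is known by construction:

* two-marker (SOX2/TBXT) sphere fields with controllable per-sphere
  marker fractions;
* brightfield-like contraction videos with events of controllable
  amplitude, spatial extent and timing;
* neurite fields (filaments + somata + sphere autofluorescence) as
  5-slice z-stacks;
* NMJ fields: α-bungarotoxin puncta with configurable size and
  intensity, EGFP overlay on innervated clusters;
* grouped line×batch×well measurement tables with specified among- and
  within-line variance structure.

All generators are pure functions of their spec (which carries the
seed): identical specs give bit-identical outputs.  Ground truth is
emitted alongside every fixture so recovery tests never re-derive truth
from the rendered images.  Noise is additive Gaussian on intensities,
clipped to the valid range.  The default field is 512×512 px, 16-bit,
1.33 µm/px — comparable to low-magnification (4×) acquisition.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import draw

from .imaging import MultiChannelImage

__all__ = [
    "SphereFixtureSpec",
    "VideoFixtureSpec",
    "NeuriteFixtureSpec",
    "NMJFixtureSpec",
    "GroupedTableSpec",
    "generate_sphere_image",
    "generate_contraction_video",
    "generate_neurite_image",
    "generate_nmj_field",
    "generate_grouped_table",
]

DEFAULT_FIELD = (512, 512)
DEFAULT_SCALE = 1.33
U16_MAX = 65535.0


def _clip_u16(arr: np.ndarray) -> np.ndarray:
    return np.clip(np.rint(arr), 0, U16_MAX).astype(np.uint16)


# ---------------------------------------------------------------------------
# sphere potency fixtures


@dataclass
class SphereFixtureSpec:
    """Two-marker sphere field with per-sphere target fractions.

    ``sox2_fraction[i]`` and ``tbxt_fraction[i]`` are the fractions of
    sphere i's nuclear area covered by each marker mask; overlap between
    the two markers is allowed, and the union covers ``1 -
    unstained_fraction[i]`` of the nuclear area.
    """

    n_spheres: int
    sox2_fraction: tuple[float, ...]
    tbxt_fraction: tuple[float, ...]
    unstained_fraction: tuple[float, ...]
    radius_px: tuple[int, int] = (18, 30)
    noise_sd: float = 200.0
    marker_intensity: float = 30000.0
    field_shape: tuple[int, int] = DEFAULT_FIELD
    scale_um_per_px: float = DEFAULT_SCALE
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("sox2_fraction", "tbxt_fraction", "unstained_fraction"):
            vals = tuple(float(v) for v in np.atleast_1d(getattr(self, name)))
            if len(vals) == 1:
                vals = vals * self.n_spheres
            if len(vals) != self.n_spheres:
                raise ValueError(f"{name} must have length n_spheres")
            if any(not 0 <= v <= 1 for v in vals):
                raise ValueError(f"{name} values must lie in [0, 1]")
            setattr(self, name, vals)
        for s, t, u in zip(self.sox2_fraction, self.tbxt_fraction, self.unstained_fraction):
            overlap = s + t - (1 - u)
            if overlap < -1e-9 or overlap > min(s, t) + 1e-9:
                raise ValueError(
                    f"infeasible fractions sox2={s}, tbxt={t}, unstained={u}: "
                    "need coverage(sox2 ∪ tbxt) = 1 - unstained"
                )


def _grid_positions(n: int, shape: tuple[int, int], margin: int, rng) -> list[tuple[int, int]]:
    """Deterministic jittered grid placement; errors if n does not fit."""
    per_side = math.ceil(math.sqrt(n))
    cell_h = (shape[0] - 2 * margin) / per_side
    cell_w = (shape[1] - 2 * margin) / per_side
    if cell_h < 2 * margin or cell_w < 2 * margin:
        raise ValueError(f"cannot pack {n} objects of radius {margin} into field {shape}")
    cells = [(i, j) for i in range(per_side) for j in range(per_side)][:n]
    positions = []
    for i, j in cells:
        jr = rng.uniform(-0.15, 0.15) * cell_h
        jc = rng.uniform(-0.15, 0.15) * cell_w
        positions.append(
            (int(margin + (i + 0.5) * cell_h + jr), int(margin + (j + 0.5) * cell_w + jc))
        )
    return positions


def generate_sphere_image(spec: SphereFixtureSpec):
    """Render a nuclear/SOX2/TBXT field of non-overlapping spheres.

    Returns ``(MultiChannelImage, ground_truth)`` where ground truth is a
    DataFrame with the realized (post-rasterization) per-sphere marker
    percentages and potency score ``pct_sox2 - pct_tbxt``.
    """
    rng = np.random.default_rng(spec.seed)
    shape = spec.field_shape
    r_lo, r_hi = spec.radius_px
    positions = _grid_positions(spec.n_spheres, shape, r_hi + 2, rng)

    nuclear = np.zeros(shape, float)
    sox2 = np.zeros(shape, float)
    tbxt = np.zeros(shape, float)
    records = []
    for i, (cy, cx) in enumerate(positions):
        radius = int(rng.integers(r_lo, r_hi + 1))
        rr, cc = draw.disk((cy, cx), radius, shape=shape)
        n_pix = len(rr)
        # order disc pixels by angle so marker masks are contiguous sectors
        angles = np.arctan2(rr - cy, cc - cx)
        order = np.argsort(angles, kind="stable")
        rr, cc = rr[order], cc[order]
        s, t, u = spec.sox2_fraction[i], spec.tbxt_fraction[i], spec.unstained_fraction[i]
        n_sox2 = int(round(s * n_pix))
        n_stained = int(round((1 - u) * n_pix))
        n_tbxt = int(round(t * n_pix))
        tb_start = max(0, n_stained - n_tbxt)
        nuclear[rr, cc] = spec.marker_intensity
        sox2[rr[:n_sox2], cc[:n_sox2]] = spec.marker_intensity
        tbxt[rr[tb_start:n_stained], cc[tb_start:n_stained]] = spec.marker_intensity
        pct_sox2 = 100.0 * n_sox2 / n_pix
        pct_tbxt = 100.0 * (n_stained - tb_start) / n_pix
        pct_unstained = 100.0 * (n_pix - n_stained) / n_pix
        records.append(
            {
                "sphere_id": i,
                "centroid_r": cy,
                "centroid_c": cx,
                "radius_px": radius,
                "nuclear_area_px2": n_pix,
                "pct_sox2": pct_sox2,
                "pct_tbxt": pct_tbxt,
                "pct_unstained": pct_unstained,
                "potency": pct_sox2 - pct_tbxt,
                "excluded": pct_unstained >= 25.0,
            }
        )
    channels = {}
    for name, plane in [("nuclear", nuclear), ("sox2", sox2), ("tbxt", tbxt)]:
        channels[name] = _clip_u16(plane + rng.normal(0, spec.noise_sd, shape))
    image = MultiChannelImage(channels, spec.scale_um_per_px, 16)
    return image, pd.DataFrame(records)


# ---------------------------------------------------------------------------
# contraction video fixtures


@dataclass
class VideoFixtureSpec:
    """Textured time-lapse with single-frame contraction-like events.

    At each event frame, the pixels of a contiguous region covering
    ``event_extent`` of the field are brightened by ``event_amplitude``
    for exactly one frame — the simplest perturbation a
    frame-subtraction detector responds to.
    """

    n_frames: int = 100
    frame_interval: float = 0.5
    event_times: tuple[int, ...] = ()
    event_amplitude: float = 50.0
    event_extent: float = 0.3
    texture_contrast: float = 40.0
    noise_sd: float = 1.0
    field_shape: tuple[int, int] = (64, 64)
    seed: int = 0

    def __post_init__(self) -> None:
        self.event_times = tuple(int(t) for t in self.event_times)
        if list(self.event_times) != sorted(set(self.event_times)):
            raise ValueError("event_times must be strictly increasing")
        if any(not 0 <= t < self.n_frames for t in self.event_times):
            raise ValueError("event_times must lie in [0, n_frames)")
        if not 0 <= self.event_extent <= 1:
            raise ValueError("event_extent must lie in [0, 1]")


def generate_contraction_video(spec: VideoFixtureSpec):
    """Render the video and return ``(frames, ground_truth)``.

    Frames are float64 (T, H, W).  Ground truth is a DataFrame with one
    row per event: onset frame, the expected frame-delta magnitude
    (amplitude × extent), extent fraction and size class ("large" iff
    extent > 0.5).
    """
    rng = np.random.default_rng(spec.seed)
    shape = spec.field_shape
    texture = ndimage.gaussian_filter(rng.uniform(-1, 1, shape), 2.0)
    texture = 128.0 + spec.texture_contrast * texture / max(np.abs(texture).max(), 1e-12)
    frames = np.tile(texture, (spec.n_frames, 1, 1))
    if spec.noise_sd > 0:
        frames = frames + rng.normal(0, spec.noise_sd, frames.shape)
    n_pix = shape[0] * shape[1]
    k = int(round(spec.event_extent * n_pix))
    region = np.zeros(n_pix, bool)
    region[:k] = True  # contiguous raster-order block of exact size
    region = region.reshape(shape)
    records = []
    for t in spec.event_times:
        frames[t][region] += spec.event_amplitude
        records.append(
            {
                "onset_frame": t,
                "magnitude": spec.event_amplitude * k / n_pix,
                "extent_fraction": k / n_pix,
                "size_class": "large" if k / n_pix > 0.5 else "small",
            }
        )
    truth = pd.DataFrame(
        records, columns=["onset_frame", "magnitude", "extent_fraction", "size_class"]
    )
    return frames, truth


# ---------------------------------------------------------------------------
# neurite fixtures


@dataclass
class NeuriteFixtureSpec:
    """Neurite field: thin bright filaments, compact somata, diffuse spheres.

    Filaments are elongated low-circularity rectangles; somata are
    compact high-circularity discs; autofluorescent spheres are large
    diffuse blobs.  The background carries a smooth haze component (the
    broad tissue autofluorescence of wide-field EGFP imaging) on top of
    per-pixel shot noise — both are required for the automatic
    thresholds of the segmentation recipe to behave as they do on real
    acquisitions.  ``angles_deg`` optionally fixes filament
    orientations (degrees); otherwise they are drawn from the seeded
    rng.  Filaments are placed clear of spheres and somata so the
    painted area is recoverable ground truth.
    """

    n_filaments: int = 3
    filament_width_px: int = 10
    filament_length_px: int = 200
    n_somata: int = 2
    n_autofluor_spheres: int = 1
    background_sd: float = 80.0
    background_level: float = 500.0
    haze_sd: float = 250.0
    haze_scale_px: float = 50.0
    filament_intensity: float = 1000.0
    soma_intensity: float = 25000.0
    autofluor_intensity: float = 8000.0
    autofluor_radius_px: tuple[int, int] = (85, 110)
    angles_deg: tuple[float, ...] | None = None
    field_shape: tuple[int, int] = DEFAULT_FIELD
    scale_um_per_px: float = DEFAULT_SCALE
    seed: int = 0


def _paint_filament(canvas: np.ndarray, cy: int, cx: int, length: int, width: int,
                    angle_deg: float, value: float) -> np.ndarray:
    """Paint a rotated rectangle; returns the boolean footprint painted."""
    theta = math.radians(angle_deg)
    dy, dx = math.sin(theta), math.cos(theta)
    py, px = -dx, dy  # unit normal
    hl, hw = length / 2.0, width / 2.0
    corners_r = [cy + a * hl * dy + b * hw * py for a, b in ((-1, -1), (-1, 1), (1, 1), (1, -1))]
    corners_c = [cx + a * hl * dx + b * hw * px for a, b in ((-1, -1), (-1, 1), (1, 1), (1, -1))]
    if angle_deg % 180 == 0:
        # axis-aligned: integer block, exact width×length footprint
        r0 = int(round(cy - hw))
        c0 = int(round(cx - hl))
        rr, cc = np.meshgrid(
            np.arange(r0, r0 + width), np.arange(c0, c0 + length), indexing="ij"
        )
        rr, cc = rr.ravel(), cc.ravel()
    else:
        rr, cc = draw.polygon(corners_r, corners_c, shape=canvas.shape)
    inside = (rr >= 0) & (rr < canvas.shape[0]) & (cc >= 0) & (cc < canvas.shape[1])
    rr, cc = rr[inside], cc[inside]
    footprint = np.zeros(canvas.shape, bool)
    footprint[rr, cc] = True
    canvas[rr, cc] += value  # additive: constant contrast over the haze
    return footprint


def generate_neurite_image(spec: NeuriteFixtureSpec):
    """Render a 5-slice z-stack (1 µm spacing) and its neurite ground truth.

    Returns ``(stack, ground_truth_neurite_area_px2)``; the ground truth
    is the painted filament footprint area before noise, excluding
    pixels later covered by somata (which the segmentation is required
    to subtract).
    """
    rng = np.random.default_rng(spec.seed)
    shape = spec.field_shape
    # diffuse low-frequency background haze: wide-field EGFP images carry
    # broad tissue autofluorescence that survives heavy blurring; the
    # triangle-threshold autofluorescence step of the segmentation keys
    # on the shape of this background distribution
    haze = ndimage.gaussian_filter(rng.normal(0, 1, shape), spec.haze_scale_px)
    if haze.std() > 0:
        haze = haze / haze.std() * spec.haze_sd
    base = np.full(shape, spec.background_level, float) + haze
    if spec.angles_deg is not None and len(spec.angles_deg) != spec.n_filaments:
        raise ValueError("angles_deg must have length n_filaments")
    margin = spec.filament_length_px // 2 + 2
    if 2 * margin >= min(shape):
        raise ValueError("filament length exceeds field")

    # bright structures first, so filaments can be placed clear of them
    exclusion = np.zeros(shape, bool)
    for _ in range(spec.n_autofluor_spheres):
        r = int(rng.integers(*spec.autofluor_radius_px))
        cy = int(rng.integers(r, shape[0] - r))
        cx = int(rng.integers(r, shape[1] - r))
        blob = np.zeros(shape, float)
        rr, cc = draw.disk((cy, cx), r, shape=shape)
        blob[rr, cc] = spec.autofluor_intensity
        base += ndimage.gaussian_filter(blob, 20.0)
        err, ecc = draw.disk((cy, cx), r + 45, shape=shape)
        exclusion[err, ecc] = True
    soma_mask = np.zeros(shape, bool)
    for _ in range(spec.n_somata):
        r = int(rng.integers(12, 20))
        cy = int(rng.integers(r + 2, shape[0] - r - 2))
        cx = int(rng.integers(r + 2, shape[1] - r - 2))
        rr, cc = draw.disk((cy, cx), r, shape=shape)
        base[rr, cc] = spec.soma_intensity
        soma_mask[rr, cc] = True
        err, ecc = draw.disk((cy, cx), r + 10, shape=shape)
        exclusion[err, ecc] = True

    filament_mask = np.zeros(shape, bool)
    for i in range(spec.n_filaments):
        for _attempt in range(200):
            cy = int(rng.integers(margin, shape[0] - margin))
            cx = int(rng.integers(margin, shape[1] - margin))
            angle = (
                spec.angles_deg[i]
                if spec.angles_deg is not None
                else float(rng.uniform(0, 180))
            )
            probe = np.zeros(shape, float)
            fp = _paint_filament(
                probe, cy, cx, spec.filament_length_px, spec.filament_width_px,
                angle, 1.0,
            )
            if not (fp & (exclusion | filament_mask)).any():
                break
        else:
            raise ValueError("could not place filament clear of other structures")
        base[fp] += spec.filament_intensity
        filament_mask |= fp
    truth_area = int((filament_mask & ~soma_mask).sum())
    slice_gain = [0.6, 0.8, 1.0, 0.8, 0.6]  # focus profile across the 5 slices
    stack = np.stack(
        [
            _clip_u16(base * g + rng.normal(0, spec.background_sd, shape))
            for g in slice_gain
        ]
    )
    return stack, truth_area


# ---------------------------------------------------------------------------
# NMJ fixtures


@dataclass
class NMJFixtureSpec:
    """α-bungarotoxin puncta field with EGFP overlay on innervated clusters.

    ``diameter_um`` is each cluster's maximal dimension; clusters whose
    EGFP mean intensity exceeds ``egfp_gate`` are innervated, and
    ``innervated_truth`` must be consistent with the configured
    intensities.
    """

    n_clusters: int
    diameter_um: tuple[float, ...]
    btx_intensity: tuple[float, ...]
    egfp_intensity: tuple[float, ...]
    innervated_truth: tuple[bool, ...]
    btx_gate: float = 1000.0
    egfp_gate: float = 5000.0
    dim_range_um: tuple[float, float] = (10.0, 50.0)
    noise_sd: float = 20.0
    aspect: float = 0.6
    field_shape: tuple[int, int] = DEFAULT_FIELD
    scale_um_per_px: float = DEFAULT_SCALE
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("diameter_um", "btx_intensity", "egfp_intensity", "innervated_truth"):
            vals = tuple(np.atleast_1d(getattr(self, name)).tolist())
            if len(vals) == 1:
                vals = vals * self.n_clusters
            if len(vals) != self.n_clusters:
                raise ValueError(f"{name} must have length n_clusters")
            setattr(self, name, vals)
        for flag, egfp in zip(self.innervated_truth, self.egfp_intensity):
            if bool(flag) != (egfp > self.egfp_gate):
                raise ValueError(
                    "innervated_truth inconsistent with egfp_intensity and gate"
                )


def generate_nmj_field(spec: NMJFixtureSpec):
    """Render BTX/EGFP channels; returns ``(MultiChannelImage, ground_truth)``.

    Ground truth has one row per cluster: configured maximal dimension,
    realized area (µm²), mean intensities, innervation flag and whether
    the cluster falls inside the size/intensity retention gates.
    """
    rng = np.random.default_rng(spec.seed)
    shape = spec.field_shape
    max_d_px = max(spec.diameter_um) / spec.scale_um_per_px
    if max_d_px >= min(shape):
        raise ValueError("cluster diameter exceeds field")
    positions = _grid_positions(spec.n_clusters, shape, int(max_d_px / 2) + 2, rng)
    btx = np.zeros(shape, float)
    egfp = np.zeros(shape, float)
    records = []
    lo, hi = spec.dim_range_um
    for i, (cy, cx) in enumerate(positions):
        major = spec.diameter_um[i] / spec.scale_um_per_px / 2.0
        minor = major * spec.aspect
        theta = float(rng.uniform(0, np.pi))
        rr, cc = draw.ellipse(cy, cx, major, minor, shape=shape, rotation=theta)
        btx[rr, cc] = spec.btx_intensity[i]
        egfp[rr, cc] = spec.egfp_intensity[i]
        records.append(
            {
                "cluster_id": i,
                "centroid_r": cy,
                "centroid_c": cx,
                "diameter_um": spec.diameter_um[i],
                "area_um2": len(rr) * spec.scale_um_per_px**2,
                "btx_intensity": spec.btx_intensity[i],
                "egfp_intensity": spec.egfp_intensity[i],
                "innervated": bool(spec.innervated_truth[i]),
                "retained": (lo <= spec.diameter_um[i] <= hi)
                and (spec.btx_intensity[i] > spec.btx_gate),
            }
        )
    channels = {
        "btx": _clip_u16(btx + rng.normal(0, spec.noise_sd, shape)),
        "egfp": _clip_u16(egfp + rng.normal(0, spec.noise_sd, shape)),
    }
    image = MultiChannelImage(channels, spec.scale_um_per_px, 16)
    return image, pd.DataFrame(records)


# ---------------------------------------------------------------------------
# grouped measurement tables


@dataclass
class GroupedTableSpec:
    """Line × batch × well measurement table with known variance structure.

    Well values are ``line_mean + batch_offset + N(0, within_line_sd)``
    with batch offsets drawn once per batch from ``N(0, batch_sd)``.
    """

    n_lines: int = 5
    wells_per_line_per_batch: int = 2
    n_batches: int = 3
    line_means: tuple[float, ...] = (100.0,)
    within_line_sd: float = 10.0
    batch_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        vals = tuple(float(v) for v in np.atleast_1d(self.line_means))
        if len(vals) == 1:
            vals = vals * self.n_lines
        if len(vals) != self.n_lines:
            raise ValueError("line_means must have length n_lines")
        self.line_means = vals


def generate_grouped_table(spec: GroupedTableSpec) -> pd.DataFrame:
    """Generate the table; columns line_id, batch_id, well_id, value.

    The true among-line variance is the variance of ``line_means`` and
    the true within-line variance is ``within_line_sd**2``; both are
    attached as DataFrame attrs for recovery tests.
    """
    rng = np.random.default_rng(spec.seed)
    batch_offsets = rng.normal(0, spec.batch_sd, spec.n_batches) if spec.batch_sd > 0 else np.zeros(spec.n_batches)
    rows = []
    for li in range(spec.n_lines):
        for bi in range(spec.n_batches):
            noise = (
                rng.normal(0, spec.within_line_sd, spec.wells_per_line_per_batch)
                if spec.within_line_sd > 0
                else np.zeros(spec.wells_per_line_per_batch)
            )
            for wi in range(spec.wells_per_line_per_batch):
                rows.append(
                    {
                        "line_id": f"line{li:02d}",
                        "batch_id": f"batch{bi}",
                        "well_id": f"L{li:02d}B{bi}W{wi}",
                        "value": spec.line_means[li] + batch_offsets[bi] + noise[wi],
                    }
                )
    table = pd.DataFrame(rows)
    table.attrs["true_among_line_variance"] = float(np.var(spec.line_means, ddof=1)) if spec.n_lines > 1 else 0.0
    table.attrs["true_within_line_variance"] = spec.within_line_sd**2
    return table
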