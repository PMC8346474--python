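"""Sphere neuromesodermal-potency scoring.

Day-2 spheres are stained for the neural marker SOX2, the mesodermal
marker TBXT (Brachyury) and a nuclear dye.  Each sphere's potency is
the difference between the percentages of its nuclear area covered by
the SOX2 and TBXT masks, ranging from −100 (TBXT-only, myogenic) to
+100 (SOX2-only, neurogenic), with 0 indicating balanced,
neuromesodermal expression.  Spheres with ≥25% unstained nuclear area
are excluded from scoring.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .imaging import LabeledMask, MultiChannelImage, auto_threshold, label_objects

__all__ = [
    "SphereRecord",
    "WellPotencySummary",
    "stitch_tiles",
    "detect_spheres",
    "marker_masks",
    "score_sphere",
    "classify_lineage",
    "double_positive_area",
    "analyze_well",
]

UNSTAINED_EXCLUSION_PCT = 25.0


@dataclass
class SphereRecord:
    sphere_id: int
    nuclear_area_px2: float
    nuclear_area_um2: float
    pct_sox2: float
    pct_tbxt: float
    pct_unstained: float
    potency: float
    lineage_class: str
    excluded: bool
    exclude_reason: str = ""


@dataclass
class WellPotencySummary:
    n_spheres_total: int
    n_spheres_retained: int
    potencies: np.ndarray
    double_positive_area_fraction: float  # % of well area SOX2+ ∧ TBXT+

    @property
    def mean_potency(self) -> float:
        return float(np.mean(self.potencies)) if len(self.potencies) else float("nan")


def stitch_tiles(tiles, layout: tuple[int, int]) -> MultiChannelImage:
    """Abutting grid placement of equally sized tiles (no registration).

    ``tiles`` is a row-major sequence of MultiChannelImage; ``layout``
    is (rows, cols) and must match the tile count.
    """
    rows, cols = layout
    tiles = list(tiles)
    if len(tiles) != rows * cols:
        raise ValueError(f"layout {layout} inconsistent with {len(tiles)} tiles")
    shapes = {t.shape for t in tiles}
    if len(shapes) != 1:
        raise ValueError("ragged grid: all tiles must share a shape")
    names = list(tiles[0].channels)
    channels = {}
    for name in names:
        grid = [
            [tiles[r * cols + c].channel(name) for c in range(cols)] for r in range(rows)
        ]
        channels[name] = np.block(grid)
    return MultiChannelImage(channels, tiles[0].scale_um_per_px, tiles[0].bit_depth)


def detect_spheres(
    image: MultiChannelImage,
    nuclear_channel: str = "nuclear",
    min_sphere_area: float = 500.0,
) -> LabeledMask:
    """Threshold the nuclear channel (Otsu), fill holes, drop debris.

    Objects of at least ``min_sphere_area`` px² are retained.  A
    strictly constant nuclear channel raises, since no threshold exists.
    """
    img = image.projected()
    nuclear = np.asarray(img.channel(nuclear_channel), float)
    thr = auto_threshold(nuclear, "otsu")
    mask = ndimage.binary_fill_holes(nuclear > thr)
    labeled = label_objects(mask, img.scale_um_per_px)
    keep = labeled.objects.loc[
        labeled.objects["area_px2"] >= min_sphere_area, "label"
    ].tolist()
    return labeled.select(keep)


def marker_masks(
    image: MultiChannelImage,
    sox2_channel: str = "sox2",
    tbxt_channel: str = "tbxt",
    sox2_threshold: float | None = None,
    tbxt_threshold: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-well marker positivity masks (Otsu unless overridden)."""
    img = image.projected()
    masks = []
    for chan, thr in ((sox2_channel, sox2_threshold), (tbxt_channel, tbxt_threshold)):
        plane = np.asarray(img.channel(chan), float)
        if thr is None:
            thr = auto_threshold(plane, "otsu")
        masks.append(plane > thr)
    return masks[0], masks[1]


def score_sphere(
    sphere_mask: np.ndarray,
    sox2_mask: np.ndarray,
    tbxt_mask: np.ndarray,
    sphere_id: int = 0,
    scale_um_per_px: float = 1.0,
    cutoff: float = 25.0,
) -> SphereRecord:
    """Score one sphere from its nuclear footprint and the marker masks.

    Percentages are taken over the sphere's nuclear pixels; potency is
    ``pct_sox2 - pct_tbxt``.  Spheres with ≥25% unstained nuclear area
    are flagged excluded.
    """
    sphere_mask = np.asarray(sphere_mask, bool)
    n_nuc = int(sphere_mask.sum())
    if n_nuc == 0:
        raise ValueError("zero nuclear area")
    sox2_in = np.asarray(sox2_mask, bool) & sphere_mask
    tbxt_in = np.asarray(tbxt_mask, bool) & sphere_mask
    pct_sox2 = 100.0 * sox2_in.sum() / n_nuc
    pct_tbxt = 100.0 * tbxt_in.sum() / n_nuc
    pct_unstained = 100.0 * (~(sox2_in | tbxt_in) & sphere_mask).sum() / n_nuc
    potency = pct_sox2 - pct_tbxt
    excluded = pct_unstained >= UNSTAINED_EXCLUSION_PCT
    return SphereRecord(
        sphere_id=sphere_id,
        nuclear_area_px2=float(n_nuc),
        nuclear_area_um2=float(n_nuc) * scale_um_per_px**2,
        pct_sox2=float(pct_sox2),
        pct_tbxt=float(pct_tbxt),
        pct_unstained=float(pct_unstained),
        potency=float(potency),
        lineage_class=classify_lineage(potency, cutoff),
        excluded=bool(excluded),
        exclude_reason="unstained >= 25%" if excluded else "",
    )


def classify_lineage(potency: float, cutoff: float = 25.0) -> str:
    """Map a potency score to a lineage class.

    Scores below −cutoff are myogenic (TBXT-dominated), above +cutoff
    neurogenic (SOX2-dominated), and the closed interval
    [−cutoff, +cutoff] neuromesodermal.  The cutoff is a configuration
    parameter, not a published value.
    """
    if not -100 - 1e-9 <= potency <= 100 + 1e-9:
        raise ValueError("potency must lie in [-100, 100]")
    if not 0 < cutoff < 100:
        raise ValueError("cutoff must lie in (0, 100)")
    if potency < -cutoff:
        return "myogenic"
    if potency > cutoff:
        return "neurogenic"
    return "neuromesodermal"


def double_positive_area(
    image: MultiChannelImage,
    sox2_channel: str = "sox2",
    tbxt_channel: str = "tbxt",
    sox2_threshold: float | None = None,
    tbxt_threshold: float | None = None,
) -> float:
    """Percentage of the whole well area positive for both markers."""
    sox2, tbxt = marker_masks(
        image, sox2_channel, tbxt_channel, sox2_threshold, tbxt_threshold
    )
    return float(100.0 * (sox2 & tbxt).mean())


def analyze_well(
    image: MultiChannelImage,
    nuclear_channel: str = "nuclear",
    sox2_channel: str = "sox2",
    tbxt_channel: str = "tbxt",
    min_sphere_area: float = 500.0,
    cutoff: float = 25.0,
    sox2_threshold: float | None = None,
    tbxt_threshold: float | None = None,
) -> tuple[pd.DataFrame, WellPotencySummary]:
    """Full per-well analysis: detect spheres, score each, summarize.

    Returns a per-sphere table (one SphereRecord per row) and the
    well-level summary with the SOX2+/TBXT+ double-positive fraction.
    """
    spheres = detect_spheres(image, nuclear_channel, min_sphere_area)
    sox2, tbxt = marker_masks(
        image, sox2_channel, tbxt_channel, sox2_threshold, tbxt_threshold
    )
    records = []
    for lab in spheres.objects["label"]:
        rec = score_sphere(
            spheres.labels == lab,
            sox2,
            tbxt,
            sphere_id=int(lab),
            scale_um_per_px=image.scale_um_per_px,
            cutoff=cutoff,
        )
        records.append(rec.__dict__)
    table = pd.DataFrame(
        records,
        columns=[
            "sphere_id", "nuclear_area_px2", "nuclear_area_um2", "pct_sox2",
            "pct_tbxt", "pct_unstained", "potency", "lineage_class", "excluded",
            "exclude_reason",
        ],
    )
    retained = table[~table["excluded"]] if len(table) else table
    summary = WellPotencySummary(
        n_spheres_total=len(table),
        n_spheres_retained=len(retained),
        potencies=retained["potency"].to_numpy() if len(table) else np.array([]),
        double_positive_area_fraction=double_positive_area(
            image, sox2_channel, tbxt_channel, sox2_threshold, tbxt_threshold
        ),
    )
    return table, summary
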