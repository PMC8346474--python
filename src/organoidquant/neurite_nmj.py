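"""Neurite-outgrowth segmentation and NMJ innervation scoring.

Neurites are segmented from hSYN::EGFP-labeled fields by a fixed
five-step recipe operating on the maximum-intensity projection of each
5 × 1 µm z-stack:

1. max projection;
2. neurite candidates: 2σ Gaussian blur → 5 px rolling-ball background
   subtraction → minimum-error threshold → keep objects with area
   > 100 px² and circularity < 0.5;
3. cell bodies: 2σ blur → Otsu threshold → area > 100 px² and
   circularity > 0.3;
4. sphere autofluorescence: 10σ blur → triangle threshold;
5. final mask = neurites − (bodies ∪ autofluorescence), refined to
   large tracks with area > 1000 px² and circularity < 0.2.

NMJs are α-bungarotoxin (BTX) clusters of maximal dimension 10–50 µm
with BTX mean intensity above 1000; a retained cluster is innervated
when its EGFP mean intensity exceeds 5000.  Culture-level metrics are
normalized to the mean of batch-matched isogenic control cultures.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .imaging import (
    MultiChannelImage,
    auto_threshold,
    filter_objects,
    gaussian_blur,
    label_objects,
    max_projection,
    rolling_ball_subtract,
)

__all__ = [
    "NeuriteParams",
    "NeuriteResult",
    "NMJParams",
    "segment_neurites",
    "growth_curve",
    "detect_nmj_clusters",
    "summarize_nmj",
]


@dataclass
class NeuriteParams:
    """Tunable parameters of the five-step neurite segmentation."""

    neurite_blur_sigma: float = 2.0
    rolling_ball_radius: int = 5
    neurite_min_area: float = 100.0
    neurite_max_circ: float = 0.5
    # plausibility guard: neurites are thin sparse structures; if the
    # candidate threshold selects more than this fraction of the field
    # the image carries no neurite signal (thresholding collapsed onto
    # background noise) and the stage reports an empty mask
    max_candidate_fraction: float = 0.25
    soma_blur_sigma: float = 2.0
    soma_min_area: float = 100.0
    soma_min_circ: float = 0.3
    autofluor_blur_sigma: float = 10.0
    final_min_area: float = 1000.0
    final_max_circ: float = 0.2


@dataclass
class NeuriteResult:
    mask: np.ndarray
    neurite_area_px2: float
    neurite_area_um2: float
    n_tracks: int


def _threshold_mask(image: np.ndarray, method: str) -> np.ndarray:
    """Foreground mask via auto threshold; empty for constant images."""
    try:
        thr = auto_threshold(image, method)
    except ValueError:
        return np.zeros(image.shape, bool)
    return image > thr


def segment_neurites(
    stack: np.ndarray,
    scale_um_per_px: float = 1.33,
    params: NeuriteParams | None = None,
) -> NeuriteResult:
    """Run the five-step recipe on a z-stack (or a single 2-D image)."""
    p = params or NeuriteParams()
    stack = np.asarray(stack, float)
    image = max_projection(stack) if stack.ndim == 3 else stack

    # step 2: neurite candidates
    neur = rolling_ball_subtract(
        gaussian_blur(image, p.neurite_blur_sigma), p.rolling_ball_radius
    )
    cand = _threshold_mask(neur, "minimum_error")
    if cand.mean() > p.max_candidate_fraction:
        # threshold collapsed onto background noise: no neurite signal
        empty = np.zeros(image.shape, bool)
        return NeuriteResult(empty, 0.0, 0.0, 0)
    neur_lab = label_objects(cand, scale_um_per_px)
    neur_lab = filter_objects(
        neur_lab, min_area=p.neurite_min_area, max_circ=p.neurite_max_circ
    )

    # step 3: cell bodies
    soma = gaussian_blur(image, p.soma_blur_sigma)
    soma_lab = label_objects(_threshold_mask(soma, "otsu"), scale_um_per_px)
    soma_lab = filter_objects(soma_lab, min_area=p.soma_min_area, min_circ=p.soma_min_circ)

    # step 4: sphere autofluorescence
    auto = gaussian_blur(image, p.autofluor_blur_sigma)
    auto_mask = _threshold_mask(auto, "triangle")

    # step 5: subtraction and refinement to large tracks
    final = neur_lab.mask & ~(soma_lab.mask | auto_mask)
    final_lab = label_objects(final, scale_um_per_px)
    final_lab = filter_objects(
        final_lab, min_area=p.final_min_area, max_circ=p.final_max_circ
    )
    area = float(final_lab.objects["area_px2"].sum()) if final_lab.n_objects else 0.0
    return NeuriteResult(
        mask=final_lab.mask,
        neurite_area_px2=area,
        neurite_area_um2=area * scale_um_per_px**2,
        n_tracks=final_lab.n_objects,
    )


def growth_curve(areas_by_time: np.ndarray) -> np.ndarray:
    """Fold change of per-well total neurite area vs the first time point."""
    areas = np.asarray(areas_by_time, float)
    if areas.size < 2:
        raise ValueError("need >= 2 time points")
    if areas[0] <= 0:
        raise ValueError("zero initial area: well must be excluded")
    return areas / areas[0]


@dataclass
class NMJParams:
    """Gates for NMJ cluster retention and innervation calling.

    Size bounds are on the maximal Feret diameter and are inclusive;
    intensity gates are on the mean pixel intensity over the cluster
    footprint and are strict (above the threshold).
    """

    btx_gate: float = 1000.0
    egfp_gate: float = 5000.0
    dim_min_um: float = 10.0
    dim_max_um: float = 50.0
    detect_method: str = "triangle"


def detect_nmj_clusters(
    image: MultiChannelImage,
    btx_channel: str = "btx",
    egfp_channel: str = "egfp",
    params: NMJParams | None = None,
) -> pd.DataFrame:
    """Detect, gate and annotate BTX clusters on a two-channel field.

    Candidate clusters are segmented on the max-projected BTX channel
    with an automatic threshold, then filtered to maximal dimension in
    [dim_min, dim_max] µm and BTX mean intensity above the BTX gate;
    ``innervated`` marks clusters whose EGFP mean exceeds the EGFP gate.
    Returns one row per retained cluster.
    """
    p = params or NMJParams()
    img = image.projected()
    if img.scale_um_per_px <= 0:
        raise ValueError("missing or invalid scale")
    btx = np.asarray(img.channel(btx_channel), float)
    egfp = np.asarray(img.channel(egfp_channel), float)
    mask = _threshold_mask(btx, p.detect_method)
    labeled = label_objects(
        mask,
        img.scale_um_per_px,
        intensity_images={"btx": btx, "egfp": egfp},
    )
    obj = labeled.objects
    retained = obj[
        (obj["feret_um"] >= p.dim_min_um)
        & (obj["feret_um"] <= p.dim_max_um)
        & (obj["mean_btx"] > p.btx_gate)
    ].copy()
    retained["innervated"] = retained["mean_egfp"] > p.egfp_gate
    return retained.reset_index(drop=True)


def summarize_nmj(
    clusters: pd.DataFrame,
    culture_col: str = "culture_id",
) -> pd.DataFrame:
    """Per-culture innervation percentage and mean cluster areas.

    ``clusters`` must carry a culture identifier column plus the
    ``innervated`` flag and ``area_um2`` produced by
    :func:`detect_nmj_clusters`.  Cultures with zero clusters yield NaN
    percentages and are flagged.
    """
    rows = []
    for culture, sub in clusters.groupby(culture_col):
        n = len(sub)
        n_inn = int(sub["innervated"].sum())
        rows.append(
            {
                culture_col: culture,
                "n_clusters": n,
                "n_innervated": n_inn,
                "pct_innervated": 100.0 * n_inn / n if n else float("nan"),
                "mean_area_innervated_um2": (
                    float(sub.loc[sub["innervated"], "area_um2"].mean())
                    if n_inn
                    else float("nan")
                ),
                "mean_area_uninnervated_um2": (
                    float(sub.loc[~sub["innervated"], "area_um2"].mean())
                    if n - n_inn
                    else float("nan")
                ),
            }
        )
    return pd.DataFrame(rows)


def normalize_to_isogenic_controls(
    summary: pd.DataFrame,
    metadata: pd.DataFrame,
    value_col: str,
    culture_col: str = "culture_id",
    batch_col: str = "batch_id",
    control_col: str = "is_control",
) -> pd.DataFrame:
    """Normalize per-culture metrics to batch-matched control means.

    ``metadata`` maps cultures to differentiation batches and flags the
    isogenic control cultures; each culture's value is divided by the
    mean of the control cultures within its own batch.  A zero control
    mean raises.
    """
    merged = summary.merge(metadata, on=culture_col, validate="one_to_one")
    out = merged.copy()
    out[f"{value_col}_normalized"] = np.nan
    for batch, sub in merged.groupby(batch_col):
        ctrl = sub.loc[sub[control_col], value_col]
        if ctrl.empty:
            raise ValueError(f"no control cultures in batch {batch!r}")
        ctrl_mean = ctrl.mean()
        if ctrl_mean == 0:
            raise ValueError(f"zero control mean in batch {batch!r}")
        out.loc[sub.index, f"{value_col}_normalized"] = sub[value_col] / ctrl_mean
    return out


__all__.append("normalize_to_isogenic_controls")
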