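"""Pipeline orchestration: configuration, demo fixtures, end-to-end runs.

A :class:`PipelineConfig` holds every stage parameter (defaults match
the analysis recipes), rejects unknown keys, and is echoed into the run
manifest so a run can be reproduced byte-for-byte.  :func:`make_demo`
writes one fixture of each kind (sphere field, contraction video,
neurite stack, NMJ field, grouped table) under a directory;
:func:`run_pipeline` executes every stage over such a bundle and writes
CSV outputs plus a JSON manifest.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from . import __version__
from .dynamics import classify_extent, detect_contractions, frame_delta, summarize_sites
from .imaging import MultiChannelImage
from .neurite_nmj import (
    NMJParams,
    detect_nmj_clusters,
    segment_neurites,
    summarize_nmj,
)
from .spheres import analyze_well
from .stats import among_line_variance, within_line_variance
from .synthetic import (
    GroupedTableSpec,
    NeuriteFixtureSpec,
    NMJFixtureSpec,
    SphereFixtureSpec,
    VideoFixtureSpec,
    generate_contraction_video,
    generate_grouped_table,
    generate_neurite_image,
    generate_nmj_field,
    generate_sphere_image,
)

__all__ = ["PipelineConfig", "RunManifest", "make_demo", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Flat stage-parameter configuration; unknown keys are rejected."""

    scale_um_per_px: float = 1.33
    seed: int = 0
    min_sphere_area: float = 500.0
    potency_cutoff: float = 25.0
    k_mad: float = 5.0
    merge_gap: int = 2
    frame_interval: float = 0.5
    site_duration_s: float = 300.0
    btx_gate: float = 1000.0
    egfp_gate: float = 5000.0
    dim_min_um: float = 10.0
    dim_max_um: float = 50.0

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        data = {}
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, value = line.partition("=")
            key = key.strip()
            value = value.strip()
            data[key] = int(value) if value.lstrip("-").isdigit() else float(value)
        return cls.from_dict(data)

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


@dataclass
class RunManifest:
    version: str
    config: dict
    config_hash: str
    inputs: list[str]
    stage_counts: dict[str, int] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    def write(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, sort_keys=True))


def make_demo(seed: int, outdir) -> dict[str, Path]:
    """Generate one fixture of each kind; returns the file inventory.

    Fixtures are written as TIFF (images/videos) and CSV (ground truth
    and tables) and are sized to run end-to-end in minutes on one CPU.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    inventory: dict[str, Path] = {}

    # spheres spanning the potency axis: stained fraction 0.9, marker
    # overlap 0.2, so sox2 + tbxt = 1.1 and potency = 100*(sox2 - tbxt)
    spread = rng.uniform(-0.5, 0.5, 9)
    sphere_spec = SphereFixtureSpec(
        n_spheres=9,
        sox2_fraction=tuple((1.1 + spread) / 2),
        tbxt_fraction=tuple((1.1 - spread) / 2),
        unstained_fraction=(0.1,),
        field_shape=(384, 384),
        seed=int(rng.integers(2**31)),
    )
    image, truth = generate_sphere_image(sphere_spec)
    path = outdir / "sphere_field.tif"
    tifffile.imwrite(path, np.stack([image.channel(c) for c in ("nuclear", "sox2", "tbxt")]), photometric="minisblack")
    truth.to_csv(outdir / "sphere_truth.csv", index=False)
    inventory["sphere_field"] = path

    video_spec = VideoFixtureSpec(
        n_frames=120,
        event_times=(20, 50, 80),
        event_extent=0.3,
        field_shape=(64, 64),
        seed=int(rng.integers(2**31)),
    )
    frames, vtruth = generate_contraction_video(video_spec)
    path = outdir / "contraction_video.tif"
    tifffile.imwrite(path, frames.astype(np.float32), photometric="minisblack")
    vtruth.to_csv(outdir / "contraction_truth.csv", index=False)
    inventory["contraction_video"] = path

    neurite_spec = NeuriteFixtureSpec(n_filaments=2, seed=int(rng.integers(2**31)))
    stack, narea = generate_neurite_image(neurite_spec)
    path = outdir / "neurite_stack.tif"
    tifffile.imwrite(path, stack, photometric="minisblack")
    (outdir / "neurite_truth.csv").write_text(f"ground_truth_neurite_area_px2\n{narea}\n")
    inventory["neurite_stack"] = path

    n_clusters = 12
    innervated = tuple(bool(b) for b in rng.random(n_clusters) < 0.5)
    nmj_spec = NMJFixtureSpec(
        n_clusters=n_clusters,
        diameter_um=tuple(rng.uniform(15, 45, n_clusters)),
        btx_intensity=(8000.0,),
        egfp_intensity=tuple(12000.0 if b else 500.0 for b in innervated),
        innervated_truth=innervated,
        field_shape=(384, 384),
        seed=int(rng.integers(2**31)),
    )
    nmj_image, ntruth = generate_nmj_field(nmj_spec)
    path = outdir / "nmj_field.tif"
    tifffile.imwrite(path, np.stack([nmj_image.channel("btx"), nmj_image.channel("egfp")]), photometric="minisblack")
    ntruth.to_csv(outdir / "nmj_truth.csv", index=False)
    inventory["nmj_field"] = path

    table_spec = GroupedTableSpec(
        n_lines=11,
        line_means=tuple(
            np.concatenate([rng.normal(100, 25, 5), rng.normal(100, 3, 6)])
        ),
        within_line_sd=8.0,
        batch_sd=10.0,
        wells_per_line_per_batch=2,
        n_batches=3,
        seed=int(rng.integers(2**31)),
    )
    table = generate_grouped_table(table_spec)
    table["group"] = np.where(
        table["line_id"].str[-2:].astype(int) < 5, "non-isogenic", "isogenic"
    )
    table.to_csv(outdir / "grouped_table.csv", index=False)
    inventory["grouped_table"] = outdir / "grouped_table.csv"
    return inventory


def run_pipeline(config: PipelineConfig, datadir, outdir) -> RunManifest:
    """Run every stage over a demo-format bundle and write CSV outputs."""
    datadir, outdir = Path(datadir), Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        version=__version__,
        config=asdict(config),
        config_hash=config.config_hash(),
        inputs=sorted(str(p.name) for p in datadir.iterdir()),
    )

    # spheres
    arr = tifffile.imread(datadir / "sphere_field.tif")
    image = MultiChannelImage(
        {"nuclear": arr[0], "sox2": arr[1], "tbxt": arr[2]}, config.scale_um_per_px
    )
    sphere_table, summary = analyze_well(
        image, min_sphere_area=config.min_sphere_area, cutoff=config.potency_cutoff
    )
    sphere_table.to_csv(outdir / "spheres.csv", index=False)
    manifest.stage_counts["spheres_detected"] = summary.n_spheres_total
    manifest.stage_counts["spheres_retained"] = summary.n_spheres_retained

    # contraction video
    frames = tifffile.imread(datadir / "contraction_video.tif").astype(float)
    signal = frame_delta(frames, config.frame_interval)
    events = [
        classify_extent(frames, e)
        for e in detect_contractions(signal, config.k_mad, config.merge_gap)
    ]
    pd.DataFrame([e.__dict__ for e in events]).to_csv(outdir / "events.csv", index=False)
    _, culture = summarize_sites({"site0": events}, config.site_duration_s)
    manifest.stage_counts["contraction_events"] = len(events)

    # neurites
    stack = tifffile.imread(datadir / "neurite_stack.tif")
    neurite = segment_neurites(stack, config.scale_um_per_px)
    pd.DataFrame(
        [{"neurite_area_px2": neurite.neurite_area_px2, "n_tracks": neurite.n_tracks}]
    ).to_csv(outdir / "neurites.csv", index=False)
    manifest.stage_counts["neurite_tracks"] = neurite.n_tracks

    # NMJ
    arr = tifffile.imread(datadir / "nmj_field.tif")
    nmj_image = MultiChannelImage({"btx": arr[0], "egfp": arr[1]}, config.scale_um_per_px)
    clusters = detect_nmj_clusters(
        nmj_image,
        params=NMJParams(
            btx_gate=config.btx_gate,
            egfp_gate=config.egfp_gate,
            dim_min_um=config.dim_min_um,
            dim_max_um=config.dim_max_um,
        ),
    )
    clusters["culture_id"] = "demo"
    clusters.to_csv(outdir / "nmj_clusters.csv", index=False)
    summarize_nmj(clusters).to_csv(outdir / "nmj_summary.csv", index=False)
    manifest.stage_counts["nmj_clusters"] = len(clusters)

    # statistics
    table = pd.read_csv(datadir / "grouped_table.csv")
    group_map = dict(zip(table["line_id"], table["group"]))
    among = among_line_variance(table, group_map)
    within = within_line_variance(table, group_map)
    pd.DataFrame(
        [
            {"mode": "among", "statistic": among.test.statistic, "p": among.test.p_value},
            {"mode": "within", "statistic": within.test.statistic, "p": within.test.p_value},
        ]
    ).to_csv(outdir / "variance_stats.csv", index=False)
    manifest.stage_counts["lines"] = table["line_id"].nunique()
    manifest.write(outdir / "manifest.json")
    return manifest
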