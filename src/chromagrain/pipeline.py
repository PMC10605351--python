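"""Batch orchestration: segment -> quantify -> granules -> compare.

One structured config drives the whole chain over a manifest of images
with group labels. Every QC exclusion and every parameter value used is
recorded in a machine-readable run log; a failing image is reported and
skipped, the remaining images are still processed.
"""

from __future__ import annotations

import json
import logging
import traceback
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import yaml

from . import __version__
from .granularity import analyze_granularity
from .group_stats import (
    MetricKind,
    boxplot_summary,
    pairwise_comparisons,
)
from .image_io import (
    CalibratedImage,
    ChannelRole,
    read_multichannel_image,
    write_tables,
)
from .quantify import compute_nucleus_metrics, metrics_table
from .segmentation import QCReason, flag_weak_signal, mask_background, segment_nuclei

log = logging.getLogger("chromagrain")


@dataclass
class ImageEntry:
    path: str | list[str]
    group: str


@dataclass
class RunConfig:
    images: list[ImageEntry]
    channel_map: dict
    pixel_edge_nm: float = 25.88
    bit_depth: int = 12
    output_dir: str = "chromagrain_out"
    seed: int = 0
    segmentation: dict = field(default_factory=dict)
    granularity: dict = field(default_factory=dict)
    stats: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        images = [ImageEntry(path=e["path"], group=str(e["group"])) for e in raw["images"]]
        return cls(
            images=images,
            channel_map=raw["channel_map"],
            pixel_edge_nm=float(raw.get("pixel_edge_nm", 25.88)),
            bit_depth=int(raw.get("bit_depth", 12)),
            output_dir=str(raw.get("output_dir", "chromagrain_out")),
            seed=int(raw.get("seed", 0)),
            segmentation=dict(raw.get("segmentation", {})),
            granularity=dict(raw.get("granularity", {})),
            stats=dict(raw.get("stats", {})),
        )

    def validate(self) -> None:
        if not self.images:
            raise ValueError("config lists no images")
        for entry in self.images:
            paths = entry.path if isinstance(entry.path, list) else [entry.path]
            for p in paths:
                if not Path(p).exists():
                    raise FileNotFoundError(f"input image not found: {p}")
            if not entry.group:
                raise ValueError(f"image {entry.path} has no group label")


@dataclass
class RunResult:
    output_dir: Path
    tables: dict[str, pd.DataFrame]
    failures: list[tuple[str, str, str]]  # (image_id, stage, message)

    @property
    def ok(self) -> bool:
        return not self.failures


def _granularity_channels(cfg: dict, image: CalibratedImage) -> list[ChannelRole]:
    names = cfg.get("channels")
    if names is None:
        defaults = (ChannelRole.COHESIN, ChannelRole.HC_H3K9ME3)
        return [r for r in defaults if r in image.channels]
    return [ChannelRole.from_string(n) for n in names]


def analyze_image(
    image: CalibratedImage,
    seg_cfg: dict,
    gran_cfg: dict,
    exclusions: list[dict] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Single-image analysis: returns (nucleus metrics, per-granule,
    granularity summary, threshold provenance) tables."""
    masks = segment_nuclei(
        image.dna,
        min_area_um2=float(seg_cfg.get("min_area_um2", 20.0)),
        pixel_edge_nm=image.pixel_edge_nm,
        threshold=seg_cfg.get("threshold"),
    )
    min_mean = float(seg_cfg.get("min_mean_intensity", 0.0))
    roles = _granularity_channels(gran_cfg, image)
    if min_mean > 0:
        for rec in masks.passing():
            for role in roles:
                updated = flag_weak_signal(
                    image.channels[role], rec, masks.mask_of(rec.label), min_mean
                )
                if not updated.qc_pass:
                    masks.replace_record(updated)
                    break
    if exclusions is not None:
        for rec in masks.nuclei:
            if not rec.qc_pass:
                exclusions.append(
                    {
                        "image_id": image.source_id,
                        "nucleus_label": rec.label,
                        "reason": rec.qc_reason.value,
                    }
                )
    clean = mask_background(image, masks)
    metrics = compute_nucleus_metrics(clean, masks, passing_only=True)
    mtable = metrics_table(metrics, image.pixel_edge_nm)

    gran_rows, summ_rows, thr_rows = [], [], []
    gkw = dict(
        n_bins=int(gran_cfg.get("n_bins", 256)),
        intensity_max=image.intensity_max,
        max_passes=int(gran_cfg.get("max_smoothing_passes", 1000)),
        median_window=int(gran_cfg.get("median_window", 3)),
        connectivity=int(gran_cfg.get("connectivity", 8)),
        min_size_px=int(gran_cfg.get("min_size_px", 5)),
    )
    for rec in masks.passing():
        mask = masks.mask_of(rec.label)
        for role in roles:
            gset, summary = analyze_granularity(
                clean.channels[role], mask, nucleus_label=rec.label,
                channel_role=role, **gkw,
            )
            bt = gset.threshold_used
            thr_rows.append(
                {
                    "nucleus_label": rec.label,
                    "channel": role.value,
                    "mode_lo_j": bt.mode_lo,
                    "mode_hi_k": bt.mode_hi,
                    "threshold_t": bt.threshold,
                    "smoothing_passes": bt.smoothing_passes,
                    "bimodal": bt.bimodal,
                }
            )
            if summary is None:
                if exclusions is not None:
                    exclusions.append(
                        {
                            "image_id": image.source_id,
                            "nucleus_label": rec.label,
                            "reason": f"no_granulation_{role.value}",
                        }
                    )
                continue
            for g in gset.granules:
                gran_rows.append(
                    {
                        "nucleus_label": rec.label,
                        "channel": role.value,
                        "granule_id": g.granule_id,
                        "pixel_count": g.pixel_count,
                        "mean_intensity": g.mean_intensity,
                        "centroid_row": g.centroid[0],
                        "centroid_col": g.centroid[1],
                    }
                )
            summ_rows.append(
                {
                    "nucleus_label": rec.label,
                    "channel": role.value,
                    "n_granules": summary.n_granules,
                    "mean_area_px": summary.mean_area_px,
                    "pixelwise_mean_intensity": summary.pixelwise_mean_intensity,
                    "granulewise_mean_intensity": summary.granulewise_mean_intensity,
                }
            )
    return mtable, pd.DataFrame(gran_rows), pd.DataFrame(summ_rows), pd.DataFrame(thr_rows)


_COMPARE_METRICS: list[tuple[str, MetricKind]] = [("area_um2", MetricKind.NUCLEUS_SIZE)]


def _group_tables(
    per_image: list[tuple[str, str, pd.DataFrame, pd.DataFrame]],
    stats_cfg: dict,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise comparisons and boxplot summaries for every metric.

    Metrics: nucleus area (t-test) and every amount / granularity
    column (Kruskal-Wallis), each compared between all group pairs.
    """
    metric_values: dict[str, dict[str, list[float]]] = {}

    def add(metric: str, group: str, values: Iterable[float]) -> None:
        vals = [float(v) for v in values if pd.notna(v)]
        if vals:
            metric_values.setdefault(metric, {}).setdefault(group, []).extend(vals)

    for image_id, group, mtable, stable in per_image:
        if not mtable.empty:
            add("area_um2", group, mtable["area_um2"])
            for col in mtable.columns:
                if col.endswith("_amount_px") or col.endswith("_mean_intensity"):
                    add(col, group, mtable[col])
        if not stable.empty:
            for channel, sub in stable.groupby("channel"):
                for col in ("n_granules", "mean_area_px", "pixelwise_mean_intensity"):
                    add(f"{channel}_{col}", group, sub[col])

    comp_rows, box_rows = [], []
    holm = bool(stats_cfg.get("holm", False))
    for metric, by_group in metric_values.items():
        kind = MetricKind.NUCLEUS_SIZE if metric == "area_um2" else MetricKind.OTHER
        usable = {g: v for g, v in by_group.items() if len(v) >= 3}
        if len(usable) >= 2:
            for comp in pairwise_comparisons(usable, kind, metric_name=metric, holm=holm):
                comp_rows.append(
                    {
                        "metric": metric,
                        "group_a": comp.group_labels[0],
                        "group_b": comp.group_labels[1],
                        "test": comp.test_used.value,
                        "statistic": comp.statistic,
                        "p_value": comp.p_value,
                        "tier": comp.tier.value,
                    }
                )
        for group, vals in by_group.items():
            if len(vals) < 2:
                continue
            s = boxplot_summary(vals)
            box_rows.append(
                {
                    "metric": metric,
                    "group": group,
                    "n": s.n,
                    "median": s.median,
                    "q1": s.q1,
                    "q3": s.q3,
                    "mean": s.mean,
                    "sd": s.sd,
                    "whisker_lo": s.whisker_lo,
                    "whisker_hi": s.whisker_hi,
                    "n_outliers": len(s.outliers),
                }
            )
    return pd.DataFrame(comp_rows), pd.DataFrame(box_rows)


def run_on_images(
    images_with_groups: Sequence[tuple[CalibratedImage, str]],
    output_dir,
    seg_cfg: dict | None = None,
    gran_cfg: dict | None = None,
    stats_cfg: dict | None = None,
    seed: int = 0,
) -> RunResult:
    """Run the analysis chain over in-memory images (the file-based
    entry point :func:`run_pipeline` delegates here after reading)."""
    seg_cfg = seg_cfg or {}
    gran_cfg = gran_cfg or {}
    stats_cfg = stats_cfg or {}
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)

    exclusions: list[dict] = []
    failures: list[tuple[str, str, str]] = []
    per_image = []
    nuc_frames, gran_frames, summ_frames, thr_frames = [], [], [], []
    for image, group in images_with_groups:
        try:
            mtable, gtable, stable, ttable = analyze_image(
                image, seg_cfg, gran_cfg, exclusions
            )
        except Exception as exc:  # keep processing the remaining images
            log.error("image %s failed: %s", image.source_id, exc)
            failures.append((image.source_id, "analyze", str(exc)))
            continue
        for frame in (mtable, gtable, stable, ttable):
            frame.insert(0, "group", group)
            frame.insert(0, "image_id", image.source_id)
        per_image.append((image.source_id, group, mtable, stable))
        nuc_frames.append(mtable)
        gran_frames.append(gtable)
        summ_frames.append(stable)
        thr_frames.append(ttable)

    def cat(frames):
        frames = [f for f in frames if not f.empty]
        return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()

    comparisons, boxplots = _group_tables(per_image, stats_cfg)
    tables = {
        "nucleus_metrics": cat(nuc_frames),
        "granules": cat(gran_frames),
        "granularity_summary": cat(summ_frames),
        "thresholds": cat(thr_frames),
        "comparisons": comparisons,
        "boxplot_summaries": boxplots,
    }
    write_tables(tables, out)
    run_log = {
        "version": __version__,
        "seed": seed,
        "parameters": {
            "segmentation": {
                "min_area_um2": float(seg_cfg.get("min_area_um2", 20.0)),
                "min_mean_intensity": float(seg_cfg.get("min_mean_intensity", 0.0)),
                "threshold": seg_cfg.get("threshold", "otsu"),
            },
            "granularity": {
                "n_bins": int(gran_cfg.get("n_bins", 256)),
                "min_size_px": int(gran_cfg.get("min_size_px", 5)),
                "connectivity": int(gran_cfg.get("connectivity", 8)),
                "median_window": int(gran_cfg.get("median_window", 3)),
                "max_smoothing_passes": int(gran_cfg.get("max_smoothing_passes", 1000)),
                "histogram_domain": "within-nucleus pixels only",
            },
            "stats": {"holm": bool(stats_cfg.get("holm", False))},
        },
        "n_images": len(images_with_groups),
        "exclusions": exclusions,
        "failures": [
            {"image_id": i, "stage": s, "message": m} for i, s, m in failures
        ],
    }
    with open(out / "run_log.json", "w") as fh:
        json.dump(run_log, fh, indent=2)
    return RunResult(output_dir=out, tables=tables, failures=failures)


def run_pipeline(config: RunConfig) -> RunResult:
    """Execute the full chain described by a validated RunConfig."""
    config.validate()
    images: list[tuple[CalibratedImage, str]] = []
    failures: list[tuple[str, str, str]] = []
    for entry in config.images:
        try:
            img = read_multichannel_image(
                entry.path,
                config.channel_map,
                pixel_edge_nm=config.pixel_edge_nm,
                bit_depth=config.bit_depth,
            )
        except Exception as exc:
            name = str(entry.path)
            log.error("reading %s failed: %s", name, exc)
            failures.append((name, "read", str(exc)))
            continue
        images.append((img, entry.group))
    result = run_on_images(
        images,
        config.output_dir,
        seg_cfg=config.segmentation,
        gran_cfg=config.granularity,
        stats_cfg=config.stats,
        seed=config.seed,
    )
    result.failures = failures + result.failures
    return result
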