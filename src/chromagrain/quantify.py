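"""Per-nucleus size and signal-amount metrics.

The "amount" of a chromatin mark in a nucleus is the within-mask mean
intensity times the nucleus size in pixels — i.e. the integrated
within-mask intensity, in arbitrary units x pixels. No background
subtraction is applied inside the mask. A convenience amount in
intensity x um^2 is derived from the pixel calibration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .image_io import CalibratedImage, ChannelRole, pixels_to_um2
from .segmentation import NucleusMaskSet


@dataclass(frozen=True)
class ChannelAmount:
    mean_intensity: float
    amount: float  # mean_intensity * pixel_count == integrated intensity


@dataclass(frozen=True)
class NucleusMetrics:
    nucleus_label: int
    pixel_count: int
    area_um2: float
    per_channel: dict[ChannelRole, ChannelAmount]


def nucleus_area_um2(mask: np.ndarray, pixel_edge_nm: float) -> float:
    """Nucleus area in um^2 from its pixel mask and calibration."""
    mask = np.asarray(mask, dtype=bool)
    n = int(mask.sum())
    if n == 0:
        raise ValueError("nucleus mask is empty")
    return pixels_to_um2(n, pixel_edge_nm)


def channel_amount(channel: np.ndarray, mask: np.ndarray) -> ChannelAmount:
    """Mean within-mask intensity and amount (mean x pixel count)."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("nucleus mask is empty")
    values = np.asarray(channel)[mask]
    mean = float(values.mean(dtype=np.float64))
    return ChannelAmount(mean_intensity=mean, amount=float(values.sum(dtype=np.float64)))


def compute_nucleus_metrics(
    image: CalibratedImage, masks: NucleusMaskSet, passing_only: bool = True
) -> list[NucleusMetrics]:
    """Per-nucleus area and per-channel amounts for a segmented image."""
    out = []
    records = masks.passing() if passing_only else masks.nuclei
    for rec in records:
        mask = masks.mask_of(rec.label)
        per = {role: channel_amount(grid, mask) for role, grid in image.channels.items()}
        out.append(
            NucleusMetrics(
                nucleus_label=rec.label,
                pixel_count=rec.pixel_count,
                area_um2=pixels_to_um2(rec.pixel_count, image.pixel_edge_nm),
                per_channel=per,
            )
        )
    return out


def metrics_table(metrics: list[NucleusMetrics], pixel_edge_nm: float) -> pd.DataFrame:
    """Flatten metrics to one row per nucleus, columns per channel.

    Emits both the amount in intensity*pixels (primary) and the derived
    intensity*um^2 column.
    """
    rows = []
    for m in metrics:
        row: dict = {
            "nucleus_label": m.nucleus_label,
            "pixel_count": m.pixel_count,
            "area_um2": m.area_um2,
        }
        for role, ca in m.per_channel.items():
            key = role.value
            row[f"{key}_mean_intensity"] = ca.mean_intensity
            row[f"{key}_amount_px"] = ca.amount
            row[f"{key}_amount_um2"] = pixels_to_um2(1, pixel_edge_nm) * ca.amount
        rows.append(row)
    return pd.DataFrame(rows)
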