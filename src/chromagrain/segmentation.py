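"""Nucleus segmentation from the DNA counterstain channel.

The counterstain is thresholded with Otsu's method, holes are filled,
and 8-connected components become candidate nuclei. Quality control is
rule-based: components touching the frame edge are excluded as
incomplete, components below a minimum physical area are excluded as
debris, and nuclei whose label signal is too weak can be excluded per
channel. Every exclusion carries an explicit reason; nothing is dropped
silently. Touching nuclei are not split — the pipeline targets isolated
nuclei from low-background fields.
"""

from __future__ import annotations

import dataclasses
import enum
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label

from .image_io import CalibratedImage, ChannelRole, pixels_to_um2

DEFAULT_MIN_AREA_UM2 = 20.0


class QCReason(enum.Enum):
    PASS = "pass"
    BORDER = "border"
    TOO_SMALL = "too_small"
    TOO_WEAK = "too_weak"


@dataclass(frozen=True)
class NucleusRecord:
    """One candidate nucleus with its QC verdict.

    ``bounding_box`` is (row_min, col_min, row_max, col_max), 0-based,
    half-open. ``qc_pass`` is derived: true iff ``qc_reason`` is PASS.
    """

    label: int
    pixel_count: int
    bounding_box: tuple[int, int, int, int]
    touches_border: bool
    qc_reason: QCReason

    @property
    def qc_pass(self) -> bool:
        return self.qc_reason is QCReason.PASS


@dataclass
class NucleusMaskSet:
    """Labeled nucleus regions: 0 = background, n > 0 = nucleus n.

    Labels are consecutive 1..N and correspond one-to-one with the
    ``nuclei`` records (all candidates, passing or not).
    """

    label_map: np.ndarray
    nuclei: list[NucleusRecord]

    def __post_init__(self) -> None:
        present = set(np.unique(self.label_map)) - {0}
        recorded = {r.label for r in self.nuclei}
        if present != recorded:
            raise ValueError("label_map labels and nucleus records disagree")
        if recorded and recorded != set(range(1, len(self.nuclei) + 1)):
            raise ValueError("labels must be consecutive 1..N")

    def mask_of(self, label: int) -> np.ndarray:
        return self.label_map == label

    def record_of(self, label: int) -> NucleusRecord:
        for r in self.nuclei:
            if r.label == label:
                return r
        raise KeyError(label)

    def passing(self) -> list[NucleusRecord]:
        return [r for r in self.nuclei if r.qc_pass]

    def replace_record(self, record: NucleusRecord) -> None:
        self.nuclei = [record if r.label == record.label else r for r in self.nuclei]


def segment_nuclei(
    dna_channel: np.ndarray,
    min_area_um2: float = DEFAULT_MIN_AREA_UM2,
    pixel_edge_nm: float = 25.88,
    threshold: float | None = None,
) -> NucleusMaskSet:
    """Segment nuclei from a DNA-counterstain grid.

    Foreground is pixels strictly above a global threshold (Otsu by
    default, overridable), holes are filled, and components are labeled
    with 8-connectivity. Components with any pixel on the frame edge are
    flagged BORDER; remaining components smaller than ``min_area_um2``
    are flagged TOO_SMALL; the rest PASS. A constant image yields an
    empty mask set.
    """
    dna = np.asarray(dna_channel)
    if dna.ndim != 2 or dna.size == 0:
        raise ValueError("dna_channel must be a nonempty 2D grid")
    empty = NucleusMaskSet(label_map=np.zeros(dna.shape, dtype=np.int32), nuclei=[])
    if dna.min() == dna.max():
        return empty
    thr = float(threshold_otsu(dna)) if threshold is None else float(threshold)
    fg = dna > thr
    if not fg.any():
        return empty
    fg = ndimage.binary_fill_holes(fg)
    labeled = cc_label(fg, connectivity=2)
    n = int(labeled.max())
    records: list[NucleusRecord] = []
    slices = ndimage.find_objects(labeled)
    h, w = dna.shape
    for lab in range(1, n + 1):
        sl = slices[lab - 1]
        mask = labeled[sl] == lab
        count = int(mask.sum())
        r0, c0 = sl[0].start, sl[1].start
        r1, c1 = sl[0].stop, sl[1].stop
        touches = r0 == 0 or c0 == 0 or r1 == h or c1 == w
        if touches:
            reason = QCReason.BORDER
        elif pixels_to_um2(count, pixel_edge_nm) < min_area_um2:
            reason = QCReason.TOO_SMALL
        else:
            reason = QCReason.PASS
        records.append(
            NucleusRecord(
                label=lab,
                pixel_count=count,
                bounding_box=(r0, c0, r1, c1),
                touches_border=touches,
                qc_reason=reason,
            )
        )
    return NucleusMaskSet(label_map=labeled.astype(np.int32), nuclei=records)


def mask_background(image: CalibratedImage, masks: NucleusMaskSet) -> CalibratedImage:
    """Zero label-channel intensities outside every nucleus mask.

    The DNA channel and all within-mask pixels are unchanged; a new
    image is returned.
    """
    if masks.label_map.shape != (image.height, image.width):
        raise ValueError("mask set and image dimensions differ")
    inside = masks.label_map > 0
    channels = {}
    for role, grid in image.channels.items():
        if role is ChannelRole.DNA_COUNTERSTAIN:
            channels[role] = grid
        else:
            channels[role] = np.where(inside, grid, 0).astype(grid.dtype)
    return CalibratedImage(
        channels=channels,
        pixel_edge_nm=image.pixel_edge_nm,
        bit_depth=image.bit_depth,
        source_id=image.source_id,
    )


def flag_weak_signal(
    channel: np.ndarray,
    record: NucleusRecord,
    mask: np.ndarray,
    min_mean_intensity: float = 0.0,
) -> NucleusRecord:
    """Flag a nucleus TOO_WEAK when its within-mask mean intensity of a
    label channel falls below ``min_mean_intensity`` (default 0: off)."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("nucleus mask is empty")
    mean = float(np.asarray(channel)[mask].mean())
    if mean < min_mean_intensity:
        return dataclasses.replace(record, qc_reason=QCReason.TOO_WEAK)
    return record
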