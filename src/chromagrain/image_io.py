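"""Calibrated multichannel image I/O and physical-unit conversion.

Images are multichannel 2D fluorescence frames: one DNA counterstain
channel (used for nucleus segmentation) plus up to three label channels
(euchromatin mark H3K4me3, heterochromatin mark H3K9me3, cohesin).
Intensities are integers validated against a declared bit depth
(default 12 bit, range 0-4095, stored in 16-bit containers), and a single
isotropic nm-per-pixel-edge scalar carries the physical calibration
(default 25.88 nm, i.e. 669.77 nm^2 per pixel).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile

DEFAULT_PIXEL_EDGE_NM = 25.88
DEFAULT_BIT_DEPTH = 12


class ChannelRole(enum.Enum):
    """Biological role of an acquisition channel.

    The DNA counterstain (DAPI) channel is mandatory: it defines the
    nucleus masks. The three label channels are each optional.
    """

    DNA_COUNTERSTAIN = "dna"
    EC_H3K4ME3 = "ec_h3k4me3"
    HC_H3K9ME3 = "hc_h3k9me3"
    COHESIN = "cohesin"

    @classmethod
    def from_string(cls, name: str) -> "ChannelRole":
        key = str(name).strip().lower()
        aliases = {
            "dna": cls.DNA_COUNTERSTAIN,
            "dapi": cls.DNA_COUNTERSTAIN,
            "dna_counterstain": cls.DNA_COUNTERSTAIN,
            "ec": cls.EC_H3K4ME3,
            "ec_h3k4me3": cls.EC_H3K4ME3,
            "h3k4me3": cls.EC_H3K4ME3,
            "hc": cls.HC_H3K9ME3,
            "hc_h3k9me3": cls.HC_H3K9ME3,
            "h3k9me3": cls.HC_H3K9ME3,
            "cohesin": cls.COHESIN,
        }
        if key not in aliases:
            raise ValueError(f"unknown channel role {name!r}")
        return aliases[key]


LABEL_ROLES = (ChannelRole.EC_H3K4ME3, ChannelRole.HC_H3K9ME3, ChannelRole.COHESIN)


@dataclass
class CalibratedImage:
    """Multichannel pixel grid plus physical calibration and channel roles.

    Parameters
    ----------
    channels
        Mapping of :class:`ChannelRole` to a 2D integer intensity grid.
        All grids must share one shape; every intensity must lie in
        ``[0, 2**bit_depth - 1]``.
    pixel_edge_nm
        Physical edge length of one (square) pixel in nanometres.
    bit_depth
        Declared acquisition bit depth; out-of-range intensities are an
        error, never clamped.
    source_id
        Opaque identifier of the originating image (file stem, scene id).
    """

    channels: dict[ChannelRole, np.ndarray]
    pixel_edge_nm: float = DEFAULT_PIXEL_EDGE_NM
    bit_depth: int = DEFAULT_BIT_DEPTH
    source_id: str = ""

    def __post_init__(self) -> None:
        if ChannelRole.DNA_COUNTERSTAIN not in self.channels:
            raise ValueError("a DNA counterstain channel is mandatory")
        if not self.pixel_edge_nm > 0:
            raise ValueError("pixel_edge_nm must be positive")
        if self.bit_depth <= 0:
            raise ValueError("bit_depth must be positive")
        ceiling = self.intensity_max
        shape = None
        clean: dict[ChannelRole, np.ndarray] = {}
        for role, grid in self.channels.items():
            arr = np.asarray(grid)
            if arr.ndim != 2 or arr.size == 0:
                raise ValueError(f"channel {role.name}: expected a nonempty 2D grid")
            if not np.issubdtype(arr.dtype, np.integer):
                raise ValueError(f"channel {role.name}: intensities must be integer")
            if shape is None:
                shape = arr.shape
            elif arr.shape != shape:
                raise ValueError(
                    f"channel {role.name}: shape {arr.shape} differs from {shape}"
                )
            if arr.min() < 0 or arr.max() > ceiling:
                raise ValueError(
                    f"channel {role.name}: intensity outside declared "
                    f"{self.bit_depth}-bit range [0, {ceiling}]"
                )
            clean[role] = arr.astype(np.uint16, copy=False)
        self.channels = clean

    @property
    def intensity_max(self) -> int:
        return 2**self.bit_depth - 1

    @property
    def height(self) -> int:
        return next(iter(self.channels.values())).shape[0]

    @property
    def width(self) -> int:
        return next(iter(self.channels.values())).shape[1]

    @property
    def dna(self) -> np.ndarray:
        return self.channels[ChannelRole.DNA_COUNTERSTAIN]

    def label_channels(self) -> dict[ChannelRole, np.ndarray]:
        return {r: g for r, g in self.channels.items() if r is not ChannelRole.DNA_COUNTERSTAIN}


def _normalize_channel_map(channel_map: Mapping) -> dict:
    out = {}
    for key, role in channel_map.items():
        out[key] = role if isinstance(role, ChannelRole) else ChannelRole.from_string(role)
    roles = list(out.values())
    if len(set(roles)) != len(roles):
        raise ValueError("channel_map assigns one role to several pages/files")
    if roles.count(ChannelRole.DNA_COUNTERSTAIN) != 1:
        raise ValueError("channel_map must assign the DNA counterstain exactly once")
    return out


def read_multichannel_image(
    paths_or_path,
    channel_map: Mapping,
    pixel_edge_nm: float = DEFAULT_PIXEL_EDGE_NM,
    bit_depth: int = DEFAULT_BIT_DEPTH,
    source_id: str | None = None,
) -> CalibratedImage:
    """Read TIFF page(s) into a :class:`CalibratedImage`.

    Two layouts are supported: a single multi-page TIFF with
    ``channel_map`` keyed by page index, or a sequence of single-channel
    TIFF files with ``channel_map`` keyed by file index. Roles may be
    given as :class:`ChannelRole` or strings (``"dna"``, ``"cohesin"``,
    ``"hc_h3k9me3"``, ``"ec_h3k4me3"``).
    """
    cmap = _normalize_channel_map(channel_map)
    channels: dict[ChannelRole, np.ndarray] = {}
    if isinstance(paths_or_path, (str, Path)):
        pages = tifffile.imread(paths_or_path)
        if pages.ndim == 2:
            pages = pages[None]
        for idx, role in cmap.items():
            idx = int(idx)
            if idx >= pages.shape[0]:
                raise ValueError(f"channel_map references page {idx}; file has {pages.shape[0]}")
            channels[role] = np.asarray(pages[idx])
        src = Path(paths_or_path).stem
    else:
        paths: Sequence = list(paths_or_path)
        for idx, role in cmap.items():
            channels[role] = np.asarray(tifffile.imread(paths[int(idx)]))
        src = Path(paths[0]).stem
    return CalibratedImage(
        channels=channels,
        pixel_edge_nm=pixel_edge_nm,
        bit_depth=bit_depth,
        source_id=source_id if source_id is not None else src,
    )


def pixel_area_nm2(pixel_edge_nm: float) -> float:
    """Physical area of one square pixel in nm^2 (edge length squared)."""
    if not pixel_edge_nm > 0:
        raise ValueError("pixel_edge_nm must be positive")
    return float(pixel_edge_nm) ** 2


def pixels_to_um2(n_pixels: int, pixel_edge_nm: float = DEFAULT_PIXEL_EDGE_NM) -> float:
    """Convert a pixel count to an area in square micrometres."""
    if n_pixels < 0:
        raise ValueError("n_pixels must be non-negative")
    return float(n_pixels) * pixel_area_nm2(pixel_edge_nm) / 1e6


def write_tables(tables: Mapping[str, pd.DataFrame], destination) -> dict[str, Path]:
    """Write named record tables as RFC-4180 CSV (UTF-8, '.' decimal).

    Column order is preserved as given; re-reading reproduces integer
    fields exactly. Returns the mapping table name -> file path.
    """
    dest = Path(destination)
    dest.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    for name, frame in tables.items():
        if not isinstance(frame, pd.DataFrame):
            frame = pd.DataFrame(list(frame))
        path = dest / f"{name}.csv"
        frame.to_csv(path, index=False, encoding="utf-8")
        written[name] = path
    return written
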