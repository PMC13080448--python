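"""Configuration, image and table I/O shared by every pipeline stage.

All analysis parameters live in :class:`PipelineConfig` so that a single
config file drives every stage identically across samples. Result tables
are plain pandas DataFrames serialized as comma-delimited UTF-8 text; raster
images are TIFF (8/16-bit, interleaved or planar) with PNG accepted for
fixtures.
"""

from __future__ import annotations

import logging
import sys
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile
import yaml

logger = logging.getLogger("ecfoam")

#: canonical channel roles of a three-channel FISH frame
CHANNEL_ROLES = ("MYC", "CHR8", "DAPI")


def configure_logging(verbose: bool = False) -> None:
    """Log to stderr; results never go to the log stream."""
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    logger.handlers[:] = [handler]
    logger.setLevel(logging.DEBUG if verbose else logging.INFO)


@dataclass
class PipelineConfig:
    """Fixed analysis parameters, held constant across all samples.

    Parameters
    ----------
    pixel_size_um
        Lateral calibration in micrometres per pixel.
    channel_order
        Mapping of channel role (``MYC``, ``CHR8``, ``DAPI``) to the raster
        channel index holding it.
    thresholds
        Per-role threshold spec: ``{"method": "otsu"}`` or
        ``{"method": "fixed", "value": v}``.
    min_focus_area_px
        Smallest connected component accepted as a MYC focus.
    chr8_min_area_px
        Area filter (pixels) applied when counting chr8 centromere objects.
    aggregate_cutoff_um
        Equivalent-diameter cutoff separating large, tumor-like aggregates
        from small ones.
    min_aggregate_diameter_um
        Smallest object treated as an aggregate rather than a dispersed cell.
    expected_chr8_per_cell
        Nominal centromere-8 count used to normalize per-cell focus counts.
    dilation_px
        Optional dilation applied to nuclear/chr8 masks before the overlap
        test that removes intrachromosomal signals.
    cell_mode
        ``single_cell_per_image`` (one metaphase spread per frame) or
        ``cluster`` (DAPI-closing based instancing).
    closing_radius_px
        Morphological closing radius used by ``cluster`` cell instancing.
    require_expected_chr8
        If true, cells whose observed chr8 count differs from
        ``expected_chr8_per_cell`` are flagged unquantifiable instead of
        being rescaled.
    ga_prefactor, ga_exponent
        Gibson-Ashby open-cell constants C and n.
    modulus_window_width, modulus_search_range
        Strain span of the sliding linear-fit window and the strain range
        searched for the linear region.
    seed
        Seed for synthetic runs.
    """

    pixel_size_um: float = 1.0
    channel_order: dict = field(
        default_factory=lambda: {"MYC": 0, "CHR8": 1, "DAPI": 2}
    )
    thresholds: dict = field(
        default_factory=lambda: {role: {"method": "otsu"} for role in CHANNEL_ROLES}
    )
    min_focus_area_px: int = 2
    chr8_min_area_px: int = 5
    aggregate_cutoff_um: float = 300.0
    min_aggregate_diameter_um: float = 40.0
    expected_chr8_per_cell: int = 2
    dilation_px: int = 0
    cell_mode: str = "single_cell_per_image"
    closing_radius_px: int = 20
    require_expected_chr8: bool = False
    ga_prefactor: float = 1.0
    ga_exponent: float = 2.0
    modulus_window_width: float = 0.10
    modulus_search_range: tuple = (0.0, 0.3)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        idx = [self.channel_order[r] for r in CHANNEL_ROLES if r in self.channel_order]
        if len(set(idx)) != len(idx):
            raise ValueError("channel indices must be distinct")
        if self.chr8_min_area_px < 1:
            raise ValueError("chr8_min_area_px must be >= 1")
        if self.min_focus_area_px < 1:
            raise ValueError("min_focus_area_px must be >= 1")
        if self.aggregate_cutoff_um <= 0:
            raise ValueError("aggregate_cutoff_um must be positive")
        if self.cell_mode not in ("single_cell_per_image", "cluster"):
            raise ValueError(f"unknown cell_mode {self.cell_mode!r}")
        self.modulus_search_range = tuple(self.modulus_search_range)

    # -- serialization -----------------------------------------------------
    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        data["modulus_search_range"] = list(self.modulus_search_range)
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)


@dataclass
class RasterImage:
    """A calibrated intensity grid, 2-D or 3-D (height x width x channels).

    ``channel_roles`` maps role names to channel indices when the image is a
    multichannel FISH frame.
    """

    pixels: np.ndarray
    pixel_size_um: float = 1.0
    channel_roles: Mapping[str, int] | None = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim not in (2, 3):
            raise ValueError("pixels must be a 2-D or 3-D grid")
        if min(self.pixels.shape[:2]) < 1:
            raise ValueError("image must be at least 1x1")
        if not np.all(np.isfinite(self.pixels.astype(float))):
            raise ValueError("intensities must be finite")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")

    @property
    def n_channels(self) -> int:
        return 1 if self.pixels.ndim == 2 else self.pixels.shape[2]

    def channel(self, role: str) -> np.ndarray:
        """Return the 2-D plane holding *role* (e.g. ``"MYC"``)."""
        if self.pixels.ndim == 2:
            return self.pixels
        if not self.channel_roles or role not in self.channel_roles:
            raise KeyError(f"channel role {role!r} not mapped")
        return self.pixels[:, :, self.channel_roles[role]]


#: FISH frames are ordinary RasterImages whose channel_roles cover
#: MYC (red), CHR8 (green) and DAPI (blue).
FishImage = RasterImage


def _to_channels_last(arr: np.ndarray) -> np.ndarray:
    # planar TIFFs come out (C, H, W); interleaved as (H, W, C)
    if arr.ndim == 3 and arr.shape[0] <= 4 < arr.shape[2]:
        return np.moveaxis(arr, 0, 2)
    return arr


def read_image(path: str | Path, config: PipelineConfig | None = None) -> RasterImage:
    """Read a TIFF or PNG raster and map channels per the config.

    Raises a ``ValueError`` naming the expected roles when the channel count
    does not match the configured channel mapping.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        arr = tifffile.imread(path)
    else:
        arr = iio.imread(path)
    arr = _to_channels_last(np.asarray(arr))
    roles = None
    px = 1.0
    if config is not None:
        px = config.pixel_size_um
        roles = dict(config.channel_order)
        n_expected = max(roles.values()) + 1
        n_have = 1 if arr.ndim == 2 else arr.shape[2]
        if n_have < n_expected:
            raise ValueError(
                f"channel count mismatch: {path.name} has {n_have} channel(s) "
                f"but config maps roles {sorted(roles)} onto {n_expected}"
            )
    logger.debug("read %s shape=%s", path, arr.shape)
    return RasterImage(pixels=arr, pixel_size_um=px, channel_roles=roles)


def write_image(image: RasterImage | np.ndarray, path: str | Path) -> None:
    """Write a raster as TIFF (float arrays are scaled to 16-bit)."""
    arr = image.pixels if isinstance(image, RasterImage) else np.asarray(image)
    if np.issubdtype(arr.dtype, np.floating):
        arr = np.clip(arr, 0.0, 1.0)
        arr = np.round(arr * 65535).astype(np.uint16)
    tifffile.imwrite(Path(path), arr)


def write_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write a result table as comma-delimited UTF-8 with a header row.

    Floats use Python repr so a read-back reproduces values to full
    precision. Column names must be unique.
    """
    if table.columns.duplicated().any():
        raise ValueError("table header names must be unique")
    table.to_csv(Path(path), index=False, encoding="utf-8")


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(Path(path), encoding="utf-8")
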