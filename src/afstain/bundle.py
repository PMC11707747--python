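"""Multichannel image container and TIFF round-trip I/O.

All images in the toolkit travel as :class:`ImageBundle`: a float32 pixel
array of shape (H, W, C) plus the metadata that the pipeline needs —
channel names, physical pixel size in micrometres, a magnification tag and
a provenance dictionary (seed, config hash) sufficient to regenerate the
artifact.

The magnification convention used throughout is 40x = 0.25 um/px and
10x = 1.0 um/px; the pixel size is the authoritative quantity and every
micrometre threshold is converted through it.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import tifffile

#: Canonical mIF channel order.
MIF_CHANNELS = ("DAPI", "PanCK", "PD-L1", "CD3", "CD8", "residualAF")

#: Reference pixel sizes (um/px) per magnification tag.
MAGNIFICATION_UM_PER_PX = {"40x": 0.25, "20x": 0.5, "10x": 1.0}


def um_per_px(magnification: str) -> float:
    """Pixel size in micrometres for a magnification tag such as ``"40x"``."""
    try:
        return MAGNIFICATION_UM_PER_PX[magnification]
    except KeyError:
        raise ValueError(f"unknown magnification tag {magnification!r}") from None


@dataclass
class ImageBundle:
    """A multichannel raster with physical and provenance metadata."""

    pixels: np.ndarray  # (H, W, C) float32
    channel_names: tuple[str, ...]
    pixel_size_um: float
    magnification: str = "40x"
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        # float dtypes are preserved (float64 keeps pixel-wise inverses
        # exact); anything else is promoted to float32
        self.pixels = np.asarray(self.pixels)
        if self.pixels.dtype not in (np.float32, np.float64):
            self.pixels = self.pixels.astype(np.float32)
        if self.pixels.ndim == 2:
            self.pixels = self.pixels[:, :, None]
        if self.pixels.ndim != 3:
            raise ValueError(f"pixels must be (H, W, C), got shape {self.pixels.shape}")
        self.channel_names = tuple(self.channel_names)
        if len(self.channel_names) != self.pixels.shape[2]:
            raise ValueError(
                f"{len(self.channel_names)} channel names for "
                f"{self.pixels.shape[2]} channels"
            )
        if not self.pixel_size_um > 0:
            raise ValueError("pixel_size_um must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.pixels.shape

    @property
    def n_channels(self) -> int:
        return self.pixels.shape[2]

    def channel(self, name: str) -> np.ndarray:
        """Single channel (H, W) by name."""
        try:
            idx = self.channel_names.index(name)
        except ValueError:
            raise KeyError(
                f"channel {name!r} not in {self.channel_names}"
            ) from None
        return self.pixels[:, :, idx]


DEFAULT_PIXEL_SIZE_UM = 0.25


def write_multichannel_image(bundle: ImageBundle, path) -> None:
    """Write a bundle as an uncompressed multichannel TIFF.

    Channel names, pixel size, magnification and provenance are stored in
    the ImageDescription tag as JSON; pixel size additionally goes into the
    standard resolution tags.  Output bytes are deterministic for a fixed
    bundle.
    """
    meta = {
        "channel_names": list(bundle.channel_names),
        "pixel_size_um": bundle.pixel_size_um,
        "magnification": bundle.magnification,
        "provenance": bundle.provenance,
    }
    # planar CYX layout; resolution tags in pixels-per-centimetre
    px_per_cm = 1e4 / bundle.pixel_size_um
    tifffile.imwrite(
        str(path),
        np.moveaxis(bundle.pixels, 2, 0),
        description=json.dumps(meta, sort_keys=True),
        resolution=(px_per_cm, px_per_cm),
        resolutionunit="CENTIMETER",
        photometric="minisblack",
    )


def read_multichannel_image(path) -> ImageBundle:
    """Read a multichannel TIFF written by :func:`write_multichannel_image`.

    Files lacking the toolkit's JSON metadata are still readable: channel
    names are auto-assigned ``ch00..`` and the pixel size falls back to the
    40x default with a warning.
    """
    with tifffile.TiffFile(str(path)) as tif:
        arr = tif.asarray()
        desc = tif.pages[0].description
    if arr.ndim == 2:
        arr = arr[None]
    pixels = np.moveaxis(arr, 0, 2)

    meta = None
    if desc:
        try:
            meta = json.loads(desc)
        except (json.JSONDecodeError, TypeError):
            meta = None
    if meta and "channel_names" in meta:
        names = tuple(meta["channel_names"])
        if len(names) != pixels.shape[2]:
            raise ValueError(
                f"metadata lists {len(names)} channels but file has "
                f"{pixels.shape[2]}"
            )
        pixel_size = float(meta["pixel_size_um"])
        magnification = meta.get("magnification", "40x")
        provenance = meta.get("provenance", {})
    else:
        names = tuple(f"ch{i:02d}" for i in range(pixels.shape[2]))
        warnings.warn(
            f"{path}: no channel-name metadata; auto-assigning {names[:2]}...",
            stacklevel=2,
        )
        pixel_size = DEFAULT_PIXEL_SIZE_UM
        magnification = "40x"
        provenance = {}
        warnings.warn(
            f"{path}: no pixel-size metadata; defaulting to "
            f"{DEFAULT_PIXEL_SIZE_UM} um/px",
            stacklevel=2,
        )
    return ImageBundle(
        pixels=pixels,
        channel_names=names,
        pixel_size_um=pixel_size,
        magnification=magnification,
        provenance=provenance,
    )
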