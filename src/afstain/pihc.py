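"""Invertible pseudo-IHC rendering via Beer-Lambert absorption.

A pseudo-IHC (pIHC) image is a brightfield IHC-like RGB rendering of three
mIF channels: DAPI drives a hematoxylin-like stain (nuclei blue-purple),
the target marker drives a DAB-like stain (brown), and the residual
autofluorescence left after spectral unmixing drives a weak gray tissue
background.  Transmitted light follows the Beer-Lambert law,

    rgb = offset + white * exp(-M a),

where ``a`` are the three normalized absorbance inputs and ``M`` is a 3x3
optical-density matrix whose columns are the RGB absorption signatures of
the three stains.  The map is strictly pixel-wise and algebraically
invertible on its un-clipped range:

    a = -M^{-1} log((rgb - offset) / white).

The ``offset`` term emulates the color cast of real brightfield scans
(visible where no tissue is present).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .bundle import ImageBundle

# Standard stain-deconvolution directions (unit RGB optical densities).
_HEMATOXYLIN = np.array([0.65, 0.70, 0.29])
_DAB = np.array([0.27, 0.57, 0.78])
_BACKGROUND_AF = np.array([0.30, 0.30, 0.30])  # weak, gray


def _default_od_matrix() -> np.ndarray:
    cols = [
        _HEMATOXYLIN / np.linalg.norm(_HEMATOXYLIN),
        _DAB / np.linalg.norm(_DAB),
        _BACKGROUND_AF / np.linalg.norm(_BACKGROUND_AF) * 0.5,
    ]
    return np.stack(cols, axis=1)


@dataclass(frozen=True)
class PIHCConfig:
    """Rendering constants: OD matrix, intensity normalization, page color."""

    od_matrix: np.ndarray = field(default_factory=_default_od_matrix)
    # raw IF intensity mapped to normalized absorbance input via raw / norm,
    # clipped at 1 (per-channel saturation)
    intensity_norms: tuple[float, float, float] = (255.0, 255.0, 255.0)
    # absorbance scale: normalized input of 1 yields this much OD along the column
    od_scale: tuple[float, float, float] = (2.0, 2.0, 0.6)
    color_offset: tuple[float, float, float] = (0.02, 0.01, 0.03)
    page_white: tuple[float, float, float] = (0.96, 0.97, 0.95)
    max_condition_number: float = 1e3

    def __post_init__(self):
        m = np.asarray(self.od_matrix, dtype=float)
        if m.shape != (3, 3):
            raise ValueError("od_matrix must be 3x3")
        if np.any(m < 0):
            raise ValueError("od coefficients must be nonnegative")
        if np.linalg.cond(m) > self.max_condition_number:
            raise ValueError("od_matrix is ill-conditioned; inverse unusable")
        if any(n <= 0 for n in self.intensity_norms):
            raise ValueError("intensity_norms must be positive")
        page = np.asarray(self.page_white) + np.asarray(self.color_offset)
        if np.any(page <= 0) or np.any(page > 1.0 + 1e-9):
            raise ValueError("page_white + color_offset must lie in (0, 1]")
        object.__setattr__(self, "od_matrix", m)

    @property
    def scaled_matrix(self) -> np.ndarray:
        """OD matrix with per-column absorbance scales folded in."""
        return self.od_matrix * np.asarray(self.od_scale)[None, :]


def _as_map(x) -> np.ndarray:
    arr = x.pixels[:, :, 0] if isinstance(x, ImageBundle) else np.asarray(x, float)
    if arr.ndim != 2:
        raise ValueError(f"expected a 2-D intensity map, got shape {arr.shape}")
    return arr


def normalize_intensity(raw: np.ndarray, norm: float) -> np.ndarray:
    """Affine normalization raw/norm with clipping at 1."""
    return np.clip(np.asarray(raw, float) / norm, 0.0, 1.0)


def mif_to_pihc(dapi, target, residual_af, config: PIHCConfig) -> ImageBundle:
    """Render three mIF intensity maps into a brightfield pIHC RGB image.

    Inputs may be 2-D arrays or single-channel :class:`ImageBundle`\\ s.
    The output pixel depends only on the three input values at that pixel,
    and every RGB channel is monotonically non-increasing in every input.
    """
    maps = [_as_map(dapi), _as_map(target), _as_map(residual_af)]
    shape = maps[0].shape
    if any(m.shape != shape for m in maps):
        raise ValueError("dapi/target/residual_af shapes differ")
    if any(np.any(m < 0) for m in maps):
        raise ValueError("intensity maps must be nonnegative")

    a = np.stack(
        [normalize_intensity(m, n) for m, n in zip(maps, config.intensity_norms)],
        axis=-1,
    )  # (H, W, 3) normalized absorbance inputs
    od = a @ config.scaled_matrix.T  # (H, W, 3) RGB optical densities
    rgb = np.asarray(config.color_offset) + np.asarray(config.page_white) * np.exp(-od)
    rgb = np.clip(rgb, 0.0, 1.0)

    px = dapi.pixel_size_um if isinstance(dapi, ImageBundle) else 0.25
    return ImageBundle(
        pixels=rgb,
        channel_names=("R", "G", "B"),
        pixel_size_um=px,
        magnification="40x",
        provenance={"kind": "pihc"},
    )


def pihc_to_mif(
    rgb: ImageBundle | np.ndarray, config: PIHCConfig
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Invert a pIHC image back to (dapi, target, residual_af) intensity maps.

    Exact algebraic inverse of :func:`mif_to_pihc` on the un-clipped range.
    Pixels whose transmittance leaves the log domain (rgb - offset <= 0)
    are clamped to the domain boundary; their count is reported with a
    warning and negative recovered intensities are clipped to zero.
    """
    arr = rgb.pixels if isinstance(rgb, ImageBundle) else np.asarray(rgb, float)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValueError("pihc image must be (H, W, 3)")
    offset = np.asarray(config.color_offset)
    white = np.asarray(config.page_white)

    trans = (arr - offset) / white
    bad = trans <= 0
    n_bad = int(bad.sum())
    if n_bad:
        warnings.warn(
            f"pihc_to_mif: {n_bad} channel values outside the log domain "
            "were clamped",
            stacklevel=2,
        )
    trans = np.clip(trans, 1e-8, 1.0)
    od = -np.log(trans)
    m_inv = np.linalg.inv(config.scaled_matrix)
    a = od @ m_inv.T
    a = np.clip(a, 0.0, 1.0)
    raw = a * np.asarray(config.intensity_norms)
    return raw[:, :, 0], raw[:, :, 1], raw[:, :, 2]


def multiplex_overlay(
    pihc_set: list[ImageBundle | np.ndarray],
    pseudo_colors: list[tuple[float, float, float]],
    config: PIHCConfig,
) -> ImageBundle:
    """Overlay several single-target pIHC images into one pseudo-colored RGB.

    Each member image is converted to optical density, multiplied by its
    pseudo-color (a per-RGB-channel OD gain, so the identity color
    ``(1, 1, 1)`` passes a single image through unchanged), and the ODs
    are summed — absorbances add when stains share a section.
    """
    if len(pihc_set) == 0:
        raise ValueError("empty pihc set")
    if len(pseudo_colors) != len(pihc_set):
        raise ValueError("need one pseudo-color per image")
    offset = np.asarray(config.color_offset)
    white = np.asarray(config.page_white)
    total_od = None
    shape = None
    for img, color in zip(pihc_set, pseudo_colors):
        arr = img.pixels if isinstance(img, ImageBundle) else np.asarray(img, float)
        if shape is None:
            shape = arr.shape
        elif arr.shape != shape:
            raise ValueError("overlay members must share a shape")
        trans = np.clip((arr - offset) / white, 1e-8, 1.0)
        od = -np.log(trans) * np.asarray(color)
        total_od = od if total_od is None else total_od + od
    rgb = np.clip(offset + white * np.exp(-total_od), 0.0, 1.0)
    px = (
        pihc_set[0].pixel_size_um
        if isinstance(pihc_set[0], ImageBundle)
        else 0.25
    )
    return ImageBundle(
        pixels=rgb,
        channel_names=("R", "G", "B"),
        pixel_size_um=px,
        magnification="40x",
        provenance={"kind": "pihc_overlay", "n_members": len(pihc_set)},
    )
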