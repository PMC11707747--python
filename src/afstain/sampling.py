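"""Paired AF/stain training-patch sampling.

Patches are sampled at 40x from the same locations of a globally aligned
AF/stain pair.  The stain patch is padded by 16 px on each side relative
to the AF patch (AF 128x128x20, stain 160x160xC at full scale) so that
residual local misalignment can be absorbed by the shift-invariant
regression loss during training.  Sampling probability is uniform over
tissue, boosted inside tumor (PanCK-positive) regions and, for the PD-L1
model, inside PD-L1-positive regions; regions flagged by the warping QC
are excluded outright.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import filters, morphology

from .bundle import ImageBundle

PAD_PX = 16  # stain padding per side, at 40x


@dataclass
class PatchPair:
    af: np.ndarray  # (S, S, 20)
    stain: np.ndarray  # (S + 32, S + 32, C)
    location_xy: tuple[int, int]  # AF patch top-left, WSI coords at 40x
    weights_patch: np.ndarray | None = None  # (S + 32, S + 32)

    def __post_init__(self):
        ah, aw = self.af.shape[:2]
        sh, sw = self.stain.shape[:2]
        if (sh, sw) != (ah + 2 * PAD_PX, aw + 2 * PAD_PX):
            raise ValueError(
                f"stain footprint {sh}x{sw} must equal AF {ah}x{aw} "
                f"padded by {PAD_PX} px per side"
            )


@dataclass
class SamplingPolicy:
    tissue_mask: np.ndarray
    exclusion_mask: np.ndarray | None = None
    tumor_weight_factor: float = 3.0
    pdl1_weight_factor: float = 3.0
    seed: int = 0

    def __post_init__(self):
        if self.tumor_weight_factor < 1 or self.pdl1_weight_factor < 1:
            raise ValueError("weight factors must be >= 1")


def tissue_mask(image: ImageBundle | np.ndarray, smooth_px: float = 4.0) -> np.ndarray:
    """Foreground tissue detection: smoothed total intensity over Otsu.

    The threshold is data-relative, so the mask is invariant to global
    intensity scaling.  A blank image yields an all-false mask with a
    warning.
    """
    arr = image.pixels if isinstance(image, ImageBundle) else np.asarray(image, float)
    if arr.ndim == 2:
        arr = arr[:, :, None]
    total = ndimage.gaussian_filter(arr.sum(axis=2), smooth_px)
    if np.ptp(total) == 0:
        warnings.warn("blank image: empty tissue mask", stacklevel=2)
        return np.zeros(total.shape, dtype=bool)
    thr = filters.threshold_otsu(total)
    mask = total > thr
    mask = morphology.remove_small_objects(mask, max_size=63)
    mask = morphology.remove_small_holes(mask, max_size=63)
    return mask


def positive_region(channel: np.ndarray, smooth_px: float = 2.0) -> np.ndarray:
    """Marker-positive region for weighting: Otsu on the smoothed channel."""
    sm = ndimage.gaussian_filter(np.asarray(channel, float), smooth_px)
    if np.ptp(sm) == 0:
        return np.zeros(sm.shape, dtype=bool)
    return sm > filters.threshold_otsu(sm)


def build_sampling_weights(
    policy: SamplingPolicy,
    panck: np.ndarray | None = None,
    pdl1: np.ndarray | None = None,
) -> np.ndarray:
    """Normalized per-pixel sampling probabilities.

    Weight 1 on tissue, multiplied by the tumor factor inside the
    PanCK-positive region and by the PD-L1 factor inside the
    PD-L1-positive region; zero outside tissue and anywhere excluded.
    """
    w = policy.tissue_mask.astype(float)
    if panck is not None:
        w = w * np.where(positive_region(panck), policy.tumor_weight_factor, 1.0)
    if pdl1 is not None:
        w = w * np.where(positive_region(pdl1), policy.pdl1_weight_factor, 1.0)
    if policy.exclusion_mask is not None:
        w = w * (~policy.exclusion_mask)
    total = w.sum()
    if total == 0:
        raise ValueError("all-zero sampling weight field")
    return w / total


def sample_paired_patches(
    af_wsi: ImageBundle | np.ndarray,
    stain_wsi: ImageBundle | np.ndarray,
    n: int,
    policy: SamplingPolicy,
    panck: np.ndarray | None = None,
    pdl1: np.ndarray | None = None,
    af_patch_px: int = 128,
) -> list[PatchPair]:
    """Draw ``n`` concentric AF/stain patch pairs from a weight raster.

    Patch centers are drawn (with replacement) from the normalized weight
    raster restricted to locations where both footprints fit; the stain
    crop is the ``af_patch_px + 32`` square concentric with the AF crop.
    Deterministic per policy seed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    af = af_wsi.pixels if isinstance(af_wsi, ImageBundle) else np.asarray(af_wsi)
    st = stain_wsi.pixels if isinstance(stain_wsi, ImageBundle) else np.asarray(stain_wsi)
    if af.ndim == 2:
        af = af[:, :, None]
    if st.ndim == 2:
        st = st[:, :, None]
    h, w = af.shape[:2]
    if st.shape[:2] != (h, w):
        raise ValueError("AF and stain WSIs must be co-registered (same shape)")
    stain_px = af_patch_px + 2 * PAD_PX
    if h < stain_px or w < stain_px:
        raise ValueError(
            f"WSI {h}x{w} smaller than the {stain_px}x{stain_px} stain footprint"
        )

    weights = build_sampling_weights(policy, panck=panck, pdl1=pdl1)
    # zero out centers whose stain footprint would leave the WSI:
    # top-left sy0 = cy - half must satisfy 0 <= sy0 <= h - stain_px
    half = stain_px // 2
    valid = np.zeros((h, w), dtype=bool)
    valid[half : h - stain_px + half + 1, half : w - stain_px + half + 1] = True
    w_valid = weights * valid
    total = w_valid.sum()
    if total == 0:
        raise ValueError("no valid patch centers after footprint restriction")
    p = (w_valid / total).ravel()

    rng = np.random.default_rng(policy.seed)
    flat_idx = rng.choice(p.size, size=n, replace=True, p=p)
    pairs: list[PatchPair] = []
    a_half = af_patch_px // 2
    for idx in flat_idx:
        cy, cx = divmod(int(idx), w)
        ay0, ax0 = cy - a_half, cx - a_half
        sy0, sx0 = cy - half, cx - half
        pair = PatchPair(
            af=af[ay0 : ay0 + af_patch_px, ax0 : ax0 + af_patch_px],
            stain=st[sy0 : sy0 + stain_px, sx0 : sx0 + stain_px],
            location_xy=(ax0, ay0),
        )
        pairs.append(pair)
    return pairs
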