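"""Synthetic tissue phantoms with known ground truth.

The study's real slides (hyperspectral autofluorescence of unstained NSCLC
tissue, paired H&E and a DAPI/PanCK/PD-L1/CD3/CD8 mIF panel) are not
available, so every downstream stage — registration QC, patch sampling,
the virtual stainer, quantification and concordance — is exercised on
phantoms generated here.  A phantom is a population of disk nuclei with
per-cell marker expression, a tumor region, and a tissue region, rendered
into:

* a 20-channel autofluorescence image (per-compartment emission spectra),
* a 6-channel mIF image (DAPI, PanCK, PD-L1, CD3, CD8, residual AF),
* an RGB H&E image (Beer-Lambert absorption of hematoxylin/eosin).

The renders are co-registered by construction; controllable translations
and compact local warps emulate the tissue distortion that the alignment
QC is designed to catch.  Rendering is bitwise-deterministic for a fixed
seed.

Cell classes and markers follow the biology of the panel: PanCK marks
epithelial tumor cells, CD3 all T cells, CD8 the cytotoxic subset, and
PD-L1 may appear on both tumor and immune cells.  CD8 additionally
receives a nonspecific low-frequency background field plus speckle,
mimicking the background fluorescence that inflates CD8 false positives
in real stains.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .bundle import MIF_CHANNELS, ImageBundle

CELL_CLASSES = ("tumor", "t_cell", "cytotoxic_t_cell", "other")
MARKERS = ("PanCK", "PD-L1", "CD3", "CD8")

N_AF_CHANNELS = 20
#: emission compartments used by the AF renderer
AF_COMPARTMENTS = ("stroma", "nucleus", "tumor_cytoplasm", "immune_cytoplasm")


class PackingError(RuntimeError):
    """Requested cell counts cannot be placed at the stated density."""


@dataclass(frozen=True)
class Nucleus:
    center_xy_px: tuple[float, float]  # (x, y), pixel-centred, 0-based
    radius_px: float
    cell_class: str


@dataclass(frozen=True)
class PhantomConfig:
    width_px: int = 256
    height_px: int = 256
    pixel_size_um: float = 0.25  # 40x
    n_tumor: int = 30
    n_t_cell: int = 15
    n_cytotoxic: int = 7  # subset of n_t_cell
    n_other: int = 10
    nucleus_radius_px: float = 5.0
    nucleus_radius_sd: float = 0.8
    min_separation_factor: float = 2.4  # centre distance >= factor * radius
    tumor_fraction: float = 0.35  # of tissue area
    t_cell_in_tumor_frac: float = 0.3  # inflamed-phenotype dial
    pdl1_tumor_pos_frac: float = 0.4
    pdl1_immune_pos_frac: float = 0.25
    max_packing_density: float = 0.25  # summed nucleus area / tissue area
    seed: int = 0


@dataclass
class TissuePhantom:
    width_px: int
    height_px: int
    pixel_size_um: float
    nuclei: list[Nucleus]
    tumor_mask: np.ndarray  # bool (H, W)
    tissue_mask: np.ndarray  # bool (H, W)
    marker_expression: list[dict[str, float]]  # one dict per nucleus
    seed: int

    def class_counts(self) -> dict[str, int]:
        counts = {c: 0 for c in CELL_CLASSES}
        for nuc in self.nuclei:
            counts[nuc.cell_class] += 1
        return counts

    def validate(self) -> None:
        """Assert the ground-truth invariants hold."""
        assert len(self.nuclei) == len(self.marker_expression)
        h, w = self.tumor_mask.shape
        assert (h, w) == (self.height_px, self.width_px)
        for nuc, expr in zip(self.nuclei, self.marker_expression):
            assert all(v >= 0 for v in expr.values())
            if nuc.cell_class == "cytotoxic_t_cell":
                assert expr["CD3"] > 0 and expr["CD8"] > 0
            elif nuc.cell_class == "t_cell":
                assert expr["CD3"] > 0
            x, y = nuc.center_xy_px
            inside = self.tumor_mask[int(round(y)), int(round(x))]
            if nuc.cell_class == "tumor":
                assert inside, "tumor nucleus outside tumor mask"
                assert expr["PanCK"] > 0
            else:
                assert expr["PanCK"] == 0


def _smooth_blob_mask(
    shape: tuple[int, int],
    rng: np.random.Generator,
    target_fraction: float,
    within: np.ndarray | None = None,
    smooth_px: float = 24.0,
) -> np.ndarray:
    """Random smooth blob covering ~``target_fraction`` of ``within``."""
    noise = rng.standard_normal(shape)
    smooth = ndimage.gaussian_filter(noise, smooth_px)
    if within is not None:
        vals = smooth[within]
        if vals.size == 0:
            return np.zeros(shape, dtype=bool)
        thr = np.quantile(vals, 1.0 - target_fraction)
        mask = (smooth > thr) & within
    else:
        thr = np.quantile(smooth, 1.0 - target_fraction)
        mask = smooth > thr
    # keep the largest connected component for a contiguous region
    labels, n = ndimage.label(mask)
    if n > 1:
        sizes = ndimage.sum_labels(mask, labels, index=np.arange(1, n + 1))
        mask = labels == (1 + int(np.argmax(sizes)))
    return mask


def _place_nuclei(
    rng: np.random.Generator,
    region: np.ndarray,
    n: int,
    cfg: PhantomConfig,
    occupied: list[tuple[float, float, float]],
) -> list[tuple[float, float, float]]:
    """Rejection-sample ``n`` (x, y, r) disks inside ``region``."""
    ys, xs = np.nonzero(region)
    if n > 0 and len(ys) == 0:
        raise PackingError("placement region is empty")
    placed: list[tuple[float, float, float]] = []
    attempts = 0
    max_attempts = 8000 * max(n, 1)
    while len(placed) < n:
        if attempts > max_attempts:
            raise PackingError(
                f"could only place {len(placed)}/{n} nuclei after "
                f"{max_attempts} attempts; reduce counts or density"
            )
        attempts += 1
        k = rng.integers(len(ys))
        x, y = float(xs[k]), float(ys[k])
        r = max(2.0, rng.normal(cfg.nucleus_radius_px, cfg.nucleus_radius_sd))
        min_sep = cfg.min_separation_factor * cfg.nucleus_radius_px
        ok = all(
            (x - ox) ** 2 + (y - oy) ** 2 >= min_sep**2
            for ox, oy, _ in occupied + placed
        )
        # keep the whole disk inside the frame
        if ok and r <= x <= cfg.width_px - 1 - r and r <= y <= cfg.height_px - 1 - r:
            placed.append((x, y, r))
    return placed


def make_phantom(config: PhantomConfig) -> TissuePhantom:
    """Generate a deterministic tissue phantom from a config.

    Raises :class:`PackingError` when the requested counts cannot fit at
    the configured minimum separation.
    """
    if config.width_px < 64 or config.height_px < 64:
        raise ValueError("phantom must be at least 64x64 px")
    if config.n_cytotoxic > config.n_t_cell:
        raise ValueError("n_cytotoxic is a subset of n_t_cell")
    shape = (config.height_px, config.width_px)
    n_cells = config.n_tumor + config.n_t_cell + config.n_other
    rng = np.random.default_rng(config.seed)

    if n_cells == 0:
        return TissuePhantom(
            width_px=config.width_px,
            height_px=config.height_px,
            pixel_size_um=config.pixel_size_um,
            nuclei=[],
            tumor_mask=np.zeros(shape, dtype=bool),
            tissue_mask=np.zeros(shape, dtype=bool),
            marker_expression=[],
            seed=config.seed,
        )

    tissue = _smooth_blob_mask(shape, rng, 0.75, smooth_px=max(shape) / 8)
    tumor = (
        _smooth_blob_mask(
            shape, rng, config.tumor_fraction, within=tissue, smooth_px=max(shape) / 10
        )
        if config.n_tumor > 0 or config.tumor_fraction > 0
        else np.zeros(shape, dtype=bool)
    )

    # density feasibility check before attempting placement
    mean_area = np.pi * config.nucleus_radius_px**2
    tissue_area = max(int(tissue.sum()), 1)
    if n_cells * mean_area / tissue_area > config.max_packing_density:
        raise PackingError(
            f"requested {n_cells} cells exceed max packing density "
            f"{config.max_packing_density}"
        )

    stroma = tissue & ~tumor
    nuclei: list[Nucleus] = []
    expression: list[dict[str, float]] = []
    occupied: list[tuple[float, float, float]] = []

    def lognorm(mean: float) -> float:
        return float(mean * rng.lognormal(0.0, 0.25))

    # tumor cells inside the tumor mask
    tumor_disks = _place_nuclei(rng, tumor, config.n_tumor, config, occupied)
    occupied += tumor_disks
    for x, y, r in tumor_disks:
        pdl1 = lognorm(80.0) if rng.random() < config.pdl1_tumor_pos_frac else 0.0
        nuclei.append(Nucleus((x, y), r, "tumor"))
        expression.append(
            {"PanCK": lognorm(120.0), "PD-L1": pdl1, "CD3": 0.0, "CD8": 0.0}
        )

    # T cells: a fraction infiltrate the tumor, the rest sit in stroma
    n_infil = int(round(config.t_cell_in_tumor_frac * config.n_t_cell))
    n_infil = min(n_infil, config.n_t_cell) if tumor.any() else 0
    t_disks = _place_nuclei(rng, tumor if n_infil else stroma, n_infil, config, occupied)
    occupied += t_disks
    more = _place_nuclei(rng, stroma, config.n_t_cell - n_infil, config, occupied)
    occupied += more
    t_disks += more
    cytotoxic_idx = set(
        rng.choice(config.n_t_cell, size=config.n_cytotoxic, replace=False).tolist()
        if config.n_t_cell
        else []
    )
    for i, (x, y, r) in enumerate(t_disks):
        cyto = i in cytotoxic_idx
        pdl1 = lognorm(50.0) if rng.random() < config.pdl1_immune_pos_frac else 0.0
        nuclei.append(Nucleus((x, y), r, "cytotoxic_t_cell" if cyto else "t_cell"))
        expression.append(
            {
                "PanCK": 0.0,
                "PD-L1": pdl1,
                "CD3": lognorm(100.0),
                "CD8": lognorm(90.0) if cyto else 0.0,
            }
        )

    other_disks = _place_nuclei(rng, stroma, config.n_other, config, occupied)
    for x, y, r in other_disks:
        nuclei.append(Nucleus((x, y), r, "other"))
        expression.append({"PanCK": 0.0, "PD-L1": 0.0, "CD3": 0.0, "CD8": 0.0})

    phantom = TissuePhantom(
        width_px=config.width_px,
        height_px=config.height_px,
        pixel_size_um=config.pixel_size_um,
        nuclei=nuclei,
        tumor_mask=tumor,
        tissue_mask=tissue,
        marker_expression=expression,
        seed=config.seed,
    )
    phantom.validate()
    return phantom


# ---------------------------------------------------------------------------
# rendering


def _default_af_spectra(rng: np.random.Generator | None = None) -> np.ndarray:
    """(4, 20) per-compartment emission spectra: smooth, distinct bumps.

    The study gives no quantitative AF spectra per tissue class, so these
    are free parameters: Gaussian bumps centred at different channels so
    that compartments are separable by linear unmixing.
    """
    centers = [3.0, 8.0, 13.0, 17.0]
    widths = [2.5, 2.0, 2.5, 2.0]
    ch = np.arange(N_AF_CHANNELS, dtype=float)
    spectra = np.stack(
        [np.exp(-0.5 * ((ch - c) / w) ** 2) for c, w in zip(centers, widths)]
    )
    return spectra / spectra.sum(axis=1, keepdims=True) * N_AF_CHANNELS


@dataclass(frozen=True)
class RenderConfig:
    pixel_size_um: float = 0.25
    background_af_level: float = 0.0
    cd8_nonspecific_amplitude: float = 0.0
    noise_sd: float = 0.0
    psf_sigma_px: float = 1.0
    dapi_amplitude: float = 200.0
    panck_region_level: float = 60.0  # membranous PanCK across the tumor region
    residual_af_factor: float = 0.3
    af_channel_spectra: np.ndarray = field(default_factory=_default_af_spectra)
    seed: int = 0

    def __post_init__(self):
        for name in (
            "background_af_level",
            "cd8_nonspecific_amplitude",
            "noise_sd",
            "psf_sigma_px",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        spectra = np.asarray(self.af_channel_spectra, dtype=float)
        if spectra.ndim != 2 or spectra.shape[1] != N_AF_CHANNELS:
            raise ValueError(
                f"af_channel_spectra must be (n_classes, {N_AF_CHANNELS})"
            )
        if not np.all(spectra.sum(axis=1) > 0):
            raise ValueError("each spectrum must have positive total emission")
        object.__setattr__(self, "af_channel_spectra", spectra)


def _check_pixel_size(phantom: TissuePhantom, config: RenderConfig) -> None:
    if not np.isclose(phantom.pixel_size_um, config.pixel_size_um):
        raise ValueError(
            f"phantom pixel size {phantom.pixel_size_um} != "
            f"render config pixel size {config.pixel_size_um}"
        )


def _disk_stamp(
    canvas: np.ndarray, x: float, y: float, r: float, amplitude: float
) -> None:
    """Add an anti-aliased disk of given amplitude in place."""
    h, w = canvas.shape
    x0, x1 = max(int(x - r - 2), 0), min(int(x + r + 3), w)
    y0, y1 = max(int(y - r - 2), 0), min(int(y + r + 3), h)
    yy, xx = np.mgrid[y0:y1, x0:x1]
    d = np.sqrt((xx - x) ** 2 + (yy - y) ** 2)
    # soft 1-px edge so that sub-pixel centres render smoothly
    canvas[y0:y1, x0:x1] += amplitude * np.clip(r + 0.5 - d, 0.0, 1.0)


def _compartment_maps(phantom: TissuePhantom) -> dict[str, np.ndarray]:
    """Unit-amplitude occupancy maps for the AF emission compartments."""
    shape = (phantom.height_px, phantom.width_px)
    nucleus = np.zeros(shape)
    tumor_cyto = np.zeros(shape)
    immune_cyto = np.zeros(shape)
    for nuc in phantom.nuclei:
        x, y = nuc.center_xy_px
        _disk_stamp(nucleus, x, y, nuc.radius_px, 1.0)
        cyto = tumor_cyto if nuc.cell_class == "tumor" else immune_cyto
        _disk_stamp(cyto, x, y, nuc.radius_px * 1.8, 0.6)
    stroma = phantom.tissue_mask.astype(float)
    return {
        "stroma": stroma,
        "nucleus": np.clip(nucleus, 0, 1.5),
        "tumor_cytoplasm": np.clip(tumor_cyto, 0, 1.5),
        "immune_cytoplasm": np.clip(immune_cyto, 0, 1.5),
    }


def render_mif(phantom: TissuePhantom, config: RenderConfig) -> ImageBundle:
    """Render the 6-channel mIF image (DAPI, PanCK, PD-L1, CD3, CD8, residualAF)."""
    _check_pixel_size(phantom, config)
    shape = (phantom.height_px, phantom.width_px)
    rng = np.random.default_rng(config.seed)

    dapi = np.zeros(shape)
    marker_maps = {m: np.zeros(shape) for m in MARKERS}
    for nuc, expr in zip(phantom.nuclei, phantom.marker_expression):
        x, y = nuc.center_xy_px
        _disk_stamp(dapi, x, y, nuc.radius_px, config.dapi_amplitude)
        for m in MARKERS:
            if expr[m] > 0:
                # membrane/cytoplasmic markers extend beyond the nucleus
                _disk_stamp(marker_maps[m], x, y, nuc.radius_px * 1.6, expr[m])
    # PanCK is membranous across the whole epithelial tumor region
    marker_maps["PanCK"] += config.panck_region_level * phantom.tumor_mask

    if config.psf_sigma_px > 0:
        dapi = ndimage.gaussian_filter(dapi, config.psf_sigma_px)
        for m in MARKERS:
            marker_maps[m] = ndimage.gaussian_filter(marker_maps[m], config.psf_sigma_px)

    # nonspecific CD8 background: smooth low-frequency field plus speckle
    if config.cd8_nonspecific_amplitude > 0:
        low = ndimage.gaussian_filter(rng.standard_normal(shape), 16.0)
        low = (low - low.min()) / max(np.ptp(low), 1e-12)
        speckle = (rng.random(shape) < 0.002) * 3.0
        marker_maps["CD8"] = (
            marker_maps["CD8"]
            + config.cd8_nonspecific_amplitude * (low + speckle) * phantom.tissue_mask
        )

    emission = sum(_compartment_maps(phantom).values())
    residual_af = config.residual_af_factor * emission

    channels = [dapi, marker_maps["PanCK"], marker_maps["PD-L1"],
                marker_maps["CD3"], marker_maps["CD8"], residual_af]
    img = np.stack(channels, axis=-1)
    if config.noise_sd > 0:
        img = img + rng.normal(0.0, config.noise_sd, img.shape)
        img = np.clip(img, 0.0, None)
    return ImageBundle(
        pixels=img,
        channel_names=MIF_CHANNELS,
        pixel_size_um=config.pixel_size_um,
        magnification="40x",
        provenance={"seed": config.seed, "kind": "phantom_mif",
                    "phantom_seed": phantom.seed},
    )


def render_af(phantom: TissuePhantom, config: RenderConfig) -> ImageBundle:
    """Render the 20-channel hyperspectral autofluorescence image."""
    _check_pixel_size(phantom, config)
    shape = (phantom.height_px, phantom.width_px)
    rng = np.random.default_rng(config.seed + 1)
    spectra = config.af_channel_spectra
    maps = _compartment_maps(phantom)
    img = np.zeros(shape + (N_AF_CHANNELS,))
    for i, comp in enumerate(AF_COMPARTMENTS[: spectra.shape[0]]):
        img += maps[comp][:, :, None] * spectra[i][None, None, :]
    if config.psf_sigma_px > 0:
        img = ndimage.gaussian_filter(img, (config.psf_sigma_px, config.psf_sigma_px, 0))
    img += config.background_af_level
    if config.noise_sd > 0:
        img = np.clip(img + rng.normal(0.0, config.noise_sd, img.shape), 0.0, None)
    return ImageBundle(
        pixels=img,
        channel_names=tuple(f"AF{i:02d}" for i in range(N_AF_CHANNELS)),
        pixel_size_um=config.pixel_size_um,
        magnification="40x",
        provenance={"seed": config.seed, "kind": "phantom_af",
                    "phantom_seed": phantom.seed},
    )


# H&E optical densities per unit dye amount (RGB rows): hematoxylin stains
# nuclei blue-purple, eosin stains cytoplasm/stroma pink.
_HEMATOXYLIN_OD = np.array([0.65, 0.70, 0.29])
_EOSIN_OD = np.array([0.07, 0.99, 0.11])


def render_he(phantom: TissuePhantom, config: RenderConfig) -> ImageBundle:
    """Render an RGB H&E image: white page, eosin stroma, hematoxylin nuclei."""
    _check_pixel_size(phantom, config)
    maps = _compartment_maps(phantom)
    hema = 1.6 * maps["nucleus"]
    eosin = 0.45 * (
        maps["stroma"] * 0.8 + maps["tumor_cytoplasm"] + maps["immune_cytoplasm"]
    )
    if config.psf_sigma_px > 0:
        hema = ndimage.gaussian_filter(hema, config.psf_sigma_px)
        eosin = ndimage.gaussian_filter(eosin, config.psf_sigma_px)
    od = hema[:, :, None] * _HEMATOXYLIN_OD + eosin[:, :, None] * _EOSIN_OD
    rgb = np.exp(-od)
    if config.noise_sd > 0:
        rng = np.random.default_rng(config.seed + 2)
        rgb = np.clip(rgb + rng.normal(0.0, config.noise_sd / 255.0, rgb.shape), 0, 1)
    return ImageBundle(
        pixels=rgb,
        channel_names=("R", "G", "B"),
        pixel_size_um=config.pixel_size_um,
        magnification="40x",
        provenance={"seed": config.seed, "kind": "phantom_he",
                    "phantom_seed": phantom.seed},
    )


# ---------------------------------------------------------------------------
# warping fixtures


@dataclass(frozen=True)
class LocalWarp:
    center_xy_px: tuple[float, float]
    radius_px: float
    displacement_xy_px: tuple[float, float]


@dataclass(frozen=True)
class WarpSpec:
    """Pure translation plus optional compactly-supported local warps."""

    translation_xy_px: tuple[float, float] = (0.0, 0.0)
    local_warps: tuple[LocalWarp, ...] = ()


def apply_warp(image: ImageBundle, warp: WarpSpec, order: int = 1) -> ImageBundle:
    """Warp an image: sub-pixel translation and/or local displacements.

    The local displacement field is a raised-cosine bump that is exactly
    zero at and beyond each warp's radius, so pixels outside the support
    are bitwise unchanged.
    """
    h, w, c = image.shape
    tx, ty = warp.translation_xy_px
    if abs(tx) >= w or abs(ty) >= h:
        raise ValueError("translation exceeds image extent")
    for lw in warp.local_warps:
        dx, dy = lw.displacement_xy_px
        if abs(dx) >= w or abs(dy) >= h:
            raise ValueError("local displacement exceeds image extent")

    if not warp.local_warps and tx == 0 and ty == 0:
        return ImageBundle(
            pixels=image.pixels.copy(),
            channel_names=image.channel_names,
            pixel_size_um=image.pixel_size_um,
            magnification=image.magnification,
            provenance=dict(image.provenance),
        )

    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    # output pixel (x, y) samples the source at (x - dx, y - dy):
    # content moves BY the stated vector
    src_x = xx - tx
    src_y = yy - ty
    for lw in warp.local_warps:
        cx, cy = lw.center_xy_px
        dx, dy = lw.displacement_xy_px
        d = np.sqrt((xx - cx) ** 2 + (yy - cy) ** 2)
        # flat top: the full displacement applies within half the radius,
        # then tapers smoothly to exactly zero at the support boundary
        ramp = 0.5 * (1 + np.cos(np.pi * (2.0 * d / lw.radius_px - 1.0)))
        bump = np.where(d <= lw.radius_px / 2.0, 1.0,
                        np.where(d < lw.radius_px, ramp, 0.0))
        src_x = src_x - dx * bump
        src_y = src_y - dy * bump

    out = np.empty_like(image.pixels)
    for k in range(c):
        out[:, :, k] = ndimage.map_coordinates(
            image.pixels[:, :, k].astype(float),
            [src_y, src_x],
            order=order,
            mode="nearest",
        )
    return ImageBundle(
        pixels=out,
        channel_names=image.channel_names,
        pixel_size_um=image.pixel_size_um,
        magnification=image.magnification,
        provenance={**image.provenance, "warp": {
            "translation_xy_px": list(warp.translation_xy_px),
            "n_local_warps": len(warp.local_warps)}},
    )
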