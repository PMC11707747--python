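"""Global affine alignment and local tissue-warping QC.

Autofluorescence and stained images of the same slide come from different
scanners and must be registered before paired patches can be sampled.
Two stages are implemented:

1. **Global affine alignment** — an iterative multi-resolution search for
   the 2x3 affine transform that minimizes a gradient-based multimodal
   distance between the pair.  Pairs that cannot be aligned are flagged
   and excluded.

2. **Local warping QC** — staining (mIF in particular, with its harsher
   antigen retrieval) can fold or tear tissue locally even after a good
   global alignment.  Each local patch pair is converted to grayscale,
   normalized to [0, 1], and a pure-translation alignment is run with the
   Powell method over a 3-level Gaussian pyramid, using the normalized
   gradient field (NGF) or normalized total gradient (NTG) as the
   distance.  The magnitude of the recovered translation, expressed in
   micrometres at the 10x reference (1.0 um/px), is the alignment score;
   a region scoring strictly above 6 um is considered misaligned and
   excluded from sampling.

The NGF distance follows the standard edge-orientation definition:

    d(a, b) = sum_px [ 1 - ( grad a . grad b )^2
                           / (|grad a|_eps^2 |grad b|_eps^2) ],

with |u|_eps^2 = |u|^2 + eps^2; eps defaults to 0.01 of the intensity
range.  Squaring makes the alignment insensitive to contrast inversion.
NTG is sum|grad(a - b)| / (sum|grad a| + sum|grad b|).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import interpolate, ndimage, optimize

from .bundle import ImageBundle

TEN_X_UM_PER_PX = 1.0  # the 10x reference pixel size


# ---------------------------------------------------------------------------
# grayscale + distance metrics


def to_grayscale(image: ImageBundle | np.ndarray) -> np.ndarray:
    """Grayscale in [0, 1]: luminance for RGB, channel mean otherwise."""
    if isinstance(image, ImageBundle):
        arr = image.pixels
        names = image.channel_names
    else:
        arr = np.asarray(image, dtype=float)
        names = None
        if arr.ndim == 2:
            arr = arr[:, :, None]
    if arr.shape[2] == 3 and (names is None or tuple(names) == ("R", "G", "B")):
        gray = arr @ np.array([0.2126, 0.7152, 0.0722])
    else:
        gray = arr.mean(axis=2)
    lo, hi = float(gray.min()), float(gray.max())
    if hi > lo:
        gray = (gray - lo) / (hi - lo)
    else:
        gray = np.zeros_like(gray)
    return gray


def _gradients(a: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    gy, gx = np.gradient(a)
    return gx, gy


def gradient_field_distance(
    a: np.ndarray, b: np.ndarray, metric: str = "NGF", eps: float = 0.01
) -> float:
    """Gradient-based multimodal distance between two [0, 1] patches.

    NGF is symmetric and insensitive to affine intensity rescaling of
    either input (including contrast inversion); both metrics are 0 for
    perfectly gradient-aligned images.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("patches must have equal shape")
    metric = metric.upper()
    if metric == "NGF":
        if eps <= 0 and (np.ptp(a) == 0 or np.ptp(b) == 0):
            raise ZeroDivisionError("constant patch with eps=0")
        ax, ay = _gradients(a)
        bx, by = _gradients(b)
        # edge-orientation alignment, squared -> sign (contrast) insensitive
        inner = ax * bx + ay * by
        na2 = ax**2 + ay**2 + eps**2
        nb2 = bx**2 + by**2 + eps**2
        return float(np.sum(1.0 - inner**2 / (na2 * nb2)))
    if metric == "NTG":
        dx, dy = _gradients(a - b)
        ax, ay = _gradients(a)
        bx, by = _gradients(b)
        denom = np.sum(np.hypot(ax, ay)) + np.sum(np.hypot(bx, by))
        if denom == 0:
            if eps <= 0:
                raise ZeroDivisionError("constant patches with eps=0")
            return 0.0
        return float(np.sum(np.hypot(dx, dy)) / denom)
    raise ValueError(f"unknown metric {metric!r}; use 'NGF' or 'NTG'")


def _alignment_residual(a: np.ndarray, b: np.ndarray, eps: float = 0.01) -> float:
    """Mean NGF term over edge pixels only; convergence heuristic.

    Flat regions score a full NGF term by construction (no orientation to
    align), so the failure check averages only where either image has
    appreciable gradient.  Near 0 for well-aligned pairs, near 1 for
    unrelated content.
    """
    ax, ay = _gradients(a)
    bx, by = _gradients(b)
    ga = np.hypot(ax, ay)
    gb = np.hypot(bx, by)
    thr = 0.1 * max(np.percentile(ga, 95), np.percentile(gb, 95), 1e-12)
    mask = (ga > thr) | (gb > thr)
    if not mask.any():
        return 0.0
    inner = ax * bx + ay * by
    term = 1.0 - inner**2 / ((ga**2 + eps**2) * (gb**2 + eps**2))
    return float(term[mask].mean())


# ---------------------------------------------------------------------------
# global affine


@dataclass
class AffineTransform:
    """2x3 matrix mapping moving-image coordinates onto the fixed image."""

    matrix: np.ndarray  # 2x3, rows (y, x): [A | t]
    source_pixel_size_um: float = 0.25
    target_pixel_size_um: float = 0.25
    residual: float = float("nan")  # mean per-pixel NGF after alignment
    converged: bool = True

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float).reshape(2, 3)
        if abs(np.linalg.det(self.matrix[:, :2])) < 1e-12:
            raise ValueError("linear part is singular")

    def apply_to_points(self, pts_yx: np.ndarray) -> np.ndarray:
        pts = np.asarray(pts_yx, dtype=float)
        return pts @ self.matrix[:, :2].T + self.matrix[:, 2]


@dataclass(frozen=True)
class AffineConfig:
    metric: str = "NGF"
    eps: float = 0.01
    pyramid_levels: int = 3
    max_iter: int = 200
    fail_residual: float = 0.3  # edge-pixel NGF residual above this -> failure



def _warp_affine(moving: np.ndarray, params: np.ndarray, shape) -> np.ndarray:
    """Resample `moving` on the fixed grid under params=(a11,a12,a21,a22,ty,tx)."""
    mat = np.array([[params[0], params[1]], [params[2], params[3]]])
    off = np.array([params[4], params[5]])
    return ndimage.affine_transform(
        moving, mat, offset=off, output_shape=shape, order=1, mode="nearest"
    )


def global_affine_align(
    moving: ImageBundle | np.ndarray,
    fixed: ImageBundle | np.ndarray,
    config: AffineConfig = AffineConfig(),
) -> AffineTransform:
    """Iterative multi-resolution affine registration of an image pair.

    Minimizes the configured gradient distance over the 6 affine
    parameters, coarse to fine over a Gaussian pyramid, with Powell at
    each level.  Deterministic for a fixed config.  Non-convergence
    (residual similarity above ``fail_residual``) is reported via
    ``converged=False`` so the pair can be excluded.
    """
    mov_px = moving.pixel_size_um if isinstance(moving, ImageBundle) else 0.25
    fix_px = fixed.pixel_size_um if isinstance(fixed, ImageBundle) else 0.25
    g_mov = to_grayscale(moving)
    g_fix = to_grayscale(fixed)
    if g_mov.size == 0 or g_fix.size == 0:
        raise ValueError("empty image")

    # pyramid, coarse -> fine
    levels = []
    m, f = g_mov, g_fix
    for _ in range(config.pyramid_levels):
        levels.append((m, f))
        m = ndimage.zoom(ndimage.gaussian_filter(m, 1.0), 0.5, order=1)
        f = ndimage.zoom(ndimage.gaussian_filter(f, 1.0), 0.5, order=1)
    levels = levels[::-1]

    params = np.array([1.0, 0.0, 0.0, 1.0, 0.0, 0.0])
    for li, (mlev, flev) in enumerate(levels):
        scale = 2.0 ** (len(levels) - 1 - li)

        margin = max(2, min(flev.shape) // 16)  # ignore resampling borders
        fcrop = _crop_margin(flev, margin)
        fgx, fgy = _gradients(fcrop)
        gmag = np.hypot(fgx, fgy)
        # score edge pixels of the fixed image only: weak-gradient pixels
        # carry orientation noise that creates spurious shallow minima
        edge_mask = gmag > 0.1 * max(np.percentile(gmag, 95), 1e-12)
        fnx = np.where(edge_mask, fgx / np.maximum(gmag, 1e-12), 0.0)
        fny = np.where(edge_mask, fgy / np.maximum(gmag, 1e-12), 0.0)

        def cost(p):
            warped = _crop_margin(_warp_affine(mlev, p, flev.shape), margin)
            if config.metric.upper() == "NGF":
                # pure orientation alignment: magnitude-free, so the
                # optimum cannot be gamed by steepening gradients
                wgx, wgy = _gradients(warped)
                inner = wgx * fnx + wgy * fny
                wm2 = wgx**2 + wgy**2
                term = 1.0 - inner**2 / np.maximum(wm2, 1e-24)
                return float(term[edge_mask].sum())
            return gradient_field_distance(warped, fcrop, config.metric, config.eps)

        res = optimize.minimize(
            cost,
            params,
            method="Powell",
            options={"maxiter": config.max_iter, "xtol": 1e-4, "ftol": 1e-6},
        )
        # keep the warm start unless Powell strictly improved on it, so an
        # already-optimal start (identical images) is returned unchanged
        if res.fun < cost(params) - 1e-10:
            params = res.x
        if li < len(levels) - 1:
            # translations double when moving to the next finer level
            params = params.copy()
            params[4] *= 2.0
            params[5] *= 2.0
        del scale

    final = _warp_affine(levels[-1][0], params, levels[-1][1].shape)
    residual = _alignment_residual(final, levels[-1][1], config.eps)
    converged = bool(residual < config.fail_residual)

    # matrix maps fixed coords -> moving coords (the resampling convention);
    # report the moving->fixed transform, i.e. the inverse
    lin = np.array([[params[0], params[1]], [params[2], params[3]]])
    off = np.array([params[4], params[5]])
    inv_lin = np.linalg.inv(lin)
    inv_off = -inv_lin @ off
    matrix = np.hstack([inv_lin, inv_off[:, None]])
    return AffineTransform(
        matrix=matrix,
        source_pixel_size_um=mov_px,
        target_pixel_size_um=fix_px,
        residual=residual,
        converged=converged,
    )


# ---------------------------------------------------------------------------
# local translational score


@dataclass
class AlignmentScore:
    translation_vector_px: tuple[float, float]  # (tx, ty) at the input scale
    score_um_at_10x: float
    metric: str
    converged: bool
    pixel_size_um: float

    @property
    def magnitude_px(self) -> float:
        return float(np.hypot(*self.translation_vector_px))


@dataclass(frozen=True)
class QCDecision:
    misaligned: bool
    threshold_um: float = 6.0
    score_um_at_10x: float = 0.0


def qc_decision(score: AlignmentScore, threshold_um: float = 6.0) -> QCDecision:
    """Strict rule: misaligned iff score exceeds the threshold (6 um at 10x)."""
    return QCDecision(
        misaligned=bool(score.score_um_at_10x > threshold_um),
        threshold_um=threshold_um,
        score_um_at_10x=score.score_um_at_10x,
    )


def _crop_margin(a: np.ndarray, margin: int) -> np.ndarray:
    return a[margin:-margin or None, margin:-margin or None]


def _integer_shift_landscape(
    ga: np.ndarray,
    gb: np.ndarray,
    ks_y: np.ndarray,
    ks_x: np.ndarray,
    margin: int,
    metric: str,
    eps: float,
) -> np.ndarray:
    """Gradient distance at exact integer shifts of ``gb`` (pure slicing).

    Integer shifts need no resampling, so the landscape carries no
    interpolation bias; subpixel estimates come from fitting it.
    """
    h, w = ga.shape
    ay0, ay1, ax0, ax1 = margin, h - margin, margin, w - margin
    a_win = ga[ay0:ay1, ax0:ax1]
    D = np.empty((len(ks_y), len(ks_x)))
    for iy, ky in enumerate(ks_y):
        for ix, kx in enumerate(ks_x):
            b_win = gb[ay0 - ky : ay1 - ky, ax0 - kx : ax1 - kx]
            D[iy, ix] = gradient_field_distance(a_win, b_win, metric, eps)
    return D


def local_translation_score(
    a: ImageBundle | np.ndarray,
    b: ImageBundle | np.ndarray,
    metric: str = "NGF",
    pyramid_levels: int = 3,
    pixel_size_um: float | None = None,
    eps: float = 0.01,
    max_shift_px: float = 32.0,
) -> AlignmentScore:
    """Translational alignment score of a patch pair, in um at 10x.

    Coarse-to-fine over a Gaussian pyramid with the stated number of
    levels: at each level the gradient distance is evaluated on exact
    integer shifts (no resampling, hence no interpolation bias), and at
    the finest level the integer minimum is refined to sub-pixel
    precision by running Powell on a bicubic fit of the local landscape.
    The translation magnitude, converted through the pixel size, is the
    score; it is reported at 0.1 um resolution, which is coarser than
    the estimator's observed error (a few hundredths of a pixel) so that
    threshold decisions are stable.  Deterministic.
    """
    if pixel_size_um is None:
        if isinstance(a, ImageBundle):
            pixel_size_um = a.pixel_size_um
        else:
            raise ValueError("pixel_size_um required for raw arrays")
    ga, gb = to_grayscale(a), to_grayscale(b)
    if ga.shape != gb.shape:
        raise ValueError("patches must have equal shape")
    if min(ga.shape) < 32:
        raise ValueError("patches must be at least 32 px")

    pyr = []
    pa, pb = ga, gb
    for _ in range(pyramid_levels):
        pyr.append((pa, pb))
        pa = ndimage.zoom(ndimage.gaussian_filter(pa, 1.0), 0.5, order=1)
        pb = ndimage.zoom(ndimage.gaussian_filter(pb, 1.0), 0.5, order=1)
    pyr = pyr[::-1]

    t = np.zeros(2, dtype=int)  # (tx, ty) applied to b
    converged = True
    D = None
    ks_x = ks_y = None
    for li, (la, lb) in enumerate(pyr):
        level_scale = 2.0 ** (len(pyr) - 1 - li)
        # cap the search window so the scored interior keeps at least half
        # the patch: a too-small interior biases the recovered magnitude
        bound = int(np.ceil(min(max_shift_px / level_scale, min(la.shape) / 4)))
        if li == 0:
            ks_y = np.arange(-bound, bound + 1)
            ks_x = np.arange(-bound, bound + 1)
        else:  # refine around the warm start from the coarser level
            ks_y = np.arange(t[1] - 3, t[1] + 4)
            ks_x = np.arange(t[0] - 3, t[0] + 4)
        # the margin only needs to cover the offsets actually searched:
        # a larger margin shrinks the scored interior and adds noise
        max_k = int(max(np.abs(ks_y).max(), np.abs(ks_x).max(), 1))
        margin = min(max_k + 2, (min(la.shape) - 8) // 2)
        if margin < 1:
            margin = 1
        # clip offsets so every slice stays inside the level image
        ks_y = ks_y[(ks_y > -margin) & (ks_y < margin)]
        ks_x = ks_x[(ks_x > -margin) & (ks_x < margin)]
        if ks_y.size == 0 or ks_x.size == 0:
            converged = False
            break
        D = _integer_shift_landscape(la, lb, ks_y, ks_x, margin, metric, eps)
        iy, ix = np.unravel_index(int(np.argmin(D)), D.shape)
        t = np.array([ks_x[ix], ks_y[iy]])
        if li < len(pyr) - 1:
            t = t * 2

    if converged and D is not None and min(D.shape) >= 4:
        # sub-pixel refinement: Powell on a bicubic fit of the landscape
        # around the integer minimum (ties and flat basins stay integer)
        spline = interpolate.RectBivariateSpline(ks_y, ks_x, D, kx=3, ky=3)
        res = optimize.minimize(
            lambda p: float(spline(p[1], p[0])[0, 0]),
            np.asarray(t, dtype=float),
            method="Powell",
            bounds=[(ks_x[0], ks_x[-1]), (ks_y[0], ks_y[-1])],
            options={"xtol": 1e-4, "ftol": 1e-12, "maxiter": 200},
        )
        refined = res.x
        if np.all(np.abs(refined - t) <= 1.0):
            t = refined

    if not converged:
        return AlignmentScore(
            translation_vector_px=(float("inf"), float("inf")),
            score_um_at_10x=float("inf"),
            metric=metric,
            converged=False,
            pixel_size_um=pixel_size_um,
        )
    # um is magnification-free; quantize to the method resolution (0.1 um)
    score_um = round(float(np.hypot(*t)) * pixel_size_um, 1)
    return AlignmentScore(
        translation_vector_px=(float(t[0]), float(t[1])),
        score_um_at_10x=score_um,
        metric=metric,
        converged=True,
        pixel_size_um=pixel_size_um,
    )


# ---------------------------------------------------------------------------
# exclusion mask


@dataclass(frozen=True)
class GridSpec:
    tile_px: int = 256  # at the image's own resolution
    overlap: float = 0.5


def qc_exclusion_mask(
    af_wsi: ImageBundle | np.ndarray,
    stain_wsi: ImageBundle | np.ndarray,
    grid_spec: GridSpec = GridSpec(),
    threshold_um: float = 6.0,
    metric: str = "NGF",
    pixel_size_um: float | None = None,
) -> tuple[np.ndarray, list[dict]]:
    """Tile a globally aligned pair, score each tile, flag warped regions.

    Returns a full-resolution boolean mask (True = excluded) where a pixel
    is flagged if **any** covering tile scored strictly above the
    threshold, plus the per-tile score records.
    """
    if pixel_size_um is None:
        if isinstance(af_wsi, ImageBundle):
            pixel_size_um = af_wsi.pixel_size_um
        else:
            raise ValueError("pixel_size_um required for raw arrays")
    ga, gb = to_grayscale(af_wsi), to_grayscale(stain_wsi)
    if ga.shape != gb.shape:
        raise ValueError("aligned pair must share a shape")
    h, w = ga.shape
    tile = min(grid_spec.tile_px, h, w)
    if tile < 32:
        raise ValueError("empty or too-small overlap region")
    step = max(1, int(round(tile * (1.0 - grid_spec.overlap))))

    mask = np.zeros((h, w), dtype=bool)
    records: list[dict] = []
    ys = list(range(0, max(h - tile, 0) + 1, step))
    xs = list(range(0, max(w - tile, 0) + 1, step))
    if ys[-1] != h - tile:
        ys.append(h - tile)
    if xs[-1] != w - tile:
        xs.append(w - tile)
    for y0 in ys:
        for x0 in xs:
            pa = ga[y0 : y0 + tile, x0 : x0 + tile]
            pb = gb[y0 : y0 + tile, x0 : x0 + tile]
            score = local_translation_score(
                pa, pb, metric=metric, pixel_size_um=pixel_size_um,
                max_shift_px=tile / 8,
            )
            flagged = qc_decision(score, threshold_um).misaligned
            records.append(
                {
                    "y0": y0,
                    "x0": x0,
                    "tile_px": tile,
                    "score_um_at_10x": score.score_um_at_10x,
                    "flagged": flagged,
                }
            )
            if flagged:
                mask[y0 : y0 + tile, x0 : x0 + tile] = True
    return mask, records
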