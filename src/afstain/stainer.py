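"""The virtual stainer: losses, training loop, WSI inference, validation.

A pix2pix-style conditional GAN translates 20-channel autofluorescence
patches into stain patches (H&E RGB, or pIHC for the mIF targets).  The
pieces implemented here:

* **Pixel weighting** (intensity-based): w = max(1, log(min(i, imax))),
  where i is the IF intensity of the target stain — high-expression
  pixels matter more for heterogeneous, low-prevalence targets.  For CD8
  every pixel with intensity below 15 gets weight 1, suppressing label
  noise from background and nonspecific fluorescence.
* **Shift-invariant regression loss**: the stain target carries a 16-px
  pad per side; the L1+L2 error is minimized over all integer crop
  offsets so residual local misalignment of the global registration does
  not penalize a correct prediction.
* **Rotational consistency loss**: the generator should commute with
  90-degree rotations; orientation biases are penalized.
* **Adversarial losses**: one conditional discriminator (sees AF +
  stain) and two unconditional discriminators at full and half scale, in
  a non-saturating minimax game.
* **Training**: Glorot init, Adam, step-keyed learning-rate and
  loss-weight schedules, periodic validation by L1 and a Fréchet feature
  distance, checkpointing, and rank-sum checkpoint selection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg as sla
from scipy import stats

from .nn import Adam, PatchDiscriminator, Tensor, UNetGenerator
from .nn import autodiff as ad

# ---------------------------------------------------------------------------
# pixel weighting


@dataclass(frozen=True)
class WeightingScheme:
    """Intensity-based pixel weighting for the regression loss.

    ``clamp_below`` zeroes out the log boost below a raw-intensity floor
    (15 for CD8); ``log_base`` selects natural or base-10 logs.
    """

    imax: float = 255.0
    clamp_below: float = 0.0
    log_base: str = "e"  # "e" or "10"

    def __post_init__(self):
        if self.imax <= 1:
            raise ValueError("imax must exceed 1; the weighting degenerates")
        if self.clamp_below < 0:
            raise ValueError("clamp_below must be nonnegative")
        if self.log_base not in ("e", "10"):
            raise ValueError("log_base must be 'e' or '10'")


CD8_WEIGHTING = WeightingScheme(imax=255.0, clamp_below=15.0)


def pixel_weight(i, scheme: WeightingScheme):
    """w = max(1, log(min(i, imax))), forced to 1 below ``clamp_below``.

    Element-wise over arrays; always >= 1, non-decreasing in i, constant
    for i >= imax.
    """
    arr = np.asarray(i, dtype=float)
    if np.any(arr < 0):
        raise ValueError("intensities must be nonnegative")
    log = np.log if scheme.log_base == "e" else np.log10
    with np.errstate(divide="ignore"):
        w = np.maximum(1.0, log(np.minimum(arr, scheme.imax)))
    if scheme.clamp_below > 0:
        w = np.where(arr < scheme.clamp_below, 1.0, w)
    return w if w.ndim else float(w)


# ---------------------------------------------------------------------------
# shift-invariant regression loss


try:  # JIT the exhaustive offset search when numba is present
    from numba import njit as _njit
except ImportError:  # pragma: no cover - numba is an optional accelerator
    _njit = None


def _offset_losses_kernel(pred, target_padded, weights):
    h, w, c = pred.shape
    hp, wp = target_padded.shape[:2]
    n_oy, n_ox = hp - h + 1, wp - w + 1
    losses = np.empty((n_oy, n_ox))
    for oy in range(n_oy):
        for ox in range(n_ox):
            l1 = 0.0
            l2 = 0.0
            wsum = 0.0
            for y in range(h):
                for x in range(w):
                    wv = weights[oy + y, ox + x]
                    wsum += wv
                    for k in range(c):
                        d = pred[y, x, k] - target_padded[oy + y, ox + x, k]
                        l1 += wv * abs(d)
                        l2 += wv * d * d
            losses[oy, ox] = (l1 + l2) / (wsum * c)
    return losses


if _njit is not None:
    _offset_losses_kernel = _njit(_offset_losses_kernel)


def _offset_losses_numpy(
    pred: np.ndarray, target_padded: np.ndarray, weights: np.ndarray | None
) -> np.ndarray:
    """(n_off, n_off) weighted L1+L2 loss for every integer crop offset.

    Exhaustive search, vectorized over the x offsets with a sliding
    window view, one Python iteration per y offset.
    """
    if pred.ndim == 2:
        pred = pred[:, :, None]
    if target_padded.ndim == 2:
        target_padded = target_padded[:, :, None]
    h, w, c = pred.shape
    hp, wp = target_padded.shape[:2]
    n_oy, n_ox = hp - h + 1, wp - w + 1
    if weights is None:
        weights = np.ones((hp, wp))
    losses = np.empty((n_oy, n_ox))
    swv = np.lib.stride_tricks.sliding_window_view
    for oy in range(n_oy):
        band = target_padded[oy : oy + h]  # (h, wp, c)
        wband = weights[oy : oy + h]  # (h, wp)
        crops = swv(band, w, axis=1)  # (h, n_ox, c, w)
        wcrops = swv(wband, w, axis=1)  # (h, n_ox, w)
        d = pred.transpose(0, 2, 1)[:, None] - crops  # (h, n_ox, c, w)
        wx = wcrops[:, :, None, :]  # (h, n_ox, 1, w)
        wsum = wcrops.sum(axis=(0, 2)) * c  # (n_ox,)
        l1 = (wx * np.abs(d)).sum(axis=(0, 2, 3))
        l2 = (wx * d * d).sum(axis=(0, 2, 3))
        losses[oy] = (l1 + l2) / wsum
    return losses


def _offset_losses(
    pred: np.ndarray, target_padded: np.ndarray, weights: np.ndarray | None
) -> np.ndarray:
    """Weighted L1+L2 loss at every integer crop offset (exhaustive)."""
    if pred.ndim == 2:
        pred = pred[:, :, None]
    if target_padded.ndim == 2:
        target_padded = target_padded[:, :, None]
    if _njit is None:
        return _offset_losses_numpy(pred, target_padded, weights)
    if weights is None:
        weights = np.ones(target_padded.shape[:2])
    return _offset_losses_kernel(
        np.ascontiguousarray(pred, dtype=np.float64),
        np.ascontiguousarray(target_padded, dtype=np.float64),
        np.ascontiguousarray(weights, dtype=np.float64),
    )


def shift_invariant_regression_loss(
    pred: np.ndarray,
    target_padded: np.ndarray,
    weights: np.ndarray | None = None,
) -> tuple[float, tuple[int, int]]:
    """Minimum weighted L1+L2 over all integer crop offsets of the target.

    ``pred`` is (H, W, C); ``target_padded`` is (H+2p, W+2p, C) and the
    optional weight map matches the padded frame.  Returns the loss and
    the minimizing offset ``(ox, oy)`` (crop start, x = column).  The
    weight map is normalized inside, so uniform weights reproduce the
    unweighted loss exactly.
    """
    pred = np.asarray(pred, float)
    target_padded = np.asarray(target_padded, float)
    if pred.ndim == 2:
        pred = pred[:, :, None]
    if target_padded.ndim == 2:
        target_padded = target_padded[:, :, None]
    if pred.shape[2] != target_padded.shape[2]:
        raise ValueError("channel counts differ")
    if (
        target_padded.shape[0] < pred.shape[0]
        or target_padded.shape[1] < pred.shape[1]
    ):
        raise ValueError("target must be at least as large as the prediction")
    if weights is not None and weights.shape != target_padded.shape[:2]:
        raise ValueError("weights must match the padded target frame")
    losses = _offset_losses(pred, target_padded, weights)
    oy, ox = np.unravel_index(int(np.argmin(losses)), losses.shape)
    return float(losses[oy, ox]), (int(ox), int(oy))


def _shift_invariant_loss_tensor(
    pred: Tensor, targets: np.ndarray, weights: np.ndarray | None
) -> Tensor:
    """Differentiable batch version: offsets chosen on values, loss built
    at the chosen offsets."""
    n, h, w, c = pred.shape
    terms = []
    for k in range(n):
        wmap = weights[k] if weights is not None else None
        losses = _offset_losses(pred.value[k], targets[k], wmap)
        oy, ox = np.unravel_index(int(np.argmin(losses)), losses.shape)
        crop = targets[k, oy : oy + h, ox : ox + w]
        wc = (
            wmap[oy : oy + h, ox : ox + w]
            if wmap is not None
            else np.ones((h, w))
        )
        wc3 = wc[:, :, None] / (wc.sum() * c)
        pk = ad.crop(pred, (k,))
        d = pk - crop
        terms.append(ad.total(ad.absolute(d) * wc3) + ad.total(ad.square(d) * wc3))
    out = terms[0]
    for t in terms[1:]:
        out = out + t
    return out * (1.0 / n)


# ---------------------------------------------------------------------------
# rotational consistency


def _rot_loss_tensor(generator: UNetGenerator, af: np.ndarray, k: int) -> Tensor:
    base = generator(af)
    rot = generator(np.rot90(af, k, axes=(1, 2)).copy())
    back = ad.rot90(rot, -k)
    return ad.mean(ad.absolute(base - back))


def rotational_consistency_loss(
    generator,
    af_patch: np.ndarray,
    k: int | None = None,
    average: bool = False,
) -> float:
    """Mean L1 between G(x) and rot_k^{-1}(G(rot_k(x))).

    ``k`` picks one of the 90/180/270-degree rotations (1, 2, 3); with
    ``average=True`` the three are averaged.  A spatially pointwise
    generator scores exactly 0.
    """
    af = np.asarray(af_patch, float)
    if af.ndim == 3:
        af = af[None]
    if af.shape[1] != af.shape[2]:
        raise ValueError("rotational consistency requires square patches")
    ks = (1, 2, 3) if average else ((k,) if k is not None else (1,))
    vals = [float(_rot_loss_tensor(generator, af, kk).value) for kk in ks]
    return float(np.mean(vals))


# ---------------------------------------------------------------------------
# adversarial losses


class DiscriminatorSet:
    """1 conditional + 2 unconditional (full and half scale) discriminators."""

    def __init__(
        self,
        rng: np.random.Generator,
        af_channels: int,
        stain_channels: int,
        base_filters: int = 8,
        n_layers: int = 2,
    ):
        self.conditional = PatchDiscriminator(
            rng, af_channels + stain_channels, base_filters, n_layers
        )
        self.uncond_full = PatchDiscriminator(rng, stain_channels, base_filters, n_layers)
        self.uncond_down = PatchDiscriminator(rng, stain_channels, base_filters, n_layers)

    def parameters(self):
        return (
            self.conditional.parameters()
            + self.uncond_full.parameters()
            + self.uncond_down.parameters()
        )


def _bce_logit(logit: Tensor, target: float) -> Tensor:
    """Binary cross-entropy on a logit: softplus(l) - target * l."""
    return ad.softplus(logit) - ad.mul(logit, target)


def adversarial_losses(
    discriminators: DiscriminatorSet,
    af: np.ndarray,
    real_stain: np.ndarray,
    fake_stain,
    branch_weights: tuple[float, float, float] = (1.0, 1.0, 1.0),
) -> tuple[Tensor, Tensor]:
    """Generator-side and discriminator-side adversarial scalars.

    Non-saturating GAN objective per branch, weighted and summed.  The
    conditional branch sees AF concatenated with the stain; the two
    unconditional branches see the stain at full and half scale.
    ``fake_stain`` may be a Tensor (generator step, gradients flow) or an
    array (discriminator step, detached).
    """
    fake = fake_stain if isinstance(fake_stain, Tensor) else Tensor(fake_stain)
    fake_const = Tensor(fake.value.copy())  # detached view for the D side
    w_cond, w_full, w_down = branch_weights

    def branches(stain):
        cond_in = ad.concat([Tensor(np.asarray(af, float)), stain], axis=-1)
        return (
            discriminators.conditional(cond_in),
            discriminators.uncond_full(stain),
            discriminators.uncond_down(ad.avg_pool2(stain)),
        )

    g_logits = branches(fake)
    g_adv = (
        w_cond * _bce_logit(g_logits[0], 1.0)
        + w_full * _bce_logit(g_logits[1], 1.0)
        + w_down * _bce_logit(g_logits[2], 1.0)
    )

    r_logits = branches(Tensor(np.asarray(real_stain, float)))
    f_logits = branches(fake_const)
    d_adv = (
        w_cond * (_bce_logit(r_logits[0], 1.0) + _bce_logit(f_logits[0], 0.0)) * 0.5
        + w_full * (_bce_logit(r_logits[1], 1.0) + _bce_logit(f_logits[1], 0.0)) * 0.5
        + w_down * (_bce_logit(r_logits[2], 1.0) + _bce_logit(f_logits[2], 0.0)) * 0.5
    )
    return g_adv, d_adv


# ---------------------------------------------------------------------------
# Fréchet feature distance


def frechet_feature_distance(
    feats_real: np.ndarray, feats_fake: np.ndarray
) -> float:
    """||mu1 - mu2||^2 + Tr(S1 + S2 - 2 (S1 S2)^{1/2}) on sample moments."""
    a = np.asarray(feats_real, float)
    b = np.asarray(feats_fake, float)
    if a.ndim == 1:  # a plain sample vector: n scalar features
        a = a[:, None]
    if b.ndim == 1:
        b = b[:, None]
    if a.shape[0] < 2 or b.shape[0] < 2:
        raise ValueError("need at least 2 feature vectors per set")
    mu1, mu2 = a.mean(axis=0), b.mean(axis=0)
    s1 = np.atleast_2d(np.cov(a, rowvar=False))
    s2 = np.atleast_2d(np.cov(b, rowvar=False))
    diff = mu1 - mu2
    eigmin = min(np.linalg.eigvalsh(s1).min(), np.linalg.eigvalsh(s2).min())
    if eigmin < 1e-10:
        warnings.warn(
            "singular covariance; applying diagonal regularization",
            stacklevel=2,
        )
        reg = 1e-8 * np.eye(s1.shape[0])
        s1 = s1 + reg
        s2 = s2 + reg
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # sqrtm warns on near-singular input
        covmean = sla.sqrtm(s1 @ s2)
    if np.iscomplexobj(covmean):
        covmean = covmean.real
    return float(diff @ diff + np.trace(s1) + np.trace(s2) - 2.0 * np.trace(covmean))


class RandomProjectionFeatures:
    """Fixed-seed random-projection embedding of image patches.

    A pluggable stand-in feature extractor for monitoring the Fréchet
    distance during desk-scale training: patches are flattened and
    projected onto ``dim`` fixed Gaussian directions.
    """

    def __init__(self, dim: int = 16, seed: int = 0):
        self.dim = dim
        self.seed = seed
        self._proj: np.ndarray | None = None

    def __call__(self, patches: np.ndarray) -> np.ndarray:
        x = np.asarray(patches, float)
        flat = x.reshape(x.shape[0], -1)
        if self._proj is None or self._proj.shape[0] != flat.shape[1]:
            rng = np.random.default_rng(self.seed)
            self._proj = rng.standard_normal((flat.shape[1], self.dim))
            self._proj /= np.sqrt(flat.shape[1])
        return flat @ self._proj


# ---------------------------------------------------------------------------
# training


@dataclass(frozen=True)
class StainerConfig:
    in_channels: int = 20
    out_channels: int = 3
    base_filters: int = 16
    depth: int = 2
    kernel: int = 3
    disc_base_filters: int = 8
    disc_layers: int = 2
    lambda_reg: float = 1.0
    lambda_cond_adv: float = 0.0
    lambda_uncond_adv: float = 0.0
    lambda_rot: float = 0.0
    lambda_l2: float = 0.0
    lr: float = 2e-3
    lr_schedule: dict = field(default_factory=dict)  # step -> lr
    loss_weight_schedule: dict = field(default_factory=dict)  # step -> {name: value}
    batch_size: int = 4
    n_steps: int = 200
    val_interval: int = 50
    weighting: WeightingScheme | None = None
    frechet_dim: int = 16
    seed: int = 0


@dataclass
class Checkpoint:
    step: int
    arrays: list
    val_l1: float
    val_fd: float


@dataclass
class TrainState:
    step: int
    config: StainerConfig
    generator: UNetGenerator
    history: list  # per-step dicts: step, g_loss, (d_loss)
    val_records: list  # dicts: step, l1, frechet
    checkpoints: list  # Checkpoint


class TrainingDiverged(RuntimeError):
    def __init__(self, step: int, diagnostics: dict):
        super().__init__(f"NaN loss at step {step}: {diagnostics}")
        self.diagnostics = diagnostics


def _schedule_value(schedule: dict, step: int, default):
    """Piecewise-constant schedule: value of the largest key <= step."""
    best = default
    best_key = -1
    for k, v in schedule.items():
        if k <= step and k > best_key:
            best, best_key = v, k
    return best


def _stack_pairs(pairs) -> tuple[np.ndarray, np.ndarray]:
    af = np.stack([np.asarray(p.af, float) for p in pairs])
    st = np.stack([np.asarray(p.stain, float) for p in pairs])
    return af, st


def _center_crop(batch: np.ndarray, h: int, w: int) -> np.ndarray:
    hp, wp = batch.shape[1:3]
    oy, ox = (hp - h) // 2, (wp - w) // 2
    return batch[:, oy : oy + h, ox : ox + w]


def validation_metrics(
    generator: UNetGenerator,
    val_af: np.ndarray,
    val_stain: np.ndarray,
    extractor: RandomProjectionFeatures,
) -> tuple[float, float]:
    pred = generator(val_af).value
    real = _center_crop(val_stain, pred.shape[1], pred.shape[2])
    l1 = float(np.mean(np.abs(pred - real)))
    fd = frechet_feature_distance(extractor(real), extractor(pred))
    return l1, fd


def train(train_pairs, val_pairs, config: StainerConfig) -> TrainState:
    """Run the adversarial training loop on patch pairs.

    ``train_pairs`` / ``val_pairs`` are sequences of objects with ``af``
    (S, S, Cin) and ``stain`` (S+2p, S+2p, Cout) arrays (e.g.
    :class:`afstain.sampling.PatchPair`).  Fully seeded: two runs with
    the same (config, data) produce identical histories and weights.
    """
    if len(train_pairs) < 1:
        raise ValueError("need at least one training pair")
    af_tr, st_tr = _stack_pairs(train_pairs)
    af_va, st_va = _stack_pairs(val_pairs) if len(val_pairs) else (af_tr, st_tr)

    rng = np.random.default_rng(config.seed)
    generator = UNetGenerator(
        rng,
        in_channels=config.in_channels,
        out_channels=config.out_channels,
        base_filters=config.base_filters,
        depth=config.depth,
        kernel=config.kernel,
    )
    use_adv = config.lambda_cond_adv > 0 or config.lambda_uncond_adv > 0
    discs = DiscriminatorSet(
        rng, config.in_channels, config.out_channels,
        config.disc_base_filters, config.disc_layers,
    ) if use_adv else None

    g_opt = Adam(generator.parameters(), lr=config.lr)
    d_opt = Adam(discs.parameters(), lr=config.lr) if use_adv else None
    extractor = RandomProjectionFeatures(config.frechet_dim, seed=config.seed)

    # per-patch pixel weights from the raw target-stain intensity
    if config.weighting is not None:
        w_tr = pixel_weight(st_tr.mean(axis=3), config.weighting)
    else:
        w_tr = None

    state = TrainState(
        step=0, config=config, generator=generator,
        history=[], val_records=[], checkpoints=[],
    )

    lam = {
        "reg": config.lambda_reg,
        "cond_adv": config.lambda_cond_adv,
        "uncond_adv": config.lambda_uncond_adv,
        "rot": config.lambda_rot,
        "l2": config.lambda_l2,
    }

    for step in range(1, config.n_steps + 1):
        lr = _schedule_value(config.lr_schedule, step, config.lr)
        g_opt.lr = lr
        if d_opt is not None:
            d_opt.lr = lr
        sched = _schedule_value(config.loss_weight_schedule, step, None)
        if sched:
            lam.update(sched)

        idx = rng.integers(0, af_tr.shape[0], size=min(config.batch_size, af_tr.shape[0]))
        af_b, st_b = af_tr[idx], st_tr[idx]
        w_b = w_tr[idx] if w_tr is not None else None

        pred = generator(af_b)
        g_loss = _shift_invariant_loss_tensor(pred, st_b, w_b) * lam["reg"]
        if lam["rot"] > 0:
            k = 1 + (step % 3)  # cycle the three rotations deterministically
            g_loss = g_loss + lam["rot"] * _rot_loss_tensor(generator, af_b, k)
        d_adv = None
        if use_adv:
            real_crop = _center_crop(st_b, pred.shape[1], pred.shape[2])
            g_adv, d_adv = adversarial_losses(
                discs, af_b, real_crop, pred,
                branch_weights=(lam["cond_adv"], lam["uncond_adv"], lam["uncond_adv"]),
            )
            g_loss = g_loss + g_adv
        if lam["l2"] > 0:
            g_loss = g_loss + lam["l2"] * generator.weight_sq_norm()

        if not np.isfinite(g_loss.value):
            raise TrainingDiverged(step, {
                "g_loss": float(g_loss.value),
                "lr": lr,
                "pred_absmax": float(np.abs(pred.value).max()),
            })

        g_opt.zero_grad()
        g_loss.backward()
        g_opt.step()

        rec = {"step": step, "g_loss": float(g_loss.value), "lr": lr}
        if use_adv:
            d_opt.zero_grad()
            d_adv.backward()
            d_opt.step()
            rec["d_loss"] = float(d_adv.value)
        state.history.append(rec)
        state.step = step

        if step % config.val_interval == 0 or step == config.n_steps:
            l1, fd = validation_metrics(generator, af_va, st_va, extractor)
            state.val_records.append({"step": step, "l1": l1, "frechet": fd})
            state.checkpoints.append(
                Checkpoint(step, generator.state_arrays(), l1, fd)
            )
    return state


def select_checkpoint(state: TrainState) -> Checkpoint:
    """Checkpoint with the best rank-sum of validation L1 and Fréchet
    distance; ties go to the earlier step."""
    if not state.checkpoints:
        raise ValueError("no validated checkpoints")
    l1s = np.array([c.val_l1 for c in state.checkpoints])
    fds = np.array([c.val_fd for c in state.checkpoints])
    ranksum = stats.rankdata(l1s) + stats.rankdata(fds)
    best = int(np.argmin(ranksum))  # argmin takes the earliest on ties
    return state.checkpoints[best]


# ---------------------------------------------------------------------------
# WSI inference


@dataclass(frozen=True)
class TileSpec:
    tile_px: int = 128
    overlap_px: int = 32


def _feather_window(size: int, overlap: int) -> np.ndarray:
    """1-D cosine ramp: 0->1 over the overlap, flat 1 in the interior."""
    w = np.ones(size)
    if overlap > 0:
        ramp = 0.5 * (1 - np.cos(np.pi * (np.arange(overlap) + 0.5) / overlap))
        w[:overlap] = ramp
        w[-overlap:] = ramp[::-1]
    return w


def predict_wsi(
    af_wsi: np.ndarray, generator: UNetGenerator, tile_spec: TileSpec = TileSpec()
) -> np.ndarray:
    """Overlapping-tile generator inference with cosine-feathered seams.

    Output spatial dimensions match the input.  When a single tile covers
    the whole image the result is identical to one direct generator pass.
    """
    af = np.asarray(af_wsi, float)
    if af.ndim != 3:
        raise ValueError("AF WSI must be (H, W, C)")
    if af.shape[2] != generator.enc[0].w.value.shape[2]:
        raise ValueError(
            f"generator expects {generator.enc[0].w.value.shape[2]} channels, "
            f"got {af.shape[2]}"
        )
    h, w = af.shape[:2]
    mult = 2**generator.depth

    def run(patch: np.ndarray) -> np.ndarray:
        ph = (-patch.shape[0]) % mult
        pw = (-patch.shape[1]) % mult
        if ph or pw:
            patch = np.pad(patch, ((0, ph), (0, pw), (0, 0)), mode="reflect")
        out = generator(patch[None]).value[0]
        return out[: out.shape[0] - ph or None, : out.shape[1] - pw or None]

    tile = tile_spec.tile_px
    if tile >= h and tile >= w:
        return run(af)

    step = tile - tile_spec.overlap_px
    if step <= 0:
        raise ValueError("overlap must be smaller than the tile")
    out_c = generator.head.w.value.shape[3]
    acc = np.zeros((h, w, out_c))
    wacc = np.zeros((h, w))
    win = None
    ys = sorted(set(list(range(0, max(h - tile, 0) + 1, step)) + [max(h - tile, 0)]))
    xs = sorted(set(list(range(0, max(w - tile, 0) + 1, step)) + [max(w - tile, 0)]))
    for y0 in ys:
        for x0 in xs:
            th, tw = min(tile, h - y0), min(tile, w - x0)
            pred = run(af[y0 : y0 + th, x0 : x0 + tw])
            wy = _feather_window(th, min(tile_spec.overlap_px, th // 2))
            wx = _feather_window(tw, min(tile_spec.overlap_px, tw // 2))
            win = wy[:, None] * wx[None, :]
            acc[y0 : y0 + th, x0 : x0 + tw] += pred * win[:, :, None]
            wacc[y0 : y0 + th, x0 : x0 + tw] += win
    return acc / np.maximum(wacc, 1e-12)[:, :, None]
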