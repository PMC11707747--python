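"""Shared fixtures: small phantoms and their noiseless renders."""

import numpy as np
import pytest

import afstain as a


@pytest.fixture(scope="session")
def phantom():
    """Mixed-population phantom: tumor, T cells (some cytotoxic), others."""
    cfg = a.PhantomConfig(
        width_px=192,
        height_px=192,
        n_tumor=20,
        n_t_cell=10,
        n_cytotoxic=5,
        n_other=8,
        seed=11,
    )
    return a.make_phantom(cfg)


@pytest.fixture(scope="session")
def render_cfg():
    return a.RenderConfig(noise_sd=0.0)


@pytest.fixture(scope="session")
def mif(phantom, render_cfg):
    return a.render_mif(phantom, render_cfg)


@pytest.fixture(scope="session")
def af(phantom, render_cfg):
    return a.render_af(phantom, render_cfg)


@pytest.fixture(scope="session")
def he(phantom, render_cfg):
    return a.render_he(phantom, render_cfg)


@pytest.fixture(scope="session")
def textured_patch_10x():
    """Textured 96x96 H&E patch at the 10x reference (1.0 um/px)."""
    p = a.make_phantom(
        a.PhantomConfig(
            width_px=96,
            height_px=96,
            pixel_size_um=1.0,
            n_tumor=8,
            n_t_cell=6,
            n_cytotoxic=3,
            n_other=4,
            nucleus_radius_px=3.5,
            seed=3,
        )
    )
    return a.render_he(p, a.RenderConfig(pixel_size_um=1.0, noise_sd=0.0))


def small_training_pairs(n_pairs=8, patch_px=64, seed=11):
    """Paired AF/H&E patches from a noiseless phantom for training tests."""
    p = a.make_phantom(
        a.PhantomConfig(
            width_px=192, height_px=192, n_tumor=20, n_t_cell=10,
            n_cytotoxic=5, n_other=8, seed=seed,
        )
    )
    r = a.RenderConfig(noise_sd=0.0)
    af_img = a.render_af(p, r)
    he_img = a.render_he(p, r)
    policy = a.SamplingPolicy(tissue_mask=a.tissue_mask(af_img), seed=5)
    return a.sample_paired_patches(af_img, he_img, n_pairs, policy, af_patch_px=patch_px)
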