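"""Forward imaging model: PSF blur, shot noise, read noise, quantization.

Per channel: anisotropic Gaussian PSF blur with physical-unit sigmas,
multiplication by the photon scale, Poisson sampling, additive Gaussian read
noise and a constant background offset, then clipping and quantization to
unsigned 16-bit. With ``photon_scale = 0`` and no read noise the output is
the constant background; with zero-width PSF and no noise it is the
quantized input.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from ..stack import ImageStack
from .spec import Optics


def render(scene: ImageStack, optics: Optics, seed: int,
           shot_noise: bool = True) -> ImageStack:
    """Render a noiseless scene into a noisy 16-bit stack (deterministic in
    seed). ``shot_noise=False`` replaces Poisson sampling by its expectation,
    giving a fully noise-free rendering when the read noise is also zero."""
    if optics.psf_sigma_xy_um < 0 or optics.psf_sigma_z_um < 0:
        raise ValueError("PSF sigmas must be >= 0")
    if optics.photon_scale < 0:
        raise ValueError("photon_scale must be >= 0")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x9E3779B9]))
    dz, dy, dx = scene.voxel_size
    sigma_vox = (optics.psf_sigma_z_um / dz,
                 optics.psf_sigma_xy_um / dy,
                 optics.psf_sigma_xy_um / dx)
    out = np.empty(scene.voxels.shape, dtype=np.uint16)
    for c in range(scene.n_channels):
        img = scene.voxels[c].astype(np.float64)
        if any(s > 0 for s in sigma_vox):
            img = ndimage.gaussian_filter(img, sigma=sigma_vox, mode="constant")
        expected = np.clip(img * optics.photon_scale, 0.0, None)
        counts = rng.poisson(expected).astype(np.float64) if shot_noise else expected
        if optics.read_noise_sd > 0:
            counts += rng.normal(0.0, optics.read_noise_sd, size=counts.shape)
        counts += optics.background
        out[c] = np.clip(np.rint(counts), 0, 65535).astype(np.uint16)
    return ImageStack(voxels=out, voxel_size=scene.voxel_size,
                      channel_names=list(scene.channel_names))
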