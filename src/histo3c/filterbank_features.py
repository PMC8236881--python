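"""Filter-bank descriptors: Gabor block energies and HOG.

The Gabor bank has 5 scales x 8 orientations of complex kernels on a fixed
39x39 support.  Center frequencies descend geometrically from 0.25
cycles/pixel by factors of sqrt(2); orientations are k*pi/8.  Each filter's
response magnitude is pooled as the mean over a non-overlapping grid of
46x70-pixel blocks (100 blocks on a 700x460 image), giving 40 x 100 = 4000
values per channel ordered (scale, orientation, block row, block col).

HOG uses central-difference gradients, unsigned orientations on [0, 180),
a 4x8 grid of cells each holding a magnitude-weighted 9-bin histogram with
linear bin interpolation, and a single global L2 normalization: 288 values
per channel.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.signal import fftconvolve

from histo3c.image_channels import Channel, ChannelMode, RGBImage, apply_per_channel

_F_MAX = 0.25  # cycles/pixel at the finest scale
_SCALE_FACTOR = np.sqrt(2.0)
#: sigma/wavelength ratio for a one-octave half-response bandwidth
_SIGMA_PER_LAMBDA = (1.0 / np.pi) * np.sqrt(np.log(2.0) / 2.0) * 3.0


@dataclass(frozen=True)
class GaborBankConfig:
    n_scales: int = 5
    n_orientations: int = 8
    kernel_size: int = 39
    block_rows: int = 46
    block_cols: int = 70
    frequencies: tuple = ()

    def __post_init__(self) -> None:
        if self.kernel_size % 2 == 0:
            raise ValueError("kernel_size must be odd")
        if not self.frequencies:
            freqs = tuple(_F_MAX / _SCALE_FACTOR**s for s in range(self.n_scales))
            object.__setattr__(self, "frequencies", freqs)
        elif len(self.frequencies) != self.n_scales:
            raise ValueError("frequencies must have one entry per scale")


@dataclass(frozen=True)
class HOGConfig:
    n_bins: int = 9
    grid_rows: int = 4
    grid_cols: int = 8
    signed: bool = False

    @property
    def dimension(self) -> int:
        return self.n_bins * self.grid_rows * self.grid_cols


@lru_cache(maxsize=8)
def gabor_kernels(config: GaborBankConfig = GaborBankConfig()) -> tuple:
    """The n_scales x n_orientations complex kernels, scale-major order."""
    half = config.kernel_size // 2
    y, x = np.mgrid[-half : half + 1, -half : half + 1].astype(np.float64)
    kernels = []
    for f in config.frequencies:
        lam = 1.0 / f
        sigma = _SIGMA_PER_LAMBDA * lam
        for k in range(config.n_orientations):
            theta = k * np.pi / config.n_orientations
            xr = x * np.cos(theta) + y * np.sin(theta)
            yr = -x * np.sin(theta) + y * np.cos(theta)
            envelope = np.exp(-(xr**2 + yr**2) / (2.0 * sigma**2))
            carrier = np.exp(2j * np.pi * f * xr)
            kernels.append(envelope * carrier)
    return tuple(kernels)


def block_means(arr: np.ndarray, block_rows: int, block_cols: int) -> np.ndarray:
    """Mean over each block of a non-overlapping grid, center-cropping the
    array to the largest grid that fits.  Returns an (n_rows, n_cols) array."""
    h, w = arr.shape
    n_r, n_c = h // block_rows, w // block_cols
    if n_r == 0 or n_c == 0:
        raise ValueError(f"array {arr.shape} smaller than one {block_rows}x{block_cols} block")
    r0 = (h - n_r * block_rows) // 2
    c0 = (w - n_c * block_cols) // 2
    crop = arr[r0 : r0 + n_r * block_rows, c0 : c0 + n_c * block_cols]
    return crop.reshape(n_r, block_rows, n_c, block_cols).mean(axis=(1, 3))


def gabor_descriptor(channel: Channel, config: GaborBankConfig = GaborBankConfig()) -> np.ndarray:
    """Block-pooled Gabor response magnitudes; 4000-D on 700x460 defaults."""
    px = np.asarray(channel.pixels, dtype=np.float64)
    out = []
    for kernel in gabor_kernels(config):
        mag = np.abs(fftconvolve(px, kernel, mode="same"))
        out.append(block_means(mag, config.block_rows, config.block_cols).ravel())
    return np.concatenate(out)


def hog_descriptor(channel: Channel, config: HOGConfig = HOGConfig()) -> np.ndarray:
    """Grid-of-cells orientation histogram, globally L2-normalized; 288-D."""
    px = np.asarray(channel.pixels, dtype=np.float64)
    if px.shape[0] < config.grid_rows or px.shape[1] < config.grid_cols:
        raise ValueError(f"channel {px.shape} smaller than the {config.grid_rows}x{config.grid_cols} cell grid")
    gy, gx = np.gradient(px)
    mag = np.hypot(gx, gy)
    span = 2 * np.pi if config.signed else np.pi
    ang = np.arctan2(gy, gx)
    ang = np.mod(ang, span)

    h, w = px.shape
    cell_h, cell_w = h // config.grid_rows, w // config.grid_cols
    r0 = (h - cell_h * config.grid_rows) // 2
    c0 = (w - cell_w * config.grid_cols) // 2

    n_bins = config.n_bins
    bin_width = span / n_bins
    pos = ang / bin_width - 0.5
    lo = np.floor(pos).astype(np.int64)
    frac = pos - lo
    lo_bin = np.mod(lo, n_bins)
    hi_bin = np.mod(lo + 1, n_bins)

    hist = np.zeros((config.grid_rows, config.grid_cols, n_bins))
    for i in range(config.grid_rows):
        for j in range(config.grid_cols):
            rs = slice(r0 + i * cell_h, r0 + (i + 1) * cell_h)
            cs = slice(c0 + j * cell_w, c0 + (j + 1) * cell_w)
            m, lb, hb, fr = (a[rs, cs].ravel() for a in (mag, lo_bin, hi_bin, frac))
            np.add.at(hist[i, j], lb, m * (1.0 - fr))
            np.add.at(hist[i, j], hb, m * fr)
    vec = hist.ravel()
    norm = np.linalg.norm(vec)
    if norm > 0:
        vec = vec / norm
    return vec


def gabor_image_descriptor(image: RGBImage, mode: "ChannelMode | str" = ChannelMode.RGB_FUSED) -> np.ndarray:
    """Gabor bank per channel: 12000 fused, 4000 otherwise (700x460 input)."""
    return apply_per_channel(image, mode, gabor_descriptor)


def hog_image_descriptor(image: RGBImage, mode: "ChannelMode | str" = ChannelMode.RGB_FUSED) -> np.ndarray:
    """HOG per channel: 864 fused, 288 otherwise."""
    return apply_per_channel(image, mode, hog_descriptor)
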