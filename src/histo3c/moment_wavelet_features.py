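"""Per-channel mean intensity (APVEC), Hu invariant moments, wavelet energies."""

from __future__ import annotations

import warnings

import numpy as np
import pywt
from skimage.measure import moments_central, moments_hu, moments_normalized

from histo3c.image_channels import Channel, ChannelMode, RGBImage, apply_per_channel

#: floor inside the log-magnitude transform of the Hu invariants
HU_LOG_EPS = 1e-30

DEFAULT_WAVELET = "coif5"
DEFAULT_LEVELS = 5
#: periodized decomposition keeps the transform orthonormal, so subband
#: energies partition the input energy exactly on dyadic sizes
DEFAULT_WAVELET_MODE = "periodization"


def apvec(channel: Channel) -> float:
    """Mean pixel intensity of one channel: (1/MN) * sum f(x, y)."""
    px = np.asarray(channel.pixels)
    if px.size == 0:
        raise ValueError("empty channel")
    return float(px.mean(dtype=np.float64))


def apvec_descriptor(image: RGBImage, mode: "ChannelMode | str" = ChannelMode.RGB_FUSED) -> np.ndarray:
    """One mean per channel: 3 values fused, 1 otherwise."""
    return apply_per_channel(image, mode, lambda ch: np.array([apvec(ch)]))


def hu_moments(channel: Channel, log_scale: bool = True) -> np.ndarray:
    """The seven Hu invariants of a channel treated as a mass distribution.

    Built from second- and third-order normalized central moments, hence
    invariant to translation and rotation and (approximately, on a pixel
    grid) to scale.  The raw invariants span tens of orders of magnitude;
    by default they are reported as sign(h) * log10(|h| + eps) so that they
    can share one feature scaling with the other descriptors.
    """
    px = np.asarray(channel.pixels, dtype=np.float64)
    if px.sum() == 0:
        raise ValueError("Hu moments undefined for an all-zero channel")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # 0/0 in unused nu entries
        nu = moments_normalized(moments_central(px))
    h = moments_hu(nu)
    if not log_scale:
        return h
    return np.sign(h) * np.log10(np.abs(h) + HU_LOG_EPS)


def hu_descriptor(image: RGBImage, mode: "ChannelMode | str" = ChannelMode.RGB_FUSED) -> np.ndarray:
    """Seven Hu invariants per channel: 21 fused, 7 otherwise."""
    return apply_per_channel(image, mode, hu_moments)


def max_wavelet_level(shape: tuple, wavelet: str = DEFAULT_WAVELET) -> int:
    """Deepest decomposition level that still leaves a nonempty subband."""
    return int(np.floor(np.log2(min(shape)))) if min(shape) >= 2 else 0


def wavelet_energies(
    channel: Channel,
    wavelet: str = DEFAULT_WAVELET,
    levels: int = DEFAULT_LEVELS,
    mode: str = DEFAULT_WAVELET_MODE,
) -> np.ndarray:
    """Detail-subband energies of a 2-D wavelet decomposition.

    For each level l = 1..levels (finest to coarsest) the energy is the sum
    of squared coefficients over the horizontal, vertical and diagonal
    detail subbands at that level.  Default: coif5, 5 levels.
    """
    px = np.asarray(channel.pixels, dtype=np.float64)
    feasible = max_wavelet_level(px.shape, wavelet)
    if levels > feasible:
        raise ValueError(
            f"channel {px.shape} supports at most {feasible} decomposition levels, got {levels}"
        )
    with warnings.catch_warnings():
        # pywt warns when `levels` exceeds its boundary-effect-free depth;
        # the decomposition itself is still well defined.
        warnings.simplefilter("ignore", UserWarning)
        coeffs = pywt.wavedec2(px, wavelet, mode=mode, level=levels)
    # coeffs = [cA_n, (cH_n, cV_n, cD_n), ..., (cH_1, cV_1, cD_1)]
    energies = []
    for detail in reversed(coeffs[1:]):  # finest first
        energies.append(sum(float((band**2).sum()) for band in detail))
    return np.asarray(energies)


def wavelet_approx_energy(
    channel: Channel,
    wavelet: str = DEFAULT_WAVELET,
    levels: int = DEFAULT_LEVELS,
    mode: str = DEFAULT_WAVELET_MODE,
) -> float:
    """Energy of the coarsest approximation subband (for energy audits)."""
    px = np.asarray(channel.pixels, dtype=np.float64)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        coeffs = pywt.wavedec2(px, wavelet, mode=mode, level=levels)
    return float((coeffs[0] ** 2).sum())


def wavelet_descriptor(image: RGBImage, mode: "ChannelMode | str" = ChannelMode.RGB_FUSED) -> np.ndarray:
    """Five detail energies per channel: 15 fused, 5 otherwise."""
    return apply_per_channel(image, mode, wavelet_energies)
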