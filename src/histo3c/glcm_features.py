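"""Gray-level co-occurrence matrices and the 22 Haralick-family statistics.

Co-occurrence is computed at 256 gray levels (8-bit intensities used as-is,
no requantization), offset distance 1, symmetrized (each pixel pair counted
in both orders, so 0 deg and 180 deg coincide) and normalized to a joint
probability distribution.  The single-direction descriptor (GLCM1) uses the
0 deg offset only; the four-direction descriptor (GLCM4) concatenates the
22 statistics for 0, 45, 90 and 135 deg into an 88-vector per channel.

The 22 statistics are the classical Haralick set extended by Soh &
Tsatsoulis and Clausi: autocorrelation, contrast, two correlation variants,
cluster prominence, cluster shade, dissimilarity, energy, entropy, two
homogeneity variants, maximum probability, sum of squares (variance), sum
average, sum variance, sum entropy, difference variance, difference
entropy, the two information measures of correlation, inverse difference
normalized and inverse difference moment normalized.  Entropy-type features
use base-2 logarithms with the 0*log(0) = 0 convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.feature import graycomatrix

from histo3c.image_channels import Channel, ChannelMode, RGBImage, apply_per_channel

N_LEVELS = 256

#: Angle (degrees) -> radians for skimage's graycomatrix.
ANGLES = {0: 0.0, 45: np.pi / 4, 90: np.pi / 2, 135: 3 * np.pi / 4}
DIRECTION_ORDER = (0, 45, 90, 135)

HARALICK_NAMES = (
    "autocorrelation",
    "contrast",
    "correlation_i",
    "correlation_ii",
    "cluster_prominence",
    "cluster_shade",
    "dissimilarity",
    "energy",
    "entropy",
    "homogeneity_i",
    "homogeneity_ii",
    "maximum_probability",
    "sum_of_squares",
    "sum_average",
    "sum_variance",
    "sum_entropy",
    "difference_variance",
    "difference_entropy",
    "imc1",
    "imc2",
    "inverse_difference",
    "inverse_difference_moment",
)

_EPS = 1e-12


@dataclass
class GLCMatrix:
    """A symmetric, normalized 256x256 co-occurrence probability matrix."""

    probabilities: np.ndarray
    direction: int  # degrees, one of 0/45/90/135
    distance: int = 1

    def __post_init__(self) -> None:
        p = np.asarray(self.probabilities, dtype=np.float64)
        if p.shape != (N_LEVELS, N_LEVELS):
            raise ValueError(f"GLCM must be {N_LEVELS}x{N_LEVELS}, got {p.shape}")
        self.probabilities = p


def compute_glcm(channel: Channel, direction: int = 0, distance: int = 1) -> GLCMatrix:
    """Symmetric normalized GLCM of an 8-bit channel at one offset.

    direction is in degrees (0, 45, 90 or 135); distance in pixels.
    """
    if direction not in ANGLES:
        raise ValueError(f"direction must be one of {tuple(ANGLES)}, got {direction}")
    if distance < 1:
        raise ValueError("distance must be >= 1")
    px = channel.pixels
    if px.shape[0] <= distance and px.shape[1] <= distance:
        raise ValueError(f"channel {px.shape} too small for offset distance {distance}")
    glcm = graycomatrix(
        px.astype(np.uint8),
        distances=[distance],
        angles=[ANGLES[direction]],
        levels=N_LEVELS,
        symmetric=True,
        normed=True,
    )[:, :, 0, 0]
    return GLCMatrix(glcm, direction, distance)


def _entropy2(p: np.ndarray) -> float:
    """Base-2 entropy with 0*log(0) = 0."""
    nz = p[p > 0]
    return float(-(nz * np.log2(nz)).sum())


# index grids reused across calls (256 levels fixed)
_I = np.arange(N_LEVELS, dtype=np.float64)[:, None] * np.ones((1, N_LEVELS))
_J = _I.T
_ABS_D = np.abs(_I - _J)
_SUM_IDX = (np.arange(N_LEVELS)[:, None] + np.arange(N_LEVELS)[None, :]).ravel()
_DIFF_IDX = np.abs(np.arange(N_LEVELS)[:, None] - np.arange(N_LEVELS)[None, :]).ravel()


def haralick_22(glcm: GLCMatrix) -> np.ndarray:
    """The 22 co-occurrence statistics, in the fixed documented order.

    Raises if the matrix is not normalized.  All outputs are finite even
    for degenerate (single-cell) matrices; correlation-type features are
    defined as 0 when a marginal is constant.
    """
    p = glcm.probabilities
    total = p.sum()
    if not np.isclose(total, 1.0, atol=1e-9):
        raise ValueError(f"GLCM not normalized: entries sum to {total}")

    i, j = _I, _J
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    levels = np.arange(N_LEVELS, dtype=np.float64)
    mu_x = float(levels @ px)
    mu_y = float(levels @ py)
    sd_x = float(np.sqrt(((levels - mu_x) ** 2) @ px))
    sd_y = float(np.sqrt(((levels - mu_y) ** 2) @ py))

    p_sum = np.bincount(_SUM_IDX, weights=p.ravel(), minlength=2 * N_LEVELS - 1)
    p_diff = np.bincount(_DIFF_IDX, weights=p.ravel(), minlength=N_LEVELS)
    k_sum = np.arange(p_sum.size, dtype=np.float64)
    k_diff = np.arange(p_diff.size, dtype=np.float64)

    autocorrelation = float((i * j * p).sum())
    contrast = float(((i - j) ** 2 * p).sum())
    if sd_x * sd_y < _EPS:
        correlation_i = correlation_ii = 0.0
    else:
        correlation_i = (autocorrelation - mu_x * mu_y) / (sd_x * sd_y)
        correlation_ii = float((((i - mu_x) * (j - mu_y) * p).sum()) / (sd_x * sd_y))
    cluster_prominence = float(((i + j - mu_x - mu_y) ** 4 * p).sum())
    cluster_shade = float(((i + j - mu_x - mu_y) ** 3 * p).sum())
    dissimilarity = float((_ABS_D * p).sum())
    energy = float((p**2).sum())
    entropy = _entropy2(p)
    homogeneity_i = float((p / (1.0 + _ABS_D)).sum())
    homogeneity_ii = float((p / (1.0 + (i - j) ** 2)).sum())
    maximum_probability = float(p.max())
    sum_of_squares = float((((i - mu_x) ** 2) * p).sum())
    sum_average = float(k_sum @ p_sum)
    sum_entropy = _entropy2(p_sum)
    # Haralick's sum variance is the second moment of p_{x+y} about sum entropy
    sum_variance = float(((k_sum - sum_entropy) ** 2) @ p_sum)
    mu_diff = float(k_diff @ p_diff)
    difference_variance = float(((k_diff - mu_diff) ** 2) @ p_diff)
    difference_entropy = _entropy2(p_diff)

    hx = _entropy2(px)
    hy = _entropy2(py)
    pxpy = np.outer(px, py)
    mask = (p > 0) & (pxpy > 0)
    hxy1 = float(-(p[mask] * np.log2(pxpy[mask])).sum())
    nz = pxpy > 0
    hxy2 = float(-(pxpy[nz] * np.log2(pxpy[nz])).sum())
    denom = max(hx, hy)
    imc1 = (entropy - hxy1) / denom if denom > _EPS else 0.0
    imc2 = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - entropy)))))

    inverse_difference = float((p / (1.0 + _ABS_D / N_LEVELS)).sum())
    inverse_difference_moment = float((p / (1.0 + (i - j) ** 2 / N_LEVELS**2)).sum())

    out = np.array(
        [
            autocorrelation,
            contrast,
            correlation_i,
            correlation_ii,
            cluster_prominence,
            cluster_shade,
            dissimilarity,
            energy,
            entropy,
            homogeneity_i,
            homogeneity_ii,
            maximum_probability,
            sum_of_squares,
            sum_average,
            sum_variance,
            sum_entropy,
            difference_variance,
            difference_entropy,
            imc1,
            imc2,
            inverse_difference,
            inverse_difference_moment,
        ]
    )
    if not np.all(np.isfinite(out)):
        raise FloatingPointError("non-finite Haralick feature")
    return out


def haralick_channel(channel: Channel, directions=(0,), distance: int = 1) -> np.ndarray:
    """22 statistics per direction, concatenated in the given direction order."""
    return np.concatenate(
        [haralick_22(compute_glcm(channel, d, distance)) for d in directions]
    )


def glcm1_descriptor(image: RGBImage, mode: "ChannelMode | str" = ChannelMode.RGB_FUSED) -> np.ndarray:
    """Single-direction (0 deg) GLCM descriptor: 22 per channel, 66 fused."""
    return apply_per_channel(image, mode, lambda ch: haralick_channel(ch, (0,)))


def glcm4_descriptor(image: RGBImage, mode: "ChannelMode | str" = ChannelMode.RGB_FUSED) -> np.ndarray:
    """Four-direction GLCM descriptor: 88 per channel, 264 fused."""
    return apply_per_channel(image, mode, lambda ch: haralick_channel(ch, DIRECTION_ORDER))
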