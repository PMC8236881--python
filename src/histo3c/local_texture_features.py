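"""Local texture descriptors: LBP, completed LBP (CLBP), Tamura statistics.

LBP here is the original 3x3-window operator: the eight physical
neighbors of each interior pixel are thresholded against the center with
s(x) = 1 iff x >= 0, and assembled into an 8-bit code.  Neighbors are
ordered counter-clockwise starting from the east neighbor, bit p
weighting 2**p.  Border pixels have no full neighborhood and are skipped
(no padding).

CLBP decomposes the local differences g_p - g_c into a sign component S
(identical to LBP) and a magnitude component M that thresholds
D_p = |g_p - g_c| against D_c, the mean of D_p over all neighbors of all
interior pixels of the channel.  Both code maps are collapsed through the
rotation-invariant uniform (riu2) mapping to P+2 = 10 bins, and the two
normalized histograms are concatenated (S then M) into the 20-D
descriptor.  The center component C (center intensity thresholded against
the channel's mean center intensity) is computed and exposed but is not
part of the default 20-D vector.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy import ndimage

from histo3c.image_channels import Channel, ChannelMode, RGBImage, apply_per_channel


@dataclass(frozen=True)
class LBPConfig:
    P: int = 8
    R: int = 1

    def __post_init__(self) -> None:
        if self.P < 4:
            raise ValueError("P must be >= 4")
        if self.R < 1:
            raise ValueError("R must be >= 1")


# eight 3x3 neighbors, counter-clockwise from east; (row offset, col offset)
_NEIGHBOR_OFFSETS = (
    (0, 1),
    (-1, 1),
    (-1, 0),
    (-1, -1),
    (0, -1),
    (1, -1),
    (1, 0),
    (1, 1),
)


def _neighbor_stack(px: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Center values and the (8, H-2, W-2) stack of neighbor values."""
    if px.shape[0] < 3 or px.shape[1] < 3:
        raise ValueError(f"channel {px.shape} too small for a 3x3 neighborhood")
    c = px[1:-1, 1:-1]
    nbrs = np.stack(
        [px[1 + dr : px.shape[0] - 1 + dr, 1 + dc : px.shape[1] - 1 + dc] for dr, dc in _NEIGHBOR_OFFSETS]
    )
    return c, nbrs


def lbp_codes(channel: Channel, config: LBPConfig = LBPConfig()) -> np.ndarray:
    """8-bit LBP code of every interior pixel."""
    if (config.P, config.R) != (8, 1):
        raise NotImplementedError("the 3x3-window operator is defined for P=8, R=1")
    px = np.asarray(channel.pixels, dtype=np.int64)
    c, nbrs = _neighbor_stack(px)
    bits = (nbrs - c[None] >= 0).astype(np.int64)
    weights = (1 << np.arange(config.P)).reshape(-1, 1, 1)
    return (bits * weights).sum(axis=0)


def lbp_histogram(channel: Channel, config: LBPConfig = LBPConfig()) -> np.ndarray:
    """Normalized 2**P-bin histogram of LBP codes (sums to 1)."""
    codes = lbp_codes(channel, config)
    hist = np.bincount(codes.ravel(), minlength=2**config.P).astype(np.float64)
    return hist / hist.sum()


@lru_cache(maxsize=None)
def riu2_table(P: int = 8) -> np.ndarray:
    """Lookup table mapping each of the 2**P codes to its riu2 bin.

    Uniform codes (at most two 0/1 transitions on the circular pattern)
    map to their popcount 0..P; all non-uniform codes share bin P+1.
    """
    table = np.empty(2**P, dtype=np.int64)
    for code in range(2**P):
        bits = [(code >> p) & 1 for p in range(P)]
        transitions = sum(bits[p] != bits[(p + 1) % P] for p in range(P))
        table[code] = sum(bits) if transitions <= 2 else P + 1
    return table


def clbp_codes(channel: Channel, config: LBPConfig = LBPConfig()) -> dict:
    """Per-pixel CLBP component codes and the global thresholds.

    Returns a dict with 's', 'm', 'c' code maps plus 'd_c' (the global
    mean absolute local difference) and 'g_n' (the global mean center
    intensity used by the C component).
    """
    if (config.P, config.R) != (8, 1):
        raise NotImplementedError("the 3x3-window operator is defined for P=8, R=1")
    px = np.asarray(channel.pixels, dtype=np.float64)
    c, nbrs = _neighbor_stack(px)
    diffs = nbrs - c[None]
    weights = (1 << np.arange(config.P)).reshape(-1, 1, 1)

    s_codes = ((diffs >= 0).astype(np.int64) * weights).sum(axis=0)
    d_p = np.abs(diffs)
    d_c = float(d_p.mean())
    m_codes = ((d_p - d_c >= 0).astype(np.int64) * weights).sum(axis=0)
    g_n = float(c.mean())
    c_codes = (c - g_n >= 0).astype(np.int64)
    return {"s": s_codes, "m": m_codes, "c": c_codes, "d_c": d_c, "g_n": g_n}


def clbp_descriptor(channel: Channel, config: LBPConfig = LBPConfig()) -> np.ndarray:
    """20-D CLBP descriptor: riu2 histograms of S and M, concatenated."""
    codes = clbp_codes(channel, config)
    table = riu2_table(config.P)
    n_bins = config.P + 2
    out = []
    for key in ("s", "m"):
        riu = table[codes[key]]
        hist = np.bincount(riu.ravel(), minlength=n_bins).astype(np.float64)
        out.append(hist / hist.sum())
    return np.concatenate(out)


def lbp_image_descriptor(image: RGBImage, mode: "ChannelMode | str" = ChannelMode.RGB_FUSED) -> np.ndarray:
    """256-bin LBP histogram per channel: 768 fused, 256 otherwise."""
    return apply_per_channel(image, mode, lbp_histogram)


def clbp_image_descriptor(image: RGBImage, mode: "ChannelMode | str" = ChannelMode.RGB_FUSED) -> np.ndarray:
    """20-D CLBP descriptor per channel: 60 fused, 20 otherwise."""
    return apply_per_channel(image, mode, clbp_descriptor)


# ---------------------------------------------------------------------------
# Tamura statistics
# ---------------------------------------------------------------------------

#: coarseness window half-exponents: window sizes 2**k, k = 1..5
TAMURA_KMAX = 5
#: directionality histogram bins
TAMURA_DIR_BINS = 16
#: gradient-magnitude percentile below which pixels do not vote a direction
TAMURA_DIR_THRESHOLD_PCT = 12.0
#: subimage grid used by the regularity statistic
TAMURA_REG_GRID = 4
#: direction co-occurrence shift (pixels) used by line-likeness
TAMURA_LINE_DIST = 4


def _coarseness(px: np.ndarray, kmax: int) -> float:
    h, w = px.shape
    kmax = max(1, min(kmax, int(np.floor(np.log2(min(h, w)))) - 1))
    best = np.zeros((h, w))
    best_k = np.zeros((h, w))
    for k in range(1, kmax + 1):
        size = 2**k
        avg = ndimage.uniform_filter(px, size=size, mode="reflect")
        half = size // 2
        # horizontal and vertical differences between neighborhoods 2**k apart
        eh = np.abs(np.roll(avg, -half, axis=1) - np.roll(avg, half, axis=1))
        ev = np.abs(np.roll(avg, -half, axis=0) - np.roll(avg, half, axis=0))
        e = np.maximum(eh, ev)
        better = e > best
        best = np.where(better, e, best)
        best_k = np.where(better, k, best_k)
    return float((2.0**best_k).mean())


def _contrast(px: np.ndarray) -> float:
    sd = px.std()
    if sd == 0:
        return 0.0
    mu4 = ((px - px.mean()) ** 4).mean()
    kurtosis = mu4 / sd**4
    return float(sd / kurtosis**0.25)


def _gradient_directions(px: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    kh = np.array([[-1, 0, 1], [-1, 0, 1], [-1, 0, 1]], dtype=np.float64)
    dh = ndimage.convolve(px, kh, mode="reflect")
    dv = ndimage.convolve(px, kh.T, mode="reflect")
    mag = (np.abs(dh) + np.abs(dv)) / 2.0
    theta = np.arctan2(dv, dh) + np.pi / 2.0  # [.., ..) folded below
    theta = np.mod(theta, np.pi)
    return mag, theta


def _direction_histogram(px: np.ndarray) -> np.ndarray:
    mag, theta = _gradient_directions(px)
    thresh = np.percentile(mag, TAMURA_DIR_THRESHOLD_PCT)
    sel = mag > max(thresh, 1e-9)
    if not sel.any():
        return np.zeros(TAMURA_DIR_BINS)
    bins = np.minimum((theta[sel] / np.pi * TAMURA_DIR_BINS).astype(int), TAMURA_DIR_BINS - 1)
    hist = np.bincount(bins, minlength=TAMURA_DIR_BINS).astype(np.float64)
    return hist / hist.sum()


def _directionality(px: np.ndarray) -> float:
    """1 minus the normalized angular spread about the dominant direction."""
    hist = _direction_histogram(px)
    if hist.sum() == 0:
        return 0.0
    peak = int(hist.argmax())
    idx = np.arange(TAMURA_DIR_BINS)
    # circular distance in bins to the peak
    dist = np.minimum(np.abs(idx - peak), TAMURA_DIR_BINS - np.abs(idx - peak))
    spread = float((dist**2 * hist).sum())
    max_spread = (TAMURA_DIR_BINS / 2) ** 2
    return float(1.0 - spread / max_spread)


def _line_likeness(px: np.ndarray) -> float:
    """Cosine-weighted co-occurrence of gradient directions at a fixed shift."""
    mag, theta = _gradient_directions(px)
    bins = np.minimum((theta / np.pi * TAMURA_DIR_BINS).astype(int), TAMURA_DIR_BINS - 1)
    d = TAMURA_LINE_DIST
    if px.shape[0] <= d or px.shape[1] <= d:
        return 0.0
    a = bins[:, :-d].ravel()
    b = bins[:, d:].ravel()
    co = np.zeros((TAMURA_DIR_BINS, TAMURA_DIR_BINS))
    np.add.at(co, (a, b), 1.0)
    total = co.sum()
    if total == 0:
        return 0.0
    ii, jj = np.meshgrid(np.arange(TAMURA_DIR_BINS), np.arange(TAMURA_DIR_BINS), indexing="ij")
    return float((co * np.cos((ii - jj) * 2 * np.pi / TAMURA_DIR_BINS)).sum() / total)


def _regularity(px: np.ndarray) -> float:
    """1 - r * (sum of the normalized stds of the other four statistics
    over a 4x4 subimage grid)."""
    h, w = px.shape
    g = TAMURA_REG_GRID
    rows = np.array_split(np.arange(h), g)
    cols = np.array_split(np.arange(w), g)
    feats = []
    for rs in rows:
        for cs in cols:
            sub = px[np.ix_(rs, cs)]
            feats.append(
                [
                    _coarseness(sub, TAMURA_KMAX),
                    _contrast(sub),
                    _directionality(sub),
                    _line_likeness(sub),
                ]
            )
    feats = np.asarray(feats)
    stds = feats.std(axis=0)
    scales = np.maximum(np.abs(feats.mean(axis=0)), 1e-9)
    return float(1.0 - 0.25 * float((stds / scales).sum()))


def tamura_features(channel: Channel) -> np.ndarray:
    """Tamura's six perceptual texture statistics.

    Order: coarseness, contrast, directionality, line-likeness,
    regularity, roughness (= coarseness + contrast).
    """
    px = np.asarray(channel.pixels, dtype=np.float64)
    if px.shape[0] < 32 or px.shape[1] < 32:
        raise ValueError(f"channel {px.shape} too small for Tamura statistics (need >= 32x32)")
    crs = _coarseness(px, TAMURA_KMAX)
    con = _contrast(px)
    dirn = _directionality(px)
    lin = _line_likeness(px)
    reg = _regularity(px)
    rough = crs + con
    return np.array([crs, con, dirn, lin, reg, rough])


def tamura_descriptor(image: RGBImage, mode: "ChannelMode | str" = ChannelMode.RGB_FUSED) -> np.ndarray:
    """Six Tamura statistics per channel: 18 fused, 6 otherwise."""
    return apply_per_channel(image, mode, tamura_features)
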