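"""Image and manifest I/O, channel splitting, grayscale conversion.

Coordinate convention: arrays are row-major, 0-based, indexed (row, col);
image sizes are quoted width x height in prose (a "700x460" image is an
array of shape (460, 700, 3)).
"""

from __future__ import annotations

import os
import re
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Callable, Iterator, Optional, Sequence

import numpy as np
import pandas as pd
from PIL import Image

#: ITU-R BT.601 luma weights for R, G, B.
LUMA_WEIGHTS = (0.299, 0.587, 0.114)

@dataclass(frozen=True)
class SampleMeta:
    """Per-image metadata: who the image belongs to and what it shows."""

    image_id: str
    patient_id: str
    class_label: str  # "benign" | "malignant"
    magnification: str  # "40X" | "100X" | "200X" | "400X"
    subclass: Optional[str] = None

    def __post_init__(self) -> None:
        if self.class_label not in ("benign", "malignant"):
            raise ValueError(f"class_label must be benign/malignant, got {self.class_label!r}")


@dataclass
class RGBImage:
    """An 8-bit three-channel image with its sample metadata."""

    pixels: np.ndarray  # (H, W, 3) uint8
    meta: SampleMeta

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError(f"RGBImage needs an (H, W, 3) array, got shape {self.pixels.shape}")
        if self.pixels.dtype != np.uint8:
            if self.pixels.min() < 0 or self.pixels.max() > 255:
                raise ValueError("intensities must lie in [0, 255]")
            self.pixels = self.pixels.astype(np.uint8)

    @property
    def shape(self) -> tuple:
        return self.pixels.shape


@dataclass
class Channel:
    """A single 2-D intensity plane extracted from an image."""

    pixels: np.ndarray  # (H, W) uint8
    origin: str  # "R" | "G" | "B" | "gray"

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValueError(f"Channel needs a 2-D array, got shape {self.pixels.shape}")

    @property
    def shape(self) -> tuple:
        return self.pixels.shape


class ChannelMode(str, Enum):
    """How an image is turned into channel planes before feature extraction."""

    RGB_FUSED = "rgb"
    GRAY = "gray"
    R = "R"
    G = "G"
    B = "B"

    @classmethod
    def parse(cls, value: "ChannelMode | str") -> "ChannelMode":
        if isinstance(value, cls):
            return value
        for m in cls:
            if m.value.lower() == str(value).lower():
                return m
        raise ValueError(f"unknown channel mode {value!r}")


def split_channels(image: RGBImage) -> tuple[Channel, Channel, Channel]:
    """Split an RGB image into its three planes, in fixed R, G, B order."""
    r, g, b = (image.pixels[:, :, i] for i in range(3))
    return Channel(r, "R"), Channel(g, "G"), Channel(b, "B")


def merge_channels(r: Channel, g: Channel, b: Channel, meta: SampleMeta) -> RGBImage:
    """Inverse of :func:`split_channels`."""
    return RGBImage(np.stack([r.pixels, g.pixels, b.pixels], axis=-1), meta)


def to_gray(image: RGBImage, weights: Sequence[float] = LUMA_WEIGHTS) -> Channel:
    """Luma-weighted grayscale conversion, rounded back to the 8-bit range.

    Default weights are ITU-R BT.601 (0.299, 0.587, 0.114).
    """
    w = np.asarray(weights, dtype=np.float64)
    gray = image.pixels.astype(np.float64) @ w
    gray = np.clip(np.round(gray), 0, 255).astype(np.uint8)
    return Channel(gray, "gray")


def iter_channels(image: RGBImage, mode: "ChannelMode | str") -> Iterator[Channel]:
    """Yield the channel planes a descriptor sees under the given mode.

    rgb_fused yields R, G, B in order; gray yields the luma plane; R/G/B
    yield the single named plane.
    """
    mode = ChannelMode.parse(mode)
    if mode is ChannelMode.RGB_FUSED:
        yield from split_channels(image)
    elif mode is ChannelMode.GRAY:
        yield to_gray(image)
    else:
        idx = {"R": 0, "G": 1, "B": 2}[mode.value]
        yield Channel(image.pixels[:, :, idx], mode.value)


def apply_per_channel(
    image: RGBImage, mode: "ChannelMode | str", fn: Callable[[Channel], np.ndarray]
) -> np.ndarray:
    """Apply a channel-level feature function under a channel mode.

    Under rgb_fused the per-channel vectors are concatenated R, G, B;
    otherwise the single channel's vector is returned.
    """
    parts = [np.atleast_1d(np.asarray(fn(ch), dtype=np.float64)) for ch in iter_channels(image, mode)]
    return np.concatenate(parts)


def parse_breakhis_filename(name: str) -> dict:
    """Parse the BreaKHis filename convention.

    ``SOB_B_TA-14-4659-40-001.png`` ->
    class benign, subclass TA, patient "14-4659", magnification 40X, seq 001.
    The patient field itself may contain hyphens; the trailing two hyphen
    groups are always magnification and sequence number.
    """
    stem = Path(name).stem
    head, _, tail = stem.partition("-")
    m = re.match(r"^(?P<proc>[A-Za-z]+)_(?P<cls>[BM])_(?P<sub>[A-Za-z]+)$", head)
    if m is None:
        raise ValueError(f"not a BreaKHis-style filename: {name!r}")
    parts = tail.split("-")
    if len(parts) < 3:
        raise ValueError(f"not a BreaKHis-style filename: {name!r}")
    mag, seq = parts[-2], parts[-1]
    patient = "-".join(parts[:-2])
    if not mag.isdigit() or not patient:
        raise ValueError(f"not a BreaKHis-style filename: {name!r}")
    return {
        "class_label": "benign" if m.group("cls") == "B" else "malignant",
        "subclass": m.group("sub"),
        "patient_id": patient,
        "magnification": f"{int(mag)}X",
        "sequence": seq,
        "procedure": m.group("proc"),
    }


def read_image(path: "str | os.PathLike", meta: SampleMeta) -> RGBImage:
    """Read a PNG/TIFF/JPEG file as an RGBImage; grayscale files are rejected."""
    with Image.open(path) as im:
        if im.mode == "RGBA":
            im = im.convert("RGB")
        arr = np.asarray(im)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValueError(f"{path}: expected a 3-channel image, got shape {arr.shape}")
    return RGBImage(arr, meta)


def load_manifest(path: "str | os.PathLike") -> list[RGBImage]:
    """Load a manifest CSV and its referenced images.

    The manifest has columns image_path, patient_id, class_label, subclass,
    magnification (relative paths resolved against the manifest's
    directory).  If the metadata columns are absent, each filename must
    follow the BreaKHis convention and is parsed instead.
    """
    path = Path(path)
    df = pd.read_csv(path)
    if "image_path" not in df.columns:
        raise ValueError(f"{path}: manifest must have an image_path column")
    root = path.parent
    images: list[RGBImage] = []
    has_meta = {"patient_id", "class_label", "magnification"}.issubset(df.columns)
    for i, row in df.iterrows():
        img_path = Path(row["image_path"])
        if not img_path.is_absolute():
            img_path = root / img_path
        if not img_path.exists():
            raise FileNotFoundError(f"manifest row {i}: missing image file {img_path}")
        if has_meta:
            meta = SampleMeta(
                image_id=Path(row["image_path"]).stem,
                patient_id=str(row["patient_id"]),
                class_label=str(row["class_label"]),
                subclass=str(row["subclass"]) if "subclass" in df.columns else None,
                magnification=str(row["magnification"]),
            )
        else:
            parsed = parse_breakhis_filename(img_path.name)
            meta = SampleMeta(
                image_id=img_path.stem,
                patient_id=parsed["patient_id"],
                class_label=parsed["class_label"],
                subclass=parsed["subclass"],
                magnification=parsed["magnification"],
            )
        images.append(read_image(img_path, meta))
    return images
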