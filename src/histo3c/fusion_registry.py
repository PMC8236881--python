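"""Descriptor registry, three-channel fusion, and cascade feature fusion.

Each of the ten descriptors has a declared per-channel dimension; under
the rgb_fused mode the per-channel vectors are concatenated in R, G, B
order (three times the per-channel length).  Cross-descriptor fusion is
plain cascade concatenation with no reweighting — any scaling happens
downstream when the classifier is trained.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

from histo3c import glcm_features, filterbank_features, local_texture_features, moment_wavelet_features
from histo3c.image_channels import ChannelMode, RGBImage


@dataclass
class FeatureVector:
    """A named descriptor output with its channel mode and values."""

    descriptor: str
    mode: ChannelMode
    values: np.ndarray
    per_channel_dim: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.mode = ChannelMode.parse(self.mode)
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"{self.descriptor}: non-finite feature values")

    def __len__(self) -> int:
        return self.values.size


@dataclass(frozen=True)
class DescriptorSpec:
    """Registry entry: name, declared per-channel dimension, extractor."""

    name: str
    per_channel_dim: int
    extractor: Callable  # (RGBImage, mode) -> np.ndarray


REGISTRY: dict[str, DescriptorSpec] = {
    spec.name: spec
    for spec in (
        DescriptorSpec("GLCM1", 22, glcm_features.glcm1_descriptor),
        DescriptorSpec("GLCM4", 88, glcm_features.glcm4_descriptor),
        DescriptorSpec("APVEC", 1, moment_wavelet_features.apvec_descriptor),
        DescriptorSpec("HIM", 7, moment_wavelet_features.hu_descriptor),
        DescriptorSpec("Wavelet", 5, moment_wavelet_features.wavelet_descriptor),
        DescriptorSpec("Tamura", 6, local_texture_features.tamura_descriptor),
        DescriptorSpec("LBP", 256, local_texture_features.lbp_image_descriptor),
        DescriptorSpec("CLBP", 20, local_texture_features.clbp_image_descriptor),
        DescriptorSpec("Gabor", 4000, filterbank_features.gabor_image_descriptor),
        DescriptorSpec("Hog", 288, filterbank_features.hog_image_descriptor),
    )
}


def expected_length(spec: DescriptorSpec, mode: "ChannelMode | str") -> int:
    mode = ChannelMode.parse(mode)
    return spec.per_channel_dim * (3 if mode is ChannelMode.RGB_FUSED else 1)


def extract(image: RGBImage, descriptor: "str | DescriptorSpec", mode: "ChannelMode | str" = ChannelMode.RGB_FUSED) -> FeatureVector:
    """Run one registered descriptor on an image under a channel mode."""
    if isinstance(descriptor, str):
        try:
            descriptor = REGISTRY[descriptor]
        except KeyError:
            raise KeyError(f"unknown descriptor {descriptor!r}; known: {sorted(REGISTRY)}") from None
    mode = ChannelMode.parse(mode)
    values = descriptor.extractor(image, mode)
    fv = FeatureVector(descriptor.name, mode, values, descriptor.per_channel_dim)
    expected = expected_length(descriptor, mode)
    if len(fv) != expected:
        raise AssertionError(
            f"{descriptor.name} ({mode.value}): got {len(fv)} values, declared {expected}"
        )
    return fv


def fuse_descriptors(vectors: Sequence[FeatureVector]) -> FeatureVector:
    """Cascade-fuse feature vectors from the same image and mode.

    The result's name records the order (e.g. ``GLCM1+APVEC``); its length
    is the sum of the parts.
    """
    if not vectors:
        raise ValueError("nothing to fuse")
    modes = {v.mode for v in vectors}
    if len(modes) > 1:
        raise ValueError(f"cannot fuse mixed channel modes: {sorted(m.value for m in modes)}")
    name = "+".join(v.descriptor for v in vectors)
    values = np.concatenate([v.values for v in vectors])
    dim = sum(v.per_channel_dim for v in vectors)
    return FeatureVector(name, vectors[0].mode, values, dim)


def audit_registry(probe: RGBImage) -> dict[str, int]:
    """Check every descriptor's actual output length against its declared
    dimension on a probe image; returns {name: per-channel length}."""
    lengths = {}
    for spec in REGISTRY.values():
        fv = extract(probe, spec, ChannelMode.GRAY)
        if len(fv) != spec.per_channel_dim:
            raise AssertionError(
                f"{spec.name}: declared {spec.per_channel_dim}, measured {len(fv)}"
            )
        lengths[spec.name] = len(fv)
    return lengths


_META_COLUMNS = ("image_id", "patient_id", "class_label", "magnification")


def extract_table(
    images: Iterable[RGBImage],
    descriptor: "str | DescriptorSpec",
    mode: "ChannelMode | str" = ChannelMode.RGB_FUSED,
) -> pd.DataFrame:
    """Feature matrix for a dataset: metadata columns then f_000, f_001, ...

    Rows are sorted by image_id so downstream model fits see a fixed order.
    """
    rows = []
    for image in images:
        fv = extract(image, descriptor, mode)
        rows.append((image.meta, fv.values))
    if not rows:
        raise ValueError("no images to extract features from")
    n_feat = rows[0][1].size
    cols = [f"f_{i:03d}" for i in range(n_feat)]
    df = pd.DataFrame(
        [
            {
                "image_id": meta.image_id,
                "patient_id": meta.patient_id,
                "class_label": meta.class_label,
                "magnification": meta.magnification,
                **dict(zip(cols, values)),
            }
            for meta, values in rows
        ]
    )
    return df.sort_values("image_id", ignore_index=True)


def feature_columns(table: pd.DataFrame) -> list[str]:
    return [c for c in table.columns if c.startswith("f_")]


def fuse_tables(tables: Sequence[pd.DataFrame]) -> pd.DataFrame:
    """Cascade-fuse per-descriptor feature tables row-wise by image_id."""
    if not tables:
        raise ValueError("nothing to fuse")
    base = tables[0][list(_META_COLUMNS)].copy()
    blocks = []
    offset = 0
    for t in tables:
        t = t.sort_values("image_id", ignore_index=True)
        if not t["image_id"].equals(base["image_id"]):
            raise ValueError("feature tables cover different images")
        fcols = feature_columns(t)
        block = t[fcols].to_numpy()
        blocks.append(
            pd.DataFrame(block, columns=[f"f_{offset + i:03d}" for i in range(block.shape[1])])
        )
        offset += block.shape[1]
    return pd.concat([base] + blocks, axis=1)


def dataset_hash(images: Sequence[RGBImage]) -> str:
    """Stable short hash of image ids and pixel content, for cache keys."""
    h = hashlib.sha256()
    for image in sorted(images, key=lambda im: im.meta.image_id):
        h.update(image.meta.image_id.encode())
        h.update(image.pixels.tobytes())
    return h.hexdigest()[:16]


def save_table(table: pd.DataFrame, path: "str | Path") -> None:
    table.to_csv(path, index=False)


def load_table(path: "str | Path") -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"image_id": str, "patient_id": str})
    missing = [c for c in _META_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: feature table missing columns {missing}")
    return df


def cached_extract_table(
    images: Sequence[RGBImage],
    descriptor: "str | DescriptorSpec",
    mode: "ChannelMode | str",
    cache_dir: "str | Path",
) -> pd.DataFrame:
    """extract_table with a CSV cache keyed by (descriptor, mode, dataset hash)."""
    name = descriptor if isinstance(descriptor, str) else descriptor.name
    mode = ChannelMode.parse(mode)
    cache_dir = Path(cache_dir)
    cache_dir.mkdir(parents=True, exist_ok=True)
    key = f"{name}_{mode.value}_{dataset_hash(images)}.csv"
    path = cache_dir / key
    if path.exists():
        return load_table(path)
    table = extract_table(images, descriptor, mode)
    save_table(table, path)
    return table
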