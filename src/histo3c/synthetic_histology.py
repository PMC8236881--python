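"""Seeded generator of H&E-like patient-grouped RGB images.

The generator emulates the structure of a benign/malignant breast-tumor
histology archive: every patient is wholly benign or malignant, each
patient contributes several images per magnification, and the two classes
differ in nuclear texture (benign: sparse, large, low-contrast elliptical
nucleus blobs on a pink eosin-dominated background; malignant: dense,
small, high-contrast blue-purple blobs) and in stain chroma (the
hematoxylin/eosin balance).

Two knobs control where the class signal lives:

* ``class_effect`` scales the overall benign/malignant separation; at 0
  both classes are drawn from one distribution.
* ``chroma_effect`` moves the signal from luminance into hue: the
  structural (luminance-visible) separation is scaled by
  ``1 / (1 + chroma_effect)`` while a luma-orthogonal color shift grows
  with ``class_effect * chroma_effect``.  With a large ``chroma_effect``
  the classes are nearly indistinguishable in grayscale but well
  separated in RGB.

Patients carry their own random offsets (stain tint, cell density and
size), so images of one patient are correlated and patient-disjoint
splitting actually matters.  Magnification is simulated purely as a
nucleus-size scale factor.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from PIL import Image
from skimage.draw import ellipse

from histo3c.image_channels import RGBImage, SampleMeta

#: benign and malignant subclass codes, assigned round-robin to patients
BENIGN_SUBCLASSES = ("A", "F", "PT", "TA")
MALIGNANT_SUBCLASSES = ("DC", "LC", "MC", "PC")

#: magnification -> nucleus-size scale factor
MAG_SCALE = {"40X": 0.6, "100X": 1.0, "200X": 1.5, "400X": 2.4}

# H&E palette (R, G, B): eosin-pink background, hematoxylin blue-purple nuclei
_BG_COLOR = np.array([232.0, 190.0, 205.0])
_NUCLEUS_COLOR = np.array([120.0, 95.0, 165.0])
#: luma-orthogonal direction of the chroma shift (BT.601 weights give it
#: exactly zero luminance: 0.299*1 + 0.587*(-0.299/0.587) = 0)
_CHROMA_DIR = np.array([1.0, -0.299 / 0.587, 0.0])
_CHROMA_STEP = 1.2  # intensity units per unit of class_effect * chroma_effect
_CHROMA_CAP = 45.0

# base morphology on a 460x700 field at scale 1.0
_BLOB_AREA_PER_NUCLEUS = 4500.0
_BASE_RADIUS = 9.0
_BASE_OPACITY = 0.75

# patient-level variation (log-sd for multiplicative, sd for additive)
_PATIENT_TINT_SD = 3.0
_PATIENT_DENSITY_LOG_SD = 0.15
_PATIENT_RADIUS_LOG_SD = 0.08


@dataclass(frozen=True)
class SynthConfig:
    """Dataset-level generator settings (the defaults are the desk-scale
    study conditions: 6 benign / 14 malignant patients, 10 images each)."""

    n_patients_benign: int = 6
    n_patients_malignant: int = 14
    images_per_patient: int = 10
    image_height: int = 460
    image_width: int = 700
    magnifications: tuple = ("200X",)
    class_effect: float = 3.0
    chroma_effect: float = 1.0
    noise_sd: float = 8.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_patients_benign", "n_patients_malignant", "images_per_patient"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.image_height < 64 or self.image_width < 64:
            raise ValueError("image dimensions must be >= 64")
        if self.class_effect < 0 or self.chroma_effect < 0 or self.noise_sd < 0:
            raise ValueError("effects and noise_sd must be >= 0")
        bad = [m for m in self.magnifications if m not in MAG_SCALE]
        if bad:
            raise ValueError(f"unknown magnifications {bad}; known: {sorted(MAG_SCALE)}")
        object.__setattr__(self, "magnifications", tuple(self.magnifications))


def chroma_demo_config(**overrides) -> SynthConfig:
    """Defaults with the class signal pushed almost entirely into hue."""
    params = dict(chroma_effect=8.0)
    params.update(overrides)
    return SynthConfig(**params)


def _class_params(config: SynthConfig, class_label: str) -> dict:
    """Blob-model parameters for one class under the two effect knobs."""
    sign = 1.0 if class_label == "malignant" else -1.0
    t_lum = config.class_effect / (1.0 + config.chroma_effect)
    t_chroma = config.class_effect * config.chroma_effect
    shift = np.clip(sign * t_chroma * _CHROMA_STEP, -_CHROMA_CAP, _CHROMA_CAP)
    return {
        "density_mult": max(0.1, 1.0 + 0.25 * sign * t_lum),
        "radius_mult": max(0.3, 1.0 - 0.15 * sign * t_lum),
        "opacity": float(np.clip(_BASE_OPACITY * (1.0 + 0.20 * sign * t_lum), 0.05, 1.0)),
        "nucleus_color": _NUCLEUS_COLOR + shift * _CHROMA_DIR,
        "bg_color": _BG_COLOR + 0.4 * shift * _CHROMA_DIR,
    }


def _render_image(
    rng: np.random.Generator, config: SynthConfig, params: dict, patient: dict, mag: str
) -> np.ndarray:
    h, w = config.image_height, config.image_width
    scale = MAG_SCALE[mag]
    img = np.empty((h, w, 3), dtype=np.float64)
    img[:] = params["bg_color"] + patient["tint"]

    n_blobs = max(
        1,
        int(
            round(
                h * w / (_BLOB_AREA_PER_NUCLEUS * scale**2)
                * params["density_mult"]
                * patient["density_mult"]
            )
        ),
    )
    radius = _BASE_RADIUS * scale * params["radius_mult"] * patient["radius_mult"]
    color = params["nucleus_color"] + patient["tint"]
    for _ in range(n_blobs):
        rc = rng.uniform(0, h)
        cc = rng.uniform(0, w)
        rr = radius * rng.lognormal(0.0, 0.2)
        elong = rng.uniform(0.6, 1.0)
        rot = rng.uniform(0, np.pi)
        rows, cols = ellipse(rc, cc, rr, rr * elong, shape=(h, w), rotation=rot)
        if rows.size == 0:
            continue
        a = params["opacity"] * rng.uniform(0.85, 1.0)
        blob_color = color + rng.normal(0.0, 4.0, size=3)
        img[rows, cols] = (1.0 - a) * img[rows, cols] + a * blob_color

    if config.noise_sd > 0:
        img += rng.normal(0.0, config.noise_sd, size=img.shape)
    return np.clip(np.round(img), 0, 255).astype(np.uint8)


def generate_dataset(config: SynthConfig) -> list[RGBImage]:
    """Generate the full patient-grouped dataset for a configuration.

    Returns n_patients * images_per_patient * len(magnifications) images;
    bit-identical for identical configurations (including the seed).
    """
    images: list[RGBImage] = []
    specs = [("benign", "B", config.n_patients_benign, BENIGN_SUBCLASSES, 1000),
             ("malignant", "M", config.n_patients_malignant, MALIGNANT_SUBCLASSES, 2000)]
    patient_index = 0
    for class_label, _code, n_patients, subclasses, base_id in specs:
        params = _class_params(config, class_label)
        for i in range(n_patients):
            patient_rng = np.random.default_rng(
                np.random.SeedSequence((config.seed, patient_index))
            )
            patient = {
                "tint": patient_rng.normal(0.0, _PATIENT_TINT_SD, size=3),
                "density_mult": patient_rng.lognormal(0.0, _PATIENT_DENSITY_LOG_SD),
                "radius_mult": patient_rng.lognormal(0.0, _PATIENT_RADIUS_LOG_SD),
            }
            patient_id = f"14-{base_id + i}"
            subclass = subclasses[i % len(subclasses)]
            for mag_index, mag in enumerate(config.magnifications):
                mag_num = mag.rstrip("X")
                for j in range(config.images_per_patient):
                    image_rng = np.random.default_rng(
                        np.random.SeedSequence((config.seed, patient_index, mag_index, j))
                    )
                    pixels = _render_image(image_rng, config, params, patient, mag)
                    image_id = f"SOB_{_code}_{subclass}-{patient_id}-{mag_num}-{j + 1:03d}"
                    meta = SampleMeta(
                        image_id=image_id,
                        patient_id=patient_id,
                        class_label=class_label,
                        subclass=subclass,
                        magnification=mag,
                    )
                    images.append(RGBImage(pixels, meta))
            patient_index += 1
    return images


def write_breakhis_tree(dataset: Sequence[RGBImage], root_path: "str | Path") -> Path:
    """Write a dataset as PNGs in a class/subclass/patient/magnification
    tree with BreaKHis-style filenames, plus a CSV manifest.

    Returns the manifest path.  Round-trips through
    :func:`histo3c.image_channels.load_manifest`.
    """
    if not dataset:
        raise ValueError("empty dataset: nothing to write")
    root = Path(root_path)
    root.mkdir(parents=True, exist_ok=True)
    manifest_path = root / "manifest.csv"
    rows = []
    for image in dataset:
        m = image.meta
        rel = Path(m.class_label) / (m.subclass or "NA") / m.patient_id / m.magnification / f"{m.image_id}.png"
        out = root / rel
        out.parent.mkdir(parents=True, exist_ok=True)
        Image.fromarray(image.pixels).save(out)
        rows.append(
            {
                "image_path": str(rel),
                "patient_id": m.patient_id,
                "class_label": m.class_label,
                "subclass": m.subclass or "",
                "magnification": m.magnification,
            }
        )
    with open(manifest_path, "w", newline="") as fh:
        writer = csv.DictWriter(
            fh, fieldnames=["image_path", "patient_id", "class_label", "subclass", "magnification"]
        )
        writer.writeheader()
        writer.writerows(rows)
    return manifest_path
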