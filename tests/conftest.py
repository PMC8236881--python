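import numpy as np
import pytest

from histo3c.image_channels import Channel, RGBImage, SampleMeta
from histo3c.synthetic_histology import SynthConfig, generate_dataset


def make_meta(image_id="img-0", patient_id="14-1000", class_label="benign",
              magnification="200X", subclass="TA"):
    return SampleMeta(image_id, patient_id, class_label, magnification, subclass)


def make_image(pixels, **meta_kwargs):
    return RGBImage(np.asarray(pixels, dtype=np.uint8), make_meta(**meta_kwargs))


def constant_image(r, g, b, shape=(32, 32)):
    px = np.empty(shape + (3,), dtype=np.uint8)
    px[..., 0], px[..., 1], px[..., 2] = r, g, b
    return make_image(px)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def probe_image():
    """A single full-size (700 wide x 460 tall) synthetic probe image."""
    cfg = SynthConfig(n_patients_benign=1, n_patients_malignant=1,
                      images_per_patient=1, seed=42)
    return generate_dataset(cfg)[0]


@pytest.fixture(scope="session")
def random_channel(rng):
    return Channel(rng.integers(0, 256, (48, 48), dtype=np.uint8).astype(np.uint8), "gray")


@pytest.fixture(scope="session")
def small_dataset():
    """A small patient-grouped dataset for protocol tests (12 patients)."""
    cfg = SynthConfig(n_patients_benign=4, n_patients_malignant=8,
                      images_per_patient=4, image_height=160, image_width=160,
                      seed=0)
    return generate_dataset(cfg)
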