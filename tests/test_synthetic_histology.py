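import numpy as np
import pytest

from histo3c.fusion_registry import extract_table
from histo3c.evaluation import run_experiment
from histo3c.synthetic_histology import (
    MAG_SCALE,
    SynthConfig,
    chroma_demo_config,
    generate_dataset,
    write_breakhis_tree,
)


def small(**overrides):
    base = dict(n_patients_benign=2, n_patients_malignant=3, images_per_patient=2,
                image_height=64, image_width=64, seed=7)
    base.update(overrides)
    return SynthConfig(**base)


class TestConfig:
    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            SynthConfig(n_patients_benign=0)
        with pytest.raises(ValueError):
            SynthConfig(image_height=32)
        with pytest.raises(ValueError):
            SynthConfig(class_effect=-1)
        with pytest.raises(ValueError):
            SynthConfig(magnifications=("10X",))


class TestGeneration:
    def test_dataset_size_and_shape(self):
        cfg = small(magnifications=("40X", "400X"))
        ds = generate_dataset(cfg)
        assert len(ds) == 5 * 2 * 2  # patients x images x magnifications
        for im in ds:
            assert im.pixels.shape == (64, 64, 3)
            assert im.pixels.dtype == np.uint8

    def test_full_size_images_are_700_by_460(self):
        cfg = SynthConfig(n_patients_benign=1, n_patients_malignant=1,
                          images_per_patient=1, class_effect=3.0, seed=1)
        for im in generate_dataset(cfg):
            assert im.pixels.shape == (460, 700, 3)  # 700 wide x 460 tall

    def test_determinism(self):
        a = generate_dataset(small())
        b = generate_dataset(small())
        assert len(a) == len(b)
        for x, y in zip(a, b):
            assert x.meta == y.meta
            assert np.array_equal(x.pixels, y.pixels)

    def test_seed_changes_pixels(self):
        a = generate_dataset(small(seed=7))[0]
        b = generate_dataset(small(seed=8))[0]
        assert not np.array_equal(a.pixels, b.pixels)

    def test_patient_maps_to_one_class_and_ids_unique(self):
        ds = generate_dataset(small(images_per_patient=3))
        ids = [im.meta.image_id for im in ds]
        assert len(set(ids)) == len(ids)
        by_patient = {}
        for im in ds:
            by_patient.setdefault(im.meta.patient_id, set()).add(im.meta.class_label)
        assert all(len(v) == 1 for v in by_patient.values())

    def test_magnification_scales_blob_size(self):
        """Higher magnification means fewer, larger nuclei in the field,
        hence less edge per unit area."""
        assert MAG_SCALE["400X"] > MAG_SCALE["40X"]
        base = dict(n_patients_benign=3, n_patients_malignant=3, images_per_patient=2,
                    image_height=256, image_width=256, noise_sd=0.0, seed=7)
        cfg40 = SynthConfig(magnifications=("40X",), **base)
        cfg400 = SynthConfig(magnifications=("400X",), **base)
        def mean_abs_gradient(ds):
            return float(np.mean([np.abs(np.diff(im.pixels[..., 0].astype(float), axis=1)).mean()
                                  for im in ds]))
        assert mean_abs_gradient(generate_dataset(cfg40)) > mean_abs_gradient(generate_dataset(cfg400))

    def test_null_effect_classes_indistinguishable(self):
        """With both effects at 0, a label permutation test on the mean
        red intensity finds no separation beyond chance."""
        cfg = SynthConfig(n_patients_benign=10, n_patients_malignant=10,
                          images_per_patient=2, image_height=64, image_width=64,
                          class_effect=0.0, chroma_effect=0.0, seed=11)
        ds = generate_dataset(cfg)
        vals = np.array([im.pixels[..., 0].mean() for im in ds])
        labels = np.array([im.meta.class_label == "malignant" for im in ds])
        observed = abs(vals[labels].mean() - vals[~labels].mean())
        rng = np.random.default_rng(0)
        null = []
        for _ in range(500):
            perm = rng.permutation(labels)
            null.append(abs(vals[perm].mean() - vals[~perm].mean()))
        p = (np.sum(np.asarray(null) >= observed) + 1) / 501
        assert p > 0.01

    def test_malignant_denser_higher_contrast(self):
        """At a strong class effect malignant images carry many small,
        opaque blue-purple nuclei: more dark pixels and higher
        within-image variance than the sparse, faint benign pattern."""
        cfg = SynthConfig(n_patients_benign=3, n_patients_malignant=3,
                          images_per_patient=2, image_height=256, image_width=256,
                          class_effect=3.0, chroma_effect=0.0, seed=7)
        ds = generate_dataset(cfg)
        def per_class(fn):
            return {c: float(np.mean([fn(im) for im in ds if im.meta.class_label == c]))
                    for c in ("benign", "malignant")}
        var = per_class(lambda im: im.pixels[..., 0].var())
        dark = per_class(lambda im: (im.pixels[..., 1] < 150).mean())
        assert var["malignant"] > var["benign"]
        assert dark["malignant"] > dark["benign"]


class TestWriter:
    def test_tree_layout_and_counts(self, tmp_path):
        cfg = small(n_patients_benign=1, n_patients_malignant=1, images_per_patient=1)
        ds = generate_dataset(cfg)
        manifest = write_breakhis_tree(ds, tmp_path)
        pngs = sorted(tmp_path.rglob("*.png"))
        assert len(pngs) == 2
        lines = manifest.read_text().splitlines()
        assert lines[0] == "image_path,patient_id,class_label,subclass,magnification"
        assert len(lines) == 3
        # layout: class/subclass/patient/magnification/file
        rel = pngs[0].relative_to(tmp_path)
        assert rel.parts[0] in ("benign", "malignant")
        assert len(rel.parts) == 5

    def test_empty_dataset_errors_without_writing(self, tmp_path):
        out = tmp_path / "tree"
        with pytest.raises(ValueError):
            write_breakhis_tree([], out)
        assert not out.exists()


class TestSeparability:
    def test_accuracy_monotone_in_class_effect(self):
        """Image-level GLCM1+SVM accuracy does not decrease over
        class_effect in {0, 1, 3} (within trial noise)."""
        accs = []
        for effect in (0.0, 1.0, 3.0):
            cfg = SynthConfig(n_patients_benign=4, n_patients_malignant=8,
                              images_per_patient=4, image_height=160, image_width=160,
                              class_effect=effect, seed=0)
            table = extract_table(generate_dataset(cfg), "GLCM1", "rgb")
            report = run_experiment(table, seed=0)
            accs.append(float(report[report.metric == "image_accuracy"]["mean"].iloc[0]))
        assert accs[1] >= accs[0] - 0.05
        assert accs[2] >= accs[1] - 0.05
        assert accs[2] > accs[0]

    def test_chroma_signal_lives_in_hue_not_luminance(self):
        """With a high chroma effect, three-channel APVEC separates the
        classes while grayscale APVEC stays near the majority rate."""
        cfg = chroma_demo_config(n_patients_benign=6, n_patients_malignant=14,
                                 images_per_patient=4, image_height=160, image_width=160,
                                 seed=0)
        ds = generate_dataset(cfg)
        accs = {}
        for mode in ("rgb", "gray"):
            report = run_experiment(extract_table(ds, "APVEC", mode), seed=0)
            accs[mode] = float(report[report.metric == "image_accuracy"]["mean"].iloc[0])
        assert accs["rgb"] - accs["gray"] >= 0.10
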