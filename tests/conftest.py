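"""Shared fixtures: every test input is generated programmatically."""

from __future__ import annotations

import numpy as np
import pytest

from icdetect import slide_io, synthetic
from icdetect.synthetic import REFERENCE_STYLE, SyntheticSlideSpec


def square(x0: float, y0: float, side: float) -> np.ndarray:
    return np.array(
        [[x0, y0], [x0 + side, y0], [x0 + side, y0 + side], [x0, y0 + side]], dtype=float
    )


@pytest.fixture(scope="session")
def ref_style():
    return REFERENCE_STYLE


@pytest.fixture(scope="session")
def random_slide(ref_style):
    """A 2048px slide with three epithelial blobs, one hosting an IC region."""
    spec = synthetic.random_slide_spec(
        2048, 2048, with_ic=True, epithelial_area_fraction=0.1, seed=5
    )
    pyramid, annotations = synthetic.generate_slide(spec, ref_style, "random5")
    return spec, pyramid, annotations


@pytest.fixture(scope="session")
def square_slide(ref_style):
    """A slide with one grid-aligned 768x768 epithelial square in tissue."""
    spec = SyntheticSlideSpec(
        width_px=2048,
        height_px=2048,
        tissue_polygons=[square(128, 128, 1792)],
        epithelial_polygons=[square(512, 512, 768)],
        epithelial_area_fraction=0.18,
        seed=11,
    )
    pyramid, annotations = synthetic.generate_slide(spec, ref_style, "square11")
    return spec, pyramid, annotations


@pytest.fixture(scope="session")
def background_slide(ref_style):
    spec = SyntheticSlideSpec(width_px=1024, height_px=1024, seed=0)
    pyramid, _ = synthetic.generate_slide(spec, ref_style, "blank")
    return pyramid


@pytest.fixture(scope="session")
def uniform_slide():
    level0 = np.full((1024, 1024, 3), 200, dtype=np.uint8)
    return slide_io.pyramid_from_array(level0, "uniform", 0.44)


@pytest.fixture(scope="session")
def cohort_dir(tmp_path_factory, ref_style):
    """A small on-disk cohort: 3 patients x 2 slides at 1024px."""
    out = tmp_path_factory.mktemp("cohort")
    cohort = synthetic.generate_cohort(
        n_patients=3,
        slides_per_patient=2,
        ic_slide_fraction=0.5,
        epithelial_area_fraction=0.1,
        style=ref_style,
        seed=21,
        out_dir=out,
        slide_size=1024,
    )
    return out, cohort


@pytest.fixture(scope="session")
def toy_set():
    """A linearly separable two-color toy set (red = IC, green = Rest)."""
    rng = np.random.default_rng(7)

    def make(n):
        y = rng.integers(0, 2, n)
        x = np.zeros((n, 64, 64, 3), np.uint8)
        x[y == 1, :, :, 0] = 200
        x[y == 0, :, :, 1] = 200
        x = np.clip(x.astype(np.int64) + rng.normal(0, 10, x.shape), 0, 255).astype(np.uint8)
        return x, y

    return make(200), make(100)


@pytest.fixture(scope="session")
def fixture_bundle(ref_style):
    """A small classifier trained on extracted x5 patches of a dedicated
    epithelium-rich training cohort; used by the end-to-end slide tests."""
    from icdetect import filtering, pipeline
    from icdetect.classifier import TrainConfig, train_bundle
    from icdetect.scoring import select_threshold

    images, labels = [], []
    for seed in range(8):
        spec = synthetic.random_slide_spec(
            2048,
            2048,
            with_ic=(seed % 2 == 0),
            epithelial_area_fraction=0.35,
            n_epithelial=3,
            seed=100 + seed,
        )
        pyramid, anns = synthetic.generate_slide(spec, ref_style, f"train{seed}")
        x, y, _ = pipeline.extract_slide_dataset(pyramid, anns)
        if len(y):
            images.append(x)
            labels.append(y)
    x = np.concatenate(images)
    y = np.concatenate(labels)
    n_val = max(8, len(y) // 5)
    cfg = TrainConfig(max_epochs=6, es_patience=2, seed=3)
    bundle = train_bundle(x[n_val:], y[n_val:], x[:n_val], y[:n_val], cfg)
    if bundle.p0 is None:  # val slice single-class: fall back to a fixed P0
        bundle.p0 = 0.5
    bundle.slide_threshold = 0.1
    return bundle
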