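import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_n_sample():
    """A healthy-eye synthetic crop (image, disc mask, cup mask, spec)."""
    from glaupie.synthetic_fundus import generate_fundus, spec_for_label

    spec = spec_for_label("N", seed=7, image_size=224, disc_radius=50.0)
    image, disc, cup = generate_fundus(spec)
    return image, disc, cup, spec


@pytest.fixture(scope="session")
def od_os_twins():
    """Mirror-pair synthetic crops generated from the same seed."""
    from glaupie.synthetic_fundus import generate_fundus, spec_for_label

    od = generate_fundus(spec_for_label("G", seed=11, image_size=160, disc_radius=36.0))
    os_ = generate_fundus(
        spec_for_label("G", seed=11, image_size=160, disc_radius=36.0, eye_side="OS")
    )
    return od, os_


@pytest.fixture()
def tiny_manifest():
    """In-memory manifest of 24 separable images (bright G vs dark N)."""
    rng = np.random.default_rng(42)
    images, labels = [], []
    for i in range(24):
        bright = i % 2 == 0
        base = 0.75 if bright else 0.25
        images.append(np.clip(rng.normal(base, 0.05, (32, 32, 3)), 0, 1))
        labels.append("G" if bright else "N")
    manifest = pd.DataFrame({
        "path": [f"mem_{i}" for i in range(24)],
        "label": labels,
        "eye_side": ["OD"] * 24,
        "agreement": ["3/3"] * 24,
        "split": ["train"] * 24,
    })
    return manifest, np.stack(images)


@pytest.fixture(scope="session")
def tiny_train_config():
    from glaupie.classifier_harness import TrainConfig

    return TrainConfig(backbone="tiny", epochs=6, batch_size=8, folds=1,
                       seed=0, input_size=32, patch_size=8)
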