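import numpy as np
import pytest

from petreid import SynthConfig, generate_dataset, generate_profiles


@pytest.fixture(scope="session")
def small_dataset():
    """12 identities x 3-4 photos with moderately informative modalities."""
    cfg = SynthConfig(n_identities=12, min_photos=3, max_photos=4, seed=5)
    manifest, vision, text = generate_dataset(cfg)
    return cfg, manifest, vision, text


@pytest.fixture(scope="session")
def small_profiles(small_dataset):
    cfg, _, _, _ = small_dataset
    return generate_profiles(cfg)


@pytest.fixture(scope="session")
def toy_images(small_dataset, small_profiles):
    """photo_id -> rendered toy image for the small dataset."""
    from petreid import render_toy_image

    cfg, manifest, _, _ = small_dataset
    by_id = {p.identity_id: p for p in small_profiles}
    images = {}
    for rec in manifest.records:
        j = int(rec.photo_id.rsplit("_p", 1)[1])
        images[rec.photo_id] = render_toy_image(by_id[rec.identity_id], j, cfg.seed)
    return images


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
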