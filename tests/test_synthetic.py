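"""Properties of the synthetic multimodal pet-data generator."""

import numpy as np
import pytest

from petreid import (
    SynthConfig,
    generate_dataset,
    generate_profiles,
    render_description,
    render_toy_image,
    topk_accuracy,
)
from petreid.errors import ConfigError, ValidationError
from petreid.synthetic import ATTRIBUTE_VOCABULARIES


class TestConfig:
    def test_single_identity_rejected(self):
        with pytest.raises(ConfigError, match="negatives"):
            SynthConfig(n_identities=1)

    def test_informativeness_bounds(self):
        with pytest.raises(ConfigError):
            SynthConfig(vision_informativeness=1.5)


class TestGeneration:
    def test_seeded_determinism(self):
        cfg = SynthConfig(n_identities=8, seed=3)
        m1, v1, t1 = generate_dataset(cfg)
        m2, v2, t2 = generate_dataset(cfg)
        assert [r.photo_id for r in m1] == [r.photo_id for r in m2]
        assert [r.description for r in m1] == [r.description for r in m2]
        for pid in v1.vectors:
            np.testing.assert_array_equal(v1[pid], v2[pid])
            np.testing.assert_array_equal(t1[pid], t2[pid])

    def test_count_arithmetic(self):
        cfg = SynthConfig(n_identities=50, min_photos=4, max_photos=4, seed=0)
        manifest, vision, text = generate_dataset(cfg)
        assert len(manifest) == 200
        assert len(vision) == 200 and len(text) == 200

    def test_photo_counts_within_configured_range(self):
        cfg = SynthConfig(n_identities=40, min_photos=2, max_photos=10, seed=1)
        manifest, _, _ = generate_dataset(cfg)
        counts = [len(v) for v in manifest.photos_by_identity().values()]
        assert min(counts) >= 2 and max(counts) <= 10

    def test_fully_informative_noiseless_embeddings_equal_prototypes(self):
        cfg = SynthConfig(n_identities=5, vision_informativeness=1.0,
                          text_informativeness=1.0, noise_scale=0.0, seed=2)
        manifest, vision, text = generate_dataset(cfg)
        prototypes = {p.identity_id: p.prototypes for p in generate_profiles(cfg)}
        for rec in manifest.records:
            np.testing.assert_allclose(vision[rec.photo_id],
                                       prototypes[rec.identity_id]["vision"], atol=1e-12)
            np.testing.assert_allclose(text[rec.photo_id],
                                       prototypes[rec.identity_id]["text"], atol=1e-12)

    def test_generated_manifest_passes_validation(self):
        # DatasetManifest construction enforces the invariants; embeddings resolve.
        cfg = SynthConfig(n_identities=10, seed=7)
        manifest, vision, text = generate_dataset(cfg)
        vision.check_against(manifest)
        text.check_against(manifest)

    def test_uninformative_text_is_at_chance(self):
        """rho_t = 0: text-only leave-one-out Top-1 sits at ~1/n_identities."""
        n_id, accs = 100, []
        for seed in range(10):
            cfg = SynthConfig(n_identities=n_id, min_photos=2, max_photos=4,
                              text_informativeness=0.0, seed=seed)
            manifest, _, text = generate_dataset(cfg)
            acc, _, _ = topk_accuracy(manifest=manifest, embeddings=text, ks=(1,))
            accs.append(acc[1])
        chance = 1.0 / n_id
        se = np.std(accs, ddof=1) / np.sqrt(len(accs))
        assert abs(np.mean(accs) - chance) <= 3 * max(se, 1e-3)

    @pytest.mark.parametrize("modality", ["vision", "text"])
    def test_informativeness_monotonicity(self, modality):
        """Single-modality Top-1 is non-decreasing in that modality's rho."""
        means = []
        for rho in (0.0, 0.5, 1.0):
            accs = []
            for seed in range(5):
                kwargs = {f"{modality}_informativeness": rho}
                cfg = SynthConfig(n_identities=25, min_photos=3, max_photos=3,
                                  noise_scale=0.05, seed=seed, **kwargs)
                manifest, vision, text = generate_dataset(cfg)
                emb = vision if modality == "vision" else text
                acc, _, _ = topk_accuracy(emb, manifest, ks=(1,))
                accs.append(acc[1])
            means.append(np.mean(accs))
        assert means[0] <= means[1] <= means[2]
        assert means[2] == 1.0  # rho = 1, tiny noise: perfectly separable


class TestDescriptions:
    def test_template_mentions_all_tokens_once(self, small_profiles):
        profile = small_profiles[0]
        text = render_description(profile)
        assert text.count(profile.species) == 1
        for value in profile.attributes.values():
            assert text.count(value) == 1

    def test_template_locality_in_coat_color(self, small_profiles):
        import dataclasses

        p1 = small_profiles[0]
        other_color = next(c for c in ATTRIBUTE_VOCABULARIES["coat_color"]
                           if c != p1.attributes["coat_color"])
        p2 = dataclasses.replace(p1, attributes={**p1.attributes, "coat_color": other_color})
        d1, d2 = render_description(p1), render_description(p2)
        assert d1 != d2
        assert d1.replace(p1.attributes["coat_color"], "#") == \
               d2.replace(other_color, "#")

    def test_rendering_is_deterministic(self, small_profiles):
        assert render_description(small_profiles[3]) == render_description(small_profiles[3])

    def test_missing_attribute_is_error(self, small_profiles):
        import dataclasses

        attrs = dict(small_profiles[0].attributes)
        attrs.pop("mark")
        broken = dataclasses.replace(small_profiles[0], attributes=attrs)
        with pytest.raises(ValidationError, match="mark"):
            render_description(broken)


class TestToyImages:
    def test_pixel_determinism(self, small_profiles):
        a = render_toy_image(small_profiles[0], 1, seed=9)
        b = render_toy_image(small_profiles[0], 1, seed=9)
        np.testing.assert_array_equal(a, b)

    def test_jittered_photos_share_dominant_color_bin(self, small_profiles):
        """Two photos of one identity differ but agree on the modal color bin."""
        profile = small_profiles[1]
        a = render_toy_image(profile, 0, seed=9)
        b = render_toy_image(profile, 1, seed=9)
        assert not np.array_equal(a, b)

        def dominant_bin(img):
            quantized = (img // 64).reshape(-1, 3)
            codes = quantized[:, 0] * 16 + quantized[:, 1] * 4 + quantized[:, 2]
            return np.bincount(codes).argmax()

        assert dominant_bin(a) == dominant_bin(b)

    def test_coat_color_changes_dominant_channel(self, small_profiles):
        import dataclasses

        base = dataclasses.replace(
            small_profiles[0],
            attributes={**small_profiles[0].attributes,
                        "coat_color": "black", "pattern": "solid", "size": "large"},
        )
        ginger = dataclasses.replace(
            base, attributes={**base.attributes, "coat_color": "ginger"})
        img_black = render_toy_image(base, 0, seed=4).astype(float)
        img_ginger = render_toy_image(ginger, 0, seed=4).astype(float)
        # ginger is strongly red-dominant; black is channel-balanced and dark
        assert img_ginger[:, :, 0].mean() - img_ginger[:, :, 2].mean() > \
               img_black[:, :, 0].mean() - img_black[:, :, 2].mean() + 5
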