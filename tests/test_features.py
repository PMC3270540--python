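import math

import numpy as np
import pytest

from cooctex.config import RunConfig
from cooctex.cooccurrence import (
    CoocTensor,
    count_cooccurrence,
    standard_direction_sets,
    to_probability,
)
from cooctex.errors import ValidationError
from cooctex.features import (
    compute_feature_vector,
    extended_haralick,
    feature_table,
    laws_features,
    mean_grey,
    wavelet_entropies,
)
from cooctex.image_prep import QuantizedMap, quantize
from helpers import classical_haralick, skimage_reference_glcm


def normalized_tensor(entries: dict, order: int = 2, levels: int = 16) -> CoocTensor:
    total = sum(entries.values())
    return CoocTensor(
        order=order,
        levels=levels,
        entries={k: v / total for k, v in entries.items()},
        normalized=True,
        total=total,
    )


class TestExtendedHaralick:
    def test_delta_distribution_identities(self):
        h = extended_haralick(normalized_tensor({(3, 3): 1.0}))
        assert h.energy == 1.0
        assert h.entropy == 0.0
        assert h.contrast == 0.0
        assert h.homogeneity == 1.0
        assert h.max_probability == 1.0
        assert h.correlation == 0.0  # zero marginal variance convention

    def test_uniform_distribution_identities(self):
        K = 7
        entries = {(i, (i + 1) % K): 1.0 for i in range(K)}
        h = extended_haralick(normalized_tensor(entries))
        assert h.entropy == pytest.approx(math.log(K), abs=1e-12)
        assert h.energy == pytest.approx(1.0 / K, abs=1e-12)

    def test_unnormalized_tensor_rejected(self):
        with pytest.raises(ValidationError):
            extended_haralick(CoocTensor(2, 4, {(0, 0): 2.0}, normalized=False, total=2.0))

    def test_contrast_zero_iff_equal_components(self):
        equal = normalized_tensor({(2, 2): 3.0, (5, 5): 1.0})
        mixed = normalized_tensor({(2, 2): 3.0, (5, 4): 1.0})
        assert extended_haralick(equal).contrast == 0.0
        assert extended_haralick(mixed).contrast > 0.0

    def test_order2_reduces_to_classical_haralick(self, random_image_factory):
        """Order-2 features match an independent scikit-image oracle to 1e-9."""
        our_sets = standard_direction_sets(2)
        for seed in range(10):
            img = random_image_factory(seed, 8, 8, high=6)
            qmap = QuantizedMap(
                labels=img.astype(int), levels=6, valid_mask=np.ones(img.shape, bool)
            )
            ours = {
                d.name: extended_haralick(to_probability(count_cooccurrence(qmap, d)))
                for d in our_sets
            }
            reference = [classical_haralick(P) for P in skimage_reference_glcm(img)]
            for field in ("energy", "entropy", "contrast", "homogeneity",
                          "correlation", "max_probability"):
                got = sorted(getattr(h, field) for h in ours.values())
                want = sorted(r[field] for r in reference)
                np.testing.assert_allclose(got, want, atol=1e-9)

    def test_entropy_bounded_by_log_support(self, random_map_factory):
        qmap = random_map_factory(5, 10, 10, levels=6)
        for dset in standard_direction_sets(3):
            h = extended_haralick(to_probability(count_cooccurrence(qmap, dset)))
            p = to_probability(count_cooccurrence(qmap, dset))
            assert h.entropy <= math.log(len(p.entries)) + 1e-12


class TestSimpleFeatures:
    def test_mean_grey_cases(self):
        assert mean_grey(np.full((5, 5), 42, dtype=np.uint8)) == 42.0
        half = np.zeros((10, 10), dtype=np.uint8)
        half[:5] = 100
        assert mean_grey(half) == 50.0
        assert mean_grey(np.array([[0, 50], [100, 150]], dtype=np.uint8)) == 75.0


class TestLawsFeatures:
    def test_constant_image_has_no_microstructures(self):
        out = laws_features(np.full((20, 20), 80, dtype=np.uint8))
        for name, value in out.items():
            if name.endswith("frequency"):
                assert value == 0.0

    def test_spot_texture_favours_spot_class(self):
        # blob-shaped spots at the Laws kernel scale; a 1-pixel impulse would
        # instead excite the wave/ripple kernels (more nonzero taps)
        from scipy import ndimage

        rng = np.random.default_rng(0)
        img = np.full((50, 50), 100.0)
        for _ in range(15):
            y, x = rng.integers(3, 47, 2)
            blob = np.zeros((50, 50))
            blob[y, x] = 155
            img += ndimage.gaussian_filter(blob, 1.0) * 6
        out = laws_features(np.clip(img, 0, 255).astype(np.uint8), threshold_k=1.0)
        assert out["laws_spot_density"] > out["laws_wave_density"]

    def test_white_noise_density_near_half_at_zero_threshold(self, random_image_factory):
        img = random_image_factory(99, 60, 60)
        out = laws_features(img, threshold_k=0.0)
        # hits = pixels above the map mean; right-skew keeps this below 0.5
        for cls in ("edge", "spot", "wave", "ripple"):
            assert 0.25 < out[f"laws_{cls}_density"] < 0.6

    def test_small_image_rejected(self):
        with pytest.raises(ValidationError):
            laws_features(np.zeros((4, 10), dtype=np.uint8))


class TestWaveletEntropies:
    def test_twenty_named_subbands(self, random_image_factory):
        out = wavelet_entropies(random_image_factory(3, 50, 50))
        assert len(out) == 20
        assert "wl1_LL" in out and "wl2_HH_HH" in out
        assert sum(k.startswith("wl1_") for k in out) == 4
        assert sum(k.startswith("wl2_") for k in out) == 16

    def test_constant_image_detail_entropies_zero(self):
        out = wavelet_entropies(np.full((16, 16), 120, dtype=np.uint8))
        for name, value in out.items():
            if name != "wl1_LL" and not name.endswith("_LL"):
                assert value == 0.0, name

    def test_single_dominant_coefficient_entropy_zero(self):
        # one nonzero detail coefficient => degenerate distribution
        img = np.zeros((8, 8), dtype=np.uint8)
        img[0, 0] = 200
        out = wavelet_entropies(img)
        assert out["wl1_HH"] == 0.0

    def test_degenerate_size_rejected(self):
        with pytest.raises(ValidationError):
            wavelet_entropies(np.zeros((3, 50), dtype=np.uint8))


class TestFeatureVector:
    def test_configured_direction_tag_appears(self, random_image_factory):
        config = RunConfig(glcm3_mode="0_270", eocm3_mode="0_90")
        feats = compute_feature_vector(random_image_factory(4), config)
        assert "glcm3_0_270_entropy" in feats
        assert "eocm3_0_90_energy" in feats
        assert "glcm3_avg_entropy" not in feats

    def test_constant_roi_degenerates_cleanly(self):
        img = np.full((50, 50), 77, dtype=np.uint8)
        feats = compute_feature_vector(img)
        assert feats["mean_grey"] == 77.0
        assert feats["glcm2_avg_entropy"] == 0.0
        assert feats["glcm2_avg_max_probability"] == 1.0
        # no edges: EOCM features and orientation variability are missing
        assert math.isnan(feats["eocm2_avg_entropy"])
        assert math.isnan(feats["edge_orientation_variability"])

    def test_schema_stable_across_rois(self, random_image_factory):
        config = RunConfig()
        keys = None
        for seed in range(3):
            feats = compute_feature_vector(random_image_factory(seed + 50), config)
            if keys is None:
                keys = list(feats)
            assert list(feats) == keys

    def test_glcm5_excluded_by_config(self, random_image_factory):
        feats = compute_feature_vector(
            random_image_factory(8), RunConfig(include_glcm5=False)
        )
        assert not any(k.startswith("glcm5") for k in feats)

    def test_feature_table_layout(self, random_image_factory):
        imgs = [random_image_factory(s, 32, 32) for s in range(4)]
        df = feature_table(imgs, ["a", "a", "b", "b"])
        assert df.shape[0] == 4
        assert df.columns[-1] == "class"
        assert list(df["class"]) == ["a", "a", "b", "b"]
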