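import numpy as np
import pytest

from cardiosynth.errors import ResolutionError, ShapeMismatchError
from cardiosynth.io import ImageFrame
from cardiosynth.swd import (DescriptorSet, SWDConfig, laplacian_pyramid,
                             multiscale_swd, rank_most_similar, reconstruct,
                             sample_patch_descriptors, sliced_wasserstein)


def brute_force_swd(a: np.ndarray, b: np.ndarray, dirs: np.ndarray) -> float:
    """Independent oracle: explicitly project, sort, average |differences|."""
    dists = []
    for k in range(dirs.shape[1]):
        pa = np.sort([float(x @ dirs[:, k]) for x in a])
        pb = np.sort([float(x @ dirs[:, k]) for x in b])
        dists.append(np.mean(np.abs(np.array(pa) - np.array(pb))))
    return float(np.mean(dists))


class TestLaplacianPyramid:
    def test_reconstruction_within_tolerance(self):
        rng = np.random.default_rng(0)
        for _ in range(3):
            img = rng.uniform(size=(64, 64))
            bands = laplacian_pyramid(img, min_resolution=16)
            assert np.abs(reconstruct(bands) - img).max() < 1e-6

    def test_constant_image_all_energy_in_residual(self):
        img = np.full((64, 64), 0.37)
        bands = laplacian_pyramid(img, min_resolution=16)
        for b in bands[:-1]:
            assert np.abs(b.band).max() < 1e-9
        assert np.allclose(bands[-1].band, 0.37)

    def test_band_count_256_to_16(self):
        img = np.zeros((256, 256))
        bands = laplacian_pyramid(img, min_resolution=16)
        assert len(bands) == 5                    # 256,128,64,32 diffs + 16 residual
        assert bands[-1].is_residual
        assert bands[-1].band.shape == (16, 16)

    def test_non_power_of_two_rejected(self):
        with pytest.raises(ResolutionError):
            laplacian_pyramid(np.zeros((48, 48)))


class TestPatchDescriptors:
    def test_seeded_determinism(self):
        band = laplacian_pyramid(np.random.default_rng(1).uniform(
            size=(32, 32)))[0]
        a = sample_patch_descriptors(band, 16, 7, rng_seed=5)
        b = sample_patch_descriptors(band, 16, 7, rng_seed=5)
        assert np.array_equal(a.patches, b.patches)

    def test_constant_band_gives_zero_descriptors(self):
        band = laplacian_pyramid(np.full((32, 32), 0.5))[-1]
        d = sample_patch_descriptors(band, 8, 5, rng_seed=0)
        assert np.all(d.patches == 0)

    def test_shape_contract(self):
        band = laplacian_pyramid(np.random.default_rng(2).uniform(
            size=(32, 32)))[0]
        d = sample_patch_descriptors(band, 64, 7, rng_seed=1)
        assert d.patches.shape == (64, 49)

    def test_patches_standardized(self):
        band = laplacian_pyramid(np.random.default_rng(3).uniform(
            size=(64, 64)))[0]
        d = sample_patch_descriptors(band, 32, 7, rng_seed=2)
        assert np.allclose(d.patches.mean(axis=1), 0, atol=1e-10)
        assert np.allclose(d.patches.std(axis=1), 1, atol=1e-10)

    def test_patch_larger_than_band_rejected(self):
        band = laplacian_pyramid(np.zeros((16, 16)), min_resolution=16)[-1]
        with pytest.raises(ShapeMismatchError):
            sample_patch_descriptors(band, 4, 17)


class TestSlicedWasserstein:
    def test_identity_is_zero(self):
        rng = np.random.default_rng(4)
        p = rng.normal(size=(20, 9))
        d = DescriptorSet(p, 0, 3)
        assert sliced_wasserstein(d, d, 16, 0) == 0.0

    def test_1d_shifted_sets_closed_form(self):
        # in 1-D every unit projection is +-1, so the distance is the shift
        c = 1.7
        a = DescriptorSet(np.zeros((10, 1)), 0, 1)
        b = DescriptorSet(np.full((10, 1), c), 0, 1)
        assert sliced_wasserstein(a, b, 64, 3) == pytest.approx(c, abs=1e-12)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(5)
        for n, dim, nproj in [(8, 3, 4), (32, 5, 8), (16, 9, 8)]:
            a, b = rng.normal(size=(n, dim)), rng.normal(size=(n, dim))
            seed = int(rng.integers(1000))
            got = sliced_wasserstein(DescriptorSet(a, 0, 3),
                                     DescriptorSet(b, 0, 3), nproj, seed)
            dirs = np.random.default_rng(seed).standard_normal((dim, nproj))
            dirs /= np.linalg.norm(dirs, axis=0, keepdims=True)
            assert got == pytest.approx(brute_force_swd(a, b, dirs), abs=1e-10)

    def test_translation_lipschitz_bound(self):
        rng = np.random.default_rng(6)
        dim = 4
        c = 0.9
        zero = DescriptorSet(np.zeros((12, dim)), 0, 2)
        shifted = DescriptorSet(np.full((12, dim), c), 0, 2)
        # per projection the distance is |c * sum(u)| <= c * sqrt(dim)
        d = sliced_wasserstein(zero, shifted, 32, 7)
        assert 0 <= d <= c * np.sqrt(dim) + 1e-12

    def test_mismatched_sets_rejected(self):
        a = DescriptorSet(np.zeros((4, 3)), 0, 2)
        b = DescriptorSet(np.zeros((4, 5)), 0, 2)
        with pytest.raises(ShapeMismatchError):
            sliced_wasserstein(a, b, 4, 0)
        c = DescriptorSet(np.zeros((6, 3)), 0, 2)
        with pytest.raises(ShapeMismatchError):
            sliced_wasserstein(a, c, 4, 0)


class TestMultiscaleSWD:
    def test_identical_sets_zero_at_every_level(self, sax_frames_32):
        frames = sax_frames_32[:6]
        res = multiscale_swd(frames, list(frames), SWDConfig(seed=3))
        assert all(v == 0.0 for v in res.per_level.values())
        assert res.average == 0.0

    def test_noise_set_strictly_positive(self, sax_frames_32):
        rng = np.random.default_rng(8)
        noise = [ImageFrame(rng.uniform(size=(32, 32))) for _ in range(6)]
        res = multiscale_swd(sax_frames_32[:6], noise, SWDConfig(seed=3))
        assert res.average > 0

    def test_mixed_sizes_rejected(self, sax_frames_32):
        with pytest.raises(ShapeMismatchError):
            multiscale_swd(sax_frames_32[:2],
                           [ImageFrame(np.zeros((64, 64)))], SWDConfig())


class TestRankMostSimilar:
    def test_bitwise_copy_ranks_first_with_zero_distance(self, sax_frames_32):
        refs = sax_frames_32[:8]
        query = ImageFrame(refs[3].pixels.copy())
        res = rank_most_similar(query, refs, SWDConfig(seed=1))
        assert res.ranking[0] == (3, 0.0)

    def test_noisy_copy_outranks_unrelated_phantom(self, sax_frames_32):
        rng = np.random.default_rng(9)
        query = sax_frames_32[0]
        noisy = ImageFrame(np.clip(
            query.pixels + rng.normal(0, 0.01, (32, 32)), 0, 1))
        unrelated = sax_frames_32[20]
        res = rank_most_similar(query, [noisy, unrelated], SWDConfig(seed=2))
        assert res.ranking[0][0] == 0

    def test_ranking_is_sorted_permutation(self, sax_frames_32):
        res = rank_most_similar(sax_frames_32[0], sax_frames_32[1:7],
                                SWDConfig(seed=4))
        dists = [d for _, d in res.ranking]
        assert dists == sorted(dists)
        assert sorted(j for j, _ in res.ranking) == list(range(6))
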