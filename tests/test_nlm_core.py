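import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from blocknlm import (
    FilterParams,
    Patch,
    ValidationError,
    Volume,
    bayes_distance,
    bayes_nlm_filter_voxelwise,
    bayes_weights,
    classic_nlm_filter,
    classic_nlm_weights,
    extract_patch,
    gaussian_l2_distance,
    patch_kernel,
)
from _oracles import bayes_voxel_oracle, classic_nlm_oracle


class TestFilterParams:
    def test_step_defaults_to_ref_radius_plus_one(self):
        assert FilterParams(ref_radius=2, search_radius=5).stride == 3
        assert FilterParams(ref_radius=2, search_radius=5, step=1).stride == 1

    def test_derived_sizes(self):
        p = FilterParams(ref_radius=1, search_radius=5)
        assert p.patch_size == 27
        assert p.window_size == 11**3
        assert p.margin == 6

    @pytest.mark.parametrize(
        "kw",
        [
            {"ref_radius": 0, "search_radius": 2},
            {"ref_radius": 3, "search_radius": 2},
            {"ref_radius": 1, "search_radius": 2, "step": 0},
            {"ref_radius": 1, "search_radius": 2, "decay": 0.0},
            {"ref_radius": 1, "search_radius": 2, "gamma": -1.0},
            {"ref_radius": 1, "search_radius": 2, "alpha": 0.0},
        ],
        ids=["R<1", "M<R", "n<1", "h=0", "gamma<0", "alpha=0"],
    )
    def test_invalid(self, kw):
        with pytest.raises(ValidationError):
            FilterParams(**kw)


class TestPatch:
    def test_requires_odd_cube_length(self):
        Patch(np.zeros(27))
        with pytest.raises(ValidationError):
            Patch(np.zeros(8))

    def test_extract_is_x_fastest(self):
        data = np.arange(27.0).reshape((3, 3, 3), order="F")
        p = extract_patch(Volume(data), (1, 1, 1), 1)
        assert np.array_equal(p.values, np.arange(27.0))

    def test_extract_out_of_bounds(self):
        with pytest.raises(ValidationError):
            extract_patch(Volume(np.zeros((3, 3, 3))), (0, 1, 1), 1)


class TestDistances:
    @pytest.mark.parametrize("alpha", [0.5, 1.0, 2.7, None])
    @pytest.mark.parametrize("radius", [1, 2])
    def test_kernel_normalized(self, radius, alpha):
        assert patch_kernel(radius, alpha).sum() == pytest.approx(1.0, abs=1e-12)

    def test_identical_patches_zero(self, rng):
        p = rng.uniform(1, 10, 27)
        assert gaussian_l2_distance(p, p, 1.0) == 0.0
        assert bayes_distance(p, p, 0.5) == 0.0

    def test_constant_difference_gives_c_squared(self, rng):
        """Normalized kernel: p_i - p_j = c everywhere -> distance c^2."""
        p = rng.uniform(1, 10, 27)
        assert gaussian_l2_distance(p + 3.0, p, 1.0) == pytest.approx(9.0, rel=1e-12)

    def test_bayes_gamma_zero_is_plain_l2(self):
        assert bayes_distance([3.0], [1.0], gamma=0.0) == 4.0

    def test_bayes_candidate_denominator(self):
        """Hand evaluation: (4-1)^2/1 + (9-4)^2/4 at gamma = 0.5."""
        assert bayes_distance([4.0, 9.0], [1.0, 4.0], gamma=0.5) == pytest.approx(15.25)
        # asymmetric: denominator comes from the candidate, not the reference
        assert bayes_distance([1.0, 4.0], [4.0, 9.0], gamma=0.5) == pytest.approx(
            9 / 4 + 25 / 9
        )

    def test_bayes_clamps_tiny_candidates(self):
        d = bayes_distance([1.0], [0.0], gamma=0.5)
        assert d == pytest.approx(1.0 / 1e-3)

    def test_size_mismatch(self):
        with pytest.raises(ValidationError):
            bayes_distance([1.0, 2.0], [1.0], gamma=0.5)
        with pytest.raises(ValidationError):
            gaussian_l2_distance(np.zeros(27), np.zeros(1))


class TestWeights:
    def test_identical_candidates_uniform(self, rng):
        ref = rng.uniform(1, 10, 27)
        for fn in (
            lambda c: classic_nlm_weights(ref, c, h=20.0),
            lambda c: bayes_weights(ref, c, h=20.0),
        ):
            w = fn([ref] * 5)
            assert np.allclose(w, 0.2, atol=1e-15)

    def test_closed_form_two_thirds_one_third(self):
        """Distances {0, h^2 ln 2} -> weights {2/3, 1/3}."""
        h = 5.0
        ref = np.array([0.0])
        far = np.array([math.sqrt(h * h * math.log(2))])
        w = bayes_weights(ref, [ref, far], h=h, gamma=0.0)
        assert np.allclose(w, [2 / 3, 1 / 3], atol=1e-12)

    def test_huge_h_flattens_classic_weights(self, rng):
        ref = rng.uniform(1, 255, 27)
        cands = [rng.uniform(1, 255, 27) for _ in range(7)]
        w = classic_nlm_weights(ref, cands, h=1e6 * 255)
        assert np.max(np.abs(w - 1 / 7)) < 1e-6

    def test_empty_candidates(self):
        with pytest.raises(ValidationError):
            bayes_weights(np.zeros(27), [], h=1.0)
        with pytest.raises(ValidationError):
            classic_nlm_weights(np.zeros(27), [], h=1.0)

    @given(seed=st.integers(0, 2**20), k=st.integers(1, 8))
    def test_normalization_and_convexity_property(self, seed, k):
        """Weights sum to 1; weighted averages stay in the candidates' range."""
        r = np.random.Generator(np.random.PCG64(seed))
        ref = r.uniform(0.5, 255, 27)
        cands = [r.uniform(0.5, 255, 27) for _ in range(k)]
        for w in (
            bayes_weights(ref, cands, h=20.0),
            classic_nlm_weights(ref, cands, h=20.0),
        ):
            assert abs(w.sum() - 1.0) < 1e-12
            centers = np.array([c[13] for c in cands])
            est = float(w @ centers)
            assert centers.min() - 1e-9 <= est <= centers.max() + 1e-9


class TestVoxelwiseFilters:
    @pytest.mark.parametrize("fn", [classic_nlm_filter, bayes_nlm_filter_voxelwise])
    def test_constant_volume_preserved(self, fn):
        v = Volume(np.full((9, 9, 9), 77.0))
        out = fn(v, FilterParams(ref_radius=1, search_radius=2))
        assert np.allclose(out.data, 77.0, atol=1e-12)

    def test_too_small_volume_names_minimum(self):
        p = FilterParams(ref_radius=1, search_radius=5)
        with pytest.raises(ValidationError, match="13"):
            classic_nlm_filter(Volume(np.ones((8, 8, 8))), p)

    def test_border_copied_unchanged(self, random_volume):
        p = FilterParams(ref_radius=1, search_radius=2)
        out = bayes_nlm_filter_voxelwise(random_volume, p)
        m = p.margin
        assert np.array_equal(out.data[:m], random_volume.data[:m])
        assert np.array_equal(out.data[:, :, -m:], random_volume.data[:, :, -m:])

    def test_output_within_search_window_range(self, random_volume):
        """Each restored voxel is a convex combination over its window."""
        p = FilterParams(ref_radius=1, search_radius=2)
        out = bayes_nlm_filter_voxelwise(random_volume, p)
        a = random_volume.data
        m = p.search_radius
        for idx in [(3, 4, 5), (6, 3, 3), (4, 4, 4)]:
            win = a[
                idx[0] - m : idx[0] + m + 1,
                idx[1] - m : idx[1] + m + 1,
                idx[2] - m : idx[2] + m + 1,
            ]
            assert win.min() - 1e-9 <= out.data[idx] <= win.max() + 1e-9

    def test_classic_matches_bruteforce(self, random_volume):
        p = FilterParams(ref_radius=1, search_radius=2, decay=20.0, alpha=1.0)
        out = classic_nlm_filter(random_volume, p)
        ref = classic_nlm_oracle(random_volume.data, R=1, M=2, h=20.0, alpha=1.0)
        assert np.max(np.abs(out.data - ref)) < 1e-10

    def test_bayes_matches_bruteforce(self, random_volume):
        p = FilterParams(ref_radius=1, search_radius=2, decay=20.0, gamma=0.5)
        out = bayes_nlm_filter_voxelwise(random_volume, p)
        ref = bayes_voxel_oracle(random_volume.data, R=1, M=2, h=20.0, gamma=0.5)
        assert np.max(np.abs(out.data - ref)) < 1e-10

    def test_gamma_zero_reduces_to_flat_classic(self, random_volume):
        """gamma=0 Bayes weights equal classic flat-kernel weights with
        the decay rescaled by sqrt(P) (normalized vs plain L2 sum)."""
        h = 30.0
        p_bayes = FilterParams(ref_radius=1, search_radius=2, decay=h, gamma=0.0)
        p_classic = FilterParams(
            ref_radius=1, search_radius=2, decay=h / math.sqrt(27), alpha=None
        )
        a = bayes_nlm_filter_voxelwise(random_volume, p_bayes)
        b = classic_nlm_filter(random_volume, p_classic)
        assert np.max(np.abs(a.data - b.data)) < 1e-10

    @pytest.mark.parametrize("fn", [classic_nlm_filter, bayes_nlm_filter_voxelwise])
    def test_mirror_symmetry(self, random_volume, fn):
        p = FilterParams(ref_radius=1, search_radius=2)
        mirrored = Volume(random_volume.data[::-1].copy())
        a = fn(mirrored, p).data
        b = fn(random_volume, p).data[::-1]
        assert np.max(np.abs(a - b)) < 1e-10

    def test_noise_free_constant_region_is_fixed_point(self):
        """Deep inside a constant region every candidate patch is identical,
        so the filter must leave those voxels untouched (< 1e-6)."""
        data = np.full((20, 20, 20), 50.0)
        data[:, :, 10:] = 150.0
        v = Volume(data)
        p = FilterParams(ref_radius=1, search_radius=2)
        out = bayes_nlm_filter_voxelwise(v, p)
        # z <= 6 and z >= 13: whole search+patch support in one region
        assert np.max(np.abs(out.data[:, :, 4:7] - data[:, :, 4:7])) < 1e-6
        assert np.max(np.abs(out.data[:, :, 13:16] - data[:, :, 13:16])) < 1e-6
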