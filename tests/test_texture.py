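import numpy as np
import pytest

from mrmtex.phantom import generate_phantom
from mrmtex.texture import (
    OFFSETS_2D,
    OFFSETS_3D,
    glcm_window,
    haralick_features,
    quantize,
    texture_map,
)
from mrmtex.types import (
    FEATURE_NAMES,
    STROMA,
    TUMOR,
    IntensityVolume,
    QuantizedVolume,
)

from conftest import small_phantom_config


def quantized(levels, G, mask=None, spacing=None):
    levels = np.asarray(levels)
    if mask is None:
        mask = np.ones(levels.shape, bool)
    if spacing is None:
        spacing = (1.0,) * levels.ndim
    return QuantizedVolume(levels, G, mask, spacing)


def reference_texture_map(q, radius, offsets):
    """Naive per-pixel reference: window GLCM per direction, features
    averaged over directions with at least one pair."""
    out = {name: np.full(q.shape, np.nan) for name in FEATURE_NAMES}
    ok = np.zeros(q.shape, bool)
    for center in np.ndindex(*q.shape):
        if not q.mask[center]:
            continue
        acc = np.zeros(len(FEATURE_NAMES))
        ndir = 0
        for off in offsets:
            mat = glcm_window(q, center, radius, offsets=(off,))
            if mat.empty:
                continue
            feats = haralick_features(mat)
            acc += np.array([feats[n] for n in FEATURE_NAMES])
            ndir += 1
        if ndir:
            ok[center] = True
            for k, name in enumerate(FEATURE_NAMES):
                out[name][center] = acc[k] / ndir
    return out, ok


class TestQuantize:
    def test_constant_image_all_level_zero(self):
        vol = IntensityVolume(np.full((10, 10), 5.0), (1.0, 1.0))
        with pytest.warns(UserWarning, match="constant"):
            q = quantize(vol, 64)
        assert np.all(q.levels == 0)

    def test_hand_arithmetic_bounds(self):
        # intensities {0, 63.9, 64, 128} over [0, 128] at G = 64:
        # floor(64 x / 128) -> {0, 31, 32, 64->63}
        vol = IntensityVolume(np.array([[0.0, 63.9], [64.0, 128.0]]), (1.0, 1.0))
        q = quantize(vol, 64)
        assert q.levels.tolist() == [[0, 31], [32, 63]]

    def test_requantization_of_respanned_levels_is_identity(self):
        rng = np.random.default_rng(0)
        lv = rng.integers(0, 64, size=(20, 20)).astype(float)
        lv.flat[0], lv.flat[1] = 0, 63  # pin the full range
        q1 = quantize(IntensityVolume(lv, (1.0, 1.0)), 64)
        q2 = quantize(IntensityVolume(q1.levels.astype(float), (1.0, 1.0)), 64)
        assert np.array_equal(q1.levels, q2.levels)

    def test_masked_levels_in_range_and_provenance(self, small_phantom):
        vol, _ = small_phantom
        q = quantize(vol, 64)
        vals = q.levels[q.mask]
        assert vals.min() >= 0 and vals.max() <= 63
        assert q.provenance["n_levels"] == 64
        assert q.provenance["min"] == vol.masked_values().min()

    def test_bad_levels_rejected(self, small_phantom):
        vol, _ = small_phantom
        with pytest.raises(ValueError):
            quantize(vol, 1)


class TestGlcmWindow:
    def test_hand_enumeration_2x2_horizontal(self):
        # [[0,0],[1,1]], horizontal offset, whole image as window:
        # two symmetric pairs -> p = [[0.5, 0], [0, 0.5]]
        q = quantized([[0, 0], [1, 1]], 2)
        mat = glcm_window(q, (0, 0), radius=2, offsets=((0, 1),))
        assert np.allclose(mat.p, [[0.5, 0.0], [0.0, 0.5]])

    def test_constant_window_single_entry(self):
        q = quantized(np.zeros((5, 5), int), 4)
        mat = glcm_window(q, (2, 2), radius=2)
        assert mat.p[0, 0] == 1.0
        assert mat.p.sum() == 1.0

    def test_sum_one_and_symmetry_random_windows(self):
        rng = np.random.default_rng(5)
        for _ in range(5):
            q = quantized(rng.integers(0, 8, (7, 7)), 8, mask=rng.random((7, 7)) > 0.2)
            center = (3, 3)
            if not q.mask[center]:
                continue
            mat = glcm_window(q, center, radius=3)
            if mat.empty:
                continue
            assert np.isclose(mat.p.sum(), 1.0, atol=1e-9)
            assert np.allclose(mat.p, mat.p.T)

    def test_brute_force_pair_enumeration_oracle(self):
        rng = np.random.default_rng(8)
        levels = rng.integers(0, 4, (7, 7))
        mask = rng.random((7, 7)) > 0.15
        q = quantized(levels, 4, mask=mask)
        off = (-1, 1)
        counts = np.zeros((4, 4))
        for y in range(7):
            for x in range(7):
                yy, xx = y + off[0], x + off[1]
                if 0 <= yy < 7 and 0 <= xx < 7 and mask[y, x] and mask[yy, xx]:
                    counts[levels[y, x], levels[yy, xx]] += 1
                    counts[levels[yy, xx], levels[y, x]] += 1
        mat = glcm_window(q, (3, 3), radius=3, offsets=(off,))
        assert np.allclose(mat.p, counts / counts.sum())

    def test_no_valid_pairs_flagged_empty(self):
        mask = np.zeros((5, 5), bool)
        mask[2, 2] = True  # isolated pixel: no pair exists
        q = quantized(np.ones((5, 5), int), 2, mask=mask)
        mat = glcm_window(q, (2, 2), radius=2)
        assert mat.empty
        assert not mat.p.any()


class TestHaralickFeatures:
    def test_degenerate_single_entry(self):
        a = 3
        p = np.zeros((8, 8))
        p[a, a] = 1.0
        f = haralick_features(p)
        assert f["energy"] == 1.0
        assert f["entropy"] == 0.0
        assert f["contrast"] == 0.0
        assert f["homogeneity"] == 1.0
        assert f["dissimilarity"] == 0.0
        assert f["autocorrelation"] == a**2

    def test_hand_arithmetic_2x2_diagonal(self):
        p = np.array([[0.5, 0.0], [0.0, 0.5]])
        f = haralick_features(p)
        assert f["energy"] == 0.5
        assert f["entropy"] == 1.0  # one bit
        assert f["contrast"] == 0.0
        assert f["correlation"] == 1.0
        # p_{x+y}(0) = 0.5, p_{x+y}(2) = 0.5 -> sum average = 1
        assert f["sum_average"] == 1.0

    def test_uniform_distribution_closed_form(self):
        G = 4
        p = np.full((G, G), 1.0 / G**2)
        f = haralick_features(p)
        assert np.isclose(f["entropy"], 2 * np.log2(G))
        assert np.isclose(f["energy"], 1.0 / G**2)

    def test_zero_marginal_variance_correlation_is_zero(self):
        p = np.zeros((4, 4))
        p[2, 2] = 1.0
        assert haralick_features(p)["correlation"] == 0.0

    def test_non_normalized_rejected(self):
        with pytest.raises(ValueError, match="sum"):
            haralick_features(np.full((4, 4), 1.0))


class TestTextureMap:
    def test_constant_phantom_closed_forms(self):
        q = quantized(np.zeros((16, 16), int), 64)
        stack = texture_map(q, radius=3)
        m = stack.mask
        assert m.all()
        assert np.all(stack["entropy"][m] == 0.0)
        assert np.all(stack["energy"][m] == 1.0)
        assert np.all(stack["homogeneity"][m] == 1.0)
        assert np.all(stack["contrast"][m] == 0.0)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_naive_reference_exactly(self, seed):
        rng = np.random.default_rng(seed)
        levels = rng.integers(0, 16, (32, 32))
        mask = rng.random((32, 32)) > 0.1
        q = quantized(levels, 16, mask=mask)
        stack = texture_map(q, radius=3)
        ref, ok = reference_texture_map(q, 3, OFFSETS_2D)
        assert np.array_equal(stack.mask, ok)
        for name in FEATURE_NAMES:
            a, b = stack[name][ok], ref[name][ok]
            assert np.allclose(a, b, atol=1e-10, rtol=0), name

    def test_feature_bounds_on_phantom(self, small_phantom):
        vol, _ = small_phantom
        q = quantize(vol, 64)
        stack = texture_map(q)
        m = stack.mask
        assert (stack["energy"][m] > 0).all() and (stack["energy"][m] <= 1).all()
        assert (stack["homogeneity"][m] > 0).all() and (
            stack["homogeneity"][m] <= 1
        ).all()
        assert (stack["entropy"][m] >= 0).all()
        assert (stack["entropy"][m] <= 2 * np.log2(64)).all()
        assert (stack["contrast"][m] >= 0).all()
        assert (np.abs(stack["correlation"][m]) <= 1 + 1e-12).all()

    def test_translation_invariance(self):
        rng = np.random.default_rng(3)
        levels = rng.integers(0, 8, (24, 24))
        shift = 8
        big = np.zeros((24 + shift, 24 + shift), int)
        big[shift:, shift:] = levels
        mask = np.zeros(big.shape, bool)
        mask[shift:, shift:] = True
        q0 = quantized(levels, 8)
        q1 = quantized(big, 8, mask=mask)
        s0 = texture_map(q0, radius=3)
        s1 = texture_map(q1, radius=3)
        for name in FEATURE_NAMES:
            assert np.allclose(
                s0[name], s1[name][shift:, shift:], atol=1e-12, equal_nan=True
            )

    def test_stroma_entropy_exceeds_tumor_entropy(self, default_phantom):
        vol, lab = default_phantom
        q = quantize(vol, 64)
        stack = texture_map(q)
        m = stack.mask
        ent = stack["entropy"]
        assert (
            np.nanmean(ent[m & lab.region(STROMA)])
            > np.nanmean(ent[m & lab.region(TUMOR)])
        )

    def test_monotone_heterogeneity(self):
        means = []
        for scale in (0.1, 0.25, 0.4):
            cfg = small_phantom_config(seed=6, stroma_texture_scale=scale)
            vol, lab = generate_phantom(cfg)
            q = quantize(vol, 64)
            stack = texture_map(q)
            sel = stack.mask & lab.region(STROMA)
            means.append(np.nanmean(stack["entropy"][sel]))
        assert means[0] < means[1] < means[2]

    def test_3d_13dir_mode_runs(self):
        rng = np.random.default_rng(4)
        levels = rng.integers(0, 8, (4, 12, 12))
        q = quantized(levels, 8)
        stack = texture_map(q, radius=2, mode="3d-13dir")
        assert stack.mask.all()
        assert np.isfinite(stack["entropy"][stack.mask]).all()

    def test_3d_13dir_matches_naive_reference(self):
        rng = np.random.default_rng(9)
        levels = rng.integers(0, 6, (3, 8, 8))
        mask = rng.random((3, 8, 8)) > 0.1
        q = quantized(levels, 6, mask=mask)
        stack = texture_map(q, radius=2, mode="3d-13dir")
        ref, ok = reference_texture_map(q, 2, OFFSETS_3D)
        assert np.array_equal(stack.mask, ok)
        for name in FEATURE_NAMES:
            assert np.allclose(stack[name][ok], ref[name][ok], atol=1e-10, rtol=0)

    def test_per_slice_2d_mode_on_3d_volume(self):
        rng = np.random.default_rng(10)
        levels = rng.integers(0, 8, (3, 16, 16))
        q = quantized(levels, 8)
        stack3 = texture_map(q, radius=3, mode="2d-4dir")
        for z in range(3):
            qz = quantized(levels[z], 8)
            stack2 = texture_map(qz, radius=3)
            for name in FEATURE_NAMES:
                assert np.allclose(
                    stack3[name][z], stack2[name], atol=1e-12, equal_nan=True
                )

    def test_si_map_carried_through(self, small_phantom):
        vol, _ = small_phantom
        q = quantize(vol, 64)
        stack = texture_map(q, si=vol.data)
        assert np.array_equal(stack["si"], vol.data)

    def test_offset_distance_changes_result(self):
        rng = np.random.default_rng(11)
        levels = rng.integers(0, 8, (20, 20))
        q = quantized(levels, 8)
        s1 = texture_map(q, radius=3, distance=1)
        s3 = texture_map(q, radius=3, distance=3)
        assert not np.allclose(s1["contrast"], s3["contrast"], equal_nan=True)

    def test_invalid_mode_rejected(self):
        q = quantized(np.zeros((8, 8), int), 4)
        with pytest.raises(ValueError, match="mode"):
            texture_map(q, mode="5d")
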