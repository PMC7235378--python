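import numpy as np
import pytest

from imageprops.io import RasterImage
from imageprops.structure import (
    cnn_variances,
    filter_response_grid,
    hog_pyramid,
    self_similarity,
    symmetry_scores,
)
from imageprops.synthetic import gen_mirrored_composite, gen_powerlaw_image
from tests.conftest import make_image


def smooth_patch(n=100, seed=0):
    """A patch whose variation decays to a constant at the borders, so that
    tiling it produces no seam gradients."""
    rng = np.random.default_rng(seed)
    yy, xx = np.mgrid[:n, :n]
    envelope = np.sin(np.pi * yy / (n - 1)) ** 2 * np.sin(np.pi * xx / (n - 1)) ** 2
    envelope[:3, :] = envelope[-3:, :] = 0.0
    envelope[:, :3] = envelope[:, -3:] = 0.0
    noise = rng.uniform(size=(n, n))
    from scipy.ndimage import gaussian_filter

    return 0.5 + 0.4 * envelope * (gaussian_filter(noise, 3) - 0.5) / 0.5


class TestHogPyramid:
    def test_tiled_patch_level1_equals_ground(self):
        patch = smooth_patch()
        tiled = np.tile(patch, (2, 2))
        pyr = hog_pyramid(make_image(tiled))
        for i in range(2):
            for j in range(2):
                np.testing.assert_allclose(pyr.levels[1][i, j], pyr.ground, atol=1e-6)

    def test_rot90_rolls_bins_by_four(self):
        patch = smooth_patch(seed=3)
        pyr_a = hog_pyramid(make_image(patch))
        pyr_b = hog_pyramid(make_image(np.rot90(patch)))
        # 90 degrees = 4 bins of 22.5 degrees
        for shift in (4, -4):
            if np.allclose(np.roll(pyr_a.ground, shift), pyr_b.ground, atol=1e-6):
                return
        raise AssertionError("rotation did not permute histogram bins by 4")

    def test_split_content_level1_differs(self):
        n = 128
        yy, xx = np.mgrid[:n, :n].astype(float)
        img = np.where(xx < n / 2, 0.5 + 0.4 * np.sin(xx), 0.5 + 0.4 * np.sin(yy))
        pyr = hog_pyramid(make_image(img))
        left, right = pyr.levels[1][0, 0], pyr.levels[1][0, 1]
        assert left.argmax() != right.argmax()

    def test_featureless_raises(self):
        with pytest.raises(ValueError, match="featureless"):
            hog_pyramid(RasterImage(np.full((64, 64, 3), 0.5)))


class TestSelfSimilarity:
    def test_tiling_raises_similarity(self):
        # a 2x2 tiling repeats the texture across sub-rectangles, so its
        # pyramid matches the ground histogram better than the lone patch
        lone = self_similarity(hog_pyramid(make_image(smooth_patch())))
        tiled = self_similarity(hog_pyramid(make_image(np.tile(smooth_patch(), (2, 2)))))
        assert tiled > lone

    def test_identical_histograms_give_one(self):
        pyr = hog_pyramid(make_image(np.tile(smooth_patch(50, seed=1), (8, 8))))
        # every sub-rectangle at every level contains whole tiles
        assert self_similarity(pyr) == pytest.approx(1.0, abs=0.02)

    def test_matches_brute_force_oracle(self):
        pyr = hog_pyramid(make_image(smooth_patch(seed=5)))
        sims = []
        for lvl in (1, 2, 3):
            k = 2**lvl
            for i in range(k):
                for j in range(k):
                    if not pyr.empty[lvl][i, j]:
                        s = 0.0
                        for b in range(16):
                            s += min(pyr.levels[lvl][i, j, b], pyr.ground[b])
                        sims.append(s)
        assert self_similarity(pyr) == pytest.approx(float(np.median(sims)), abs=1e-12)
        assert self_similarity(pyr, aggregate="mean") == pytest.approx(
            float(np.mean(sims)), abs=1e-12
        )

    def test_bounded(self):
        for seed in range(3):
            pyr = hog_pyramid(gen_powerlaw_image(128, -2.0, seed=seed))
            assert 0.0 <= self_similarity(pyr) <= 1.0

    def test_tiled_more_self_similar_than_split(self):
        from imageprops.synthetic import gen_split_content, gen_tiled_texture

        tiled = [
            self_similarity(hog_pyramid(gen_tiled_texture(128, 32, seed=s)))
            for s in range(3)
        ]
        split = [
            self_similarity(hog_pyramid(gen_split_content(128, seed=s)))
            for s in range(3)
        ]
        assert np.mean(tiled) > np.mean(split)


class TestFilterResponseGrid:
    def test_constant_image_zero(self):
        grid = filter_response_grid(RasterImage(np.full((64, 64, 3), 0.5)))
        np.testing.assert_allclose(grid.responses, 0.0, atol=1e-10)

    def test_vertical_grating_vertical_filters_dominate(self):
        n = 96
        xx = np.mgrid[:n, :n][1].astype(float)
        img = make_image(0.5 + 0.4 * np.sin(2 * np.pi * xx / 8))
        grid = filter_response_grid(img)
        # luminance odd block: filters 0..11, theta = k*15deg; theta=0
        # (variation along x) should dominate every cell
        lum_odd = grid.responses[:12]
        winners = lum_odd.reshape(12, -1).argmax(axis=0)
        assert np.all(winners == 0)

    def test_mirror_equivariance(self, rng):
        img = gen_powerlaw_image(64, -2.0, seed=9)
        mirrored = RasterImage(img.pixels[:, ::-1, :], id="m")
        ga = filter_response_grid(img)
        gb = filter_response_grid(mirrored)
        np.testing.assert_allclose(
            gb.responses, ga.responses[ga.mirror_map][:, :, ::-1], atol=1e-9
        )


class TestSymmetry:
    def test_exact_mirror_image_scores_one(self):
        img = gen_powerlaw_image(64, -2.0, seed=2)
        sym = gen_mirrored_composite(img, "lr", 1.0)
        assert symmetry_scores(sym).sym_lr == pytest.approx(1.0, abs=1e-9)
        sym_ud = gen_mirrored_composite(img, "ud", 1.0)
        assert symmetry_scores(sym_ud).sym_ud == pytest.approx(1.0, abs=1e-9)

    def test_score_symmetric_under_mirroring(self):
        img = gen_powerlaw_image(64, -2.5, seed=4)
        mirrored = RasterImage(img.pixels[:, ::-1, :], id="m")
        assert symmetry_scores(img).sym_lr == pytest.approx(
            symmetry_scores(mirrored).sym_lr, abs=1e-9
        )

    def test_half_dark_half_noise_less_symmetric_than_mirrored_noise(self, rng):
        n = 64
        noise = rng.uniform(size=(n, n // 2))
        asym = np.zeros((n, n))
        asym[:, n // 2 :] = noise
        sym = np.concatenate([noise[:, ::-1], noise], axis=1)
        s_asym = symmetry_scores(make_image(asym)).sym_lr
        s_sym = symmetry_scores(make_image(sym)).sym_lr
        assert s_asym < s_sym
        assert s_sym == pytest.approx(1.0, abs=1e-9)

    def test_blend_toward_mirror_monotone(self):
        base = gen_powerlaw_image(64, -2.0, seed=6)
        scores = [
            symmetry_scores(gen_mirrored_composite(base, "lr", w)).sym_lr
            for w in (0, 0.25, 0.5, 0.75, 1.0)
        ]
        assert np.all(np.diff(scores) >= -1e-9)

    def test_scores_in_unit_interval(self):
        for seed in range(3):
            s = symmetry_scores(gen_powerlaw_image(64, -1.5, seed=seed))
            assert 0.0 <= s.sym_lr <= 1.0
            assert 0.0 <= s.sym_ud <= 1.0


class TestCnnVariances:
    def _grid(self, responses):
        from imageprops.structure import FilterResponseGrid

        f = responses.shape[0]
        mm = np.arange(f)
        return FilterResponseGrid(responses, mm)

    def test_uniform_responses_zero_variances(self):
        grid = self._grid(np.ones((48, 8, 8)))
        cv = cnn_variances(grid)
        assert cv.var_pa == pytest.approx(0.0, abs=1e-15)
        assert cv.var_pf == pytest.approx(0.0, abs=1e-15)

    def test_one_hot_filter_closed_form(self):
        f = 48
        resp = np.zeros((f, 8, 8))
        resp[7] = 1.0
        cv = cnn_variances(self._grid(resp))
        a = np.zeros(f)
        a[7] = 1.0
        assert cv.var_pa == pytest.approx(float(np.var(a)), abs=1e-15)
        assert cv.var_pf == pytest.approx(0.0, abs=1e-15)

    def test_matches_double_loop_oracle(self, rng):
        resp = rng.uniform(size=(6, 4, 4))
        cv = cnn_variances(self._grid(resp))
        # oracle: explicit loops over cells and filters
        cells = resp.reshape(6, -1)
        norm = cells / cells.sum(axis=0)
        a = [np.mean([norm[f, s] for s in range(16)]) for f in range(6)]
        var_pa = np.mean([(x - np.mean(a)) ** 2 for x in a])
        var_pf = np.mean(
            [np.mean([(norm[f, s] - np.mean(norm[f])) ** 2 for s in range(16)]) for f in range(6)]
        )
        assert cv.var_pa == pytest.approx(var_pa, abs=1e-12)
        assert cv.var_pf == pytest.approx(var_pf, abs=1e-12)

    def test_superimposed_textures_reduce_pa(self):
        n = 96
        yy, xx = np.mgrid[:n, :n].astype(float)
        g1 = 0.5 + 0.25 * np.sin(2 * np.pi * xx / 8)
        g2 = 0.5 + 0.25 * np.sin(2 * np.pi * yy / 8)
        single = cnn_variances(filter_response_grid(make_image(g1)))
        mixed = cnn_variances(
            filter_response_grid(make_image(0.5 * (g1 + g2)))
        )
        assert mixed.var_pa < single.var_pa

    def test_zero_response_raises(self):
        with pytest.raises(ValueError, match="zero"):
            cnn_variances(self._grid(np.zeros((48, 8, 8))))
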