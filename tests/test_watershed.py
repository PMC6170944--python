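"""Watershed stage: morphology, gradients, thresholding and immersion
flooding, each against a literal brute-force oracle, plus the tumor-basin
selection logic on synthetic phantoms."""

import numpy as np
import pytest
from scipy import ndimage

from wmseg import (
    Image2D,
    PhantomSpec,
    WatershedConfig,
    derive_gradient_reference,
    ellipse_mask,
    generate_phantom,
    gradient_magnitude,
    morphological_smooth,
    segment_tumor,
    threshold_gradient,
    watershed_flood,
)
from wmseg.verify import pixel_metrics

from oracles import flood_oracle, open_close_oracle, sobel_oracle


class TestMorphologicalSmooth:
    def test_constant_unchanged(self):
        img = Image2D(np.full((6, 6), 8.0))
        np.testing.assert_array_equal(morphological_smooth(img).pixels, 8.0)

    def test_bright_speck_suppressed(self):
        x = np.full((7, 7), 10.0)
        x[3, 3] = 255.0
        out = morphological_smooth(Image2D(x))
        assert out.pixels[3, 3] == 10.0

    def test_matches_brute_force(self, rng):
        x = rng.integers(0, 255, (10, 10)).astype(float)
        out = morphological_smooth(Image2D(x))
        np.testing.assert_array_equal(out.pixels, open_close_oracle(x))

    def test_opening_anti_extensive_closing_extensive(self, rng):
        x = rng.integers(0, 255, (12, 12)).astype(float)
        opened = ndimage.grey_opening(x, footprint=np.ones((3, 3), bool), mode="reflect")
        assert np.all(opened <= x)
        closed = morphological_smooth(Image2D(x)).pixels
        assert np.all(closed >= opened)


class TestGradient:
    def test_constant_zero(self):
        g = gradient_magnitude(Image2D(np.full((5, 5), 7.0)))
        np.testing.assert_array_equal(g.magnitude, 0.0)

    def test_horizontal_ramp(self):
        img = Image2D(np.tile(np.arange(8, dtype=float), (8, 1)))  # I(r,c) = c
        g = gradient_magnitude(img)
        interior = np.s_[1:-1, 1:-1]
        np.testing.assert_allclose(g.gy[interior], 0.0, atol=1e-12)
        assert np.allclose(g.gx[interior], g.gx[2, 2])
        assert g.gx[2, 2] > 0

    def test_matches_brute_force_sobel(self, rng):
        x = rng.uniform(0, 255, (8, 8))
        g = gradient_magnitude(Image2D(x))
        ox, oy, omag = sobel_oracle(x)
        np.testing.assert_allclose(g.gx, ox, atol=1e-10)
        np.testing.assert_allclose(g.gy, oy, atol=1e-10)
        np.testing.assert_allclose(g.magnitude, omag, atol=1e-10)

    def test_magnitude_identity(self, rng):
        g = gradient_magnitude(Image2D(rng.uniform(0, 255, (9, 9))))
        np.testing.assert_allclose(g.magnitude, np.sqrt(g.gx**2 + g.gy**2))


class TestGradientReference:
    def test_constant_gives_zero(self):
        img = Image2D(np.full((8, 8), 50.0))
        assert derive_gradient_reference(img) == 0.0
        grad = gradient_magnitude(img)
        assert threshold_gradient(grad, 0.5 * 0.0).white_count == grad.magnitude.size

    def test_two_level_plateau_brute_force(self):
        x = np.zeros((12, 12))
        x[4:8, 4:8] = 100.0
        img = Image2D(x)
        ref = derive_gradient_reference(img)
        mag = gradient_magnitude(img).magnitude
        top = x >= x.max() - (x.max() - x.min()) / 256
        expected = max(mag[r, c] for r in range(12) for c in range(12) if top[r, c])
        assert ref == expected

    def test_scales_linearly(self, rng):
        x = rng.uniform(0, 100, (10, 10))
        r1 = derive_gradient_reference(Image2D(x))
        r2 = derive_gradient_reference(Image2D(2.0 * x))
        assert r2 == pytest.approx(2.0 * r1, rel=1e-12)


class TestThresholdGradient:
    def test_extreme_cuts(self, rng):
        g = gradient_magnitude(Image2D(rng.uniform(0, 255, (8, 8))))
        assert threshold_gradient(g, 0.0).white_count == 64
        assert threshold_gradient(g, g.magnitude.max() + 1).white_count == 0

    def test_median_cut_count(self, rng):
        g = gradient_magnitude(Image2D(rng.uniform(0, 255, (9, 9))))
        cut = float(np.median(g.magnitude))
        mask = threshold_gradient(g, cut)
        brute = sum(
            g.magnitude[r, c] >= cut for r in range(9) for c in range(9)
        )
        assert mask.white_count == brute


class TestWatershedFlood:
    def test_single_minimum_single_basin(self):
        rr, cc = np.mgrid[0:9, 0:9]
        bowl = (rr - 4) ** 2 + (cc - 4) ** 2
        lm = watershed_flood(bowl.astype(float))
        assert lm.n_basins == 1
        assert not lm.dam_mask.any()

    def test_two_basins_one_pixel_dam(self):
        surface = np.tile(np.array([0.0, 1.0, 2.0, 1.0, 0.0]), (5, 1))
        lm = watershed_flood(surface)
        assert lm.n_basins == 2
        assert np.all(lm.dam_mask[:, 2])
        assert not lm.dam_mask[:, [0, 1, 3, 4]].any()
        # removing the dam column is exactly what separates the two basins
        assert set(np.unique(lm.labels[:, :2])) == {lm.labels[0, 0]}
        assert set(np.unique(lm.labels[:, 3:])) == {lm.labels[0, 4]}

    @pytest.mark.parametrize("connectivity", [4, 8])
    def test_matches_immersion_oracle(self, connectivity):
        rng = np.random.default_rng(99)
        for _ in range(25):
            h, w = rng.integers(4, 11, 2)
            surface = rng.integers(0, 6, (h, w)).astype(float)
            lm = watershed_flood(surface, connectivity)
            labels, k = flood_oracle(surface, connectivity)
            np.testing.assert_array_equal(lm.labels, labels)
            assert lm.n_basins == k

    def test_flooding_conservation(self, rng):
        surface = rng.integers(0, 8, (12, 12)).astype(float)
        lm = watershed_flood(surface)
        assert int(lm.dam_mask.sum()) + int(lm.basin_sizes().sum()) == surface.size

    def test_invariant_under_monotone_transform(self, rng):
        surface = rng.integers(0, 10, (10, 10)).astype(float)
        a = watershed_flood(surface)
        b = watershed_flood(surface**3 + 2.0)  # strictly increasing on >= 0
        np.testing.assert_array_equal(a.labels, b.labels)
        assert a.n_basins == b.n_basins

    @staticmethod
    def _minima_membership(surface):
        """Boolean grid: pixel belongs to a regional-minimum flat zone."""
        h, w = surface.shape
        out = np.zeros((h, w), bool)
        seen = np.zeros((h, w), bool)
        for r0 in range(h):
            for c0 in range(w):
                if seen[r0, c0]:
                    continue
                lev = surface[r0, c0]
                zone = [(r0, c0)]
                seen[r0, c0] = True
                minimal = True
                i = 0
                while i < len(zone):
                    r, c = zone[i]
                    i += 1
                    for dr in (-1, 0, 1):
                        for dc in (-1, 0, 1):
                            rr, cc = r + dr, c + dc
                            if not (0 <= rr < h and 0 <= cc < w):
                                continue
                            if surface[rr, cc] < lev:
                                minimal = False
                            elif surface[rr, cc] == lev and not seen[rr, cc]:
                                seen[rr, cc] = True
                                zone.append((rr, cc))
                if minimal:
                    for r, c in zone:
                        out[r, c] = True
        return out

    def test_isolated_new_minimum_cannot_decrease_basins(self):
        """Punching a fresh hole away from every existing minimum adds a
        basin; it can never merge the others away."""
        tested = 0
        for seed in range(12):
            r = np.random.default_rng(seed)
            surface = r.integers(2, 9, (9, 9)).astype(float)
            minima = self._minima_membership(surface)
            # pick an interior pixel with no minimum pixel in its 3x3 patch
            spot = None
            for rr in range(1, 8):
                for cc in range(1, 8):
                    if not minima[rr - 1 : rr + 2, cc - 1 : cc + 2].any():
                        spot = (rr, cc)
                        break
                if spot:
                    break
            if spot is None:
                continue
            k0 = watershed_flood(surface).n_basins
            lowered = surface.copy()
            lowered[spot] = 0.0
            assert watershed_flood(lowered).n_basins >= k0
            tested += 1
        assert tested >= 3


class TestSegmentTumor:
    def test_noiseless_phantom_high_dice(self):
        img, truth = generate_phantom(
            PhantomSpec(gaussian_sigma=0.0, impulse_fraction=0.0, seed=0)
        )
        res = segment_tumor(img)
        assert res.found
        _, dice = pixel_metrics(res.tumor_mask, truth)
        assert dice >= 0.95

    def test_all_background_reports_no_tumor(self):
        rng = np.random.default_rng(3)
        x = np.clip(rng.normal(30.0, 4.0, (128, 128)), 0, 255)
        res = segment_tumor(Image2D(ndimage.gaussian_filter(x, 1.0)))
        assert not res.found
        assert res.tumor_mask.white_count == 0

    def test_two_lesions_two_candidate_basins(self):
        base = np.full((128, 128), 30.0)
        base[ellipse_mask((128, 128), (40, 40), (10, 8))] = 200.0
        base[ellipse_mask((128, 128), (90, 90), (9, 9))] = 195.0
        img = Image2D(np.clip(ndimage.gaussian_filter(base, 1.0), 0, 255))
        res = segment_tumor(img)
        assert res.found
        assert len(res.tumor_basins) >= 2
        # the two lesion centers sit in distinct basins separated by dams
        assert res.label_map.labels[40, 40] != res.label_map.labels[90, 90]

    def test_config_validation(self):
        with pytest.raises(ValueError):
            WatershedConfig(connectivity=6).validate()
        with pytest.raises(ValueError):
            WatershedConfig(gradient_threshold=0.0).validate()
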