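import numpy as np
import pytest

from evsort.simulate import (GeneratorConfig, generate_cell,
                             generate_spot_pair, _soft_disk)
from evsort.spots import (bds_score, bright_detail_image, coloc_fraction,
                          peak_spot_mask, spot_count)
from scipy import ndimage as ndi


def _spot_image(centers, amplitude=2000.0, radius=1.5, background=100.0):
    img = np.full((32, 32), background)
    for c in centers:
        img = img + amplitude * _soft_disk(c, radius)
    return img


class TestSpotMask:
    def test_flat_image_has_no_spots(self):
        assert spot_count(np.full((32, 32), 777.0)) == 0
        assert spot_count(np.zeros((32, 32))) == 0

    def test_bright_spot_detected_with_dilated_footprint(self):
        img = _spot_image([(16, 10)], amplitude=1000.0, background=100.0)
        mask = peak_spot_mask(img)
        assert mask.n_components == 1
        assert mask.mask[16, 10]
        # dilated footprint is a strict superset of the bright core
        core = img > 600
        assert np.all(mask.mask[core])

    def test_uniform_disc_yields_no_spots(self):
        """A uniformly stained cell body (the in-vitro apoptotic pattern)
        has no point 3x above its local background."""
        disc = 1500 + 10000 * _soft_disk((15.5, 15.5), 9)
        disc = ndi.gaussian_filter(disc, 2.0)
        assert spot_count(disc) == 0

    def test_close_spots_merge_under_dilation(self):
        assert spot_count(_spot_image([(15, 12), (15, 18)])) == 1
        assert spot_count(_spot_image([(8, 8), (24, 24)])) == 2

    def test_offset_invariance(self):
        img = _spot_image([(8, 8), (24, 24)])
        m1 = peak_spot_mask(img)
        m2 = peak_spot_mask(img + 12345.0)
        np.testing.assert_array_equal(m1.mask, m2.mask)
        assert m1.n_components == m2.n_components

    def test_nonpositive_ratio_rejected(self):
        with pytest.raises(ValueError):
            peak_spot_mask(np.zeros((32, 32)), ratio=0)

    def test_generator_ground_truth_recovery(self):
        """>= 95% exact spot counts on well-separated EV cohorts."""
        cfg = GeneratorConfig(spot_count_weights=(0.4, 0.4, 0.2),
                              radius_mean=10.5, radius_sd=0.7,
                              radius_min=9.5)
        hits = 0
        n = 120
        for s in range(n):
            img, gt = generate_cell("ev", cfg, seed=s)
            hits += spot_count(img.fluorescence) == gt.spot_count
        assert hits / n >= 0.95


class TestBrightDetail:
    def test_constant_image_maps_to_zero(self):
        out = bright_detail_image(np.full((32, 32), 500.0))
        np.testing.assert_array_equal(out, 0.0)

    def test_small_spot_retained(self):
        img = _spot_image([(16, 16)], amplitude=1000.0, radius=1.5,
                          background=200.0)
        out = bright_detail_image(img, detail_radius=3)
        assert out[16, 16] >= 0.8 * 1000.0

    def test_large_disc_suppressed(self):
        img = 100 + 5000 * _soft_disk((15.5, 15.5), 12)
        out = bright_detail_image(img, detail_radius=3)
        assert out[15, 15] < 250  # interior of a large structure vanishes


class TestBDS:
    def test_identical_images_cap_the_score(self):
        img = _spot_image([(10, 10), (20, 22)])
        res = bds_score(img, img.copy())
        assert res.rho == pytest.approx(1.0)
        assert res.score == 10.0
        assert res.colocalised

    def test_transform_closed_form_at_rho_0_6(self):
        """Constructed pair with Pearson rho exactly 0.6 scores
        log2(1.6/0.4) = 2."""
        pos = [(4, 4), (4, 20), (16, 4), (16, 20), (28, 12)]
        a_vals = np.array([11.0, 12.0, 13.0, 14.0, 15.0])
        za = (a_vals - a_vals.mean()) / a_vals.std()
        u = np.array([1.0, -1.0, 1.0, -1.0, 0.0])
        u -= u.mean()
        u -= za * (u @ za) / (za @ za)  # orthogonal to za, zero-mean
        zu = u / np.sqrt((u ** 2).mean())
        b_vals = 0.6 * za + 0.8 * zu
        b_vals = 10.0 + 2.0 * b_vals  # positive isolated spikes
        a = np.zeros((32, 32))
        b = np.zeros((32, 32))
        mask = np.zeros((32, 32), dtype=bool)
        for (r, c), va, vb in zip(pos, a_vals, b_vals):
            a[r, c], b[r, c], mask[r, c] = va, vb, True
        res = bds_score(a, b, mask=mask)
        assert res.rho == pytest.approx(0.6, abs=1e-12)
        assert res.score == pytest.approx(2.0, abs=1e-9)

    def test_symmetry_in_arguments(self):
        a = _spot_image([(10, 10)])
        b = _spot_image([(11, 12)])
        r1 = bds_score(a, b)
        r2 = bds_score(b, a)
        assert r1.score == pytest.approx(r2.score)

    def test_empty_mask_scores_zero(self):
        flat = np.full((32, 32), 300.0)
        res = bds_score(flat, flat.copy())
        assert res.score == 0.0 and not res.colocalised

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            bds_score(np.zeros((32, 32)), np.zeros((16, 16)))

    def test_independent_noise_scores_near_zero(self):
        rng = np.random.default_rng(5)
        scores = []
        for _ in range(100):
            a = rng.normal(1000, 50, (32, 32))
            b = rng.normal(1000, 50, (32, 32))
            mask = np.zeros((32, 32), dtype=bool)
            mask[8:24, 8:24] = True
            scores.append(bds_score(a, b, mask=mask).score)
        assert abs(float(np.mean(scores))) < 0.3


class TestColocFraction:
    def test_all_colocalised(self):
        img = _spot_image([(10, 10)])
        res = coloc_fraction([(img, img.copy())] * 4)
        assert res["fraction"] == 1.0

    def test_recovers_designed_rate(self):
        """Channel-B spots copied from channel A in 70% of cells."""
        cells = []
        for s in range(200):
            coloc = (s % 10) < 7  # exactly 70%
            cells.append(generate_spot_pair(coloc, seed=s))
        res = coloc_fraction(cells)
        assert abs(res["fraction"] - 0.70) <= 0.05

    def test_single_cell_wilson_interval_is_wide(self):
        img = _spot_image([(10, 10)])
        res = coloc_fraction([(img, img.copy())])
        assert res["fraction"] == 1.0
        assert res["ci"][0] < 0.25

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            coloc_fraction([])
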