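"""Bates sampler, coati optimizer, region growing, four-part segmentation."""

import numpy as np
import pytest
from scipy import stats

from lungscreen.metrics import dice
from lungscreen.segment import (
    Bounds,
    SegmentConfig,
    bates_random,
    coa_init,
    coa_minimize,
    coa_step,
    region_grow,
    segment_lungs,
    select_seeds,
)


def sphere(p):
    return float(np.sum(np.asarray(p) ** 2))


class TestBatesRandom:
    def test_phi_one_is_uniform(self, rng):
        draws = bates_random(1, rng, size=10_000)
        assert stats.kstest(draws, "uniform").pvalue > 0.01

    @pytest.mark.parametrize("phi", [1, 3, 8])
    def test_moments(self, phi, rng):
        n = 100_000
        draws = bates_random(phi, rng, size=n)
        se_mean = np.sqrt(1 / (12 * phi) / n)
        assert abs(draws.mean() - 0.5) < 3 * se_mean
        assert abs(draws.var() - 1 / (12 * phi)) < 0.1 / (12 * phi)

    def test_invalid_phi_rejected(self, rng):
        with pytest.raises(ValueError):
            bates_random(0, rng)

    def test_support_is_unit_interval(self, rng):
        draws = bates_random(3, rng, size=1000)
        assert draws.min() >= 0.0 and draws.max() <= 1.0


class TestCoa:
    def test_init_within_bounds(self, rng):
        b = Bounds(np.array([-2.0, 3.0]), np.array([1.0, 9.0]))
        pop = coa_init(b, m=10, fitness_fn=sphere, rng=rng)
        assert np.all(pop.positions >= b.lower) and np.all(pop.positions <= b.upper)
        assert pop.fitness.shape == (10,)

    def test_degenerate_bounds_collapse_population(self, rng):
        eps = 1e-9
        b = Bounds(np.array([2.0, 2.0]), np.array([2.0 + eps, 2.0 + eps]))
        pop = coa_init(b, m=5, fitness_fn=sphere, rng=rng)
        assert np.all(np.abs(pop.positions - 2.0) <= eps)

    def test_seeded_init_reproducible(self):
        b = Bounds(np.array([-1.0, -1.0]), np.array([1.0, 1.0]))
        p1 = coa_init(b, 8, sphere, rng=np.random.default_rng(3))
        p2 = coa_init(b, 8, sphere, rng=np.random.default_rng(3))
        assert np.array_equal(p1.positions, p2.positions)

    def test_small_population_rejected(self, rng):
        b = Bounds(np.array([0.0]), np.array([1.0]))
        with pytest.raises(ValueError):
            coa_init(b, m=3, fitness_fn=sphere, rng=rng)

    def test_step_never_worsens_best(self, rng):
        b = Bounds(np.array([-5.0, -5.0]), np.array([5.0, 5.0]))
        pop = coa_init(b, m=12, fitness_fn=sphere, rng=rng)
        best = pop.best_fitness
        for _ in range(10):
            pop = coa_step(pop, sphere, b, rng=rng)
            assert pop.best_fitness <= best + 1e-15
            best = pop.best_fitness

    def test_sphere_convergence(self):
        b = Bounds(np.array([-5.0, -5.0]), np.array([5.0, 5.0]))
        _, fbest, trace = coa_minimize(
            sphere, b, m=20, tn_max=50, rng=np.random.default_rng(0)
        )
        assert fbest < 1e-2
        assert all(a >= bb for a, bb in zip(trace, trace[1:]))

    def test_non_finite_fitness_rejected(self, rng):
        b = Bounds(np.array([-1.0]), np.array([1.0]))
        with pytest.raises(ValueError):
            coa_init(b, 4, lambda p: float("nan"), rng=rng)


class TestRegionGrow:
    def test_uniform_image_grows_everywhere(self):
        img = np.full((20, 20), 0.5)
        assert region_grow(img, (3, 3), 0.1).all()

    def test_two_region_exact_recovery(self):
        img = np.full((30, 30), 0.3)
        img[:, 15:] = 0.8
        mask = region_grow(img, (5, 5), 0.2)
        assert dice(mask, img == 0.3) == 1.0

    def test_zero_threshold_on_ramp_is_seed_only(self):
        img = np.arange(100, dtype=float).reshape(10, 10) / 100
        mask = region_grow(img, (4, 4), 0.0)
        assert mask.sum() == 1 and mask[4, 4]

    def test_zero_threshold_matches_equal_values(self):
        img = np.zeros((10, 10))
        img[2:5, 2:5] = 0.7
        mask = region_grow(img, (3, 3), 0.0)
        assert np.array_equal(mask, img == 0.7)

    def test_result_is_single_connected_component(self, rng):
        from scipy import ndimage as ndi

        img = rng.random((40, 40))
        mask = region_grow(img, (20, 20), 0.4)
        labels, n = ndi.label(mask, structure=np.ones((3, 3)))
        assert n == 1 and mask[20, 20]

    def test_invalid_arguments_rejected(self):
        img = np.zeros((10, 10))
        with pytest.raises(ValueError):
            region_grow(img, (20, 20), 0.1)
        with pytest.raises(ValueError):
            region_grow(img, (2, 2), -0.5)
        with pytest.raises(ValueError):
            region_grow(img, (2, 2), 0.5, connectivity=6)


class TestSelectSeeds:
    def test_quadrant_blob_image(self):
        # four homogeneous bright blobs, one per quadrant
        img = np.zeros((60, 60))
        mask = np.zeros((60, 60), dtype=bool)
        for r0, c0 in [(5, 5), (5, 35), (35, 5), (35, 35)]:
            img[r0: r0 + 20, c0: c0 + 20] = 0.5
            mask[r0: r0 + 20, c0: c0 + 20] = True
        cfg = SegmentConfig(m=8, tn_max=10)
        seeds = select_seeds(img, mask, cfg, np.random.default_rng(0))
        assert len(seeds) == 4
        for (r, c), (r0, c0) in zip(seeds, [(5, 5), (5, 35), (35, 5), (35, 35)]):
            assert r0 <= r < r0 + 20 and c0 <= c < c0 + 20

    def test_seeds_deterministic_and_inside_mask(self, processed_phantom):
        res, _ = processed_phantom
        cfg = SegmentConfig(m=8, tn_max=8)
        s1 = select_seeds(res.enhanced, res.lung_mask, cfg, np.random.default_rng(4))
        s2 = select_seeds(res.enhanced, res.lung_mask, cfg, np.random.default_rng(4))
        assert s1 == s2
        for r, c in s1:
            assert res.lung_mask[r, c]

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            select_seeds(np.zeros((20, 20)), np.zeros((20, 20), dtype=bool))

    def test_empty_quadrant_borrows_seed(self):
        img = np.full((40, 40), 0.5)
        mask = np.zeros((40, 40), dtype=bool)
        mask[2:18, 2:18] = True  # top-left only
        mask[2:18, 22:38] = True  # top-right
        mask[22:38, 2:18] = True  # bottom-left; bottom-right left empty
        cfg = SegmentConfig(m=6, tn_max=5)
        with pytest.warns(UserWarning, match="borrowing"):
            seeds = select_seeds(img, mask, cfg, np.random.default_rng(1))
        assert len(seeds) == 4


class TestSegmentLungs:
    def test_quadrant_dice_against_truth(self, processed_phantom):
        from lungscreen.segment import _quadrant_slices

        res, truth = processed_phantom
        seg = segment_lungs(res.enhanced, res.lung_mask, rng=np.random.default_rng(2))
        quads = _quadrant_slices(res.lung_mask)
        scores = []
        for mask, (rs, cs) in zip(seg.masks, quads):
            qt = np.zeros_like(truth.lung_mask)
            qt[rs, cs] = truth.lung_mask[rs, cs]
            scores.append(dice(mask, qt))
        assert np.mean(scores) >= 0.80

    def test_masks_disjoint_inside_lung_and_contain_seeds(self, processed_phantom):
        res, _ = processed_phantom
        seg = segment_lungs(res.enhanced, res.lung_mask, rng=np.random.default_rng(2))
        assert len(seg.masks) == 4
        total = np.zeros_like(res.lung_mask, dtype=int)
        for (r, c), mask in zip(seg.seeds, seg.masks):
            assert mask[r, c]
            assert not mask[~res.lung_mask].any()
            total += mask
        assert total.max() <= 1  # pairwise disjoint

    def test_bit_reproducible_for_fixed_seed(self, processed_phantom):
        res, _ = processed_phantom
        a = segment_lungs(res.enhanced, res.lung_mask, rng=np.random.default_rng(8))
        b = segment_lungs(res.enhanced, res.lung_mask, rng=np.random.default_rng(8))
        assert a.seeds == b.seeds
        assert all(np.array_equal(x, y) for x, y in zip(a.masks, b.masks))
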