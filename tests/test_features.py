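"""Feature extractors: gradient histogram, spectral flatness, profiles,
edge chains, on-rib/on-vessel evidence, and the assembled vector."""

import numpy as np
import pytest
from scipy import stats as sp_stats

from lungscreen.features import (
    EdgeSegment,
    FeatureConfig,
    FeatureVector,
    detect_edges,
    extract_features,
    feature_names,
    gradient_features,
    nodule_candidate,
    on_rib_features,
    on_vessel_features,
    profile_features,
    profile_stats,
    spectral_flatness,
)
from lungscreen.phantom import NoiseModel, Nodule, PhantomSpec, generate_phantom
from lungscreen.preprocess import preprocess_image
from lungscreen.segment import segment_lungs


class TestGradientFeatures:
    def test_constant_subimage_degenerate_contract(self):
        block = gradient_features(np.full((20, 20), 0.4), np.ones((20, 20), bool))
        assert block["skewness"] == 0.0
        assert block["mode_spacing"] == 1.0
        assert np.isfinite(list(block.values())).all()

    def test_two_delta_modes_spacing(self):
        # craft a gradient sample with two histogram spikes 30 bins apart
        from lungscreen.features import _histogram_modes

        counts = np.zeros(64)
        counts[10], counts[40] = 100, 80
        modes = _histogram_modes(counts)
        assert abs(modes[0] - modes[1]) == 30

    def test_bimodality_matches_moment_oracle(self, rng):
        img = rng.normal(0.5, 0.1, (40, 40))
        mask = np.ones((40, 40), bool)
        block = gradient_features(img, mask)
        from skimage.filters import sobel

        sample = sobel(img)[mask]
        g1 = sp_stats.skew(sample)
        b2 = sp_stats.kurtosis(sample, fisher=False)
        assert block["bimodality"] == pytest.approx((g1**2 + 1) / b2, abs=1e-9)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            gradient_features(np.zeros((8, 8)), np.zeros((8, 8), bool))


class TestSpectralFlatness:
    def test_constant_crop_is_zero(self):
        assert spectral_flatness(np.full((16, 16), 0.3), np.ones((16, 16), bool)) == 0.0

    def test_impulse_has_flat_spectrum(self):
        img = np.zeros((16, 16))
        img[5, 7] = 1.0
        assert spectral_flatness(img, np.ones((16, 16), bool)) == pytest.approx(1.0)

    def test_noise_flatter_than_smooth_gradient(self, rng):
        noise = rng.random((32, 32))
        smooth = np.tile(np.linspace(0, 1, 32), (32, 1))
        mask = np.ones((32, 32), bool)
        assert spectral_flatness(noise, mask) > spectral_flatness(smooth, mask)

    def test_bounded_by_am_gm(self, rng):
        for _ in range(10):
            img = rng.random((24, 24))
            assert 0.0 <= spectral_flatness(img, np.ones((24, 24), bool)) <= 1.0


class TestProfiles:
    def test_linear_profile_zero_smoothness(self):
        stats = profile_stats(np.linspace(0, 1, 11))
        assert stats["slope_smoothness"] == pytest.approx(0.0)

    def test_toy_profile_peak_ratio(self):
        stats = profile_stats(np.array([0.0, 1.0, 0.0, 2.0, 0.0]))
        assert stats["peak_ratio"] == pytest.approx(2.0)

    def test_monotone_profile_slope_ratio_one(self):
        stats = profile_stats(np.array([0.0, 1.0, 2.0, 3.0]))
        assert stats["slope_ratio"] == pytest.approx(1.0)

    def test_short_profile_rejected(self):
        with pytest.raises(ValueError):
            profile_stats(np.array([0.0, 1.0]))

    def test_mask_too_thin_raises(self):
        edge = np.zeros((10, 10))
        mask = np.zeros((10, 10), bool)
        mask[4, :] = True  # single-row mask: every column has < 3 samples
        with pytest.raises(ValueError, match="skipped"):
            profile_features(edge, mask)

    def test_profile_block_finite_on_phantom(self, processed_phantom):
        from skimage.filters import sobel

        res, _ = processed_phantom
        block = profile_features(sobel(res.enhanced), res.lung_mask)
        assert all(np.isfinite(v) for v in block.values())
        assert 0.0 <= block["rib_cross_score"] <= 1.0


class TestDetectEdges:
    def test_blank_image_no_chains(self):
        assert detect_edges(np.zeros((40, 40))) == []
        assert detect_edges(np.zeros((40, 40)), "vessel") == []

    def test_horizontal_line_is_rib_chain(self):
        img = np.zeros((60, 60))
        img[30, 10:50] = 1.0
        ribs = detect_edges(img, "rib")
        assert len(ribs) == 1
        assert abs(ribs[0].slope) < 0.05
        assert ribs[0].eccentricity >= 0.99

    def test_two_parallel_lines_centroid_gap(self):
        img = np.zeros((80, 80))
        img[20, 10:70] = 1.0
        img[40, 10:70] = 1.0
        ribs = detect_edges(img, "rib")
        assert len(ribs) == 2
        gap = abs(ribs[0].centroid[0] - ribs[1].centroid[0])
        assert gap == pytest.approx(20.0, abs=1.0)

    def test_invalid_kind_rejected(self):
        with pytest.raises(ValueError):
            detect_edges(np.zeros((10, 10)), "bone")


class TestOnRib:
    def _chain(self, row, cols=(10, 50)):
        coords = np.array([[row, c] for c in range(*cols)])
        return EdgeSegment(
            length=float(len(coords)), slope=0.0, eccentricity=1.0,
            centroid=(float(row), float(np.mean(range(*cols)))), coords=coords,
        )

    def test_centroid_on_chain_flags_on_rib(self):
        chains = [self._chain(20), self._chain(60)]
        block = on_rib_features((20.0, 30.0), chains)
        assert block["min_centroid_segment_dist"] == 0.0
        assert block["on_rib_flag"] == 1.0

    def test_no_chains_degenerate(self):
        block = on_rib_features((10.0, 10.0), [])
        assert block["on_rib_flag"] == 0.0
        assert block["seg_length"] == 0.0
        assert np.isfinite(block["min_centroid_segment_dist"])

    def test_hand_geometry(self):
        chains = [self._chain(20), self._chain(60)]
        block = on_rib_features((30.0, 30.0), chains)
        assert block["min_centroid_segment_dist"] == pytest.approx(10.0)
        assert block["inter_rib_dist"] == pytest.approx(40.0)
        assert block["on_rib_flag"] == 1.0


class TestOnVessel:
    def _chain(self, coords):
        coords = np.asarray(coords, dtype=float)
        return EdgeSegment(
            length=float(len(coords)), slope=0.0, eccentricity=0.9,
            centroid=tuple(coords.mean(axis=0)), coords=coords,
        )

    def test_no_chains_zeroes(self):
        assert on_vessel_features((100, 100), []) == {"vessel1": 0.0, "vessel2": 0.0}

    def test_vessel1_direct_evaluation(self):
        a = self._chain([[10, c] for c in range(30)])
        b = self._chain([[50, c] for c in range(20)])
        block = on_vessel_features((100, 100), [a, b])
        assert block["vessel1"] == pytest.approx(600 / 10000)

    def test_vessel2_capped_through_center(self):
        center_chain = self._chain([[49.5 + 0, 49.5 + 0]])
        block = on_vessel_features((100, 100), [center_chain])
        assert block["vessel2"] == pytest.approx(1 / 0.5)


@pytest.fixture(scope="module")
def paired_vectors():
    """Same phantom geometry with an on-rib vs a free nodule."""
    base = PhantomSpec(seed=31, noise=NoiseModel.none())
    _, truth0 = generate_phantom(base)
    interior = truth0.lung_mask.copy()
    rib_rows, rib_cols = np.nonzero(truth0.rib_mask & interior)
    k = len(rib_rows) // 2
    par = interior & ~truth0.rib_mask & ~truth0.vessel_mask
    prow, pcol = np.nonzero(par)
    kp = len(prow) // 4
    vectors = {}
    placements = {
        "on_rib": Nodule(float(rib_rows[k]), float(rib_cols[k]), 6.0, "on_rib"),
        "free": Nodule(float(prow[kp]), float(pcol[kp]), 6.0, "free"),
    }
    for tag, nod in placements.items():
        img, _ = generate_phantom(
            PhantomSpec(seed=31, noise=NoiseModel.none(), nodules=(nod,))
        )
        res = preprocess_image(img)
        seg = segment_lungs(res.enhanced, res.lung_mask,
                            rng=np.random.default_rng(5))
        vectors[tag] = (
            extract_features(seg, res.enhanced, region=res.lung_region),
            nod,
        )
    return vectors


class TestAssembly:

    def test_vector_length_and_finiteness(self, paired_vectors):
        fv, _ = paired_vectors["free"]
        assert len(fv.values) == 84
        assert np.all(np.isfinite(fv.values))

    def test_names_match_values(self, paired_vectors):
        fv, _ = paired_vectors["free"]
        assert list(fv.names) == feature_names()
        assert fv["q0_spectral_flatness"] == fv.values[7]

    def test_nodule_quadrant_blob_radius_tracks_lesion(self, paired_vectors):
        for tag in ("on_rib", "free"):
            fv, nod = paired_vectors[tag]
            radii = [fv[f"q{i}_nodule_blob_radius"] for i in range(4)]
            assert max(radii) > 4.0  # the 6-px lesion dominates its quadrant

    def test_nonfinite_vector_rejected(self):
        with pytest.raises(ValueError):
            FeatureVector(np.full(84, np.nan))

    def test_translation_moves_distances_by_at_most_one_px(self):
        img = np.zeros((60, 60))
        img[20, 5:55] = 1.0
        img[40, 5:55] = 1.0
        ribs = detect_edges(img, "rib")
        a = on_rib_features((30.0, 30.0), ribs)
        shifted = np.roll(img, 1, axis=0)
        ribs_s = detect_edges(shifted, "rib")
        b = on_rib_features((31.0, 30.0), ribs_s)
        assert abs(a["min_centroid_segment_dist"] - b["min_centroid_segment_dist"]) <= 1.0
        assert abs(a["inter_rib_dist"] - b["inter_rib_dist"]) <= 1.0


def test_nodule_candidate_prefers_compact_blob():
    rng = np.random.default_rng(0)
    img = 0.3 + rng.normal(0, 0.01, (60, 60))
    img[10:12, 5:55] = 0.9  # thin bright band
    rr, cc = np.mgrid[0:60, 0:60]
    disk = (rr - 40) ** 2 + (cc - 30) ** 2 <= 36
    img[disk] = 0.95
    (r, c), radius = nodule_candidate(img, np.ones((60, 60), bool), pct=92.0)
    assert abs(r - 40) < 2 and abs(c - 30) < 2
    assert 4.0 <= radius <= 9.0
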