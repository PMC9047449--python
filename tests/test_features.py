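"""Feature extraction: Otsu oracle, region split, moments, nuclear edge."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from qpicd.features import (
    compute_feature_vector,
    morphological_features,
    nuclear_edge_score,
    otsu_threshold,
    split_central_peripheral,
    whole_cell_phase_features,
)
from qpicd.synthetic import render_cell_frame, SigmoidParams

from conftest import make_phase, simple_spec


def brute_force_otsu(values, n_bins=256):
    """Independent oracle: for every histogram split compute the
    between-class variance by explicit summation and take the middle of
    the maximizing plateau."""
    v = np.asarray(values, dtype=float).ravel()
    counts, edges = np.histogram(v, bins=n_bins, range=(v.min(), v.max()))
    centers = 0.5 * (edges[:-1] + edges[1:])
    sbs = []
    for i in range(n_bins - 1):
        w0 = sum(counts[: i + 1])
        w1 = sum(counts[i + 1 :])
        if w0 == 0 or w1 == 0:
            sbs.append(0.0)
            continue
        mu0 = sum(c * x for c, x in zip(counts[: i + 1], centers[: i + 1])) / w0
        mu1 = sum(c * x for c, x in zip(counts[i + 1 :], centers[i + 1 :])) / w1
        sbs.append(w0 * w1 * (mu0 - mu1) ** 2)
    sbs = np.array(sbs)
    plateau = np.flatnonzero(np.isclose(sbs, sbs.max(), rtol=1e-12, atol=0.0))
    mid = plateau[(len(plateau) - 1) // 2]
    return edges[mid + 1]


class TestOtsuThreshold:
    def test_two_level_split(self):
        thr = otsu_threshold([1, 1, 1, 3, 3, 3])
        assert 1 < thr < 3

    def test_extreme_two_values(self):
        assert 0 < otsu_threshold([0.0, 10.0]) <= 10

    def test_bimodal_threshold_in_valley(self, rng):
        v = np.concatenate(
            [rng.normal(1, 0.05, 500), rng.normal(3, 0.05, 500)]
        )
        thr = otsu_threshold(v)
        assert 1.5 <= thr <= 2.5
        assert thr == pytest.approx(brute_force_otsu(v), abs=1e-9)

    def test_matches_brute_force_on_random_inputs(self, rng):
        for _ in range(30):
            n = int(rng.integers(5, 200))
            v = rng.normal(rng.uniform(0, 5), rng.uniform(0.1, 2), n)
            if np.allclose(v, v[0]):
                continue
            assert otsu_threshold(v) == pytest.approx(
                brute_force_otsu(v), abs=1e-9
            )

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            otsu_threshold([2.0, 2.0, 2.0])

    @settings(max_examples=25, derandomize=True)
    @given(st.lists(st.floats(0, 10, allow_nan=False), min_size=3, max_size=50))
    def test_threshold_within_value_range(self, values):
        v = np.asarray(values)
        if np.all(v == v[0]):
            return
        thr = otsu_threshold(v)
        assert v.min() < thr <= v.max() + 1e-12


class TestSplitCentralPeripheral:
    def test_two_level_cell_statistics(self, two_level_cell):
        image, mask = two_level_cell
        regions = split_central_peripheral(image, mask)
        assert regions.has_central
        feats = compute_feature_vector(image, mask)
        assert feats["fried_egg_score"] == pytest.approx(0.5, abs=1e-12)
        assert feats["mean_central_phase"] == pytest.approx(3.0, abs=1e-12)
        assert feats["mean_peripheral_phase"] == pytest.approx(1.0, abs=1e-12)
        assert feats["peripheral_to_central_ratio"] == pytest.approx(1 / 3, abs=1e-12)

    def test_uniform_cell_degenerates_to_empty_central(self):
        phase = np.zeros((40, 40))
        mask = np.zeros((40, 40), dtype=bool)
        mask[10:30, 10:30] = True
        phase[mask] = 1.5
        image = make_phase(phase)
        regions = split_central_peripheral(image, mask)
        assert not regions.has_central
        feats = compute_feature_vector(image, mask)
        assert feats["fried_egg_score"] == 0.0
        assert feats["nuclear_edge_score"] == 0.0
        assert np.isnan(feats["mean_central_phase"])

    def test_partition_conservation(self, rng):
        for _ in range(10):
            phase = np.zeros((50, 50))
            mask = np.zeros((50, 50), dtype=bool)
            mask[5:45, 5:45] = True
            phase[mask] = rng.uniform(0.5, 3.0, mask.sum())
            regions = split_central_peripheral(make_phase(phase), mask)
            assert not (regions.central & regions.peripheral).any()
            assert (regions.central | regions.peripheral).sum() == mask.sum()


class TestMorphologicalFeatures:
    def test_disc_limits(self, disc_mask):
        area, circ, ecc, sol = morphological_features(disc_mask, 1.0)
        assert area == pytest.approx(np.pi * 50**2, rel=0.03)
        assert 0.95 <= circ <= 1.05
        assert 0.98 <= sol <= 1.0
        assert 0.97 <= ecc <= 1.0

    def test_two_to_one_ellipse_eccentricity(self):
        yy, xx = np.mgrid[0:128, 0:128]
        mask = ((xx - 64) / 60.0) ** 2 + ((yy - 64) / 30.0) ** 2 <= 1.0
        _, _, ecc, _ = morphological_features(mask, 1.0)
        assert ecc == pytest.approx(0.5, abs=0.03)

    def test_spike_lowers_solidity(self, disc_mask):
        mask = disc_mask.copy()
        mask[64, 114:127] = True  # radial spike
        _, _, _, sol = morphological_features(mask, 1.0)
        assert sol < 1.0

    def test_tiny_mask_rejected(self):
        mask = np.zeros((10, 10), dtype=bool)
        mask[4, 4:7] = True
        with pytest.raises(ValueError):
            morphological_features(mask, 1.0)


class TestWholeCellPhase:
    def test_uniform_phase_closed_form(self):
        phase = np.zeros((40, 40))
        mask = np.zeros((40, 40), dtype=bool)
        mask[:25, :40] = True  # 1000 px
        phase[mask] = 1.0
        vol, sd = whole_cell_phase_features(make_phase(phase), mask)
        expected = 1000 * 1.0 * (0.532 / (2 * np.pi)) * 0.48**2
        assert vol == pytest.approx(expected, rel=1e-6)
        assert sd == 0.0

    def test_volume_is_linear_in_phase(self, two_level_cell):
        image, mask = two_level_cell
        v1, _ = whole_cell_phase_features(image, mask)
        doubled = make_phase(image.phase * 2)
        v2, _ = whole_cell_phase_features(doubled, mask)
        assert v2 == pytest.approx(2 * v1, rel=1e-12)

    def test_two_level_phase_sd_is_half_range(self, two_level_cell):
        image, mask = two_level_cell
        _, sd = whole_cell_phase_features(image, mask)
        assert sd == pytest.approx(1.0, abs=1e-12)


class TestNuclearEdgeScore:
    def test_rendered_ring_detected_and_localized(self, apoptotic_ring_spec):
        fr = render_cell_frame(apoptotic_ring_spec, t=3.0)
        regions = split_central_peripheral(fr.image, fr.cell_mask)
        score, band = nuclear_edge_score(fr.image, regions)
        assert score > 0
        # the detected band must trace the true ring: most of its pixels on
        # or adjacent to the rendered two-pixel ring band
        from scipy.ndimage import binary_dilation

        near_ring = binary_dilation(fr.ring_mask, iterations=2)
        assert near_ring[band].mean() >= 0.7

    def test_uniform_cell_scores_zero(self):
        phase = np.zeros((40, 40))
        mask = np.zeros((40, 40), dtype=bool)
        mask[8:32, 8:32] = True
        phase[mask] = 2.0
        image = make_phase(phase)
        regions = split_central_peripheral(image, mask)
        score, band = nuclear_edge_score(image, regions)
        assert score == 0.0 and not band.any()

    def test_oversized_ring_rejected_by_area_window(self):
        # central fraction 0.4 -> candidate ellipse/cell area ratio > 0.3
        spec = simple_spec(
            "apoptotic",
            central_fraction=0.4,
            dynamics={"nuclear_edge_score": SigmoidParams(0.8, 3.0, 1.0)},
        )
        fr = render_cell_frame(spec, t=3.0)
        regions = split_central_peripheral(fr.image, fr.cell_mask)
        score, band = nuclear_edge_score(fr.image, regions)
        assert score == 0.0 and not band.any()

    def test_score_non_negative_on_random_cells(self, rng):
        for _ in range(5):
            phase = np.zeros((48, 48))
            mask = np.zeros((48, 48), dtype=bool)
            mask[8:40, 8:40] = True
            phase[mask] = rng.uniform(0.5, 3.0, mask.sum())
            regions = split_central_peripheral(make_phase(phase), mask)
            score, _ = nuclear_edge_score(make_phase(phase), regions)
            assert score >= 0.0


class TestScaleBehaviour:
    def test_dimensionless_features_stable_under_upsampling(self):
        # render the same smooth-boundary physical phantom at 2x finer sampling
        spec = simple_spec(axis_ratio=0.8)
        fr = render_cell_frame(spec, t=0.0, grid_shape=(96, 96), pixel_size=0.48)
        feats = compute_feature_vector(fr.image, fr.cell_mask)
        fr_up = render_cell_frame(spec, t=0.0, grid_shape=(192, 192), pixel_size=0.24)
        feats_up = compute_feature_vector(fr_up.image, fr_up.cell_mask)
        for name in (
            "circularity",
            "eccentricity",
            "solidity",
            "fried_egg_score",
            "peripheral_to_central_ratio",
        ):
            assert feats_up[name] == pytest.approx(feats[name], rel=0.02), name
        assert feats_up["optical_volume"] == pytest.approx(
            feats["optical_volume"], rel=0.02
        )
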