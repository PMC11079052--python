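"""Segmentation, foci detection and measurement must recover the generator's
ground truth exactly on noise-free scenes and degrade gracefully with noise."""

import numpy as np
import pandas as pd
import pytest

import chromofoci as cf
from tests.conftest import pairwise_jaccard


class TestSegmentNuclei:
    def test_noise_free_exact_pixel_sets(self, clean_scene):
        params, channels, truth = clean_scene
        labels = cf.segment_nuclei(channels["dna"], cf.SegmentationConfig(),
                                   params.pixel_size_um)
        assert labels.max() == 5
        # matched labels must have identical pixel sets
        assert pairwise_jaccard(labels, truth.nucleus_label_mask) == [1.0] * 5

    def test_all_zero_raster_yields_zero_nuclei(self):
        labels = cf.segment_nuclei(np.zeros((64, 64)), cf.SegmentationConfig(), 0.1)
        assert labels.max() == 0

    def test_moderate_noise_jaccard(self):
        # noise at 5% of the foci level (contrast 3 over nucleoplasm 1)
        params = cf.SceneParams(nucleus_count=5, noise_sd=0.15, seed=4)
        channels, truth = cf.simulate_scene(params)
        labels = cf.segment_nuclei(channels["dna"], cf.SegmentationConfig(),
                                   params.pixel_size_um)
        assert min(pairwise_jaccard(labels, truth.nucleus_label_mask)) >= 0.95

    def test_monotone_degradation_with_noise(self):
        means = []
        for sd in (0.0, 0.15, 0.4, 0.8):
            js = []
            for seed in (0, 1, 2):
                params = cf.SceneParams(nucleus_count=4, noise_sd=sd, seed=seed)
                channels, truth = cf.simulate_scene(params)
                labels = cf.segment_nuclei(channels["dna"], cf.SegmentationConfig(),
                                           params.pixel_size_um)
                js += pairwise_jaccard(labels, truth.nucleus_label_mask)
            means.append(np.mean(js))
        assert all(a >= b for a, b in zip(means[:-1], means[1:]))

    def test_external_mask_relabeled_not_recomputed(self, clean_scene):
        params, channels, truth = clean_scene
        config = cf.SegmentationConfig(method="external_mask")
        labels = cf.segment_nuclei(channels["dna"], config, params.pixel_size_um,
                                   external_mask=truth.nucleus_label_mask)
        assert pairwise_jaccard(labels, truth.nucleus_label_mask) == [1.0] * 5
        with pytest.raises(ValueError):
            cf.segment_nuclei(channels["dna"], config, params.pixel_size_um)


class TestDetectFoci:
    def test_noise_free_exact(self, clean_scene):
        params, channels, truth = clean_scene
        foci = cf.detect_foci(channels["dna"], truth.nucleus_label_mask,
                              cf.FociConfig(), params.pixel_size_um)
        np.testing.assert_array_equal(foci, truth.foci_mask)

    def test_uniform_nucleus_yields_no_foci(self):
        img = np.zeros((40, 40))
        mask = np.zeros((40, 40), dtype=np.int32)
        mask[5:35, 5:35] = 1
        img[mask == 1] = 7.0
        foci = cf.detect_foci(img, mask, cf.FociConfig(), 0.1)
        assert not foci.any()

    def test_per_nucleus_threshold_is_brightness_invariant(self):
        # two nuclei, 4x different absolute brightness, same internal contrast
        img = np.zeros((40, 90))
        mask = np.zeros((40, 90), dtype=np.int32)
        mask[5:35, 5:35] = 1
        mask[5:35, 50:80] = 2
        img[mask == 1] = 1.0
        img[mask == 2] = 4.0
        img[15:20, 15:20] = 3.0   # focus in nucleus 1
        img[15:20, 60:65] = 12.0  # focus in nucleus 2, same 3x contrast
        foci = cf.detect_foci(img, mask, cf.FociConfig(), 0.1)
        from skimage.measure import label as cc_label
        assert cc_label(foci & (mask == 1)).max() == cc_label(foci & (mask == 2)).max() == 1

    @pytest.mark.parametrize("rule", ["otsu_within_nucleus", "mean_plus_k_sd"])
    def test_foci_subset_of_nuclei(self, clean_scene, rule):
        params, channels, truth = clean_scene
        foci = cf.detect_foci(channels["dna"], truth.nucleus_label_mask,
                              cf.FociConfig(threshold_rule=rule), params.pixel_size_um)
        assert not (foci & (truth.nucleus_label_mask == 0)).any()


class TestMeasureNuclei:
    def test_ground_truth_round_trip(self, clean_scene):
        params, channels, truth = clean_scene
        ms = cf.measure_nuclei(channels, truth.nucleus_label_mask, truth.foci_mask,
                               params.pixel_size_um)
        for m in ms:
            row = truth.per_nucleus_params.loc[m.nucleus_id]
            assert m.foci_count == row["foci_count"]
            assert m.foci_area_px == row["foci_area_px"]
            assert m.mean_foci["dna"] == pytest.approx(row["dna_foci_mean"], rel=1e-12)
            assert m.mean_nucleoplasm["dna"] == pytest.approx(
                row["dna_nucleoplasm_mean"], rel=1e-12)

    def test_area_conversion(self):
        mask = np.zeros((100, 100), dtype=np.int32)
        mask[:, :] = 1  # 10 000 px
        img = {"dna": np.ones((100, 100))}
        m = cf.measure_nuclei(img, mask, np.zeros((100, 100), bool), 0.1)[0]
        assert m.nucleus_area_um2 == pytest.approx(100.0)

    def test_ratio_direct_substitution(self):
        mask = np.zeros((10, 10), dtype=np.int32)
        mask[:] = 1
        foci = np.zeros((10, 10), bool)
        foci[:2, :2] = True
        img = np.full((10, 10), 80.0)
        img[foci] = 200.0
        m = cf.measure_nuclei({"c": img}, mask, foci, 1.0)[0]
        assert m.ratio["c"] == pytest.approx(2.5)

    def test_sum_decomposition_invariant(self, clean_scene):
        params, channels, truth = clean_scene
        for m in cf.measure_nuclei(channels, truth.nucleus_label_mask,
                                   truth.foci_mask, params.pixel_size_um):
            for ch in channels:
                foci_part = (m.mean_foci[ch] * m.foci_area_px) if m.foci_area_px else 0.0
                nucleo_part = m.mean_nucleoplasm[ch] * (m.nucleus_area_px - m.foci_area_px)
                assert m.total_nuclear[ch] == pytest.approx(foci_part + nucleo_part,
                                                            rel=1e-12)

    def test_intensity_scale_equivariance(self, clean_scene):
        params, channels, truth = clean_scene
        scaled = {k: 7.3 * v for k, v in channels.items()}
        base = cf.measure_nuclei(channels, truth.nucleus_label_mask, truth.foci_mask,
                                 params.pixel_size_um)
        big = cf.measure_nuclei(scaled, truth.nucleus_label_mask, truth.foci_mask,
                                params.pixel_size_um)
        for a, b in zip(base, big):
            assert a.nucleus_area_um2 == b.nucleus_area_um2
            for ch in a.ratio:
                assert a.ratio[ch] == pytest.approx(b.ratio[ch], rel=1e-12)

    def test_foci_outside_nucleus_rejected(self):
        mask = np.zeros((10, 10), dtype=np.int32)
        mask[2:8, 2:8] = 1
        foci = np.zeros((10, 10), bool)
        foci[0, 0] = True
        with pytest.raises(ValueError):
            cf.measure_nuclei({"dna": np.ones((10, 10))}, mask, foci, 0.1)


class TestClassifyAndSummarize:
    def _measurement(self, foci_count, ratio):
        m = cf.NucleusMeasurement(nucleus_id=1, nucleus_area_um2=100.0,
                                  foci_count=foci_count, foci_area_um2=5.0)
        if foci_count:
            m.ratio["reporter"] = ratio
        return m

    @pytest.mark.parametrize("foci_count,ratio,expected", [
        (0, None, "diffuse"),
        (3, 3.0, "spotty"),
        (3, 1.3, "mixed"),
        (3, 1.05, "diffuse"),
        (3, 1.5, "spotty"),   # boundary: at-threshold counts as spotty
    ])
    def test_classification(self, foci_count, ratio, expected):
        call = cf.classify_distribution(self._measurement(foci_count, ratio), "reporter")
        assert call.label == expected
        assert call.thresholds == (1.5, 1.1)

    def test_single_replicate_sd_flagged(self):
        calls = pd.DataFrame({"group": ["a"] * 4, "replicate": [1] * 4,
                              "label": ["spotty"] * 4})
        out = cf.summarize_calls(calls)
        assert out.loc[0, "spotty_mean"] == 1.0
        assert np.isnan(out.loc[0, "spotty_sd"])
        assert out.loc[0, "n_replicates"] == 1

    def test_two_replicate_mean(self):
        rows = ([("a", 1, "spotty")] * 2 + [("a", 1, "diffuse")] * 3
                + [("a", 2, "spotty")] * 3 + [("a", 2, "diffuse")] * 2)
        calls = pd.DataFrame(rows, columns=["group", "replicate", "label"])
        out = cf.summarize_calls(calls)
        assert out.loc[0, "spotty_mean"] == pytest.approx(0.5)  # (0.4 + 0.6) / 2

    def test_fractions_match_hand_tally(self):
        rng = np.random.default_rng(0)
        labels = rng.choice(["spotty", "mixed", "diffuse"], size=60)
        reps = rng.integers(1, 4, size=60)
        calls = pd.DataFrame({"group": "g", "replicate": reps, "label": labels})
        out = cf.summarize_calls(calls)
        # brute-force tally
        expected = np.mean([
            (labels[reps == r] == "mixed").mean() for r in np.unique(reps)
        ])
        assert out.loc[0, "mixed_mean"] == pytest.approx(expected)
        total = out.loc[0, ["spotty_mean", "mixed_mean", "diffuse_mean"]].sum()
        assert total == pytest.approx(1.0, abs=1e-12)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            cf.summarize_calls(pd.DataFrame(columns=["group", "replicate", "label"]))
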