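"""The generators must be deterministic, obey their invariants, and carry
ground truth that downstream stages can recover."""

import dataclasses

import numpy as np
import pytest

import chromofoci as cf
from chromofoci.synthetic import ScenePlacementError, two_phase_curve


class TestSimulateScene:
    def test_single_focus_ratio_equals_contrast(self):
        params = cf.SceneParams(nucleus_count=1, foci_per_nucleus_exact=1,
                                dna_foci_to_nucleoplasm_contrast=3.0, noise_sd=0.0)
        channels, truth = cf.simulate_scene(params)
        dna = channels["dna"]
        foci = truth.foci_mask
        nucleoplasm = (truth.nucleus_label_mask > 0) & ~foci
        assert dna[foci].mean() / dna[nucleoplasm].mean() == pytest.approx(3.0, abs=0)

    def test_same_seed_bit_identical(self):
        params = cf.SceneParams(nucleus_count=3, noise_sd=0.2, seed=7)
        ch1, t1 = cf.simulate_scene(params)
        ch2, t2 = cf.simulate_scene(params)
        for name in ch1:
            np.testing.assert_array_equal(ch1[name], ch2[name])
        np.testing.assert_array_equal(t1.nucleus_label_mask, t2.nucleus_label_mask)
        np.testing.assert_array_equal(t1.foci_mask, t2.foci_mask)

    def test_zero_foci_mean(self):
        _, truth = cf.simulate_scene(cf.SceneParams(foci_per_nucleus_mean=0.0))
        assert not truth.foci_mask.any()
        assert (truth.per_nucleus_params["foci_count"] == 0).all()

    def test_nuclei_disjoint_and_labels_contiguous(self, clean_scene):
        _, _, truth = clean_scene
        labels = np.unique(truth.nucleus_label_mask)
        np.testing.assert_array_equal(labels, np.arange(len(labels)))
        assert labels[-1] == 5

    def test_foci_inside_nuclei(self, clean_scene):
        _, _, truth = clean_scene
        assert not (truth.foci_mask & (truth.nucleus_label_mask == 0)).any()

    def test_diffuse_reporter_has_no_enrichment(self):
        params = cf.SceneParams(nucleus_count=2, reporter_mode="diffuse",
                                foci_per_nucleus_exact=3, noise_sd=0.0)
        channels, truth = cf.simulate_scene(params)
        rep = channels["reporter"]
        assert rep[truth.foci_mask].mean() == rep[(truth.nucleus_label_mask > 0)].mean()

    def test_mass_conservation(self, clean_scene):
        # integrated intensity = foci mean * foci area + nucleoplasm mean * rest
        _, channels, truth = clean_scene
        for _, row in truth.per_nucleus_params.iterrows():
            nucleus = truth.nucleus_label_mask == row["nucleus_id"]
            for ch in ("dna", "reporter"):
                img = channels[ch]
                total = img[nucleus].sum()
                foci = nucleus & truth.foci_mask
                nucleoplasm = nucleus & ~truth.foci_mask
                decomposed = (img[foci].sum() if foci.any() else 0.0) + img[nucleoplasm].sum()
                assert total == pytest.approx(decomposed, rel=1e-12)

    def test_pixel_values_nonnegative(self):
        channels, _ = cf.simulate_scene(cf.SceneParams(noise_sd=1.0, seed=1))
        assert all((img >= 0).all() for img in channels.values())

    def test_placement_failure_raises(self):
        params = cf.SceneParams(nucleus_count=9, nucleus_radius_px=40,
                                image_shape=(120, 120))
        with pytest.raises(ScenePlacementError):
            cf.simulate_scene(params)

    @pytest.mark.parametrize("kwargs", [
        {"focus_radius_px": 50.0},       # focus larger than nucleus
        {"dna_foci_to_nucleoplasm_contrast": 0.5},
        {"noise_sd": -1.0},
        {"nucleus_count": 0},
    ])
    def test_invalid_params_rejected(self, kwargs):
        with pytest.raises(ValueError):
            cf.SceneParams(**kwargs)


class TestSimulatePopulation:
    def test_noise_free_concentration_buffering_pins_foci_concentration(self):
        pop = cf.simulate_population(cf.PopulationParams(
            regime="concentration_buffering", noise_cv=0.0))
        assert pop["foci_concentration"].var() == 0.0

    def test_noise_free_size_buffering_ratio_constant(self):
        pop = cf.simulate_population(cf.PopulationParams(
            regime="size_buffering", noise_cv=0.0))
        ratio = pop["foci_concentration"] / pop["total_expression"]
        assert np.allclose(ratio, ratio.iloc[0], rtol=1e-12)

    def test_r2_separates_regimes(self):
        # independent closed-form Pearson oracle on the log-log relation
        def pearson_r2(x, y):
            lx, ly = np.log10(x), np.log10(y)
            cov = ((lx - lx.mean()) * (ly - ly.mean())).mean()
            return cov**2 / (lx.var() * ly.var())

        size = cf.simulate_population(cf.PopulationParams(
            regime="size_buffering", n_cells=100, noise_cv=0.1, seed=21))
        conc = cf.simulate_population(cf.PopulationParams(
            regime="concentration_buffering", n_cells=100, noise_cv=0.1, seed=21))
        assert pearson_r2(size["total_expression"], size["foci_concentration"]) > 0.9
        assert pearson_r2(conc["total_expression"], conc["foci_concentration"]) < 0.2

    def test_area_grows_with_expression_under_concentration_buffering(self):
        pop = cf.simulate_population(cf.PopulationParams(
            regime="concentration_buffering", noise_cv=0.0, seed=2))
        ordered = pop.sort_values("total_expression")["foci_area_um2"].to_numpy()
        assert (np.diff(ordered) > 0).all()

    def test_determinism(self):
        p = cf.PopulationParams(regime="size_buffering", seed=9)
        assert cf.simulate_population(p).equals(cf.simulate_population(p))

    def test_invalid_params(self):
        with pytest.raises(ValueError):
            cf.PopulationParams(regime="size_buffering", c_sat=-1.0)
        with pytest.raises(ValueError):
            cf.PopulationParams(regime="size_buffering",
                                expression_log10_range=(1.0, 1.0))


class TestSimulateFrapTrace:
    def test_noise_free_postbleach_equals_model(self):
        params = cf.FrapSimParams(y0=0.2, span_fast=0.5, k_fast=0.1,
                                  span_slow=0.2, k_slow=0.01)
        trace = cf.simulate_frap_trace(params)
        t_post = trace.time_s[params.n_prebleach:] - trace.time_s[params.n_prebleach]
        expected = two_phase_curve(t_post, 0.2, 0.5, 0.1, 0.2, 0.01)
        np.testing.assert_array_equal(trace.frap_spot[params.n_prebleach:], expected)

    def test_frame_count_and_bleach_index(self):
        trace = cf.simulate_frap_trace(cf.FrapSimParams(n_prebleach=5, interval_s=1.0,
                                                        duration_s=400.0))
        assert len(trace.time_s) == 400
        assert trace.n_prebleach == 5
        assert trace.time_s[5] == 5.0

    def test_prebleach_at_plateau_and_control_decay(self):
        params = cf.FrapSimParams(acquisition_bleach_rate=0.002, amplitude=100.0)
        trace = cf.simulate_frap_trace(params)
        np.testing.assert_allclose(
            trace.control_spot, 100.0 * np.exp(-0.002 * trace.time_s), rtol=1e-12)
        np.testing.assert_allclose(
            trace.frap_spot[:5], 100.0 * np.exp(-0.002 * trace.time_s[:5]), rtol=1e-12)

    def test_normalization_removes_acquisition_bleaching(self):
        # the normalized curve with bleaching must match the bleach-free trace
        base = dict(y0=0.2, span_fast=0.5, k_fast=0.1, span_slow=0.2, k_slow=0.01)
        clean = cf.normalize_frap(cf.simulate_frap_trace(cf.FrapSimParams(**base)))
        bleached = cf.normalize_frap(cf.simulate_frap_trace(
            cf.FrapSimParams(**base, acquisition_bleach_rate=0.001)))
        assert np.max(np.abs(clean.value - bleached.value)) < 1e-6

    def test_invalid_rates(self):
        with pytest.raises(ValueError):
            cf.FrapSimParams(k_fast=0.01, k_slow=0.1)  # violates k_fast >= k_slow
        with pytest.raises(ValueError):
            cf.FrapSimParams(acquisition_bleach_rate=-0.1)

    def test_regime_params_hit_targets(self):
        for regime, mobile, t50 in [(cf.SLOW_REGIME, 0.752, 75.5),
                                    (cf.FAST_REGIME, 0.975, 9.9)]:
            curve = two_phase_curve(np.array([t50, 395.0]), regime.y0,
                                    regime.span_fast, regime.k_fast,
                                    regime.span_slow, regime.k_slow)
            assert curve[0] == pytest.approx(0.5, abs=1e-12)
            assert curve[1] == pytest.approx(mobile, abs=1e-12)


class TestSimulateSatelliteArray:
    UNIT = "ACGTTGCATGGACCTAAGTCAATGCCTTGA"

    def test_full_methylation_flags_every_cpg(self):
        ms = cf.simulate_satellite_array(self.UNIT, 5, 0.0, 1.0, seed=0)
        assert sorted(ms.methylated_cpg) == ms.cpg_positions()

    def test_exact_tandem_copies(self):
        ms = cf.simulate_satellite_array(self.UNIT, 3, 0.0, 0.0, seed=0)
        assert len(ms.seq) == 90
        assert ms.seq == self.UNIT * 3

    def test_methylated_fraction_binomial(self):
        ms = cf.simulate_satellite_array(self.UNIT, 500, 0.0, 0.5, seed=3)
        n_cpg = len(ms.cpg_positions())
        frac = len(ms.methylated_cpg) / n_cpg
        assert abs(frac - 0.5) < 3 * np.sqrt(0.25 / n_cpg)

    def test_non_acgt_unit_rejected(self):
        with pytest.raises(ValueError):
            cf.simulate_satellite_array("ACGN", 2)

    def test_determinism(self):
        a = cf.simulate_satellite_array(self.UNIT, 10, 0.1, 0.5, seed=4)
        b = cf.simulate_satellite_array(self.UNIT, 10, 0.1, 0.5, seed=4)
        assert a.seq == b.seq and a.methylated_cpg == b.methylated_cpg
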