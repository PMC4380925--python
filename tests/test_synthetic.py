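"""Generator contracts: scenes, planted tables, traces and fold-change panels."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from shapesignal import synthetic as syn
from shapesignal.catalog import TF_NODE


class TestSimulateScene:
    def test_isolated_cell_has_zero_neighbor_fraction(self):
        spec = syn.SceneSpec(image_size=(256, 256),
                             colonies=[syn.ColonyPlan((128.0, 128.0), 1)], seed=1)
        res = syn.simulate_scene(spec)
        assert len(res.truth) == 1
        assert res.truth["neighbor_fraction"].iloc[0] == 0.0
        assert res.truth["colony_size"].iloc[0] == 1.0

    def test_hex_colony_center_cell_fully_surrounded(self, colony_scene):
        _, scene = colony_scene
        nf = scene.truth["neighbor_fraction"]
        assert nf.iloc[0] >= 0.98  # center cell of the 7-cell colony
        assert (nf.iloc[1:7] > 0.3).all()  # ring cells partially in contact

    def test_rendered_tf_ratio_matches_target(self):
        spec = syn.SceneSpec(image_size=(256, 256),
                             colonies=[syn.ColonyPlan((128.0, 128.0), 1)],
                             tf_ratio_target=2.0, tf_ratio_noise_sd=0.0, seed=3)
        res = syn.simulate_scene(spec)
        # integrate rendered pixels over the true masks
        nuc = res.nucleus_labels == 1
        from shapesignal.features import segment_regions
        regions = segment_regions(
            res.nucleus_image, res.body_image,
            true_nucleus_labels=res.nucleus_labels, true_cell_labels=res.cell_labels)
        ring = regions.perinuclear_ring == 1
        ratio = res.tf_image[nuc].mean() / res.tf_image[ring].mean()
        assert ratio == pytest.approx(2.0, abs=0.05)

    def test_every_nucleus_inside_its_cell(self, colony_scene):
        _, scene = colony_scene
        inside = scene.cell_labels[scene.nucleus_labels > 0]
        assert (inside == scene.nucleus_labels[scene.nucleus_labels > 0]).all()

    def test_same_seed_gives_identical_pixels(self):
        spec = syn.SceneSpec(image_size=(256, 256),
                             colonies=[syn.ColonyPlan((128.0, 128.0), 3)],
                             ruffle_amplitude=0.05, tf_ratio_noise_sd=0.2, seed=5)
        a, b = syn.simulate_scene(spec), syn.simulate_scene(spec)
        assert np.array_equal(a.tf_image, b.tf_image)
        assert np.array_equal(a.cell_labels, b.cell_labels)
        pd.testing.assert_frame_equal(a.truth, b.truth)

    def test_infeasible_packing_names_colony(self):
        spec = syn.SceneSpec(image_size=(256, 256),
                             colonies=[syn.ColonyPlan((128.0, 128.0), 7, packing=0.3)], seed=1)
        with pytest.raises(ValueError, match="colony 0"):
            syn.simulate_scene(spec)

    def test_nucleus_must_fit_in_body(self):
        spec = syn.SceneSpec(nucleus_radius_frac=0.7, nucleus_offset_frac=0.5)
        with pytest.raises(ValueError, match="nucleus"):
            spec.validate()


class TestSimulateFeatureTable:
    def test_no_parents_means_no_correlation(self):
        planted = syn.PlantedDependency(
            noise_sds={TF_NODE: 0.2},
            states=[syn.MixtureState(1.0,
                                     {"cell_area": 1500.0, "neighbor_fraction": 0.5},
                                     {"cell_area": 300.0, "neighbor_fraction": 0.15})],
        )
        table, _ = syn.simulate_feature_table(planted, n_cells=10_000, seed=2)
        null_sd = 1 / np.sqrt(len(table))
        for feat in ("cell_area", "neighbor_fraction"):
            r = np.corrcoef(table[feat], table[TF_NODE])[0, 1]
            assert abs(r) < 0.05
            assert abs(r) < 4 * null_sd

    def test_ols_recovers_planted_edge_coefficient(self):
        planted = syn.PlantedDependency(
            edges=[("neighbor_fraction", TF_NODE, -1.0)],
            noise_sds={TF_NODE: 0.1},
            states=[syn.MixtureState(1.0, {"neighbor_fraction": 0.5},
                                     {"neighbor_fraction": 0.15})],
        )
        table, graph = syn.simulate_feature_table(planted, n_cells=5000, seed=3)
        fit = sm.OLS(table[TF_NODE],
                     sm.add_constant(table["neighbor_fraction"])).fit()
        assert fit.params.iloc[1] == pytest.approx(-1.0, abs=0.05)
        assert list(graph.edges) == [("neighbor_fraction", TF_NODE)]

    def test_two_state_mixture_recovers_both_modes(self):
        planted = syn.PlantedDependency(
            states=[
                syn.MixtureState(0.5, {"cell_area": 800.0}, {"cell_area": 120.0}),
                syn.MixtureState(0.5, {"cell_area": 2200.0}, {"cell_area": 120.0}),
            ],
        )
        table, _ = syn.simulate_feature_table(planted, n_cells=10_000, seed=4)
        areas = table["cell_area"].to_numpy()
        lo, hi = areas[areas < 1500], areas[areas >= 1500]
        # each state's sample mean within 3 standard errors of the planted mean
        for sample, mean in [(lo, 800.0), (hi, 2200.0)]:
            se = sample.std(ddof=1) / np.sqrt(len(sample))
            assert abs(sample.mean() - mean) < 3 * se
        counts, edges = np.histogram(areas, bins=40)
        modes = edges[np.argsort(counts)[-2:]]
        assert min(abs(modes - 800)).min() < 200 and min(abs(modes - 2200)) < 200

    def test_cyclic_dag_rejected_with_cycle_listed(self):
        planted = syn.PlantedDependency(
            edges=[("a", "b", 1.0), ("b", "a", 1.0)], noise_sds={},
        )
        with pytest.raises(ValueError, match="cycle"):
            syn.simulate_feature_table(planted, n_cells=10)

    def test_rows_equal_cells_times_conditions_with_shift(self):
        planted = syn.PlantedDependency(
            states=[syn.MixtureState(1.0, {"cell_area": 1000.0}, {"cell_area": 10.0})],
            noise_sds={TF_NODE: 0.01},
            treatment_shift={"tnf_1h": 0.4},
        )
        table, _ = syn.simulate_feature_table(
            planted, n_cells=500, conditions=["untreated", "tnf_1h"], seed=5)
        assert len(table) == 1000
        shift = (table.groupby("treatment")[TF_NODE].mean().loc["tnf_1h"]
                 - table.groupby("treatment")[TF_NODE].mean().loc["untreated"])
        assert shift == pytest.approx(0.4, abs=0.05)


class TestSimulateTrace:
    def test_zero_amplitude_zero_noise_is_constant_baseline(self):
        tr = syn.simulate_trace(syn.OscillationParams(amplitude=0.0, noise_sd=0.0, baseline=1.3))
        assert np.allclose(tr.values, 1.3)
        assert len(tr.values) == 360 // 5 + 1

    def test_noiseless_maxima_spaced_one_period_apart(self):
        params = syn.OscillationParams(period=120.0, noise_sd=0.0,
                                       damping_timescale=np.inf, duration=600.0)
        tr = syn.simulate_trace(params)
        v = tr.values
        peaks = np.flatnonzero((v[1:-1] > v[:-2]) & (v[1:-1] >= v[2:])) + 1
        spacings = np.diff(tr.times[peaks])
        assert np.all(np.abs(spacings - 120.0) <= params.dt)

    def test_same_seed_identical_trace(self):
        p = syn.OscillationParams(noise_sd=0.1, seed=42)
        a, b = syn.simulate_trace(p), syn.simulate_trace(p)
        assert np.array_equal(a.values, b.values)

    def test_aliased_period_rejected(self):
        with pytest.raises(ValueError, match="alias"):
            syn.OscillationParams(period=9.0, dt=5.0).validate()


class TestFoldChangePanel:
    def test_noiseless_panel_is_exactly_linear(self):
        coefs = (1.4, -0.3, 0.4, -0.5)
        panel = syn.simulate_fold_change_panel(coefs, 50, 0.0, seed=1)
        X = np.column_stack([np.ones(50), panel["d_nf"], panel["d_ruffliness"],
                             panel["d_anucacyto"]])
        beta, *_ = np.linalg.lstsq(X, panel["d_tfratio"], rcond=None)
        assert np.allclose(beta, coefs, atol=1e-8)

    def test_default_panel_has_176_conditions(self):
        panel = syn.simulate_fold_change_panel(seed=0)
        assert len(panel) == 176
        assert (panel[["d_nf", "d_ruffliness", "d_anucacyto", "d_tfratio"]] > 0).all().all()

    def test_noise_calibration_hits_target_r2_over_seeds(self):
        coefs = (1.4, -0.3, 0.4, -0.5)
        noise = syn.noise_sd_for_target_r2(coefs, 0.37)
        r2 = []
        for seed in range(100):
            panel = syn.simulate_fold_change_panel(coefs, 176, noise, seed=seed)
            X = np.column_stack([np.ones(176), panel["d_nf"], panel["d_ruffliness"],
                                 panel["d_anucacyto"]])
            y = panel["d_tfratio"].to_numpy()
            beta, res_, *_ = np.linalg.lstsq(X, y, rcond=None)
            resid = y - X @ beta
            r2.append(1 - resid.var() / y.var())
        assert np.mean(r2) == pytest.approx(0.37, abs=0.08)

    def test_negative_noise_rejected(self):
        with pytest.raises(ValueError):
            syn.simulate_fold_change_panel(noise_sd=-0.1)
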