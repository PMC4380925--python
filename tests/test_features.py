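"""Extractor contracts: segmentation, the 77-feature catalog, NF, TF ratio."""

import numpy as np
import pandas as pd
import pytest

from shapesignal import features as ft
from shapesignal.catalog import CANONICAL_17, DEFAULT_CATALOG, FEATURE_NAMES
from conftest import match_true_to_segmented


def _square_scene(side=40, gap=0):
    """Two axis-aligned squares sharing one full side (gap=0) or separated."""
    h = 128
    lab = np.zeros((h, h), dtype=np.int32)
    lab[40:40 + side, 20:20 + side] = 1
    lab[40:40 + side, 20 + side + gap:20 + 2 * side + gap] = 2
    nuc = np.zeros_like(lab)
    for i, cx in [(1, 20 + side // 2), (2, 20 + side + gap + side // 2)]:
        nuc[40 + side // 2 - 6:40 + side // 2 + 6, cx - 6:cx + 6] = i
    return nuc, lab


class TestCatalog:
    def test_catalog_has_77_unique_names_with_canonical_subset(self):
        assert len(FEATURE_NAMES) == 77
        assert len(set(FEATURE_NAMES)) == 77
        assert len(CANONICAL_17) == 17
        assert set(CANONICAL_17) <= set(FEATURE_NAMES)

    def test_validate_table_lists_missing_names(self):
        with pytest.raises(ValueError, match="tf_ratio"):
            DEFAULT_CATALOG.validate_table([c for c in FEATURE_NAMES if c != "tf_ratio"])


class TestSegmentation:
    def test_blank_images_give_empty_result(self):
        blank = np.zeros((64, 64))
        regions = ft.segment_regions(blank, blank)
        assert len(regions.cell_ids) == 0

    def test_mismatched_shapes_rejected(self):
        with pytest.raises(ValueError, match="shapes differ"):
            ft.segment_regions(np.zeros((64, 64)), np.zeros((32, 32)))

    def test_perinuclear_ring_matches_pixelated_annulus(self, disk_regions):
        # independent oracle: pixel centers within (R, R + w_r] of the disk center
        yy, xx = np.mgrid[0:128, 0:128]
        r = np.hypot(yy - 64, xx - 64)
        oracle = int(((r > 20) & (r <= 24)).sum())
        ring = int((disk_regions.perinuclear_ring == 1).sum())
        assert ring == pytest.approx(oracle, rel=0.05)

    def test_recovered_masks_overlap_truth(self, colony_scene, colony_segmentation):
        _, scene = colony_scene
        mapping = match_true_to_segmented(scene.cell_labels, colony_segmentation.cell_labels)
        for i, j in mapping.items():
            tm = scene.cell_labels == i
            sm = colony_segmentation.cell_labels == j
            jaccard = (tm & sm).sum() / (tm | sm).sum()
            assert jaccard > 0.9


class TestShapeFeatures:
    def test_disk_roundness_and_concentric_centers(self, disk_regions):
        df = ft.shape_features(disk_regions)
        assert df["cell_roundness"].iloc[0] >= 0.95
        assert df["centers_distance"].iloc[0] == pytest.approx(0.0, abs=1.5)

    def test_a_nuc_a_cyto_uses_cell_minus_nucleus(self):
        # 2000 px^2 cell (50x40), 300 px^2 nucleus (20x15) -> 300/1700
        lab = np.zeros((96, 96), dtype=np.int32)
        lab[20:70, 20:60] = 1
        nuc = np.zeros_like(lab)
        nuc[40:60, 30:45] = 1
        regions = ft.segment_regions(nuc * 3000.0, lab * 1500.0,
                                     true_nucleus_labels=nuc, true_cell_labels=lab)
        df = ft.shape_features(regions)
        assert df["a_nuc_a_cyto"].iloc[0] == pytest.approx(300 / 1700, rel=1e-6)
        assert df["cell_area"].iloc[0] == 2000.0

    def test_cell_without_nucleus_dropped(self):
        lab = np.zeros((64, 64), dtype=np.int32)
        lab[10:30, 10:30] = 1
        lab[40:60, 40:60] = 2
        nuc = np.zeros_like(lab)
        nuc[15:25, 15:25] = 1  # only cell 1 has a nucleus
        regions = ft.segment_regions(nuc * 3000.0, lab * 1500.0,
                                     true_nucleus_labels=nuc, true_cell_labels=lab)
        df = ft.shape_features(regions)
        assert list(df.index) == [1]


class TestContextFeatures:
    def test_isolated_cell(self, disk_regions):
        df = ft.context_features(disk_regions)
        assert df["neighbor_fraction"].iloc[0] == 0.0
        assert df["colony_size"].iloc[0] == 1.0

    def test_enclosed_cell_neighbor_fraction_near_one(self, colony_scene):
        _, scene = colony_scene
        regions = ft.segment_regions(
            scene.nucleus_image, scene.body_image,
            true_nucleus_labels=scene.nucleus_labels, true_cell_labels=scene.cell_labels)
        df = ft.context_features(regions)
        assert df["neighbor_fraction"].loc[1] >= 0.98

    def test_two_squares_sharing_one_side(self):
        nuc, lab = _square_scene(side=40)
        regions = ft.segment_regions(nuc * 3000.0, lab * 1500.0,
                                     true_nucleus_labels=nuc, true_cell_labels=lab)
        df = ft.context_features(regions)
        # one shared side of four; allow one boundary pixel of slack
        perimeter_px = 4 * 40
        tol = 2.0 / perimeter_px
        assert df["neighbor_fraction"].loc[1] == pytest.approx(0.25, abs=0.25 * 0.2 + tol)
        assert (df["colony_size"] == 2.0).all()

    def test_adding_a_neighbor_never_decreases_nf(self):
        nuc_iso, lab_iso = _square_scene(side=40, gap=20)
        lab_alone = np.where(lab_iso == 1, 1, 0).astype(np.int32)
        nuc_alone = np.where(nuc_iso == 1, 1, 0).astype(np.int32)
        r_alone = ft.segment_regions(nuc_alone * 3000.0, lab_alone * 1500.0,
                                     true_nucleus_labels=nuc_alone, true_cell_labels=lab_alone)
        nf_alone = ft.context_features(r_alone)["neighbor_fraction"].loc[1]
        nuc, lab = _square_scene(side=40, gap=0)
        r_both = ft.segment_regions(nuc * 3000.0, lab * 1500.0,
                                    true_nucleus_labels=nuc, true_cell_labels=lab)
        nf_both = ft.context_features(r_both)["neighbor_fraction"].loc[1]
        assert nf_both >= nf_alone


class TestIntensityFeatures:
    def test_uniform_membrane_has_zero_ruffliness(self, disk_regions):
        flat = np.full((128, 128), 500.0)
        df = ft.intensity_features(disk_regions, {"dna": flat, "body": flat, "tf": flat})
        assert df["ruffliness"].iloc[0] == 0.0
        assert df["tf_ratio"].iloc[0] == pytest.approx(1.0)
        assert df["log10_tf_ratio"].iloc[0] == pytest.approx(0.0)

    def test_tf_ratio_arithmetic(self, disk_regions):
        yy, xx = np.mgrid[0:128, 0:128]
        tf = np.where(np.hypot(yy - 64, xx - 64) <= 20, 200.0, 100.0)
        flat = np.full((128, 128), 500.0)
        df = ft.intensity_features(disk_regions, {"dna": flat, "body": flat, "tf": tf})
        assert df["tf_ratio"].iloc[0] == pytest.approx(2.0)
        assert df["log10_tf_ratio"].iloc[0] == pytest.approx(0.3010, abs=1e-4)

    def test_zero_ring_mean_flags_record(self, disk_regions):
        zero_tf = np.zeros((128, 128))
        flat = np.full((128, 128), 500.0)
        df = ft.intensity_features(disk_regions, {"dna": flat, "body": flat, "tf": zero_tf})
        assert not df["ring_valid"].iloc[0]


class TestExtractFeatureTable:
    def test_all_77_columns_finite_with_canonical_subset(self, colony_scene):
        _, scene = colony_scene
        table = ft.extract_feature_table(scene.nucleus_image, scene.body_image, scene.tf_image)
        assert [c for c in table.columns if c in FEATURE_NAMES] == list(FEATURE_NAMES)
        assert np.isfinite(table[list(FEATURE_NAMES)].to_numpy()).all()
        assert set(CANONICAL_17) <= set(table.columns)
        assert len(table) == 8  # 7-cell colony + isolated cell

    def test_ground_truth_agreement_on_scene_suite(self, hundred_cell_suite):
        _, scene = hundred_cell_suite
        seg = ft.segment_regions(scene.nucleus_image, scene.body_image)
        table = ft.extract_feature_table(
            scene.nucleus_image, scene.body_image, scene.tf_image, regions=seg
        ).set_index("cell_id")
        mapping = match_true_to_segmented(scene.cell_labels, seg.cell_labels)
        assert len(mapping) == 100
        for i, j in mapping.items():
            truth = scene.truth.loc[i]
            got = table.loc[j]
            assert got["cell_area"] == pytest.approx(truth["cell_area"], rel=0.02)
            assert abs(got["neighbor_fraction"] - truth["neighbor_fraction"]) <= 0.05
            assert got["tf_ratio"] == pytest.approx(truth["planted_tf_ratio"], rel=0.05)

    def test_scale_covariance_under_pixel_size(self, colony_scene):
        _, scene = colony_scene
        kwargs = dict(true_nucleus_labels=scene.nucleus_labels,
                      true_cell_labels=scene.cell_labels)
        r1 = ft.segment_regions(scene.nucleus_image, scene.body_image, pixel_size=1.0, **kwargs)
        r2 = ft.segment_regions(scene.nucleus_image, scene.body_image, pixel_size=2.0, **kwargs)
        t1 = ft.extract_feature_table(scene.nucleus_image, scene.body_image,
                                      scene.tf_image, regions=r1).set_index("cell_id")
        t2 = ft.extract_feature_table(scene.nucleus_image, scene.body_image,
                                      scene.tf_image, regions=r2).set_index("cell_id")
        assert np.allclose(t2["cell_area"], 4 * t1["cell_area"])
        assert np.allclose(t2["cell_length"], 2 * t1["cell_length"])
        for inv in ("cell_roundness", "neighbor_fraction", "ruffliness",
                    "a_nuc_a_cyto", "tf_ratio"):
            assert np.allclose(t2[inv], t1[inv])

    def test_ratios_invariant_to_uniform_intensity_rescale(self, colony_scene):
        _, scene = colony_scene
        kwargs = dict(true_nucleus_labels=scene.nucleus_labels,
                      true_cell_labels=scene.cell_labels)
        regions = ft.segment_regions(scene.nucleus_image, scene.body_image, **kwargs)
        t1 = ft.extract_feature_table(scene.nucleus_image, scene.body_image,
                                      scene.tf_image, regions=regions).set_index("cell_id")
        t2 = ft.extract_feature_table(scene.nucleus_image * 3, scene.body_image * 3,
                                      scene.tf_image.astype(float) * 3,
                                      regions=regions).set_index("cell_id")
        for inv in ("tf_ratio", "ruffliness", "log10_tf_ratio"):
            assert np.allclose(t2[inv], t1[inv])

    def test_neighbor_fraction_bounded(self, hundred_cell_suite):
        _, scene = hundred_cell_suite
        nf = scene.truth["neighbor_fraction"]
        assert ((nf >= 0) & (nf <= 1)).all()
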