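"""Shared fixtures: synthetic scenes and planted datasets reused across tests."""

import numpy as np
import pytest

from shapesignal import features as ft
from shapesignal import synthetic as syn


@pytest.fixture(scope="session")
def colony_scene():
    """A 7-cell hexagonal colony plus one isolated cell, with true labels."""
    spec = syn.SceneSpec(
        image_size=(512, 512),
        colonies=[syn.ColonyPlan((150.0, 150.0), 7), syn.ColonyPlan((380.0, 380.0), 1)],
        tf_ratio_noise_sd=0.25,
        seed=11,
    )
    return spec, syn.simulate_scene(spec)


@pytest.fixture(scope="session")
def colony_segmentation(colony_scene):
    _, scene = colony_scene
    return ft.segment_regions(scene.nucleus_image, scene.body_image)


@pytest.fixture(scope="session")
def hundred_cell_suite():
    """Five 19-cell colonies + five isolated cells (100 cells) with mild shape variation."""
    colonies = [
        syn.ColonyPlan((260.0, 260.0), 19),
        syn.ColonyPlan((260.0, 780.0), 19),
        syn.ColonyPlan((260.0, 1280.0), 19),
        syn.ColonyPlan((780.0, 400.0), 19),
        syn.ColonyPlan((780.0, 950.0), 19),
    ] + [syn.ColonyPlan((1250.0, 200.0 + 300 * k), 1) for k in range(5)]
    spec = syn.SceneSpec(
        image_size=(1500, 1500),
        colonies=colonies,
        eccentricity=0.2,
        ruffle_amplitude=0.03,
        tf_ratio_noise_sd=0.25,
        seed=9,
    )
    return spec, syn.simulate_scene(spec)


@pytest.fixture(scope="session")
def disk_regions():
    """One circular cell (r=50) with concentric circular nucleus (r=20)."""
    yy, xx = np.mgrid[0:128, 0:128]
    r = np.hypot(yy - 64, xx - 64)
    nuc = (r <= 20).astype(np.int32)
    cell = (r <= 50).astype(np.int32)
    regions = ft.segment_regions(
        nuc * 3000.0,
        cell * 1500.0 + 100.0,
        true_nucleus_labels=nuc,
        true_cell_labels=cell,
        w_r=4,
    )
    return regions


def match_true_to_segmented(true_labels, seg_labels):
    """Map each true cell id to the segmented label with maximal overlap."""
    mapping = {}
    for i in np.unique(true_labels):
        if i == 0:
            continue
        counts = np.bincount(seg_labels[true_labels == i].ravel())
        counts[0] = 0
        mapping[int(i)] = int(counts.argmax()) if counts.sum() else 0
    return mapping
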