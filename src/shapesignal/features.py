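"""Segmentation and per-cell feature measurement.

A scene is a pair of registered channels: a DNA stain marking nuclei and a
cell-body stain (here also carrying the transcription-factor signal unless a
dedicated TF channel is given).  Cells are segmented by seeded watershed from
the nuclei, and four subcellular regions are derived per cell:

* nucleus — the nuclear mask;
* cytoplasm — cell minus nucleus;
* membrane band — a ring of width ``w_m`` px inside the cell boundary;
* perinuclear ring — nucleus dilated by ``w_r`` px, clipped to the cell,
  minus the nucleus.  The TF nuclear/perinuclear intensity ratio computed
  over it is the activation readout.

All length/area features are reported in μm / μm² via ``pixel_size``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import networkx as nx
from scipy import ndimage as ndi
from skimage import feature as skfeature
from skimage import filters, measure, morphology, segmentation

from .catalog import DEFAULT_CATALOG, FEATURE_NAMES, METADATA_COLUMNS

logger = logging.getLogger(__name__)

__all__ = [
    "RegionLabels",
    "segment_regions",
    "shape_features",
    "context_features",
    "intensity_features",
    "extract_feature_table",
]

_SHIFTS = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


@dataclass
class RegionLabels:
    """Per-scene label images for nuclei, cells and derived regions.

    Nucleus and cell share label ids (one nucleus per cell); 0 is background.
    ``membrane_band`` and ``perinuclear_ring`` are label images on the same
    id space.
    """

    nucleus_labels: np.ndarray
    cell_labels: np.ndarray
    membrane_band: np.ndarray
    perinuclear_ring: np.ndarray
    pixel_size: float = 1.0
    border_cells: frozenset = field(default_factory=frozenset)

    @property
    def cell_ids(self) -> np.ndarray:
        ids = np.unique(self.cell_labels)
        return ids[ids > 0]

    def validate(self) -> None:
        if self.nucleus_labels.shape != self.cell_labels.shape:
            raise ValueError("nucleus and cell label images differ in shape")
        overlap = (self.perinuclear_ring > 0) & (self.nucleus_labels > 0)
        if overlap.any():
            raise ValueError("perinuclear ring overlaps nucleus")
        outside = (self.membrane_band > 0) & (self.cell_labels == 0)
        if outside.any():
            raise ValueError("membrane band extends outside cells")


def _derived_regions(
    nucleus_labels: np.ndarray, cell_labels: np.ndarray, w_r: int, w_m: int
) -> tuple[np.ndarray, np.ndarray]:
    """Build membrane-band and perinuclear-ring label images per cell."""
    membrane = np.zeros_like(cell_labels)
    ring = np.zeros_like(cell_labels)
    slices = ndi.find_objects(cell_labels)
    for idx, sl in enumerate(slices):
        if sl is None:
            continue
        lab = idx + 1
        # pad the slice so morphology is not clipped at the bounding box
        sl = tuple(
            slice(max(s.start - w_r - 1, 0), min(s.stop + w_r + 1, dim))
            for s, dim in zip(sl, cell_labels.shape)
        )
        cell = cell_labels[sl] == lab
        nuc = nucleus_labels[sl] == lab
        # Euclidean-distance bands: free of the diagonal bias of disk-footprint
        # morphology, so a w_r ring around a radius-R nucleus counts ~pi((R+w_r)^2-R^2) px
        d_out = ndi.distance_transform_edt(cell)  # distance to outside the cell
        membrane[sl][cell & (d_out <= w_m)] = lab
        if nuc.any():
            d_nuc = ndi.distance_transform_edt(~nuc)
            ring[sl][(d_nuc > 0) & (d_nuc <= w_r) & cell] = lab
    return membrane, ring


def _border_ids(labels: np.ndarray) -> frozenset:
    edge = np.concatenate(
        [labels[0, :], labels[-1, :], labels[:, 0], labels[:, -1]]
    )
    return frozenset(int(v) for v in np.unique(edge) if v > 0)


def segment_regions(
    nucleus_image: np.ndarray,
    body_image: np.ndarray,
    pixel_size: float = 1.0,
    true_nucleus_labels: np.ndarray | None = None,
    true_cell_labels: np.ndarray | None = None,
    w_r: int = 4,
    w_m: int = 3,
    min_nucleus_area: int = 40,
    smooth_sigma: float = 1.0,
) -> RegionLabels:
    """Segment nuclei and cells and derive membrane/perinuclear regions.

    Nuclei: Gaussian smoothing, Otsu threshold, distance-transform watershed
    to split touching nuclei.  Cells: seeded watershed from the nuclei on the
    (inverted, smoothed) body channel restricted to the foreground mask.
    Pre-made label images bypass segmentation and only the derived regions
    are built — useful for ground-truth masks.
    """
    if nucleus_image.shape != body_image.shape:
        raise ValueError(
            f"channel shapes differ: {nucleus_image.shape} vs {body_image.shape}"
        )

    if true_cell_labels is not None and true_nucleus_labels is not None:
        nuc_lab = true_nucleus_labels.astype(np.int32)
        cell_lab = true_cell_labels.astype(np.int32)
    else:
        nuc_f = filters.gaussian(nucleus_image.astype(float), smooth_sigma)
        if nuc_f.max() <= 0 or np.ptp(nuc_f) == 0:
            empty = np.zeros_like(nucleus_image, dtype=np.int32)
            return RegionLabels(empty, empty.copy(), empty.copy(), empty.copy(), pixel_size)
        nuc_mask = nuc_f > filters.threshold_otsu(nuc_f)
        nuc_mask = ndi.binary_opening(nuc_mask, structure=morphology.disk(2))
        lab_tmp, _ = ndi.label(nuc_mask)
        sizes = np.bincount(lab_tmp.ravel())
        small = np.flatnonzero(sizes < min_nucleus_area)
        nuc_mask[np.isin(lab_tmp, small[small > 0])] = False
        if not nuc_mask.any():
            empty = np.zeros_like(nucleus_image, dtype=np.int32)
            return RegionLabels(empty, empty.copy(), empty.copy(), empty.copy(), pixel_size)
        dist = ndi.distance_transform_edt(nuc_mask)
        # one marker per nucleus: distance peaks at least a nucleus-radius apart
        peak_idx = skfeature.peak_local_max(
            dist, labels=nuc_mask, min_distance=7, exclude_border=False
        )
        markers = np.zeros_like(dist, dtype=np.int32)
        markers[tuple(peak_idx.T)] = np.arange(1, len(peak_idx) + 1)
        markers, _ = ndi.label(ndi.binary_dilation(markers > 0, structure=morphology.disk(2)))
        nuc_lab = segmentation.watershed(-dist, markers, mask=nuc_mask).astype(np.int32)

        body_f = filters.gaussian(body_image.astype(float), smooth_sigma)
        if np.ptp(body_f) == 0:
            body_mask = nuc_mask.copy()
        else:
            body_mask = body_f > filters.threshold_otsu(body_f)
        body_mask |= nuc_lab > 0
        # cell extent from the body-channel threshold; the split between
        # touching cells floods distance-to-nucleus, which is robust where the
        # body stain is flat across a colony and intensity carries no boundary
        elev = ndi.distance_transform_edt(nuc_lab == 0)
        cell_lab = segmentation.watershed(elev, nuc_lab, mask=body_mask).astype(np.int32)

    membrane, ring = _derived_regions(nuc_lab, cell_lab, w_r, w_m)
    regions = RegionLabels(
        nucleus_labels=nuc_lab,
        cell_labels=cell_lab,
        membrane_band=membrane,
        perinuclear_ring=ring,
        pixel_size=pixel_size,
        border_cells=_border_ids(cell_lab),
    )
    regions.validate()
    return regions


def _boundary_mask(cell_mask: np.ndarray) -> np.ndarray:
    return cell_mask & ~ndi.binary_erosion(cell_mask, structure=np.ones((3, 3), bool))


def _radial_profile(mask: np.ndarray, n_samples: int = 360) -> tuple[np.ndarray, np.ndarray]:
    """Boundary radius as a function of angle around the centroid."""
    mask = np.pad(mask, 1)  # ensure the outline is closed inside the array
    contours = measure.find_contours(mask.astype(float), 0.5)
    contour = max(contours, key=len)
    cy, cx = ndi.center_of_mass(mask)
    dy = contour[:, 0] - cy
    dx = contour[:, 1] - cx
    theta = np.arctan2(dy, dx)
    r = np.hypot(dy, dx)
    order = np.argsort(theta)
    theta, r = theta[order], r[order]
    grid = np.linspace(-np.pi, np.pi, n_samples, endpoint=False)
    # periodic interpolation over angle
    theta_ext = np.concatenate([theta - 2 * np.pi, theta, theta + 2 * np.pi])
    r_ext = np.concatenate([r, r, r])
    return grid, np.interp(grid, theta_ext, r_ext)


def _protrusion_features(
    mask: np.ndarray, perimeter_px: float, pixel_size: float,
    sigma_px: float = 10.0, excess_threshold: float = 0.15,
) -> dict[str, float]:
    """Protrusions = boundary arcs bulging >15% beyond the smoothed outline."""
    grid, r = _radial_profile(mask)
    n = len(grid)
    # sigma in angular samples equivalent to sigma_px of arc length
    arc_per_sample = max(perimeter_px / n, 1e-9)
    sigma_samples = sigma_px / arc_per_sample
    r_smooth = ndi.gaussian_filter1d(r, sigma_samples, mode="wrap")
    excess = r / np.maximum(r_smooth, 1e-9) - 1.0
    above = excess > excess_threshold
    # contiguous runs on the circle = False -> True transitions
    trans = np.sum((~above) & np.roll(above, -1))
    count = int(trans) if above.any() and not above.all() else (1 if above.all() else 0)
    extent = float(above.mean())
    bump = (r - r_smooth)[above] * pixel_size if above.any() else np.array([0.0])
    return {
        "protrusion_count": float(count),
        "protrusion_extent": extent,
        "protrusion_mean_length": float(bump.mean()),
        "protrusion_max_length": float(bump.max()),
        "boundary_smoothness": float(np.std(r / np.maximum(r_smooth, 1e-9))),
    }


def shape_features(regions: RegionLabels) -> pd.DataFrame:
    """Geometry, protrusion and polarity features for every nucleus-bearing cell.

    Roundness is the isoperimetric quotient 4π·area/perimeter² (Crofton
    perimeter); length/width are the fitted-ellipse axes; the cytoplasm
    convention for A_nuc/A_cyto is cell area minus nuclear area.
    """
    px = regions.pixel_size
    cell_props = {p.label: p for p in measure.regionprops(regions.cell_labels)}
    nuc_props = {p.label: p for p in measure.regionprops(regions.nucleus_labels)}
    rows = []
    for lab, cp in sorted(cell_props.items()):
        npr = nuc_props.get(lab)
        if npr is None:
            logger.warning("cell %d has no nucleus; dropped", lab)
            continue
        cell_area_px = cp.area
        nuc_area_px = npr.area
        cyto_px = max(cell_area_px - nuc_area_px, 1e-9)
        c_perim = cp.perimeter_crofton
        n_perim = npr.perimeter_crofton
        cy, cx = cp.centroid
        ny, nxc = npr.centroid
        centers_px = float(np.hypot(cy - ny, cx - nxc))
        mask = cp.image  # cropped to the cell bounding box
        dist_in = ndi.distance_transform_edt(mask)
        iy = int(round(ny)) - cp.bbox[0]
        ix = int(round(nxc)) - cp.bbox[1]
        in_box = 0 <= iy < mask.shape[0] and 0 <= ix < mask.shape[1]
        nb_dist = float(dist_in[iy, ix]) if in_box and mask[iy, ix] else 0.0
        equiv_r_px = np.sqrt(cell_area_px / np.pi)
        row = {
            "cell_id": lab,
            "cell_area": cell_area_px * px**2,
            "nucleus_area": nuc_area_px * px**2,
            "cyto_area": cyto_px * px**2,
            "a_nuc_a_cyto": nuc_area_px / cyto_px,
            "cell_perimeter": c_perim * px,
            "nucleus_perimeter": n_perim * px,
            "cell_roundness": 4 * np.pi * cell_area_px / max(c_perim, 1e-9) ** 2,
            "nucleus_roundness": 4 * np.pi * nuc_area_px / max(n_perim, 1e-9) ** 2,
            "cell_length": cp.axis_major_length * px,
            "cell_width": cp.axis_minor_length * px,
            "cell_length_width": cp.axis_major_length / max(cp.axis_minor_length, 1e-9),
            "nucleus_length": npr.axis_major_length * px,
            "nucleus_width": npr.axis_minor_length * px,
            "nucleus_length_width": npr.axis_major_length / max(npr.axis_minor_length, 1e-9),
            "cell_eccentricity": cp.eccentricity,
            "nucleus_eccentricity": npr.eccentricity,
            "cell_solidity": cp.solidity,
            "nucleus_solidity": npr.solidity,
            "cell_extent": cp.extent,
            "nucleus_extent": npr.extent,
            "cell_convex_area": cp.area_convex * px**2,
            "nucleus_convex_area": npr.area_convex * px**2,
            "cell_equiv_diameter": 2 * equiv_r_px * px,
            "nucleus_equiv_diameter": 2 * np.sqrt(nuc_area_px / np.pi) * px,
            "centers_distance": centers_px * px,
            "centers_distance_norm": centers_px / max(equiv_r_px, 1e-9),
            "nucleus_border_distance": nb_dist * px,
        }
        row.update(_protrusion_features(mask, c_perim, px))
        rows.append(row)
    return pd.DataFrame(rows).set_index("cell_id") if rows else pd.DataFrame(
        columns=["cell_id"]
    ).set_index("cell_id")


def _touching_other(labels: np.ndarray) -> np.ndarray:
    """Boolean image: pixel's 8-neighborhood contains a different nonzero label."""
    touch = np.zeros(labels.shape, dtype=bool)
    for dy, dx in _SHIFTS:
        shifted = np.roll(np.roll(labels, dy, axis=0), dx, axis=1)
        # roll wraps around; wrap contamination is confined to 1-px image edges
        if dy != 0:
            shifted[0 if dy > 0 else -1, :] = 0
        if dx != 0:
            shifted[:, 0 if dx > 0 else -1] = 0
        touch |= (shifted > 0) & (shifted != labels)
    return touch & (labels > 0)


def adjacency_graph(cell_labels: np.ndarray) -> nx.Graph:
    """Cell-contact graph: nodes are cell ids, edges join touching cells."""
    g = nx.Graph()
    ids = np.unique(cell_labels)
    g.add_nodes_from(int(i) for i in ids if i > 0)
    for dy, dx in _SHIFTS:
        a = cell_labels[max(dy, 0) : cell_labels.shape[0] + min(dy, 0),
                        max(dx, 0) : cell_labels.shape[1] + min(dx, 0)]
        b = cell_labels[max(-dy, 0) : cell_labels.shape[0] + min(-dy, 0),
                        max(-dx, 0) : cell_labels.shape[1] + min(-dx, 0)]
        sel = (a > 0) & (b > 0) & (a != b)
        pairs = np.unique(np.stack([a[sel], b[sel]], axis=1), axis=0) if sel.any() else []
        g.add_edges_from((int(p[0]), int(p[1])) for p in pairs)
    return g


def context_features(regions: RegionLabels, edge_nf_threshold: float = 0.55) -> pd.DataFrame:
    """Neighbor fraction, colony membership and edge/border flags per cell.

    NF is the fraction of a cell's boundary pixels whose 8-neighborhood
    touches a different cell; colonies are connected components of the
    contact graph.  A cell is a colony-edge cell when its NF falls below
    ``edge_nf_threshold`` or it touches the image border.
    """
    labels = regions.cell_labels
    touch = _touching_other(labels)
    graph = adjacency_graph(labels)
    colony_of, colony_size = {}, {}
    for cid, comp in enumerate(nx.connected_components(graph), start=1):
        for lab in comp:
            colony_of[lab] = cid
            colony_size[lab] = len(comp)
    centroids = {p.label: p.centroid for p in measure.regionprops(labels)}
    slices = ndi.find_objects(labels)
    diag_um = float(np.hypot(*labels.shape)) * regions.pixel_size
    rows = []
    for lab in sorted(int(i) for i in regions.cell_ids):
        sl = slices[lab - 1]
        sl = tuple(
            slice(max(s.start - 1, 0), min(s.stop + 1, dim))
            for s, dim in zip(sl, labels.shape)
        )
        mask = labels[sl] == lab
        boundary = _boundary_mask(mask)
        n_boundary = int(boundary.sum())
        nf = float((boundary & touch[sl]).sum() / n_boundary) if n_boundary else 0.0
        cy, cx = centroids[lab]
        others = [
            np.hypot(cy - oy, cx - ox)
            for olab, (oy, ox) in centroids.items()
            if olab != lab
        ]
        nn = min(others) * regions.pixel_size if others else diag_um
        border = lab in regions.border_cells
        rows.append(
            {
                "cell_id": lab,
                "neighbor_fraction": min(nf, 1.0),
                "n_neighbors": float(graph.degree(lab)),
                "colony_size": float(colony_size[lab]),
                "colony_id": colony_of[lab],
                "colony_edge": float(nf < edge_nf_threshold or border),
                "border_touch": float(border),
                "nearest_neighbor_distance": nn,
            }
        )
    df = pd.DataFrame(rows)
    return df.set_index("cell_id") if len(df) else df


def intensity_features(regions: RegionLabels, channels: dict[str, np.ndarray]) -> pd.DataFrame:
    """Region intensity statistics, ruffliness and the TF nuclear/ring ratio.

    Ruffliness is the coefficient of variation (SD/mean) of the body-channel
    intensity over the membrane band.  ``tf_ratio`` is the mean TF intensity
    in the nucleus over its mean in the perinuclear ring; cells with a zero
    ring mean are flagged invalid (``ring_valid`` False) and excluded
    downstream.
    """
    for name, img in channels.items():
        if img.shape != regions.cell_labels.shape:
            raise ValueError(f"channel {name!r} misaligned with labels")
    region_labels = {
        "cell": regions.cell_labels,
        "nucleus": regions.nucleus_labels,
        "cyto": np.where(regions.nucleus_labels > 0, 0, regions.cell_labels),
        "membrane": regions.membrane_band,
        "ring": regions.perinuclear_ring,
    }
    ids = [int(i) for i in regions.cell_ids]
    if not ids:
        return pd.DataFrame()
    idx = np.array(ids)
    rows = pd.DataFrame(index=pd.Index(ids, name="cell_id"))
    stats: dict[tuple[str, str], dict[str, np.ndarray]] = {}
    for ch_name, img in channels.items():
        img = img.astype(float)
        for reg_name, lab in region_labels.items():
            mean = ndi.mean(img, labels=lab, index=idx)
            sd = ndi.standard_deviation(img, labels=lab, index=idx)
            present = np.isin(idx, np.unique(lab[lab > 0]))
            mean = np.where(present, mean, 0.0)
            sd = np.where(present, sd, 0.0)
            rows[f"{ch_name}_mean_{reg_name}"] = mean
            rows[f"{ch_name}_sd_{reg_name}"] = sd
            stats[(ch_name, reg_name)] = {"mean": mean, "sd": sd}

    body_mem_mean = stats[("body", "membrane")]["mean"]
    rows["ruffliness"] = np.where(
        body_mem_mean > 0, stats[("body", "membrane")]["sd"] / np.maximum(body_mem_mean, 1e-12), 0.0
    )
    tf_nuc = stats[("tf", "nucleus")]["mean"]
    tf_ring = stats[("tf", "ring")]["mean"]
    rows["ring_valid"] = tf_ring > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(tf_ring > 0, tf_nuc / np.maximum(tf_ring, 1e-300), np.nan)
    rows["tf_ratio"] = ratio
    rows["log10_tf_ratio"] = np.where(ratio > 0, np.log10(np.maximum(ratio, 1e-300)), np.nan)
    for ch in channels:
        m = stats[(ch, "cell")]["mean"]
        rows[f"{ch}_cv_cell"] = np.where(m > 0, stats[(ch, "cell")]["sd"] / np.maximum(m, 1e-12), 0.0)
    rows["tf_nuc_cell_ratio"] = np.where(
        stats[("tf", "cell")]["mean"] > 0,
        tf_nuc / np.maximum(stats[("tf", "cell")]["mean"], 1e-12), 0.0,
    )
    rows["body_nuc_cyto_ratio"] = np.where(
        stats[("body", "cyto")]["mean"] > 0,
        stats[("body", "nucleus")]["mean"] / np.maximum(stats[("body", "cyto")]["mean"], 1e-12), 0.0,
    )
    areas = ndi.sum_labels(np.ones_like(regions.nucleus_labels, dtype=float),
                           labels=regions.nucleus_labels, index=idx)
    rows["dna_total_nucleus"] = stats[("dna", "nucleus")]["mean"] * areas
    return rows


def extract_feature_table(
    nucleus_image: np.ndarray,
    body_image: np.ndarray,
    tf_image: np.ndarray | None = None,
    pixel_size: float = 1.0,
    metadata: dict | None = None,
    regions: RegionLabels | None = None,
    **segment_kwargs,
) -> pd.DataFrame:
    """One row per retained cell, columns = the 77-feature catalog + metadata.

    Cells without a nucleus or with an invalid perinuclear ring are dropped.
    Raises a schema error if any catalog feature is left unmapped.
    """
    if tf_image is None:
        tf_image = body_image
    if regions is None:
        regions = segment_regions(nucleus_image, body_image, pixel_size, **segment_kwargs)
    shape_df = shape_features(regions)
    if len(shape_df) == 0:
        return pd.DataFrame(columns=list(METADATA_COLUMNS) + list(FEATURE_NAMES))
    ctx_df = context_features(regions)
    int_df = intensity_features(
        regions, {"dna": nucleus_image, "body": body_image, "tf": tf_image}
    )
    df = shape_df.join(ctx_df, how="inner").join(int_df, how="inner")
    invalid = ~df["ring_valid"].astype(bool)
    if invalid.any():
        warnings.warn(f"{int(invalid.sum())} cells with undefined TF ratio excluded")
        df = df[~invalid]
    df = df.drop(columns=["ring_valid", "colony_id"])
    DEFAULT_CATALOG.validate_table(df.columns)
    df = df[list(FEATURE_NAMES)]
    df = df[np.isfinite(df).all(axis=1)]
    meta = {"field_id": "f0", "well_id": "w0", "line_id": "line0",
            "medium": "base", "treatment": "untreated"}
    meta.update(metadata or {})
    out = df.reset_index()
    for key in reversed(list(meta)):
        out.insert(1, key, meta[key])
    return out
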