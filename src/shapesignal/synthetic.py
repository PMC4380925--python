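"""Synthetic screen generator with known ground truth.

Every downstream stage (feature extraction, profiling, dependency networks,
shape-response regression, wavelet dynamics) is testable without the original
image corpus: this module renders two-channel scenes with true label masks,
draws single-cell feature tables from planted structural-equation models over
multi-modal morphological states, synthesizes damped oscillatory
nuclear/perinuclear ratio traces (first peak ~30 min, period 110–120 min,
5-min sampling), and emits fold-change panels with known regression
coefficients.

Determinism contract: identical spec + seed gives bit-identical output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import networkx as nx
import tifffile

from .catalog import TF_NODE
from .dynamics import TranslocationTrace

__all__ = [
    "ColonyPlan",
    "SceneSpec",
    "SceneResult",
    "simulate_scene",
    "PlantedDependency",
    "simulate_feature_table",
    "OscillationParams",
    "simulate_trace",
    "simulate_fold_change_panel",
    "noise_sd_for_target_r2",
]


# ---------------------------------------------------------------- scenes


@dataclass
class ColonyPlan:
    """One colony: cells packed hexagonally around ``center`` (pixels)."""

    center: tuple[float, float]
    n_cells: int = 1
    # center spacing as a fraction of 2×body radius; at most ~0.85 the bodies
    # cover the triple junctions, so colony interiors have no background holes
    packing: float = 0.8


@dataclass
class SceneSpec:
    """Parameters of one rendered scene.

    Radii are μm; intensity units are arbitrary camera counts.  The nucleus
    (radius ``nucleus_radius_frac``·R, offset ``nucleus_offset_frac``·R from
    the cell center) must fit inside the body.  The TF channel is rendered so
    that the mean nuclear intensity over the mean perinuclear intensity of a
    cell equals its per-cell ratio target.
    """

    image_size: tuple[int, int] = (512, 512)
    pixel_size: float = 1.0
    colonies: list[ColonyPlan] = field(default_factory=lambda: [ColonyPlan((256.0, 256.0), 1)])
    body_radius_um: float = 25.0
    body_radius_cv: float = 0.0
    eccentricity: float = 0.0
    protrusion_count: int = 0
    protrusion_length_um: float = 0.0
    ruffle_amplitude: float = 0.0
    nucleus_radius_frac: float = 0.4
    nucleus_offset_frac: float = 0.0
    tf_cyto_baseline: float = 1000.0
    tf_ratio_target: float = 2.0
    tf_ratio_noise_sd: float = 0.0
    background: float = 100.0
    seed: int = 0

    @property
    def n_cells(self) -> int:
        return sum(c.n_cells for c in self.colonies)

    def validate(self) -> None:
        if any(c.n_cells < 0 for c in self.colonies):
            raise ValueError("colony cell counts must be >= 0")
        if self.body_radius_um <= 0 or self.nucleus_radius_frac <= 0:
            raise ValueError("radii must be positive")
        if not (0 <= self.eccentricity < 1):
            raise ValueError("eccentricity must be in [0, 1)")
        if self.nucleus_offset_frac + self.nucleus_radius_frac > 0.95:
            raise ValueError("nucleus does not fit inside the body at this offset")
        if self.tf_ratio_target <= 0:
            raise ValueError("tf ratio target must be positive")


@dataclass
class SceneResult:
    nucleus_image: np.ndarray
    body_image: np.ndarray
    tf_image: np.ndarray
    truth: pd.DataFrame
    nucleus_labels: np.ndarray
    cell_labels: np.ndarray


def _hex_positions(center: tuple[float, float], n: int, spacing: float) -> list[tuple[float, float]]:
    """Hexagonal-lattice spiral: center cell, then rings of 6k lattice sites.

    True lattice sites (axial coordinates) keep every nearest-neighbor
    spacing equal, so packed colonies have no background wedges interior to
    the colony.
    """
    cy, cx = center
    pts = [(cy, cx)]
    directions = [(1, 0), (0, 1), (-1, 1), (-1, 0), (0, -1), (1, -1)]  # axial (q, r)
    ring = 1
    while len(pts) < n:
        q, r = ring, 0  # start east, walk the ring counter-clockwise
        for dq, dr in [directions[(k + 2) % 6] for k in range(6)]:
            for _ in range(ring):
                if len(pts) >= n:
                    break
                x = spacing * (q + r / 2.0)
                y = spacing * (np.sqrt(3) / 2.0) * r
                pts.append((cy + y, cx + x))
                q, r = q + dq, r + dr
        ring += 1
    return pts[:n]


def _cell_radius_profile(
    rng: np.random.Generator, spec: SceneSpec, radius_px: float, n_theta: int = 720
) -> tuple[np.ndarray, np.ndarray]:
    """Radial boundary r(θ): perturbed ellipse + optional protrusion lobes."""
    theta = np.linspace(-np.pi, np.pi, n_theta, endpoint=False)
    q = np.sqrt(1 - spec.eccentricity**2)
    a, b = radius_px / np.sqrt(q), radius_px * np.sqrt(q)
    phi = rng.uniform(0, 2 * np.pi)
    r = a * b / np.sqrt((b * np.cos(theta - phi)) ** 2 + (a * np.sin(theta - phi)) ** 2)
    if spec.ruffle_amplitude > 0:
        modes = rng.integers(6, 13, size=3)
        phases = rng.uniform(0, 2 * np.pi, size=3)
        ruffle = sum(np.cos(m * theta + p) for m, p in zip(modes, phases)) / 3.0
        r = r * (1 + spec.ruffle_amplitude * ruffle)
    if spec.protrusion_count > 0 and spec.protrusion_length_um > 0:
        length_px = spec.protrusion_length_um / spec.pixel_size
        angles = rng.uniform(-np.pi, np.pi, size=spec.protrusion_count)
        width = 0.25
        for ang in angles:
            d = np.angle(np.exp(1j * (theta - ang)))
            r = r + length_px * np.exp(-(d / width) ** 2)
    return theta, r


def simulate_scene(spec: SceneSpec) -> SceneResult:
    """Render a scene and return channels, true labels and a ground-truth table.

    Cell bodies are radially perturbed ellipses; contested pixels between
    contacting cells go to the cell with the deepest claim, so bodies abut
    but never overlap.  The truth table is measured on the true masks with
    the same feature code the extractor uses, plus the planted per-cell
    parameters under ``planted_*`` columns.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    h, w = spec.image_size
    radius_px = spec.body_radius_um / spec.pixel_size

    centers: list[tuple[float, float]] = []
    colony_of: list[int] = []
    for ci, colony in enumerate(spec.colonies):
        spacing = 2 * radius_px * colony.packing
        pts = _hex_positions(colony.center, colony.n_cells, spacing)
        for (py, px_) in pts:
            if not (radius_px * 0.5 <= py < h - radius_px * 0.5) or not (
                radius_px * 0.5 <= px_ < w - radius_px * 0.5
            ):
                raise ValueError(f"colony {ci}: cell placement escapes the image")
        centers.extend(pts)
        colony_of.extend([ci] * colony.n_cells)

    # nuclei of different cells must not overlap
    nuc_r = spec.nucleus_radius_frac * radius_px
    for i in range(len(centers)):
        for j in range(i + 1, len(centers)):
            d = np.hypot(centers[i][0] - centers[j][0], centers[i][1] - centers[j][1])
            if d < 2 * nuc_r + 2:
                raise ValueError(
                    f"colony {colony_of[i]}: infeasible packing, nuclei of cells "
                    f"{i + 1} and {j + 1} would overlap"
                )

    depth = np.full((h, w), -np.inf)
    cell_labels = np.zeros((h, w), dtype=np.int32)
    per_cell = []
    for i, (cy, cx) in enumerate(centers, start=1):
        r_i = radius_px * (1 + spec.body_radius_cv * rng.standard_normal()) if spec.body_radius_cv else radius_px
        r_i = max(r_i, 4.0)
        theta, r_prof = _cell_radius_profile(rng, spec, r_i)
        # work on the cell's bounding box only
        reach = float(r_prof.max()) + 2
        y0, y1 = max(int(cy - reach), 0), min(int(cy + reach) + 1, h)
        x0, x1 = max(int(cx - reach), 0), min(int(cx + reach) + 1, w)
        yy, xx = np.mgrid[y0:y1, x0:x1]
        ang = np.arctan2(yy - cy, xx - cx)
        dist = np.hypot(yy - cy, xx - cx)
        r_at = np.interp(ang, theta, r_prof, period=2 * np.pi)
        claim = r_at - dist  # positive inside the desired outline
        sub_depth = depth[y0:y1, x0:x1]
        better = (claim > 0) & (claim > sub_depth)
        sub_depth[better] = claim[better]
        cell_labels[y0:y1, x0:x1][better] = i
        # per-cell TF ratio realization
        ratio = max(spec.tf_ratio_target + spec.tf_ratio_noise_sd * rng.standard_normal(), 0.05)
        off_ang = rng.uniform(0, 2 * np.pi)
        per_cell.append(
            {
                "cell_id": i,
                "colony_id": colony_of[i - 1],
                "center_y": cy,
                "center_x": cx,
                "radius_px": r_i,
                "tf_ratio": ratio,
                "nuc_cy": cy + spec.nucleus_offset_frac * r_i * np.sin(off_ang),
                "nuc_cx": cx + spec.nucleus_offset_frac * r_i * np.cos(off_ang),
            }
        )

    nucleus_labels = np.zeros_like(cell_labels)
    for rec in per_cell:
        i = rec["cell_id"]
        cy, cx = rec["nuc_cy"], rec["nuc_cx"]
        y0, y1 = max(int(cy - nuc_r) - 1, 0), min(int(cy + nuc_r) + 2, h)
        x0, x1 = max(int(cx - nuc_r) - 1, 0), min(int(cx + nuc_r) + 2, w)
        yy, xx = np.mgrid[y0:y1, x0:x1]
        nmask = (np.hypot(yy - cy, xx - cx) <= nuc_r) & (cell_labels[y0:y1, x0:x1] == i)
        nucleus_labels[y0:y1, x0:x1][nmask] = i

    # channels
    nucleus_image = np.full((h, w), spec.background, dtype=float)
    body_image = np.full((h, w), spec.background, dtype=float)
    tf_image = np.full((h, w), spec.background * 0.1, dtype=float)
    nucleus_image[nucleus_labels > 0] = 3000.0
    body_image[cell_labels > 0] = 1500.0
    if spec.ruffle_amplitude > 0:
        # intensity texture near the boundary drives planted ruffliness
        from scipy import ndimage as ndi

        interior = ndi.binary_erosion(cell_labels > 0, iterations=3)
        band = (cell_labels > 0) & ~interior
        body_image[band] *= 1 + spec.ruffle_amplitude * rng.standard_normal(int(band.sum()))
        body_image = np.clip(body_image, 0, None)
    for rec in per_cell:
        i = rec["cell_id"]
        cmask = cell_labels == i
        nmask = nucleus_labels == i
        tf_image[cmask] = spec.tf_cyto_baseline
        tf_image[nmask] = spec.tf_cyto_baseline * rec["tf_ratio"]

    truth = _measure_truth(nucleus_labels, cell_labels, nucleus_image, body_image, tf_image, spec)
    planted = pd.DataFrame(per_cell).set_index("cell_id")
    planted.columns = [f"planted_{c}" for c in planted.columns]
    truth = truth.join(planted, how="left")

    to_u16 = lambda img: np.clip(img, 0, 65535).astype(np.uint16)
    return SceneResult(
        nucleus_image=to_u16(nucleus_image),
        body_image=to_u16(body_image),
        tf_image=to_u16(tf_image),
        truth=truth,
        nucleus_labels=nucleus_labels,
        cell_labels=cell_labels,
    )


def _measure_truth(nuc_lab, cell_lab, nuc_img, body_img, tf_img, spec: SceneSpec) -> pd.DataFrame:
    """Ground-truth feature values: the extractor's own measurements on true masks."""
    from .features import segment_regions, shape_features, context_features, intensity_features

    regions = segment_regions(
        nuc_img, body_img, spec.pixel_size,
        true_nucleus_labels=nuc_lab, true_cell_labels=cell_lab,
    )
    df = shape_features(regions)
    if len(df) == 0:
        return df
    df = df.join(context_features(regions), how="inner")
    df = df.join(
        intensity_features(regions, {"dna": nuc_img, "body": body_img, "tf": tf_img}),
        how="inner",
    )
    return df


def write_scene(result: SceneResult, spec: SceneSpec, out_dir: str | Path) -> dict[str, str]:
    """Write channels + labels as 16-bit TIFF, truth as CSV, params as JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, img in [
        ("nucleus", result.nucleus_image),
        ("body", result.body_image),
        ("tf", result.tf_image),
    ]:
        p = out / f"{name}.tif"
        tifffile.imwrite(p, img.astype(np.uint16))
        paths[name] = str(p)
    for name, lab in [("nucleus_labels", result.nucleus_labels), ("cell_labels", result.cell_labels)]:
        p = out / f"{name}.tif"
        tifffile.imwrite(p, lab.astype(np.uint16))
        paths[name] = str(p)
    truth_path = out / "truth.csv"
    result.truth.to_csv(truth_path)
    paths["truth"] = str(truth_path)
    sidecar = out / "scene_params.json"
    sidecar.write_text(json.dumps(asdict(spec), indent=2, default=list))
    paths["params"] = str(sidecar)
    return paths


# ---------------------------------------------------- planted feature tables


@dataclass
class MixtureState:
    """One morphological state: mixture weight + per-feature mean/SD."""

    weight: float
    means: dict[str, float]
    sds: dict[str, float]


@dataclass
class PlantedDependency:
    """Linear-Gaussian structural-equation model over features + TF log-ratio.

    ``edges`` are (parent, child, coefficient) triples forming a DAG; each
    node's value is its state mean plus the coefficient-weighted, mean-centred
    parents plus Gaussian noise.  Morphological multi-modality comes from
    ``states`` (mixture of per-feature Gaussians); ``treatment_shift`` adds a
    condition-specific offset to the TF log-ratio.
    """

    edges: list[tuple[str, str, float]] = field(default_factory=list)
    noise_sds: dict[str, float] = field(default_factory=dict)
    states: list[MixtureState] = field(default_factory=list)
    tf_baseline: float = -0.1
    default_noise_sd: float = 0.1
    treatment_shift: dict[str, float] = field(default_factory=dict)

    def graph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes())
        for a, b, c in self.edges:
            g.add_edge(a, b, coefficient=c)
        return g

    def nodes(self) -> list[str]:
        seen: list[str] = []
        for state in self.states:
            for n in state.means:
                if n not in seen:
                    seen.append(n)
        for a, b, _ in self.edges:
            for n in (a, b):
                if n not in seen:
                    seen.append(n)
        if TF_NODE not in seen:
            seen.append(TF_NODE)
        return seen

    def validate(self) -> None:
        g = self.graph()
        if not nx.is_directed_acyclic_graph(g):
            cycle = nx.find_cycle(g)
            raise ValueError(f"planted dependency graph has a cycle: {cycle}")
        if self.states:
            total = sum(s.weight for s in self.states)
            if not np.isclose(total, 1.0):
                raise ValueError(f"mixture weights sum to {total}, expected 1")
            for s in self.states:
                if any(sd <= 0 for sd in s.sds.values()):
                    raise ValueError("mixture SDs must be positive")
        if any(sd <= 0 for sd in self.noise_sds.values()):
            raise ValueError("noise SDs must be positive")


def simulate_feature_table(
    planted: PlantedDependency,
    n_cells: int,
    conditions: list[str] | None = None,
    seed: int = 0,
    line_id: str = "line0",
) -> tuple[pd.DataFrame, nx.DiGraph]:
    """Draw ``n_cells`` cells per condition from the planted model.

    Returns the long table (one row per cell, columns = model nodes +
    ``tf_ratio`` + metadata) and the ground-truth DiGraph.
    """
    planted.validate()
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    conditions = conditions or ["untreated"]
    rng = np.random.default_rng(seed)
    g = planted.graph()
    order = list(nx.topological_sort(g))
    nodes = planted.nodes()

    states = planted.states or [MixtureState(1.0, {}, {})]
    weights = np.array([s.weight for s in states])
    # mixture-weighted overall mean per node, used to centre parent terms
    overall_mean = {
        n: float(sum(s.weight * s.means.get(n, 0.0) for s in states)) for n in nodes
    }
    overall_mean[TF_NODE] = planted.tf_baseline

    frames = []
    for cond in conditions:
        state_idx = rng.choice(len(states), size=n_cells, p=weights)
        values: dict[str, np.ndarray] = {}
        for node in order:
            mean = np.array(
                [states[k].means.get(node, overall_mean.get(node, 0.0)) for k in state_idx]
            )
            if node == TF_NODE:
                mean = np.full(n_cells, planted.tf_baseline)
            sd_state = np.array(
                [states[k].sds.get(node, 0.0) for k in state_idx]
            )
            noise_sd = planted.noise_sds.get(node, planted.default_noise_sd)
            val = mean + sd_state * rng.standard_normal(n_cells)
            for parent in g.predecessors(node):
                coef = g.edges[parent, node]["coefficient"]
                val = val + coef * (values[parent] - overall_mean[parent])
            val = val + noise_sd * rng.standard_normal(n_cells)
            if node == TF_NODE:
                val = val + planted.treatment_shift.get(cond, 0.0)
            values[node] = val
        df = pd.DataFrame({n: values[n] for n in nodes})
        df["tf_ratio"] = np.power(10.0, df[TF_NODE])
        df.insert(0, "treatment", cond)
        df.insert(0, "line_id", line_id)
        frames.append(df)
    table = pd.concat(frames, ignore_index=True)
    table.insert(0, "cell_id", np.arange(len(table)))
    return table, g


# ------------------------------------------------------------------ traces


@dataclass
class OscillationParams:
    """Damped oscillatory nuclear/perinuclear ratio trace parameters.

    The trace rises from ``baseline`` to its first maximum of height
    ``amplitude`` at ``first_peak_time`` (min), then oscillates with
    ``period`` while the envelope decays with ``damping_timescale``.
    """

    baseline: float = 1.0
    first_peak_time: float = 30.0
    amplitude: float = 0.5
    period: float = 115.0
    damping_timescale: float = 100.0
    noise_sd: float = 0.0
    dt: float = 5.0
    duration: float = 360.0
    seed: int = 0

    def validate(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.period <= 2 * self.dt:
            raise ValueError(
                f"period {self.period} min is aliased at dt={self.dt} min (need period > 2·dt)"
            )
        if self.duration < self.period:
            raise ValueError("duration must cover at least one period")
        if self.first_peak_time <= 0:
            raise ValueError("first_peak_time must be positive")


def simulate_trace(
    params: OscillationParams, cell_id: str = "cell_0", condition: str = "control"
) -> TranslocationTrace:
    """Generate one ratio trace: ramp to the first peak, then damped cosine.

    The oscillator phase is fixed so the first maximum falls exactly at
    ``first_peak_time`` with height ``amplitude`` above baseline; maxima are
    spaced one ``period`` apart with exponentially decaying heights.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    t = np.arange(0.0, params.duration + params.dt / 2, params.dt)
    t0, tau = params.first_peak_time, params.damping_timescale
    pre = t <= t0
    osc = np.empty_like(t)
    osc[pre] = np.sin(0.5 * np.pi * t[pre] / t0)  # smooth 0 -> 1 ramp
    decay = np.exp(-(t[~pre] - t0) / tau) if np.isfinite(tau) else 1.0
    osc[~pre] = decay * np.cos(2 * np.pi * (t[~pre] - t0) / params.period)
    values = params.baseline + params.amplitude * osc
    if params.noise_sd > 0:
        values = values + params.noise_sd * rng.standard_normal(len(t))
    values = np.maximum(values, 1e-6)
    return TranslocationTrace(times=t, values=values, cell_id=cell_id, condition=condition)


# ------------------------------------------------------------ fold changes


def noise_sd_for_target_r2(
    coefficients: tuple[float, float, float, float],
    target_r2: float,
    predictor_log_sds: tuple[float, float, float] = (0.25, 0.25, 0.2),
    n_mc: int = 200_000,
    seed: int = 12345,
) -> float:
    """Noise SD giving the requested population R² for the panel generator.

    Predictor fold changes are log-normal; the signal variance is estimated
    by Monte Carlo and the noise SD solved from R² = V_sig/(V_sig + σ²).
    """
    if not (0 < target_r2 < 1):
        raise ValueError("target_r2 must be in (0, 1)")
    rng = np.random.default_rng(seed)
    _, c1, c2, c3 = coefficients
    s1, s2, s3 = predictor_log_sds
    x1 = np.exp(rng.normal(0, s1, n_mc))
    x2 = np.exp(rng.normal(0, s2, n_mc))
    x3 = np.exp(rng.normal(0, s3, n_mc))
    signal = c1 * x1 + c2 * x2 + c3 * x3
    v_sig = float(np.var(signal))
    return float(np.sqrt(v_sig * (1 - target_r2) / target_r2))


def simulate_fold_change_panel(
    coefficients: tuple[float, float, float, float] = (1.4, -0.3, 0.4, -0.5),
    n_conditions: int = 176,
    noise_sd: float = 0.0,
    seed: int = 0,
    predictor_log_sds: tuple[float, float, float] = (0.25, 0.25, 0.2),
) -> pd.DataFrame:
    """Fold-change panel: Δtf_ratio = c0 + c1·ΔNF + c2·Δruffliness + c3·ΔA_nuc/A_cyto + ε.

    One row per cell-line/perturbation condition; fold changes are
    treated/control ratios scattered log-normally around 1.
    """
    if n_conditions < 5:
        raise ValueError("need at least 5 conditions")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    c0, c1, c2, c3 = coefficients
    s1, s2, s3 = predictor_log_sds
    d_nf = np.exp(rng.normal(0, s1, n_conditions))
    d_ruff = np.exp(rng.normal(0, s2, n_conditions))
    d_ratio = np.exp(rng.normal(0, s3, n_conditions))
    y = c0 + c1 * d_nf + c2 * d_ruff + c3 * d_ratio
    if noise_sd > 0:
        y = y + rng.normal(0, noise_sd, n_conditions)
    y = np.maximum(y, 1e-3)
    return pd.DataFrame(
        {
            "condition_id": [f"cond_{i:03d}" for i in range(n_conditions)],
            "d_nf": d_nf,
            "d_ruffliness": d_ruff,
            "d_anucacyto": d_ratio,
            "d_tfratio": y,
        }
    )
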