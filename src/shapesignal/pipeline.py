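"""End-to-end orchestration: configuration, staging, manifests, converters.

A run is described by a YAML/dict config naming the stages to execute and
their seeds and thresholds; every output is written under the run directory
together with a manifest (stage order, seeds, parameter values, SHA-256 of
every file) so a run is reproducible byte-for-byte from its config.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import dynamics as dyn
from . import networks as net
from . import profiling as prof
from . import regression as reg
from . import synthetic as syn
from .catalog import CANONICAL_17, TF_NODE
from .features import extract_feature_table

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_screen", "convert_external_table"]

STAGES = ("scene", "features", "profiles", "networks", "regression", "dynamics")

_CANONICAL_CELL_COLUMNS = ("line_id", "treatment", "tf_ratio")
_CANONICAL_FOLD_COLUMNS = ("condition_id", "d_nf", "d_ruffliness", "d_anucacyto", "d_tfratio")


@dataclass
class RunConfig:
    """Validated configuration of one screen run."""

    stages: list[str] = field(default_factory=lambda: list(STAGES))
    out_dir: str = "run_out"
    seed: int = 0
    n_cells: int = 2000
    n_lines: int = 4
    conditions: list[str] = field(default_factory=lambda: ["untreated", "tnf_1h"])
    confidence_threshold: float = 0.6
    alpha: float = 0.01
    cv_folds: int = 10
    interval_level: float = 0.95
    dt_min: float = 5.0
    bootstrap: int = 100
    bn_restarts: int = 5
    n_traces: int = 40
    n_panel_conditions: int = 176
    input_paths: dict = field(default_factory=dict)

    _KNOWN = None  # filled after class creation

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        known = {f for f in cls.__dataclass_fields__ if not f.startswith("_")}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        bad = [s for s in self.stages if s not in STAGES]
        if bad:
            raise ValueError(f"unknown stages: {bad}")
        for key, p in self.input_paths.items():
            if not Path(p).exists():
                raise ValueError(f"input path for {key!r} does not exist: {p}")
        if self.seed is None:
            raise ValueError("a seed is required")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_csv(df: pd.DataFrame, path: Path, **kwargs) -> None:
    df.to_csv(path, float_format="%.10g", **kwargs)


def _demo_planted(conditions: list[str]) -> syn.PlantedDependency:
    """Planted single-cell model used for self-contained demo runs."""
    means_a = {"cell_area": 900.0, "neighbor_fraction": 0.55, "ruffliness": 0.12,
               "a_nuc_a_cyto": 0.25, "nucleus_area": 180.0}
    means_b = {"cell_area": 2200.0, "neighbor_fraction": 0.30, "ruffliness": 0.22,
               "a_nuc_a_cyto": 0.15, "nucleus_area": 240.0}
    sds = {"cell_area": 150.0, "neighbor_fraction": 0.08, "ruffliness": 0.03,
           "a_nuc_a_cyto": 0.04, "nucleus_area": 30.0}
    return syn.PlantedDependency(
        edges=[
            ("cell_area", "nucleus_area", 0.08),
            ("cell_area", TF_NODE, -0.00015),
            ("ruffliness", TF_NODE, 2.0),
            ("neighbor_fraction", TF_NODE, -0.5),
        ],
        noise_sds={TF_NODE: 0.12, "nucleus_area": 20.0},
        states=[syn.MixtureState(0.5, means_a, sds), syn.MixtureState(0.5, means_b, sds)],
        treatment_shift={c: (0.25 if c != "untreated" else 0.0) for c in conditions},
    )


def run_screen(config: RunConfig) -> dict:
    """Execute the configured stages in dependency order; return the manifest.

    Stage products are written under ``config.out_dir``; a failure halts the
    run with the stage name while earlier outputs stay on disk.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.SeedSequence(config.seed)
    stage_seeds = {s: int(np.random.default_rng(child).integers(0, 2**31 - 1))
                   for s, child in zip(STAGES, rng.spawn(len(STAGES)))}
    manifest: dict = {"config": asdict(config), "stage_seeds": stage_seeds, "outputs": {}}
    produced: dict[str, object] = {}

    def record(name: str, path: Path) -> None:
        manifest["outputs"][name] = {"path": str(path), "sha256": _sha256(path)}

    for stage in [s for s in STAGES if s in config.stages]:
        logger.info("stage %s (seed %d)", stage, stage_seeds[stage])
        try:
            if stage == "scene":
                spec = syn.SceneSpec(
                    colonies=[syn.ColonyPlan((150.0, 150.0), 7), syn.ColonyPlan((360.0, 360.0), 1)],
                    tf_ratio_noise_sd=0.2,
                    ruffle_amplitude=0.08,
                    seed=stage_seeds["scene"],
                )
                scene = syn.simulate_scene(spec)
                paths = syn.write_scene(scene, spec, out / "scene")
                produced["scene"] = scene
                for k, p in paths.items():
                    record(f"scene/{k}", Path(p))
            elif stage == "features":
                scene = produced.get("scene")
                if scene is None:
                    raise RuntimeError("features stage needs the scene stage")
                table = extract_feature_table(
                    scene.nucleus_image, scene.body_image, scene.tf_image,
                    metadata={"line_id": "demo", "treatment": "untreated"},
                )
                p = out / "cells.csv"
                _write_csv(table, p, index=False)
                produced["cells"] = table
                record("cells", p)
            elif stage == "profiles":
                planted = _demo_planted(config.conditions)
                cells, truth_graph = syn.simulate_feature_table(
                    planted, n_cells=config.n_cells // 2, conditions=config.conditions,
                    seed=stage_seeds["profiles"],
                )
                # emulate wells/lines by splitting cells into replicate wells
                cells["well_id"] = "w" + (np.arange(len(cells)) % 4).astype(str)
                cells["line_id"] = "line" + (np.arange(len(cells)) % config.n_lines).astype(str)
                cells["medium"] = "base"
                feats = [c for c in cells.columns
                         if c not in ("cell_id", "line_id", "treatment", "well_id", "medium")]
                profiles, zmat = prof.well_profiles(cells, feats)
                model = prof.pca_scores(zmat, k=min(8, len(zmat) - 1))
                p1 = out / "well_profiles.csv"
                _write_csv(profiles, p1, index=False)
                p2 = out / "pca_scores.csv"
                _write_csv(model.scores, p2)
                clus = prof.cluster_lines(model.scores)
                p3 = out / "dendrogram.nwk"
                p3.write_text(clus.to_newick() + "\n")
                produced["cells_table"] = cells
                produced["profiles"] = profiles
                for name, p in [("well_profiles", p1), ("pca_scores", p2), ("dendrogram", p3)]:
                    record(name, p)
            elif stage == "networks":
                cells = produced.get("cells_table")
                if cells is None:
                    raise RuntimeError("networks stage needs the profiles stage")
                feats = [c for c in cells.columns if c in set(CANONICAL_17) | {TF_NODE}]
                nets = []
                for (line, treat), grp in cells.groupby(["line_id", "treatment"], observed=True):
                    if len(grp) < 100:
                        logger.warning("group %s/%s has %d cells; skipped", line, treat, len(grp))
                        continue
                    codes, _ = net.discretize(grp[feats])
                    model = net.learn_network(
                        codes, B=min(config.bootstrap, 25), seed=stage_seeds["networks"],
                        restarts=min(config.bn_restarts, 2),
                        metadata={"line_id": line, "treatment": treat},
                    )
                    nets.append(model)
                summary = net.dependency_summary(nets, threshold=config.confidence_threshold)
                p = out / "dependency_summary.csv"
                _write_csv(summary, p)
                record("dependency_summary", p)
                for i, m in enumerate(nets):
                    gp = out / f"network_{i:02d}.graphml"
                    m.to_graphml(gp)
                    record(f"network_{i:02d}", gp)
            elif stage == "regression":
                noise = syn.noise_sd_for_target_r2((1.4, -0.3, 0.4, -0.5), 0.37)
                panel = syn.simulate_fold_change_panel(
                    (1.4, -0.3, 0.4, -0.5), config.n_panel_conditions, noise,
                    seed=stage_seeds["regression"],
                )
                model, cv = reg.crossvalidate_and_flag_outliers(
                    panel, folds=config.cv_folds, seed=stage_seeds["regression"],
                    level=config.interval_level,
                )
                report = {
                    "intercept": model.intercept,
                    "coefficients": model.coefficients,
                    "r_squared": model.r_squared,
                    "error_variance": model.error_variance,
                    "f_pvalue": model.f_pvalue,
                    "cv_mae_mean": cv.mae_mean,
                    "cv_mae_sd": cv.mae_sd,
                    "outliers": cv.outliers,
                }
                p = out / "regression_report.json"
                p.write_text(json.dumps(report, indent=2, sort_keys=True))
                record("regression_report", p)
            elif stage == "dynamics":
                rows = []
                traces = []
                for i in range(config.n_traces):
                    pr = syn.OscillationParams(
                        noise_sd=0.03, seed=stage_seeds["dynamics"] + i, dt=config.dt_min
                    )
                    tr = syn.simulate_trace(pr, cell_id=f"cell_{i:02d}")
                    traces.append(tr)
                    peak = dyn.first_peak_metrics(tr)
                    rows.append({"cell_id": tr.cell_id, "first_peak_amplitude": peak.amplitude,
                                 "first_peak_time": peak.time})
                hist = dyn.period_frequency_comparison({"control": traces}, t=180.0)
                p1 = out / "first_peaks.csv"
                _write_csv(pd.DataFrame(rows), p1, index=False)
                p2 = out / "period_frequencies.csv"
                _write_csv(hist, p2)
                record("first_peaks", p1)
                record("period_frequencies", p2)
        except Exception as err:
            raise RuntimeError(f"stage {stage!r} failed: {err}") from err

    mp = out / "manifest.json"
    mp.write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str))
    return manifest


def convert_external_table(
    source: pd.DataFrame, column_map: dict[str, str], kind: str = "foldchange"
) -> pd.DataFrame:
    """Map an externally formatted table onto the canonical schema.

    ``column_map`` maps source column names to canonical names; unmapped
    source columns are preserved under an ``extra_`` namespace.  Raises a
    schema error naming any required canonical column still missing.
    """
    required = _CANONICAL_FOLD_COLUMNS if kind == "foldchange" else _CANONICAL_CELL_COLUMNS
    out = source.rename(columns=column_map)
    for col in source.columns:
        if col in column_map or col in required:
            continue
        out = out.rename(columns={col: f"extra_{col}"})
    missing = [c for c in required if c not in out.columns]
    if missing:
        raise ValueError(f"canonical columns missing after mapping: {missing}")
    renamed = {k: v for k, v in column_map.items() if k != v}
    if renamed:
        logger.info("renamed columns: %s", renamed)
    return out
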