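#!/usr/bin/env python
"""Generate the synthetic screen: rendered scenes + planted single-cell tables.

Scenes (two-channel images with true label masks) go to scratch/ (binary);
the planted single-cell feature tables and the ground-truth dependency
graph are written under results/screen/.
"""

from pathlib import Path

import networkx as nx
import numpy as np

from shapesignal import synthetic as syn
from shapesignal.catalog import TF_NODE

ROOT = Path(__file__).resolve().parents[1]
OUT = ROOT / "results" / "screen"
SCRATCH = ROOT / "scratch" / "scenes"

# four synthetic "cell lines": two epithelial-like (small, high NF) and two
# mesenchymal-like (large, ruffled, low NF), mirroring the screen's contrast
LINES = {
    "epi_a": dict(area=900.0, nf=0.55, ruff=0.12, anac=0.25),
    "epi_b": dict(area=1100.0, nf=0.50, ruff=0.14, anac=0.22),
    "mes_a": dict(area=2200.0, nf=0.32, ruff=0.22, anac=0.15),
    "mes_b": dict(area=1900.0, nf=0.36, ruff=0.20, anac=0.16),
}
CONDITIONS = ["untreated", "tnf_1h"]


def planted_for(line_params) -> syn.PlantedDependency:
    means = {
        "cell_area": line_params["area"],
        "neighbor_fraction": line_params["nf"],
        "ruffliness": line_params["ruff"],
        "a_nuc_a_cyto": line_params["anac"],
        "nucleus_area": line_params["area"] * 0.18,
    }
    sds = {"cell_area": 0.15 * line_params["area"], "neighbor_fraction": 0.08,
           "ruffliness": 0.03, "a_nuc_a_cyto": 0.04,
           "nucleus_area": 0.03 * line_params["area"]}
    return syn.PlantedDependency(
        edges=[
            ("cell_area", "nucleus_area", 0.1),
            ("cell_area", TF_NODE, -0.0004),
            ("ruffliness", TF_NODE, 2.5),
            ("neighbor_fraction", TF_NODE, -0.6),
        ],
        noise_sds={TF_NODE: 0.12},
        states=[syn.MixtureState(1.0, means, sds)],
        treatment_shift={"untreated": 0.0, "tnf_1h": 0.3},
    )


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    tables = []
    for i, (line, params) in enumerate(LINES.items()):
        table, graph = syn.simulate_feature_table(
            planted_for(params), n_cells=2000, conditions=CONDITIONS,
            seed=100 + i, line_id=line)
        table["well_id"] = "w" + (np.arange(len(table)) % 4).astype(str)
        table["medium"] = "base"
        tables.append(table)
        nx.write_graphml(graph, OUT / f"truth_network_{line}.graphml")
    import pandas as pd

    cells = pd.concat(tables, ignore_index=True)
    cells_path = SCRATCH.parent / "cells.csv"  # large table: scratch, regenerable
    cells_path.parent.mkdir(parents=True, exist_ok=True)
    cells.to_csv(cells_path, index=False, float_format="%.8g")

    spec = syn.SceneSpec(
        image_size=(1500, 1500),
        colonies=[syn.ColonyPlan((260.0, 260.0 + 510 * k), 19) for k in range(3)]
        + [syn.ColonyPlan((780.0, 400.0), 19), syn.ColonyPlan((780.0, 950.0), 19)]
        + [syn.ColonyPlan((1250.0, 200.0 + 300 * k), 1) for k in range(5)],
        eccentricity=0.2,
        ruffle_amplitude=0.03,
        tf_ratio_noise_sd=0.25,
        seed=9,
    )
    scene = syn.simulate_scene(spec)
    syn.write_scene(scene, spec, SCRATCH)
    scene.truth.to_csv(OUT / "scene_truth.csv", float_format="%.8g")

    print(f"wrote {len(cells)} cells across {len(LINES)} lines x {CONDITIONS} "
          f"-> {cells_path}")
    print(f"rendered a {spec.n_cells}-cell scene -> {SCRATCH} (images), "
          f"truth table -> {OUT / 'scene_truth.csv'}")


if __name__ == "__main__":
    main()
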