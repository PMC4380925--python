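"""The per-cell feature catalog.

Every cell segmented from a two-channel scene (DNA stain + cell body /
transcription-factor stain) is described by exactly 77 shape, context and
intensity features.  A fixed subset of 17 features — the ones most often
significantly different between cells with high and low NF-κB
nuclear/perinuclear ratios — feeds the dependency-network stage.

The catalog is the single source of truth for column names: the extractor,
the synthetic generator and the downstream stages all validate against it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

#: channels measured per region
CHANNELS = ("dna", "body", "tf")
#: subcellular regions intensity statistics are computed over
REGIONS = ("cell", "nucleus", "cyto", "membrane", "ring")

_GEOMETRY = (
    "cell_area",
    "nucleus_area",
    "cyto_area",
    "a_nuc_a_cyto",
    "cell_perimeter",
    "nucleus_perimeter",
    "cell_roundness",
    "nucleus_roundness",
    "cell_length",
    "cell_width",
    "cell_length_width",
    "nucleus_length",
    "nucleus_width",
    "nucleus_length_width",
    "cell_eccentricity",
    "nucleus_eccentricity",
    "cell_solidity",
    "nucleus_solidity",
    "cell_extent",
    "nucleus_extent",
    "cell_convex_area",
    "nucleus_convex_area",
    "cell_equiv_diameter",
    "nucleus_equiv_diameter",
)

_PROTRUSION = (
    "protrusion_count",
    "protrusion_extent",
    "protrusion_mean_length",
    "protrusion_max_length",
    "boundary_smoothness",
)

_POLARITY = (
    "centers_distance",
    "centers_distance_norm",
    "nucleus_border_distance",
)

_CONTEXT = (
    "neighbor_fraction",
    "n_neighbors",
    "colony_size",
    "colony_edge",
    "border_touch",
    "nearest_neighbor_distance",
)

_INTENSITY_STATS = tuple(
    f"{ch}_{stat}_{reg}" for ch in CHANNELS for reg in REGIONS for stat in ("mean", "sd")
)

_INTENSITY_DERIVED = (
    "ruffliness",
    "tf_ratio",
    "log10_tf_ratio",
    "dna_cv_cell",
    "body_cv_cell",
    "tf_cv_cell",
    "tf_nuc_cell_ratio",
    "body_nuc_cyto_ratio",
    "dna_total_nucleus",
)

#: the full ordered 77-feature catalog
FEATURE_NAMES: tuple[str, ...] = (
    _GEOMETRY + _PROTRUSION + _POLARITY + _CONTEXT + _INTENSITY_STATS + _INTENSITY_DERIVED
)

#: category tag for each feature
FEATURE_CATEGORIES: dict[str, str] = {
    **{n: "geometry" for n in _GEOMETRY},
    **{n: "protrusion" for n in _PROTRUSION},
    **{n: "polarity" for n in _POLARITY},
    **{n: "context" for n in _CONTEXT},
    **{n: "intensity" for n in _INTENSITY_STATS},
    **{n: "intensity" for n in _INTENSITY_DERIVED},
}

#: the 17-feature subset used for dependency-network learning
CANONICAL_17: tuple[str, ...] = (
    "cell_area",
    "nucleus_area",
    "a_nuc_a_cyto",
    "cell_roundness",
    "nucleus_roundness",
    "cell_length_width",
    "cell_eccentricity",
    "nucleus_eccentricity",
    "cell_solidity",
    "centers_distance",
    "protrusion_count",
    "protrusion_extent",
    "ruffliness",
    "neighbor_fraction",
    "n_neighbors",
    "colony_size",
    "nearest_neighbor_distance",
)

#: target node for the dependency networks (not part of the 17 predictors)
TF_NODE = "log10_tf_ratio"

#: metadata columns carried next to the features
METADATA_COLUMNS = ("cell_id", "field_id", "well_id", "line_id", "medium", "treatment")


@dataclass(frozen=True)
class FeatureCatalog:
    """Ordered feature catalog with category tags and the canonical subset."""

    names: tuple[str, ...] = FEATURE_NAMES
    categories: dict[str, str] = field(default_factory=lambda: dict(FEATURE_CATEGORIES))
    canonical: tuple[str, ...] = CANONICAL_17

    def __post_init__(self) -> None:
        if len(self.names) != 77:
            raise ValueError(f"catalog must have 77 entries, got {len(self.names)}")
        if len(set(self.names)) != len(self.names):
            raise ValueError("catalog names must be unique")
        missing = [n for n in self.canonical if n not in self.names]
        if missing:
            raise ValueError(f"canonical features missing from catalog: {missing}")

    def __len__(self) -> int:
        return len(self.names)

    def validate_table(self, columns) -> None:
        """Raise with the missing names if *columns* does not cover the catalog."""
        missing = [n for n in self.names if n not in set(columns)]
        if missing:
            raise ValueError(f"feature table is missing catalog columns: {missing}")


DEFAULT_CATALOG = FeatureCatalog()
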