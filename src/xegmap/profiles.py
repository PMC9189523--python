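"""Parameter presets and canned study configurations.

``PRESETS`` mirrors the analysis settings used throughout the workflow:
MNN integration of replicates (d=120, k=50), SNN clustering (k=20, d=30),
UMAP embedding (n_neighbors=50, min_dist=0.7, cosine), the three atlas
mappings (one generic knn-transfer procedure at d=120/150/120, k=50), and
the dorsoventral sub-clustering runs (d=5 within-condition, d=15 for the
joint XEG+gastruloid run, k=20, five k-means centers).

``separation_config`` builds the well-separated five-type simulation used
for the label-transfer evaluations: 100 marker genes per type at log2
fold-change 4 over baseline, NB dispersion theta=5.
"""
from __future__ import annotations

from .sim import CellType, SimConfig

PRESETS = {
    "integration": {"d": 120, "k": 50},
    "clustering": {"k": 20, "d_use": 30, "seed": 0},
    "embedding": {"n_neighbors": 50, "min_dist": 0.7, "metric": "cosine"},
    "map_gastrulation_atlas": {"d": 120, "k": 50},
    "map_endoderm_atlas": {"d": 150, "k": 50},
    "map_spinal_cord_atlas": {"d": 120, "k": 50},
    "subcluster_within": {"d": 5, "k_mnn": 20, "centers": 5},
    "subcluster_joint": {"d": 15, "k_mnn": 20, "centers": 5},
    "rejection": {"conf_min": 0.5, "min_cluster": 10},
    "spikein_thresholds": {"Ab_CD15_XEG": 50, "Ab_CD15_gastruloid": 100, "Ab_CD140": 50},
}


def separated_cell_types(n_markers: int = 150, marker_log2fc: float = 4.0) -> list[CellType]:
    # condition frequencies differ, but each type's mean frequency is 0.2 so
    # the atlas covers all types at equal density (kNN distances comparable)
    return [
        CellType("Epiblast", {"XEG": 0.15, "gastruloid": 0.25}, age_mean=6.7,
                 n_markers=n_markers, marker_log2fc=marker_log2fc),
        CellType("NMP", {"XEG": 0.15, "gastruloid": 0.25}, age_mean=8.2,
                 n_markers=n_markers, marker_log2fc=marker_log2fc),
        CellType("Spinal cord", {"XEG": 0.25, "gastruloid": 0.15}, age_mean=8.3,
                 n_markers=n_markers, marker_log2fc=marker_log2fc),
        CellType("Somitic mesoderm", {"XEG": 0.20, "gastruloid": 0.20}, age_mean=8.0,
                 n_markers=n_markers, marker_log2fc=marker_log2fc),
        CellType("Gut", {"XEG": 0.25, "gastruloid": 0.15}, age_mean=7.8,
                 n_markers=n_markers, marker_log2fc=marker_log2fc),
    ]


def separation_config(
    seed: int,
    n_genes: int = 1000,
    n_atlas_cells: int = 5000,
    n_query_cells_per_sample: int = 750,
    spikein_fraction: float = 0.0,
    **overrides,
) -> SimConfig:
    """Five clearly separated types; defaults sized for the full evaluation."""
    kwargs = dict(
        cell_types=separated_cell_types(),
        nb_dispersion=20.0,
        base_expression_scale=5.0,
    )
    kwargs.update(overrides)
    return SimConfig(
        n_genes=n_genes,
        n_atlas_cells=n_atlas_cells,
        n_query_cells_per_sample=n_query_cells_per_sample,
        spikein_fraction=spikein_fraction,
        seed=seed,
        **kwargs,
    )
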