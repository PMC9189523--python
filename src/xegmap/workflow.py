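"""Convenience composition of the pipeline stages.

These helpers wire the per-module operations into the sequences the
analysis drivers run: merge per-sample matrices, QC + normalize + HVG, and
the joint MNN run that places query cells into the atlas space for label
transfer.
"""
from __future__ import annotations

import numpy as np
import scipy.sparse as sp

from .containers import AtlasReference, CorrectedSpace, CountMatrix, NormalizedMatrix
from .integrate import mnn_correct
from .qc import filter_cells, filter_genes, normalize_log, select_hvg

EXOGENOUS_FEATURES = {"mCherry", "eGFP", "Ab_CD15", "Ab_CD140"}


def merge_matrices(matrices: list[CountMatrix]) -> CountMatrix:
    """Column-concatenate matrices sharing a gene universe."""
    genes0 = tuple(matrices[0].gene_ids)
    if any(tuple(m.gene_ids) != genes0 for m in matrices[1:]):
        raise ValueError("matrices must share a gene universe")
    return CountMatrix(
        sp.hstack([m.values for m in matrices]).tocsc(),
        matrices[0].gene_ids,
        np.concatenate([m.cell_ids for m in matrices]),
    )


def restrict_to_shared_genes(*nms: NormalizedMatrix) -> list[NormalizedMatrix]:
    shared = set(nms[0].gene_ids.tolist())
    for nm in nms[1:]:
        shared &= set(nm.gene_ids.tolist())
    order = sorted(shared)
    return [nm.subset_genes(nm.gene_index(order)) for nm in nms]


def qc_normalize(
    m: CountMatrix, min_count: int = 0, min_cells: int = 2, sf_method: str = "library"
) -> NormalizedMatrix:
    """Cell filter, merged-replicate gene filter, then log-normalize."""
    if min_count > 0:
        m = filter_cells(m, min_count)
    m = filter_genes(m, min_cells)
    return normalize_log(m, method=sf_method)


def joint_atlas_space(
    atlas_nm: NormalizedMatrix,
    query_nms: list[NormalizedMatrix],
    atlas_types: np.ndarray,
    atlas_ages: np.ndarray,
    d: int = 120,
    k: int = 50,
    hvg_exclude: set = frozenset(EXOGENOUS_FEATURES),
    hvg_top_frac: float = 0.10,
):
    """Select HVG, jointly MNN-correct atlas + query, split the result.

    The atlas is the reference batch (its geometry fixes the space); each
    query matrix merges onto it in turn. Returns (AtlasReference, query
    CorrectedSpace list aligned with query_nms).
    """
    all_nm = restrict_to_shared_genes(atlas_nm, *query_nms)
    hvg = select_hvg(all_nm, exclude=set(hvg_exclude), top_frac=hvg_top_frac)
    subs = [nm.subset_genes(nm.gene_index(hvg)) for nm in all_nm]
    cs = mnn_correct(subs, d=d, k=k)
    sizes = [nm.n_cells for nm in all_nm]
    offsets = np.concatenate([[0], np.cumsum(sizes)])
    atlas = AtlasReference(
        cs.coordinates[: sizes[0]], atlas_types, atlas_ages, cell_ids=all_nm[0].cell_ids
    )
    queries = [
        CorrectedSpace(
            cs.coordinates[offsets[i]: offsets[i + 1]],
            all_nm[i].cell_ids,
            np.full(sizes[i], i - 1),
        )
        for i in range(1, len(all_nm))
    ]
    return atlas, queries
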