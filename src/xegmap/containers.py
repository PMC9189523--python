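"""Core in-memory containers.

Count data are stored genes x cells in CSC sparse form (cells are columns),
mirroring the Matrix-Market triplet convention of 10x-style outputs. The
containers are thin: computation lives in the pipeline modules, which operate
on the underlying scipy/numpy objects directly.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp


class ConfigurationError(ValueError):
    """A simulation or pipeline configuration is invalid; names the field."""


class EmptyOutputError(ValueError):
    """A filter removed every cell or gene."""


def _check_unique(ids: np.ndarray, what: str) -> None:
    if len(np.unique(ids)) != len(ids):
        raise ValueError(f"duplicate {what} identifiers")


@dataclass
class CountMatrix:
    """Raw integer counts, genes x cells, with identifier vectors."""

    values: sp.csc_matrix
    gene_ids: np.ndarray
    cell_ids: np.ndarray

    def __post_init__(self) -> None:
        if not sp.issparse(self.values):
            self.values = sp.csc_matrix(np.asarray(self.values))
        self.values = self.values.tocsc()
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        if self.values.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise ValueError(
                f"matrix shape {self.values.shape} inconsistent with "
                f"{len(self.gene_ids)} genes x {len(self.cell_ids)} cells"
            )
        _check_unique(self.gene_ids, "gene")
        _check_unique(self.cell_ids, "cell")
        if self.values.nnz and self.values.data.min() < 0:
            raise ValueError("negative counts")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    def cell_totals(self) -> np.ndarray:
        return np.asarray(self.values.sum(axis=0)).ravel()

    def gene_index(self, genes) -> np.ndarray:
        """Positions of the requested genes; raises KeyError on a miss."""
        lookup = {g: i for i, g in enumerate(self.gene_ids)}
        try:
            return np.array([lookup[g] for g in genes], dtype=int)
        except KeyError as e:
            raise KeyError(f"gene {e.args[0]!r} not present") from None

    def subset_cells(self, mask_or_idx) -> "CountMatrix":
        idx = _as_index(mask_or_idx, self.n_cells)
        return CountMatrix(self.values[:, idx], self.gene_ids, self.cell_ids[idx])

    def subset_genes(self, mask_or_idx) -> "CountMatrix":
        idx = _as_index(mask_or_idx, self.n_genes)
        return CountMatrix(self.values[idx, :], self.gene_ids[idx], self.cell_ids)


def _as_index(mask_or_idx, n: int) -> np.ndarray:
    arr = np.asarray(mask_or_idx)
    if arr.dtype == bool:
        if arr.shape != (n,):
            raise ValueError("boolean mask has wrong length")
        return np.flatnonzero(arr)
    return arr.astype(int)


@dataclass
class NormalizedMatrix:
    """log2(count / size_factor + 1) expression, same layout as the source."""

    values: sp.csc_matrix
    gene_ids: np.ndarray
    cell_ids: np.ndarray
    size_factors: np.ndarray

    def __post_init__(self) -> None:
        self.values = self.values.tocsc()
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        self.size_factors = np.asarray(self.size_factors, dtype=float)
        if np.any(self.size_factors <= 0):
            raise ValueError("size factors must be positive")
        if abs(self.size_factors.mean() - 1.0) > 1e-6:
            raise ValueError("size factors must have unit mean")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    def dense(self) -> np.ndarray:
        return np.asarray(self.values.todense())

    def gene_index(self, genes) -> np.ndarray:
        lookup = {g: i for i, g in enumerate(self.gene_ids)}
        try:
            return np.array([lookup[g] for g in genes], dtype=int)
        except KeyError as e:
            raise KeyError(f"gene {e.args[0]!r} not present") from None

    def subset_genes(self, mask_or_idx) -> "NormalizedMatrix":
        idx = _as_index(mask_or_idx, self.n_genes)
        return NormalizedMatrix(
            self.values[idx, :], self.gene_ids[idx], self.cell_ids, self.size_factors
        )

    def subset_cells(self, mask_or_idx) -> "NormalizedMatrix":
        idx = _as_index(mask_or_idx, self.n_cells)
        sf = self.size_factors[idx]
        sf = sf / sf.mean()
        return NormalizedMatrix(self.values[:, idx], self.gene_ids, self.cell_ids[idx], sf)


@dataclass
class CorrectedSpace:
    """Cells x d coordinates in a (possibly batch-corrected) reduced space."""

    coordinates: np.ndarray
    cell_ids: np.ndarray
    batch_id: np.ndarray
    d: int = field(init=False)

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        self.batch_id = np.asarray(self.batch_id)
        if not np.all(np.isfinite(self.coordinates)):
            raise ValueError("non-finite coordinates")
        n = self.coordinates.shape[0]
        if len(self.cell_ids) != n or len(self.batch_id) != n:
            raise ValueError("row count inconsistent with identifiers")
        self.d = self.coordinates.shape[1]


@dataclass
class AtlasReference:
    """Reference atlas: corrected coordinates, type label and numeric age per cell."""

    coordinates: np.ndarray
    type_label: np.ndarray
    timepoint: np.ndarray
    cell_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        self.type_label = np.asarray(self.type_label, dtype=object)
        self.timepoint = np.asarray(self.timepoint, dtype=float)
        n = self.coordinates.shape[0]
        if len(self.type_label) != n or len(self.timepoint) != n:
            raise ValueError("label/timepoint length inconsistent with coordinates")
        if any(t is None or (isinstance(t, str) and not t) for t in self.type_label):
            raise ValueError("atlas contains unlabeled cells; drop them in the loader")
        if self.cell_ids is None:
            self.cell_ids = np.array([f"atlas_{i}" for i in range(n)], dtype=object)

    @property
    def n_cells(self) -> int:
        return self.coordinates.shape[0]


@dataclass
class GroundTruth:
    """Synthetic-only record of every planted signal."""

    cells: pd.DataFrame  # cell_id, true_type, true_spikein, true_age, sample
    de: pd.DataFrame  # gene, contrast, log2fc
    lr: pd.DataFrame  # ligand, receptor, source_type, target_type, log2fold

    def __post_init__(self) -> None:
        if self.cells["cell_id"].duplicated().any():
            raise ValueError("ground truth must cover every cell exactly once")
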