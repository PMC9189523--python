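"""Dimensionality reduction and batch integration.

The batch-correction step follows the fast mutual-nearest-neighbors recipe:
cosine-normalize expression, project all batches into a joint d-dimensional
PCA space, then merge batches sequentially — per merge, mutual k-nearest
neighbor pairs between the accumulated reference and the incoming batch
define per-cell correction vectors (Gaussian-kernel-smoothed averages of the
paired differences) that are applied to the incoming batch.

Clustering builds a shared-nearest-neighbor graph (edge weight
shared / (2k - shared)) and partitions it with the Louvain algorithm.
"""
from __future__ import annotations

import random

import igraph
import numpy as np
import scipy.sparse as sp
from sklearn.neighbors import NearestNeighbors

from .containers import CorrectedSpace, NormalizedMatrix


def _center_and_svd(x: np.ndarray, d: int):
    """PCA of cells x genes data; deterministic sign (largest loading positive)."""
    xc = x - x.mean(axis=0, keepdims=True)
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    u, s, vt = u[:, :d], s[:d], vt[:d]
    flip = np.sign(vt[np.arange(d), np.argmax(np.abs(vt), axis=1)])
    flip[flip == 0] = 1.0
    return u * s * flip, vt * flip[:, None]


def pca_reduce(nm: NormalizedMatrix, d: int, batch_id=None) -> CorrectedSpace:
    """Cell scores on the top-d principal components of gene-centered expression."""
    if d > min(nm.n_cells - 1, nm.n_genes):
        raise ValueError(f"d={d} exceeds min(n_cells - 1, n_genes)")
    x = nm.dense().T  # cells x genes
    scores, _ = _center_and_svd(x, d)
    if batch_id is None:
        batch_id = np.zeros(nm.n_cells, dtype=int)
    return CorrectedSpace(scores, nm.cell_ids, batch_id)


def cosine_normalize(x: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(x, axis=1, keepdims=True)
    return x / np.maximum(norms, 1e-12)


def _mnn_pairs(ref: np.ndarray, new: np.ndarray, k: int):
    """Mutual k-nearest-neighbor index pairs between two coordinate sets."""
    k_ref = min(k, len(ref))
    k_new = min(k, len(new))
    nn_in_ref = NearestNeighbors(n_neighbors=k_ref).fit(ref).kneighbors(new, return_distance=False)
    nn_in_new = NearestNeighbors(n_neighbors=k_new).fit(new).kneighbors(ref, return_distance=False)
    ref_sets = [set(row) for row in nn_in_new]
    pairs = [
        (r, i)
        for i, row in enumerate(nn_in_ref)
        for r in row
        if i in ref_sets[r]
    ]
    return np.array(pairs, dtype=int).reshape(-1, 2)


def mnn_correct(
    batches: list[NormalizedMatrix],
    d: int,
    k: int,
    order: list[int] | None = None,
    bandwidth_factor: float = 3.0,
) -> CorrectedSpace:
    """Sequentially merge batches into one corrected d-space.

    ``order`` lists batch indices, first entry being the reference; output
    rows keep the original batch order (batch 0 cells first), with batch_id
    recording provenance. The reference batch's geometry is unchanged beyond
    the shared cosine-normalization + joint PCA projection.
    """
    if len(batches) < 2:
        raise ValueError("need at least two batches")
    genes0 = tuple(batches[0].gene_ids)
    if any(tuple(b.gene_ids) != genes0 for b in batches[1:]):
        raise ValueError("batches must share a gene universe")
    order = list(range(len(batches))) if order is None else list(order)

    x = np.concatenate([b.dense().T for b in batches], axis=0)  # cells x genes
    sizes = [b.n_cells for b in batches]
    offsets = np.concatenate([[0], np.cumsum(sizes)])
    batch_id = np.concatenate([np.full(n, i) for i, n in enumerate(sizes)])

    x = cosine_normalize(x)
    d_eff = min(d, x.shape[0] - 1, x.shape[1])
    scores, _ = _center_and_svd(x, d_eff)

    corrected = scores.copy()
    ref_idx = np.arange(offsets[order[0]], offsets[order[0] + 1])
    for bi in order[1:]:
        new_idx = np.arange(offsets[bi], offsets[bi + 1])
        ref = corrected[ref_idx]
        new = corrected[new_idx]
        pairs = _mnn_pairs(ref, new, k)
        if len(pairs) == 0:
            raise ValueError("no mutual nearest-neighbor pairs found; increase k")
        diffs = ref[pairs[:, 0]] - new[pairs[:, 1]]  # vectors moving new -> ref
        # kernel weights use pair midpoints: for duplicated batches mirrored
        # pairs then cancel exactly, giving a zero net correction
        pair_pos = 0.5 * (ref[pairs[:, 0]] + new[pairs[:, 1]])
        pair_dist = np.linalg.norm(diffs, axis=1)
        sigma = bandwidth_factor * max(pair_dist.mean(), 1e-12)
        # smooth each new cell's correction over nearby pairs (chunked: the
        # cells x pairs kernel matrix can be large)
        fallback = diffs.mean(axis=0)
        pair_sq = (pair_pos ** 2).sum(axis=1)
        corr = np.empty_like(new)
        for lo in range(0, len(new), 512):
            blk = new[lo:lo + 512]
            d2 = (blk ** 2).sum(axis=1)[:, None] + pair_sq[None, :] - 2.0 * blk @ pair_pos.T
            np.maximum(d2, 0.0, out=d2)
            w = np.exp(-d2 / (2.0 * sigma ** 2))
            w_sum = w.sum(axis=1, keepdims=True)
            corr[lo:lo + 512] = np.where(
                w_sum > 1e-12, (w @ diffs) / np.maximum(w_sum, 1e-12), fallback
            )
        corrected[new_idx] = new + corr
        ref_idx = np.concatenate([ref_idx, new_idx])

    cell_ids = np.concatenate([b.cell_ids for b in batches])
    return CorrectedSpace(corrected, cell_ids, batch_id)


def snn_graph(coords: np.ndarray, k: int) -> igraph.Graph:
    """Shared-nearest-neighbor graph; weight = shared / (2k - shared)."""
    n = coords.shape[0]
    if k >= n:
        raise ValueError(f"k={k} must be smaller than the number of cells ({n})")
    knn = NearestNeighbors(n_neighbors=k + 1).fit(coords)
    nbrs = knn.kneighbors(coords, return_distance=False)  # includes self
    # cells are linked when their k-neighborhoods (self included) intersect;
    # the shared count is computed via the sparse adjacency product
    rows = np.repeat(np.arange(n), k + 1)
    adj = sp.csr_matrix(
        (np.ones(n * (k + 1)), (rows, nbrs.ravel())), shape=(n, n)
    )
    shared_mat = (adj @ adj.T).tocoo()
    edges, weights = [], []
    for i, j, shared in zip(shared_mat.row, shared_mat.col, shared_mat.data):
        if i < j and shared > 0:
            edges.append((int(i), int(j)))
            weights.append(shared / (2 * (k + 1) - shared))
    g = igraph.Graph(n=n, edges=edges)
    g.es["weight"] = weights
    return g


def snn_cluster(cs: CorrectedSpace, k: int, d_use: int, seed: int = 0) -> np.ndarray:
    """Louvain communities of the SNN graph on the first d_use dimensions.

    Returns integer labels contiguous from 1, relabeled by decreasing
    community size for stability.
    """
    if d_use > cs.d:
        raise ValueError(f"d_use={d_use} exceeds available dimensions ({cs.d})")
    g = snn_graph(cs.coordinates[:, :d_use], k)
    random.seed(seed)  # igraph's Louvain draws from Python's random module
    membership = np.array(g.community_multilevel(weights="weight").membership)
    # stable relabeling: 1 = largest community, ties by first occurrence
    sizes = np.bincount(membership)
    order = np.argsort(-sizes, kind="stable")
    relabel = np.empty_like(order)
    relabel[order] = np.arange(1, len(order) + 1)
    return relabel[membership]


def embed_2d(
    cs: CorrectedSpace,
    n_neighbors: int = 50,
    min_dist: float = 0.7,
    metric: str = "cosine",
    seed: int = 0,
) -> np.ndarray:
    """UMAP layout of the corrected space. Visualization only."""
    import umap

    reducer = umap.UMAP(
        n_neighbors=n_neighbors, min_dist=min_dist, metric=metric, random_state=seed
    )
    return np.asarray(reducer.fit_transform(cs.coordinates), dtype=float)


def batch_mixing_entropy(coords: np.ndarray, batch_id: np.ndarray, k: int = 30) -> float:
    """Mean Shannon entropy of batch composition in k-NN neighborhoods.

    Higher means better mixed; the theoretical maximum is log(n_batches).
    """
    nn = NearestNeighbors(n_neighbors=k + 1).fit(coords)
    nbrs = nn.kneighbors(coords, return_distance=False)[:, 1:]
    batches = np.unique(batch_id)
    ent = np.zeros(len(coords))
    for b in batches:
        p = (batch_id[nbrs] == b).mean(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            term = np.where(p > 0, -p * np.log(p), 0.0)
        ent += term
    return float(ent.mean())
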