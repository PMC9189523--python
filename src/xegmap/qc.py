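"""Cell/gene filtering, normalization, HVG selection, signature scoring.

Filtering follows the count-threshold convention used for droplet data:
cells with total transcript count strictly below the threshold are excluded
(a cell at exactly the threshold is kept), and genes expressed in fewer than
two cells across merged replicates are dropped.

Highly variable genes are selected per replicate from a CV^2-vs-mean trend
(the improvedCV2 family): fit CV^2 = a1/mean + a0 by robust least squares,
score each gene by a chi-squared test of its observed/fitted variance ratio,
and keep the top 10% by p-value; the cross-replicate set is the union.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats
from scipy.sparse.linalg import lsqr

from .containers import CountMatrix, EmptyOutputError, NormalizedMatrix


def filter_cells(m: CountMatrix, min_count: int) -> CountMatrix:
    """Drop cells with total count < min_count (strict: exactly min_count is kept)."""
    if min_count < 0:
        raise ValueError("min_count must be nonnegative")
    keep = m.cell_totals() >= min_count
    if not keep.any():
        raise EmptyOutputError(f"no cells with total count >= {min_count}")
    return m.subset_cells(keep)


def filter_genes(m: CountMatrix, min_cells: int = 2) -> CountMatrix:
    """Drop genes with nonzero counts in fewer than min_cells cells."""
    n_expressing = np.asarray((m.values > 0).sum(axis=1)).ravel()
    keep = n_expressing >= min_cells
    if not keep.any():
        raise EmptyOutputError("no genes survive the expression filter")
    return m.subset_genes(keep)


def _pooled_size_factors(m: CountMatrix, pool_sizes=(21, 41, 61, 81, 101)) -> np.ndarray:
    """Deconvolution size factors from ring pools of cells.

    Cells are ordered on a ring by library size; each pool's summed profile
    is compared to the average cell, giving one linear equation per pool in
    the member cells' factors; the system is solved by least squares.
    """
    counts = m.values.tocsc()
    n = m.n_cells
    totals = m.cell_totals()
    order = np.argsort(totals, kind="stable")
    # alternate low/high to balance pools
    ring = np.empty(n, dtype=int)
    ring[0::2] = order[: (n + 1) // 2]
    ring[1::2] = order[(n + 1) // 2:][::-1]
    ref = np.asarray(counts.mean(axis=1)).ravel()
    use = ref > 0
    rows, cols, vals, rhs = [], [], [], []
    eq = 0
    for size in pool_sizes:
        if size > n:
            continue
        for start in range(n):
            members = ring[(start + np.arange(size)) % n]
            pooled = np.asarray(counts[:, members].sum(axis=1)).ravel()
            ratios = pooled[use] / ref[use]
            theta = np.median(ratios)
            rows.extend([eq] * size)
            cols.extend(members.tolist())
            vals.extend([1.0] * size)
            rhs.append(theta)
            eq += 1
    # anchor: mean factor equals mean library-size factor
    lib = totals / totals.mean()
    rows.extend([eq] * n)
    cols.extend(range(n))
    vals.extend([np.sqrt(n)] * n)
    rhs.append(np.sqrt(n) * lib.sum())
    A = sp.csr_matrix((vals, (rows, cols)), shape=(eq + 1, n))
    sf = lsqr(A, np.asarray(rhs))[0]
    sf = np.maximum(sf, 1e-8)
    return sf / sf.mean()


def size_factors(m: CountMatrix, method: str = "library") -> np.ndarray:
    """Per-cell size factors rescaled to unit mean.

    ``library``: total count per cell (the auditable default).
    ``pooled``: scran-style pooled deconvolution.
    """
    totals = m.cell_totals()
    if np.any(totals == 0):
        bad = m.cell_ids[totals == 0][0]
        raise ValueError(f"cell {bad!r} has zero total count; filter first")
    if method == "library":
        return totals / totals.mean()
    if method == "pooled":
        return _pooled_size_factors(m)
    raise ValueError(f"unknown size-factor method {method!r}")


def normalize_log(m: CountMatrix, method: str = "library") -> NormalizedMatrix:
    """log2(count / size_factor + 1) with unit-mean size factors."""
    sf = size_factors(m, method=method)
    x = m.values.tocsc().astype(float)
    x = x.multiply(sp.csc_matrix(1.0 / sf[None, :]))  # scale columns
    x.data = np.log2(x.data + 1.0)
    return NormalizedMatrix(x.tocsc(), m.gene_ids, m.cell_ids, sf)


def invert_normalize(nm: NormalizedMatrix) -> np.ndarray:
    """Recover raw counts from a NormalizedMatrix (round-trip check)."""
    x = nm.values.copy().tocsc()
    x.data = 2.0 ** x.data - 1.0
    return np.asarray(x.multiply(sp.csc_matrix(nm.size_factors[None, :])).todense())


# -- highly variable genes ---------------------------------------------------

@dataclass
class HVGResult:
    table: pd.DataFrame  # gene, mean, cv2, trend, pvalue, selected

    @property
    def selected_genes(self) -> np.ndarray:
        return self.table.loc[self.table["selected"], "gene"].to_numpy()


def _fit_cv2_trend(mean: np.ndarray, cv2: np.ndarray, n_iter: int = 5):
    """Robust least squares for CV^2 = a1/mean + a0 (Tukey bisquare reweighting)."""
    X = np.column_stack([1.0 / mean, np.ones_like(mean)])
    w = np.ones_like(cv2)
    coef = np.array([1.0, 0.0])
    for _ in range(n_iter):
        WX = X * w[:, None]
        coef, *_ = np.linalg.lstsq(WX, cv2 * w, rcond=None)
        resid = cv2 - X @ coef
        s = np.median(np.abs(resid)) * 1.4826 + 1e-12
        u = np.clip(resid / (4.685 * s), -1, 1)
        w = (1 - u ** 2) ** 2
    a1, a0 = coef
    return max(a1, 0.0), max(a0, 1e-12)


def hvg_per_replicate(
    nm: NormalizedMatrix, min_mean: float = 0.1, top_frac: float = 0.10,
    exclude: set | None = None,
) -> HVGResult:
    """CV^2-trend excess-variance test on one replicate; top `top_frac` by p-value."""
    exclude = exclude or set()
    x = nm.values
    n = nm.n_cells
    mean = np.asarray(x.mean(axis=1)).ravel()
    sq = np.asarray(x.multiply(x).mean(axis=1)).ravel()
    var = (sq - mean ** 2) * n / max(n - 1, 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv2 = np.where(mean > 0, var / mean ** 2, np.nan)
    testable = (mean > min_mean) & np.isfinite(cv2)
    testable &= ~np.isin(nm.gene_ids.astype(str), list(exclude))
    if testable.sum() < 50:
        raise ValueError(
            f"only {testable.sum()} testable genes; CV^2 trend is unfittable"
        )
    a1, a0 = _fit_cv2_trend(mean[testable], cv2[testable])
    trend = np.where(mean > 0, a1 / np.maximum(mean, 1e-12) + a0, np.nan)
    df = n - 1
    with np.errstate(invalid="ignore"):
        chi2_stat = df * cv2 / trend
    pval = np.full(nm.n_genes, np.nan)
    pval[testable] = stats.chi2.sf(chi2_stat[testable], df)
    n_sel = int(np.ceil(top_frac * testable.sum()))
    order = np.argsort(np.where(testable, pval, np.inf), kind="stable")
    selected = np.zeros(nm.n_genes, dtype=bool)
    selected[order[:n_sel]] = True
    selected &= testable
    return HVGResult(
        pd.DataFrame(
            {
                "gene": nm.gene_ids,
                "mean": mean,
                "cv2": cv2,
                "trend": trend,
                "pvalue": pval,
                "selected": selected,
            }
        )
    )


def select_hvg(
    replicates: list[NormalizedMatrix],
    exclude: set | None = None,
    min_mean: float = 0.1,
    top_frac: float = 0.10,
) -> np.ndarray:
    """Union of per-replicate top-10% HVG over the shared gene universe.

    ``exclude`` holds genes never eligible (ribosomal list, exogenous genes,
    antibody-capture features).
    """
    union: set = set()
    for nm in replicates:
        res = hvg_per_replicate(nm, min_mean=min_mean, top_frac=top_frac, exclude=exclude)
        union.update(res.selected_genes.tolist())
    genes = replicates[0].gene_ids
    return genes[np.isin(genes.astype(str), list(union))]


def signature_score(nm: NormalizedMatrix, genes) -> np.ndarray:
    """Average standardized expression per cell over a gene list.

    Each present gene is z-scored across cells (zero-variance genes dropped);
    the per-cell score is the mean over the remaining genes.
    """
    present = [g for g in genes if g in set(nm.gene_ids)]
    if not present:
        raise ValueError("no listed gene present in the matrix")
    idx = nm.gene_index(present)
    x = np.asarray(nm.values[idx, :].todense())
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=0, keepdims=True)
    keep = sd.ravel() > 0
    if not keep.any():
        raise ValueError("all listed genes have zero variance")
    z = (x[keep] - mu[keep]) / sd[keep]
    return z.mean(axis=0)
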