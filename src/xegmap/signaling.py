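"""Ligand-receptor communication scoring between cell-type pairs.

For every (ligand, receptor) pair in a database and every ordered
(source, target) cell-type pair, the observed score is the mean of the
ligand's mean expression in the source cluster and the receptor's mean
expression in the target cluster. Significance comes from shuffling the
cell-type labels: p = (1 + #{null score >= observed}) / (1 + n_perm). Pairs
whose ligand (in source) or receptor (in target) is expressed in fewer than
``min_frac_expressing`` of the cluster's cells are assigned p = 1. Per
(source, target), the communication score is the sum of pair scores over
significant pairs, optionally restricted to ligands of interest.
"""
from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .containers import NormalizedMatrix

logger = logging.getLogger(__name__)


def map_gene_names(genes, mapping: pd.DataFrame) -> dict:
    """Apply a 1:1 two-column (source_name, target_name) mapping.

    Unmapped genes are dropped with a log entry; duplicate targets raise an
    error listing the collisions.
    """
    src, tgt = mapping.columns[:2]
    dup = mapping[tgt].duplicated(keep=False)
    if dup.any():
        pairs = mapping.loc[dup].sort_values(tgt)
        collisions = [
            f"{t!r} <- {sorted(grp[src].tolist())}" for t, grp in pairs.groupby(tgt)
        ]
        raise ValueError("duplicate mapping targets: " + "; ".join(collisions))
    table = dict(zip(mapping[src], mapping[tgt]))
    out = {}
    for g in genes:
        if g in table:
            out[g] = table[g]
        else:
            logger.warning("gene %r has no mapping; dropped", g)
    return out


def _cluster_means(x: np.ndarray, onehot: np.ndarray) -> np.ndarray:
    """genes x clusters mean expression; onehot is cells x clusters, col-normalized."""
    return x @ onehot


def lr_permutation_test(
    nm: NormalizedMatrix,
    labels: np.ndarray,
    db: pd.DataFrame,
    n_perm: int = 1000,
    seed: int = 0,
    min_frac_expressing: float = 0.10,
    min_cells: int = 10,
) -> pd.DataFrame:
    """Permutation p-values for every (pair, source, target) combination.

    ``db`` needs columns ligand, receptor. All ordered type pairs among
    types with >= min_cells cells are tested. Unknown genes are skipped
    with a log entry.
    """
    if n_perm < 100:
        logger.warning("n_perm=%d is small; p-values are coarse", n_perm)
    labels = np.asarray(labels, dtype=object)
    counts = pd.Series(labels).value_counts()
    types = sorted(t for t in counts.index if counts[t] >= min_cells)
    if not types:
        raise ValueError("no cell type reaches the minimum cell count")

    present = set(nm.gene_ids.tolist())
    db_use = db[db["ligand"].isin(present) & db["receptor"].isin(present)]
    for _, row in db[~db.index.isin(db_use.index)].iterrows():
        logger.warning("pair (%s, %s) has unknown gene(s); skipped", row["ligand"], row["receptor"])
    if db_use.empty:
        return pd.DataFrame(
            columns=[
                "ligand", "receptor", "source", "target",
                "mean_ligand", "mean_receptor", "pair_score", "pvalue", "significant",
            ]
        )

    genes = sorted(set(db_use["ligand"]) | set(db_use["receptor"]))
    gidx = nm.gene_index(genes)
    gpos = {g: i for i, g in enumerate(genes)}
    x = np.asarray(nm.values[gidx, :].todense())  # used genes x cells

    cells_in = {t: labels == t for t in types}
    onehot = np.stack([cells_in[t] / cells_in[t].sum() for t in types], axis=1)
    obs_means = _cluster_means(x, onehot)  # genes x types
    frac_expr = np.stack(
        [(x[:, cells_in[t]] > 0).mean(axis=1) for t in types], axis=1
    )

    rng = np.random.default_rng(seed)
    perm_means = np.empty((n_perm, x.shape[0], len(types)))
    idx = np.arange(nm.n_cells)
    for b in range(n_perm):
        rng.shuffle(idx)
        perm_means[b] = _cluster_means(x[:, idx], onehot)

    tpos = {t: j for j, t in enumerate(types)}
    rows = []
    for _, row in db_use.iterrows():
        li, ri = gpos[row["ligand"]], gpos[row["receptor"]]
        for s in types:
            for t in types:
                sj, tj = tpos[s], tpos[t]
                ml = obs_means[li, sj]
                mr = obs_means[ri, tj]
                score = 0.5 * (ml + mr)
                null = 0.5 * (perm_means[:, li, sj] + perm_means[:, ri, tj])
                p = (1.0 + np.sum(null >= score)) / (1.0 + n_perm)
                if (
                    frac_expr[li, sj] < min_frac_expressing
                    or frac_expr[ri, tj] < min_frac_expressing
                ):
                    p = 1.0
                rows.append(
                    {
                        "ligand": row["ligand"],
                        "receptor": row["receptor"],
                        "source": s,
                        "target": t,
                        "mean_ligand": ml,
                        "mean_receptor": mr,
                        "pair_score": score,
                        "pvalue": p,
                    }
                )
    out = pd.DataFrame(rows)
    out["significant"] = out["pvalue"] < 0.05
    return out


def aggregate_communication(
    table: pd.DataFrame, alpha: float = 0.05, ligands_of_interest=None
) -> pd.DataFrame:
    """Sum pair scores over significant pairs per (source, target).

    Type pairs without a significant pair are absent from the output.
    """
    sig = table[table["pvalue"] < alpha]
    if ligands_of_interest is not None:
        sig = sig[sig["ligand"].isin(set(ligands_of_interest))]
    if sig.empty:
        return pd.DataFrame(columns=["source", "target", "score", "n_pairs"])
    agg = (
        sig.groupby(["source", "target"])
        .agg(score=("pair_score", "sum"), n_pairs=("pair_score", "size"))
        .reset_index()
    )
    return agg
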