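"""Sub-clustering of neural ectoderm-like cells on a dorsoventral marker panel.

Cells typed as neural ectoderm (rostral/caudal neurectoderm, spinal cord,
forebrain/midbrain/hindbrain by default) are re-integrated across replicates
with MNN restricted to a curated dorsoventral marker panel, then k-means
partitioned (five centers). Sub-cluster frequencies are corrected for sample
size: relative frequencies f[s, c] within each sample are renormalized per
sub-cluster, g[s, c] = f[s, c] / sum_s f[s, c], so per sub-cluster the g
values sum to 1 across samples regardless of sample sizes.
"""
from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .containers import NormalizedMatrix
from .integrate import mnn_correct

NEURAL_TYPES = frozenset(
    {
        "Rostral neurectoderm",
        "Caudal neurectoderm",
        "Spinal cord",
        "Forebrain/Midbrain/Hindbrain",
    }
)


def load_marker_panel(path) -> pd.DataFrame:
    """TSV with columns gene, axis (dorsal|ventral)."""
    panel = pd.read_csv(path, sep="\t")
    if panel.empty or panel["gene"].duplicated().any():
        raise ValueError("marker panel must be nonempty with unique genes")
    bad = set(panel["axis"]) - {"dorsal", "ventral"}
    if bad:
        raise ValueError(f"unknown axis annotation(s): {bad}")
    return panel


def subset_neural(assignments: pd.DataFrame, neural_types=NEURAL_TYPES) -> np.ndarray:
    """Cell ids whose assigned type is in the neural ectoderm set."""
    mask = assignments["assigned_type"].isin(neural_types)
    if not mask.any():
        raise ValueError("no neural ectoderm-like cells in the assignments")
    return assignments.loc[mask, "cell_id"].to_numpy()


def marker_kmeans(
    replicates: list[NormalizedMatrix],
    panel: pd.DataFrame,
    d: int = 5,
    k_mnn: int = 20,
    centers: int = 5,
    seed: int = 0,
):
    """MNN-integrate replicates on panel genes, then k-means with fixed seed.

    Panel genes are sorted before subsetting so the result does not depend
    on the panel's row order. Returns (labels starting at 1, CorrectedSpace).
    """
    genes = sorted(set(panel["gene"]) & set(replicates[0].gene_ids.tolist()))
    if not genes:
        raise ValueError("no panel gene present in the matrices")
    subs = [nm.subset_genes(nm.gene_index(genes)) for nm in replicates]
    cs = mnn_correct(subs, d=d, k=k_mnn)
    n = cs.coordinates.shape[0]
    if centers > n:
        raise ValueError(f"centers={centers} exceeds {n} cells")
    km = KMeans(n_clusters=centers, init="k-means++", n_init=25, random_state=seed)
    labels = km.fit_predict(cs.coordinates) + 1
    return labels, cs


def dorsoventral_polarity(
    nm: NormalizedMatrix, labels: np.ndarray, panel: pd.DataFrame
) -> pd.DataFrame:
    """Name sub-clusters dorsal/ventral by mean standardized marker expression."""
    from .qc import signature_score

    dorsal = panel.loc[panel["axis"] == "dorsal", "gene"].tolist()
    ventral = panel.loc[panel["axis"] == "ventral", "gene"].tolist()
    ds = signature_score(nm, dorsal)
    vs = signature_score(nm, ventral)
    rows = []
    for lab in np.unique(labels):
        diff = ds[labels == lab].mean() - vs[labels == lab].mean()
        rows.append(
            {"subcluster": lab, "dv_score": diff, "polarity": "dorsal" if diff > 0 else "ventral"}
        )
    return pd.DataFrame(rows)


def normalized_subcluster_frequencies(
    labels: np.ndarray, samples: np.ndarray
) -> pd.DataFrame:
    """Sample-size-corrected sub-cluster frequencies.

    Returns one row per (sample, subcluster) with the within-sample relative
    frequency f and the renormalized frequency g; per sub-cluster, g sums to
    1 across samples. Sub-clusters absent from every sample are dropped with
    a warning.
    """
    labels = np.asarray(labels)
    samples = np.asarray(samples)
    if len(labels) != len(samples):
        raise ValueError("every cell needs a sample and a sub-cluster label")
    tab = pd.crosstab(pd.Series(samples, name="sample"), pd.Series(labels, name="subcluster"))
    f = tab.div(tab.sum(axis=1), axis=0)
    empty = f.columns[f.sum(axis=0) == 0]
    if len(empty):
        warnings.warn(f"sub-cluster(s) {list(empty)} absent from all samples; dropped")
        f = f.drop(columns=empty)
    g = f.div(f.sum(axis=0), axis=1)
    out = (
        f.stack().rename("f").to_frame().join(g.stack().rename("g")).reset_index()
    )
    return out
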