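#!/usr/bin/env python
"""Sub-cluster neural ectoderm-like cells on a marker panel and compute
sample-size-corrected sub-cluster frequencies.

Takes the atlas-mapping assignments, keeps cells typed as neural ectoderm
(here the simulated "Spinal cord" plus "NMP" stand in for the neural set),
re-integrates the samples with MNN restricted to a panel of the simulation's
own identity genes (a synthetic stand-in for a curated dorsoventral marker
list), k-means partitions the corrected subspace into five centers, and
writes the raw (f) and renormalized (g) frequencies per sample.
"""
import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from xegmap import io
from xegmap.neural import (
    marker_kmeans,
    normalized_subcluster_frequencies,
    subset_neural,
)
from xegmap.qc import filter_genes, normalize_log

SAMPLES = ["XEG_rep1", "XEG_rep2", "gastruloid_rep1", "gastruloid_rep2"]


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--data", type=Path, default=Path("results/data"))
    ap.add_argument("--mapping", type=Path, default=Path("results/mapping"))
    ap.add_argument("--out", type=Path, default=Path("results/neural"))
    ap.add_argument("--centers", type=int, default=5)
    ap.add_argument("--d", type=int, default=5)
    ap.add_argument("--seed", type=int, default=0)
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    assigned = pd.read_csv(args.mapping / "assignments.csv")
    neural_ids = set(
        subset_neural(assigned, neural_types={"Spinal cord", "NMP"})
    )
    print(f"{len(neural_ids)} neural ectoderm-like cells selected")

    # synthetic stand-in panel: the simulation's first identity genes,
    # split into two arbitrary axis groups for polarity labeling
    panel_genes = [f"g{i:04d}" for i in range(40)]
    panel = pd.DataFrame(
        {
            "gene": panel_genes,
            "axis": ["dorsal"] * 20 + ["ventral"] * 20,
        }
    )

    nms, samples = [], []
    for s in SAMPLES:
        m = io.read_count_matrix(args.data / s)
        keep = np.isin(m.cell_ids, list(neural_ids))
        if keep.sum() < 10:
            continue
        nm = normalize_log(filter_genes(m.subset_cells(keep)))
        nms.append(nm)
        samples.append(np.full(nm.n_cells, s, dtype=object))
    from xegmap.workflow import restrict_to_shared_genes

    nms = restrict_to_shared_genes(*nms)
    labels, cs = marker_kmeans(
        nms, panel, d=args.d, k_mnn=20, centers=args.centers, seed=args.seed
    )
    samples = np.concatenate(samples)
    out = pd.DataFrame(
        {"cell_id": cs.cell_ids, "sample": samples, "subcluster": labels}
    )
    out.to_csv(args.out / "subclusters.csv", index=False)

    freqs = normalized_subcluster_frequencies(labels, samples)
    freqs.to_csv(args.out / "subcluster_frequencies.csv", index=False)
    print(freqs.pivot(index="sample", columns="subcluster", values="g").round(3))


if __name__ == "__main__":
    main()
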