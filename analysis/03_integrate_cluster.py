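#!/usr/bin/env python
"""Replicate integration, SNN/Louvain clustering and 2-D embedding.

For each condition: MNN-correct the two replicates on the HVG union,
cluster the corrected space (SNN graph + Louvain), and compute a UMAP
layout for visualization. Writes coordinates and labels keyed by cell_id.
"""
import argparse
from pathlib import Path

import pandas as pd

from xegmap import io
from xegmap.integrate import embed_2d, mnn_correct, snn_cluster
from xegmap.qc import filter_cells, filter_genes, normalize_log, select_hvg
from xegmap.workflow import EXOGENOUS_FEATURES, merge_matrices


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--data", type=Path, default=Path("results/data"))
    ap.add_argument("--out", type=Path, default=Path("results/integration"))
    ap.add_argument("--min-count", type=int, default=500)
    ap.add_argument("--d", type=int, default=50)
    ap.add_argument("--k", type=int, default=50)
    ap.add_argument("--seed", type=int, default=0)
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    for cond in ("XEG", "gastruloid"):
        reps = [io.read_count_matrix(args.data / f"{cond}_rep{r}") for r in (1, 2)]
        reps = [filter_cells(m, args.min_count) for m in reps]
        merged = filter_genes(merge_matrices(reps))
        nms = [
            normalize_log(m.subset_genes(m.gene_index(merged.gene_ids))) for m in reps
        ]
        hvg = select_hvg(nms, exclude=EXOGENOUS_FEATURES)
        subs = [nm.subset_genes(nm.gene_index(hvg)) for nm in nms]
        cs = mnn_correct(subs, d=min(args.d, len(hvg) - 1), k=args.k)
        clusters = snn_cluster(cs, k=20, d_use=min(30, cs.d), seed=args.seed)
        emb = embed_2d(cs, n_neighbors=50, min_dist=0.7, metric="cosine", seed=args.seed)
        out = pd.DataFrame(
            {
                "cell_id": cs.cell_ids,
                "replicate": cs.batch_id + 1,
                "cluster": clusters,
                "umap1": emb[:, 0],
                "umap2": emb[:, 1],
            }
        )
        for j in range(cs.d):
            out[f"pc{j+1}"] = cs.coordinates[:, j]
        out.to_csv(args.out / f"{cond}_integrated.csv", index=False)
        print(f"{cond}: {len(hvg)} HVG, {clusters.max()} clusters "
              f"over {len(out)} cells")


if __name__ == "__main__":
    main()
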