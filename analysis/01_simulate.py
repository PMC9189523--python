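#!/usr/bin/env python
"""Generate the synthetic study: a typed/timestamped reference atlas plus
two conditions (XEG, gastruloid) x two replicates of query cells with
spike-ins, planted condition-level DE genes, and one planted
ligand-receptor interaction.

Writes 10x-style matrices (matrix.mtx + genes.tsv + barcodes.tsv) per
sample, antibody counts, ground-truth tables and the config under
results/data/.
"""
import argparse
import dataclasses
import json
from pathlib import Path

from xegmap import io
from xegmap.profiles import separation_config
from xegmap.sim import generate_atlas, generate_query, plant_lr_signal


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--out", type=Path, default=Path("results/data"))
    ap.add_argument("--seed", type=int, default=0)
    args = ap.parse_args()

    planted_de = [(f"g{i:04d}", "XEG", 1.5) for i in range(40)]
    cfg = separation_config(
        args.seed,
        n_genes=1000,
        n_atlas_cells=2000,
        n_query_cells_per_sample=500,
        spikein_fraction=0.05,
        de_genes=planted_de,
        lr_pairs=[("g0900", "g0901", "Spinal cord", "Somitic mesoderm")],
    )

    atlas_m, atlas_cells, atlas_truth = generate_atlas(cfg)
    io.write_count_matrix(atlas_m, args.out / "atlas")
    atlas_cells.rename(columns={"type": "type"}).to_csv(
        args.out / "atlas" / "labels.tsv", sep="\t", index=False
    )

    mats, cells, truth = generate_query(cfg)
    for sample, m in mats.items():
        m = plant_lr_signal(m, truth, cfg, fold=8.0)
        io.write_count_matrix(m, args.out / sample)
    io.write_antibodies(cells, args.out / "cell_metadata.tsv")
    truth.cells.to_csv(args.out / "truth_cells.csv", index=False)
    truth.de.to_csv(args.out / "truth_de.csv", index=False)
    truth.lr.to_csv(args.out / "truth_lr.csv", index=False)
    (args.out / "sim_config.json").write_text(
        json.dumps(dataclasses.asdict(cfg), indent=2, default=str)
    )
    print(f"atlas: {atlas_m.n_genes} genes x {atlas_m.n_cells} cells")
    for sample, m in mats.items():
        print(f"{sample}: {m.n_cells} cells")
    print(f"planted DE genes: {len(planted_de)}; planted LR pairs: 1")


if __name__ == "__main__":
    main()
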