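"""Reading and writing the 10x-style on-disk formats.

A sample directory holds ``matrix.mtx`` (genes x cells, Matrix-Market),
``genes.tsv`` and ``barcodes.tsv``. Antibody-capture features live in a
separate ``antibodies.tsv`` (cell_id, one column per antibody). Atlas
directories additionally carry ``labels.tsv`` with columns
cell_id, type, timepoint.
"""
from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .containers import AtlasReference, CountMatrix


def write_count_matrix(m: CountMatrix, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(str(outdir / "matrix.mtx"), m.values.astype(int))
    pd.Series(m.gene_ids).to_csv(outdir / "genes.tsv", sep="\t", index=False, header=False)
    pd.Series(m.cell_ids).to_csv(outdir / "barcodes.tsv", sep="\t", index=False, header=False)


def read_count_matrix(indir: str | Path) -> CountMatrix:
    indir = Path(indir)
    values = sp.csc_matrix(scipy.io.mmread(str(indir / "matrix.mtx")))
    genes = pd.read_csv(indir / "genes.tsv", sep="\t", header=None)[0].to_numpy()
    cells = pd.read_csv(indir / "barcodes.tsv", sep="\t", header=None)[0].to_numpy()
    return CountMatrix(values, genes, cells)


def write_antibodies(ab: pd.DataFrame, path: str | Path) -> None:
    ab.to_csv(path, sep="\t", index=False)


def read_antibodies(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def read_atlas(indir: str | Path, coordinates: np.ndarray) -> AtlasReference:
    """Attach a labels.tsv to precomputed corrected coordinates.

    Cells without a type assignment are dropped, and the coordinate rows
    with them.
    """
    labels = pd.read_csv(Path(indir) / "labels.tsv", sep="\t")
    keep = labels["type"].notna() & (labels["type"].astype(str) != "")
    labels = labels[keep]
    return AtlasReference(
        coordinates=np.asarray(coordinates)[keep.to_numpy()],
        type_label=labels["type"].to_numpy(),
        timepoint=labels["timepoint"].to_numpy(),
        cell_ids=labels["cell_id"].to_numpy(),
    )


def write_json(obj: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=_jsonable))


def _jsonable(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, np.ndarray):
        return x.tolist()
    raise TypeError(f"not JSON serializable: {type(x)}")
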