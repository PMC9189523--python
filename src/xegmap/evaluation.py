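"""End-to-end evaluations of the pipeline on synthetic data with known truth.

Each function generates its own data from a seed, runs the relevant pipeline
stages, and returns the measured quantities. The study conditions (sample
sizes, separation strength, planted effect sizes) are fixed here so the test
suite and the reporting script measure the same thing.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from .atlas import NOT_ASSIGNED, apply_rejection, map_to_atlas
from .containers import CountMatrix
from .de import nb_glm_de, welch_de
from .integrate import (
    _center_and_svd,
    batch_mixing_entropy,
    cosine_normalize,
    mnn_correct,
    snn_cluster,
)
from .neural import normalized_subcluster_frequencies
from .profiles import separation_config
from .qc import normalize_log, select_hvg
from .signaling import lr_permutation_test
from .sim import (
    SimConfig,
    generate_ambiguous_cells,
    generate_atlas,
    generate_query,
    plant_lr_signal,
)
from .workflow import joint_atlas_space, merge_matrices, qc_normalize


def _seed(base: int, stream: int) -> int:
    return int(np.random.SeedSequence([base, stream]).generate_state(1)[0] % (2**31))


# -- label transfer -----------------------------------------------------------

def label_transfer_eval(
    seed: int,
    n_atlas: int = 5000,
    n_query_per_sample: int = 700,
    n_ambiguous: int = 200,
    d: int = 50,
    k: int = 50,
) -> dict:
    """Joint MNN + knn transfer on well-separated five-type data.

    Query = 4 samples x n_query_per_sample native cells plus n_ambiguous
    planted 50/50 mixture cells (3000 query cells total at the defaults).
    Returns accuracy among assigned native cells and the fraction of
    ambiguous cells rejected.
    """
    cfg = separation_config(
        _seed(seed, 1),
        n_atlas_cells=n_atlas,
        n_query_cells_per_sample=n_query_per_sample,
    )
    am, acells, _ = generate_atlas(cfg)
    mats, _, qtruth = generate_query(cfg)
    amb, amb_truth = generate_ambiguous_cells(cfg, n_ambiguous, "Spinal cord", "Gut")
    # ambiguous cells are spread over all four samples
    quarter = n_ambiguous // 4
    names = ["XEG_rep1", "XEG_rep2", "gastruloid_rep1", "gastruloid_rep2"]
    batches = [
        merge_matrices(
            [mats[name], amb.subset_cells(np.arange(i * quarter, (i + 1) * quarter))]
        )
        for i, name in enumerate(names)
    ]
    anm = qc_normalize(am)
    qnms = [qc_normalize(m) for m in batches]
    atlas, qcss = joint_atlas_space(
        anm, qnms, acells["type"].to_numpy(), acells["timepoint"].to_numpy(), d=d, k=k
    )
    # rejection thresholds are computed per dataset (all samples pooled)
    assigned = apply_rejection(
        pd.concat([map_to_atlas(q, atlas, k=50) for q in qcss], ignore_index=True)
    )
    truth = pd.concat([qtruth.cells, amb_truth]).set_index("cell_id")["true_type"]
    merged = assigned.set_index("cell_id").join(truth)
    amb_rows = merged[merged["true_type"] == "ambiguous"]
    native = merged[merged["true_type"] != "ambiguous"]
    kept = native[native["assigned_type"] != NOT_ASSIGNED]
    return {
        "n_query": len(merged),
        "accuracy_assigned": float((kept["assigned_type"] == kept["true_type"]).mean()),
        "ambiguous_rejected_frac": float(
            (amb_rows["assigned_type"] == NOT_ASSIGNED).mean()
        ),
        "assigned_frac_native": float(len(kept) / len(native)),
    }


# -- batch mixing -------------------------------------------------------------

def batch_mixing_eval(seed: int, n_seeds: int = 20, n_cells: int = 250) -> dict:
    """Entropy of 30-NN batch composition before vs after MNN, many seeds."""
    gains = []
    for i in range(n_seeds):
        cfg = separation_config(
            _seed(seed, 100 + i),
            n_genes=600,
            n_atlas_cells=50,
            n_query_cells_per_sample=n_cells,
            batch_effect_sd=0.3,
        )
        mats, _, _ = generate_query(cfg)
        nm1, nm2 = qc_normalize(mats["XEG_rep1"]), qc_normalize(mats["XEG_rep2"])
        from .workflow import restrict_to_shared_genes

        nm1, nm2 = restrict_to_shared_genes(nm1, nm2)
        hvg = select_hvg([nm1, nm2], exclude={"mCherry", "eGFP"})
        nm1h = nm1.subset_genes(nm1.gene_index(hvg))
        nm2h = nm2.subset_genes(nm2.gene_index(hvg))
        batch = np.concatenate([np.zeros(nm1.n_cells), np.ones(nm2.n_cells)])
        raw = cosine_normalize(np.concatenate([nm1h.dense().T, nm2h.dense().T]))
        d_eff = min(20, raw.shape[1], raw.shape[0] - 1)
        uncorrected, _ = _center_and_svd(raw, d_eff)
        cs = mnn_correct([nm1h, nm2h], d=d_eff, k=20)
        before = batch_mixing_entropy(uncorrected, batch, k=30)
        after = batch_mixing_entropy(cs.coordinates, batch, k=30)
        gains.append(after - before)
    gains = np.asarray(gains)
    return {
        "n_seeds": n_seeds,
        "entropy_gain_mean": float(gains.mean()),
        "entropy_gain_min": float(gains.min()),
        "all_increased": bool(np.all(gains > 0)),
    }


# -- differential expression --------------------------------------------------

def _de_config(seed: int, de_genes, n_genes=2000, n_per=200) -> SimConfig:
    # a single homogeneous population: the null is then purely the NB noise
    # model, with no cell-type composition differences between samples
    from .sim import CellType

    return separation_config(
        seed,
        n_genes=n_genes,
        n_atlas_cells=50,
        n_query_cells_per_sample=n_per,
        spikein_fraction=0.0,
        batch_effect_sd=0.0,
        de_genes=de_genes,
        cell_types=[CellType("Spinal cord", {"XEG": 1.0, "gastruloid": 1.0}, n_markers=0)],
        nb_dispersion=2.0,
    )


def de_calibration_eval(seed: int, n_genes: int = 2000, n_per: int = 200) -> dict:
    """NB-GLM type-I error under the null and planted-logFC recovery."""
    contrast = (["XEG_rep1", "XEG_rep2"], ["gastruloid_rep1", "gastruloid_rep2"])

    # null: same type composition in both conditions, no planted effects
    cfg = _de_config(_seed(seed, 2), [], n_genes, n_per)
    mats, _, _ = generate_query(cfg)
    merged = merge_matrices([mats[s] for s in sorted(mats)])
    subsets = np.concatenate(
        [np.full(mats[s].n_cells, s, dtype=object) for s in sorted(mats)]
    )
    res = nb_glm_de(merged, subsets, contrast)
    tested = res.dropna(subset=["pvalue"])
    type1 = float((tested["pvalue"] < 0.05).mean())

    # recovery: 100 genes up in XEG at log2FC 1.5
    planted = [f"g{i:04d}" for i in range(100)]
    cfg2 = _de_config(_seed(seed, 3), [(g, "XEG", 1.5) for g in planted], n_genes, n_per)
    mats2, _, _ = generate_query(cfg2)
    merged2 = merge_matrices([mats2[s] for s in sorted(mats2)])
    subsets2 = np.concatenate(
        [np.full(mats2[s].n_cells, s, dtype=object) for s in sorted(mats2)]
    )
    res2 = nb_glm_de(merged2, subsets2, contrast).set_index("gene")
    est = res2.loc[planted, "log2fc"].astype(float)
    return {
        "n_genes_tested": int(len(tested)),
        "type1_error": type1,
        "median_abs_logfc_error": float(np.median(np.abs(est - 1.5))),
        "planted_detected_bh05": int((res2.loc[planted, "padj"] < 0.05).sum()),
    }


def welch_power_eval(seed: int) -> dict:
    """Planted log2FC=2 genes recovered by the Welch route (100 vs 100 cells)."""
    rng = np.random.default_rng(_seed(seed, 4))
    n_genes, n_per = 2000, 100
    x = rng.normal(0.0, 1.0, size=(n_genes, 2 * n_per))
    x[:50, :n_per] += 2.0
    import scipy.sparse as sp

    from .containers import NormalizedMatrix

    nm = NormalizedMatrix(
        sp.csc_matrix(x),
        np.array([f"g{i}" for i in range(n_genes)], dtype=object),
        np.array([f"c{i}" for i in range(2 * n_per)], dtype=object),
        np.ones(2 * n_per),
    )
    out = welch_de(nm, [f"c{i}" for i in range(n_per)], [f"c{i}" for i in range(n_per, 2 * n_per)])
    return {"welch_planted_detected_bh05": int((out["padj"][:50] < 0.05).sum())}


# -- ligand-receptor ----------------------------------------------------------

def lr_calibration_eval(seed: int, n_pairs: int = 200, n_perm: int = 500) -> dict:
    """Permutation-test p-value calibration under a shuffled-label null."""
    rng = np.random.default_rng(_seed(seed, 5))
    n_genes, n_cells = 2 * n_pairs, 500
    import scipy.sparse as sp

    from .containers import NormalizedMatrix

    x = rng.lognormal(0.0, 0.7, size=(n_genes, n_cells))
    nm = NormalizedMatrix(
        sp.csc_matrix(x),
        np.array([f"g{i}" for i in range(n_genes)], dtype=object),
        np.array([f"c{i}" for i in range(n_cells)], dtype=object),
        np.ones(n_cells),
    )
    labels = rng.choice(["A", "B"], n_cells)
    db = pd.DataFrame(
        {
            "ligand": [f"g{2*i}" for i in range(n_pairs)],
            "receptor": [f"g{2*i+1}" for i in range(n_pairs)],
        }
    )
    out = lr_permutation_test(
        nm, labels, db, n_perm=n_perm, seed=_seed(seed, 6), min_frac_expressing=0.0
    )
    sub = out[(out["source"] == "A") & (out["target"] == "B")]
    return {
        "n_pairs": int(len(sub)),
        "null_p05_frac": float((sub["pvalue"] < 0.05).mean()),
    }


def lr_detection_eval(seed: int, n_seeds: int = 20, fold: float = 8.0) -> dict:
    """Planted 8-fold ligand-receptor pair detected at p<0.05 across seeds."""
    hits = 0
    for i in range(n_seeds):
        cfg = separation_config(
            _seed(seed, 200 + i),
            n_genes=300,
            n_atlas_cells=50,
            n_query_cells_per_sample=400,
            spikein_fraction=0.0,
            lr_pairs=[("g0000", "g0001", "NMP", "Gut")],
        )
        mats, _, truth = generate_query(cfg)
        m = plant_lr_signal(mats["XEG_rep1"], truth, cfg, fold=fold)
        nm = normalize_log(m)
        types = (
            truth.cells.set_index("cell_id").loc[list(nm.cell_ids), "true_type"].to_numpy()
        )
        db = pd.DataFrame({"ligand": ["g0000"], "receptor": ["g0001"]})
        out = lr_permutation_test(nm, types, db, n_perm=500, seed=_seed(seed, 300 + i))
        row = out[(out["source"] == "NMP") & (out["target"] == "Gut")].iloc[0]
        hits += row["pvalue"] < 0.05
    return {"n_seeds": n_seeds, "planted_lr_detected_frac": float(hits / n_seeds)}


# -- frequency normalization --------------------------------------------------

def frequency_invariance_eval(seed: int) -> dict:
    """Identical composition at n=100 vs n=10000: g should be ~0.5 each."""
    rng = np.random.default_rng(_seed(seed, 7))
    p = np.array([0.3, 0.25, 0.2, 0.15, 0.1])
    small = rng.choice(5, 100, p=p) + 1
    large = rng.choice(5, 10000, p=p) + 1
    labels = np.concatenate([small, large])
    samples = np.array(["small"] * 100 + ["large"] * 10000)
    out = normalized_subcluster_frequencies(labels, samples)
    g_small = out[out["sample"] == "small"].set_index("subcluster")["g"]
    dev = np.abs(g_small - 0.5)
    return {
        "max_abs_deviation_from_half": float(dev.max()),
        "n_subclusters": int(len(g_small)),
    }


# -- spike-in identification --------------------------------------------------

def spikein_eval(seed: int) -> dict:
    """Precision/recall of antibody+cluster spike-in calls at 5% spike-in rate."""
    from .integrate import pca_reduce
    from .spikein import E14_CD15, XEN_SPIKEIN, SpikeinRule, flag_transgene, identify_spikeins

    cfg = separation_config(
        _seed(seed, 8),
        n_genes=400,
        n_atlas_cells=50,
        n_query_cells_per_sample=800,
        spikein_fraction=0.05,
    )
    mats, cells, truth = generate_query(cfg)
    m = mats["XEG_rep1"]
    nm = qc_normalize(m)
    cs = pca_reduce(nm, d=20)
    clusters = snn_cluster(cs, k=20, d_use=20, seed=0)
    tr = truth.cells.set_index("cell_id").loc[list(nm.cell_ids)]
    ab = (
        cells.set_index("cell_id")
        .loc[list(nm.cell_ids), ["Ab_CD15", "Ab_CD140"]]
        .reset_index(drop=True)
    )
    mch = flag_transgene(m, "mCherry")

    def modal_cluster(label):
        mask = (tr["true_spikein"] == label).to_numpy()
        vals, counts = np.unique(clusters[mask], return_counts=True)
        return {int(vals[np.argmax(counts)])}

    out = identify_spikeins(
        clusters,
        ab,
        mch,
        SpikeinRule("Ab_CD15", 50, modal_cluster("E14_CD15")),
        cd140_rule=SpikeinRule("Ab_CD140", 50, modal_cluster("XEN_CD140")),
        xen_derived_clusters=set(),
    )
    metrics = {}
    for key, called_label, true_label in (
        ("cd15", E14_CD15, "E14_CD15"),
        ("cd140", XEN_SPIKEIN, "XEN_CD140"),
    ):
        called = out == called_label
        is_true = (tr["true_spikein"] == true_label).to_numpy()
        metrics[f"{key}_precision"] = float((called & is_true).sum() / max(called.sum(), 1))
        metrics[f"{key}_recall"] = float((called & is_true).sum() / is_true.sum())
    return metrics


# -- determinism --------------------------------------------------------------

def _pipeline_fingerprint(seed: int) -> bytes:
    """Run a compact version of every stage and hash-relevant outputs."""
    import hashlib

    cfg = separation_config(
        seed, n_genes=300, n_atlas_cells=400, n_query_cells_per_sample=150
    )
    am, acells, _ = generate_atlas(cfg)
    mats, cells, truth = generate_query(cfg)
    anm = qc_normalize(am)
    qnms = [qc_normalize(mats[s]) for s in sorted(mats)]
    atlas, qcss = joint_atlas_space(
        anm, qnms, acells["type"].to_numpy(), acells["timepoint"].to_numpy(), d=20, k=20
    )
    assigned = pd.concat(
        [apply_rejection(map_to_atlas(q, atlas, k=20)) for q in qcss],
        ignore_index=True,
    )
    clusters = snn_cluster(qcss[0], k=15, d_use=10, seed=0)
    nm0 = qnms[0]
    types0 = (
        truth.cells.set_index("cell_id").loc[list(nm0.cell_ids), "true_type"].to_numpy()
    )
    db = pd.DataFrame({"ligand": ["g0000"], "receptor": ["g0001"]})
    lr = lr_permutation_test(nm0, types0, db, n_perm=200, seed=3)
    h = hashlib.sha256()
    h.update(np.asarray(am.values.todense()).tobytes())
    h.update(anm.values.toarray().tobytes())
    h.update(atlas.coordinates.tobytes())
    for q in qcss:
        h.update(q.coordinates.tobytes())
    h.update(assigned.to_csv(index=False).encode())
    h.update(clusters.tobytes())
    h.update(lr.to_csv(index=False).encode())
    return h.digest()


def determinism_eval(seed: int) -> dict:
    f1 = _pipeline_fingerprint(_seed(seed, 9))
    f2 = _pipeline_fingerprint(_seed(seed, 9))
    return {"byte_identical": bool(f1 == f2)}
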