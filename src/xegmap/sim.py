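"""Synthetic gastruloid/XEG-style single-cell data with known ground truth.

The generator emulates the statistical structure the downstream pipeline
assumes: negative-binomial counts over cell-type mean profiles with
log-normal per-cell size factors, two conditions ("XEG", "gastruloid") x two
replicates with a per-gene multiplicative batch effect between replicates,
spike-in subpopulations carrying hashing-antibody counts (Ab_CD15, Ab_CD140)
and transgenes (mCherry, eGFP), an atlas of typed and timestamped cells, and
optional planted differential-expression and ligand-receptor signals.

Counts for gene g in a cell of type t are NB with mean
``profile[t, g] * size_factor * batch_factor`` and a common dispersion theta
(variance mu + mu^2/theta; theta = inf gives Poisson). Every planted signal
is recorded in a GroundTruth table.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .containers import ConfigurationError, CountMatrix, GroundTruth

CONDITIONS = ("XEG", "gastruloid")
SPIKEIN_LABELS = ("ES_mCherry", "E14_CD15", "XEN_CD140")
ANTIBODIES = ("Ab_CD15", "Ab_CD140")
TRANSGENES = ("mCherry", "eGFP")


@dataclass
class CellType:
    """One simulated population: name, per-condition frequency, age profile."""

    name: str
    frequency: dict  # condition -> fraction; atlas uses the mean of the two
    age_mean: float = 7.5
    age_sd: float = 0.4
    n_markers: int = 60
    marker_log2fc: float = 3.0


def default_cell_types() -> list[CellType]:
    return [
        CellType("Epiblast", {"XEG": 0.15, "gastruloid": 0.25}, age_mean=6.7),
        CellType("NMP", {"XEG": 0.25, "gastruloid": 0.30}, age_mean=8.2),
        CellType("Spinal cord", {"XEG": 0.25, "gastruloid": 0.15}, age_mean=8.3),
        CellType("Somitic mesoderm", {"XEG": 0.20, "gastruloid": 0.25}, age_mean=8.0),
        CellType("Gut", {"XEG": 0.15, "gastruloid": 0.05}, age_mean=7.8),
    ]


@dataclass
class SimConfig:
    n_genes: int = 2000
    n_atlas_cells: int = 5000
    n_query_cells_per_sample: int = 750
    cell_types: list[CellType] = field(default_factory=default_cell_types)
    timepoints: tuple = (6.5, 7.0, 7.5, 8.0, 8.5)
    batch_effect_sd: float = 0.15
    nb_dispersion: float = 2.0
    size_factor_sd: float = 0.3
    base_expression_scale: float = 1.0  # scales all profile means (depth)
    spikein_fraction: float = 0.05  # per spike-in class, per query sample
    antibody_signal_mean: float = 200.0
    antibody_background_mean: float = 2.0
    antibody_dispersion: float = 10.0  # hashing counts are deep; tighter than genes
    de_genes: list = field(default_factory=list)  # (gene, contrast, log2fc)
    lr_pairs: list = field(default_factory=list)  # (ligand, receptor, source, target)
    seed: int = 0

    def gene_names(self) -> np.ndarray:
        names = [f"g{i:04d}" for i in range(self.n_genes)]
        return np.array(names + list(TRANSGENES), dtype=object)

    def validate(self) -> None:
        for cond in CONDITIONS:
            total = sum(t.frequency.get(cond, 0.0) for t in self.cell_types)
            if abs(total - 1.0) > 1e-9:
                raise ConfigurationError(
                    f"cell_types: frequencies for condition {cond!r} sum to {total}, not 1"
                )
        if not (self.nb_dispersion > 0):
            raise ConfigurationError("nb_dispersion: must be strictly positive")
        if self.batch_effect_sd < 0:
            raise ConfigurationError("batch_effect_sd: must be nonnegative")
        if not (0 <= self.spikein_fraction < 1):
            raise ConfigurationError("spikein_fraction: must be in [0, 1)")
        for name, val in (
            ("antibody_signal_mean", self.antibody_signal_mean),
            ("antibody_background_mean", self.antibody_background_mean),
            ("antibody_dispersion", self.antibody_dispersion),
            ("size_factor_sd", self.size_factor_sd),
        ):
            if val is None or val < 0 or (name != "size_factor_sd" and val <= 0):
                raise ConfigurationError(f"{name}: must be positive")
        universe = set(self.gene_names())
        for g, _, _ in self.de_genes:
            if g not in universe:
                raise ConfigurationError(f"de_genes: unknown gene {g!r}")
        names = {t.name for t in self.cell_types}
        for lig, rec, src, tgt in self.lr_pairs:
            for g in (lig, rec):
                if g not in universe:
                    raise ConfigurationError(f"lr_pairs: unknown gene {g!r}")
            for t in (src, tgt):
                if t not in names:
                    raise ConfigurationError(f"lr_pairs: unknown cell type {t!r}")


# -- mean profiles -----------------------------------------------------------

def type_profiles(config: SimConfig) -> pd.DataFrame:
    """Deterministic per-type mean expression profiles (types x genes).

    Shared between atlas and query so label transfer is well-posed. Each type
    upregulates its own random marker set over a common baseline; transgene
    columns are zero (populated per population at query time). Spike-in
    classes get profiles of their own.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 101]))
    genes = config.gene_names()
    base = rng.lognormal(mean=0.0, sigma=1.0, size=config.n_genes)
    base *= config.base_expression_scale
    base = np.concatenate([base, np.zeros(len(TRANSGENES))])
    rows = {}
    all_pops = [(t.name, t.n_markers, t.marker_log2fc) for t in config.cell_types]
    all_pops += [(s, 80, 4.0) for s in SPIKEIN_LABELS]
    # marker sets are disjoint across populations when the gene universe
    # allows it, so every type has its own identity genes
    demand = sum(min(n, config.n_genes) for _, n, _ in all_pops)
    pool = rng.permutation(config.n_genes)
    offset = 0
    for name, n_markers, lfc in all_pops:
        profile = base.copy()
        n_markers = min(n_markers, config.n_genes)
        if demand <= config.n_genes:
            markers = pool[offset: offset + n_markers]
            offset += n_markers
        else:
            markers = rng.choice(config.n_genes, size=n_markers, replace=False)
        # markers share a common baseline (the lognormal median) so planted
        # identities are symmetric across types
        profile[markers] = config.base_expression_scale * 2.0 ** lfc
        rows[name] = profile
    return pd.DataFrame(rows, index=genes).T


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, theta: float) -> np.ndarray:
    mu = np.maximum(mu, 0.0)
    if not np.isfinite(theta):
        return rng.poisson(mu)
    # gamma-Poisson mixture; exact NB(theta, theta/(theta+mu))
    return rng.poisson(rng.gamma(theta, mu / theta))


def _draw_cells(rng, config, type_names, profiles, n, freqs):
    """Sample types and counts for n cells; returns (counts genes x n, types)."""
    k = len(type_names)
    assignment = rng.choice(k, size=n, p=freqs)
    sf = np.exp(rng.normal(0.0, config.size_factor_sd, size=n))
    sf /= sf.mean()
    mu = profiles.loc[list(type_names)].to_numpy()[assignment].T * sf[None, :]
    counts = _nb_draw(rng, mu, config.nb_dispersion)
    return counts, np.asarray(type_names, dtype=object)[assignment], sf


# -- atlas -------------------------------------------------------------------

def generate_atlas(config: SimConfig):
    """Typed, timestamped reference cells; returns (CountMatrix, CellTable, GroundTruth)."""
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 202]))
    profiles = type_profiles(config)
    names = [t.name for t in config.cell_types]
    freqs = np.array([np.mean(list(t.frequency.values())) for t in config.cell_types])
    freqs = freqs / freqs.sum()
    counts, types, _ = _draw_cells(rng, config, names, profiles, config.n_atlas_cells, freqs)
    tp = np.asarray(config.timepoints, dtype=float)
    by_type = {t.name: t for t in config.cell_types}
    ages = np.empty(config.n_atlas_cells)
    for i, ty in enumerate(types):
        ct = by_type[ty]
        w = np.exp(-0.5 * ((tp - ct.age_mean) / ct.age_sd) ** 2)
        ages[i] = rng.choice(tp, p=w / w.sum())
    cell_ids = np.array([f"atlas_{i:05d}" for i in range(config.n_atlas_cells)], dtype=object)
    m = CountMatrix(sp.csc_matrix(counts), config.gene_names(), cell_ids)
    cells = pd.DataFrame(
        {"cell_id": cell_ids, "type": types, "timepoint": ages, "sample": "atlas"}
    )
    truth = GroundTruth(
        cells=pd.DataFrame(
            {
                "cell_id": cell_ids,
                "true_type": types,
                "true_spikein": "none",
                "true_age": ages,
                "sample": "atlas",
            }
        ),
        de=pd.DataFrame(columns=["gene", "contrast", "log2fc"]),
        lr=pd.DataFrame(columns=["ligand", "receptor", "source_type", "target_type", "log2fold"]),
    )
    return m, cells, truth


# -- query samples -----------------------------------------------------------

SAMPLES = tuple(f"{c}_rep{r}" for c in CONDITIONS for r in (1, 2))


def generate_query(config: SimConfig, profiles: pd.DataFrame | None = None):
    """Two conditions x two replicates of query cells with spike-ins.

    Returns ``(matrices, cells, truth)`` where matrices maps sample name to
    CountMatrix, cells is the per-cell metadata table across samples (with
    antibody-count columns), and truth the combined GroundTruth.
    """
    config.validate()
    if profiles is None:
        profiles = type_profiles(config)
    genes = config.gene_names()
    mcherry_col = list(genes).index("mCherry")
    egfp_col = list(genes).index("eGFP")
    theta = config.nb_dispersion

    matrices: dict[str, CountMatrix] = {}
    cell_rows = []
    truth_rows = []
    for cond in CONDITIONS:
        for rep in (1, 2):
            sample = f"{cond}_rep{rep}"
            rng = np.random.default_rng(
                np.random.SeedSequence([config.seed, 303, CONDITIONS.index(cond), rep])
            )
            n = config.n_query_cells_per_sample
            n_spike = int(round(n * config.spikein_fraction))
            spike_classes = list(SPIKEIN_LABELS) if cond == "XEG" else ["ES_mCherry", "E14_CD15"]
            n_native = n - n_spike * len(spike_classes)
            names = [t.name for t in config.cell_types]
            freqs = np.array([t.frequency[cond] for t in config.cell_types])
            counts, types, _ = _draw_cells(rng, config, names, profiles, n_native, freqs)
            spike_types = np.repeat(spike_classes, n_spike)
            if len(spike_types):
                sf = np.exp(rng.normal(0.0, config.size_factor_sd, size=len(spike_types)))
                sf /= max(sf.mean(), 1e-12)
                mu = profiles.loc[spike_types].to_numpy().T * sf[None, :]
                spike_counts = _nb_draw(rng, mu, theta)
                counts = np.concatenate([counts, spike_counts], axis=1)
            all_types = np.concatenate([types, spike_types]).astype(object)
            spikein = np.concatenate(
                [np.full(n_native, "none", dtype=object), spike_types]
            ).astype(object)

            # planted condition/type DE on the mean scale (re-draw affected genes)
            for gene, contrast, lfc in config.de_genes:
                gi = list(genes).index(gene)
                if contrast == cond or contrast in set(all_types):
                    hit = (
                        np.ones(n, dtype=bool)
                        if contrast == cond
                        else (all_types == contrast)
                    )
                    base_rows = profiles.loc[all_types[hit], gene].to_numpy()
                    mu_g = base_rows * (2.0 ** lfc - 1.0)
                    counts[gi, hit] += _nb_draw(rng, mu_g, theta)

            # transgenes: mCherry in ES spike-ins, eGFP in XEN spike-ins
            counts[mcherry_col, :] = 0
            counts[egfp_col, :] = 0
            es = spikein == "ES_mCherry"
            xen = spikein == "XEN_CD140"
            counts[mcherry_col, es] = _nb_draw(rng, np.full(es.sum(), 20.0), theta)
            counts[egfp_col, xen] = _nb_draw(rng, np.full(xen.sum(), 20.0), theta)

            # replicate batch effect: per-gene log-normal factor, replicate 2 only
            if config.batch_effect_sd > 0 and rep == 2:
                brng = np.random.default_rng(
                    np.random.SeedSequence([config.seed, 404, CONDITIONS.index(cond)])
                )
                factor = np.exp(brng.normal(0.0, config.batch_effect_sd, size=len(genes)))
                counts = _nb_draw(rng, counts * factor[:, None], np.inf)

            # hashing antibodies: NB signal in the tagged class, background else
            ab = {}
            for ab_name, tag in (("Ab_CD15", "E14_CD15"), ("Ab_CD140", "XEN_CD140")):
                mean = np.where(
                    spikein == tag, config.antibody_signal_mean, config.antibody_background_mean
                )
                ab[ab_name] = _nb_draw(rng, mean, config.antibody_dispersion)

            cell_ids = np.array(
                [f"{sample}_c{i:05d}" for i in range(n)], dtype=object
            )
            matrices[sample] = CountMatrix(sp.csc_matrix(counts), genes, cell_ids)
            cell_rows.append(
                pd.DataFrame(
                    {
                        "cell_id": cell_ids,
                        "sample": sample,
                        "condition": cond,
                        "replicate": rep,
                        "Ab_CD15": ab["Ab_CD15"],
                        "Ab_CD140": ab["Ab_CD140"],
                    }
                )
            )
            truth_rows.append(
                pd.DataFrame(
                    {
                        "cell_id": cell_ids,
                        "true_type": all_types,
                        "true_spikein": spikein,
                        "true_age": np.nan,
                        "sample": sample,
                    }
                )
            )

    cells = pd.concat(cell_rows, ignore_index=True)
    truth = GroundTruth(
        cells=pd.concat(truth_rows, ignore_index=True),
        de=pd.DataFrame(config.de_genes, columns=["gene", "contrast", "log2fc"]),
        lr=pd.DataFrame(
            config.lr_pairs, columns=["ligand", "receptor", "source_type", "target_type"]
        ).assign(log2fold=np.nan),
    )
    return matrices, cells, truth


def generate_ambiguous_cells(
    config: SimConfig,
    n: int,
    type_a: str,
    type_b: str,
    seed: int | None = None,
):
    """Cells drawn from a 50/50 mixture of two type profiles.

    Such cells sit between the two populations in expression space, so a
    well-behaved label-transfer step should reject them on confidence.
    Returns (CountMatrix, truth cell table with true_type 'ambiguous').
    """
    config.validate()
    profiles = type_profiles(config)
    for t in (type_a, type_b):
        if t not in profiles.index:
            raise ConfigurationError(f"unknown cell type {t!r}")
    rng = np.random.default_rng(
        np.random.SeedSequence([config.seed if seed is None else seed, 606])
    )
    sf = np.exp(rng.normal(0.0, config.size_factor_sd, size=n))
    sf /= sf.mean()
    mu = 0.5 * (profiles.loc[type_a].to_numpy() + profiles.loc[type_b].to_numpy())
    counts = _nb_draw(rng, mu[:, None] * sf[None, :], config.nb_dispersion)
    cell_ids = np.array([f"ambig_c{i:05d}" for i in range(n)], dtype=object)
    m = CountMatrix(sp.csc_matrix(counts), config.gene_names(), cell_ids)
    truth = pd.DataFrame(
        {
            "cell_id": cell_ids,
            "true_type": "ambiguous",
            "true_spikein": "none",
            "true_age": np.nan,
            "sample": "ambiguous",
        }
    )
    return m, truth


def plant_lr_signal(
    m: CountMatrix,
    truth: GroundTruth,
    config: SimConfig,
    fold: float = 8.0,
    seed: int | None = None,
) -> CountMatrix:
    """Elevate ligand means in source cells and receptor means in target cells.

    Adds NB(mu * (fold - 1), theta) counts on top of the existing draws so
    the mean is multiplied by ``fold`` exactly while counts stay integer;
    fold = 1 or an empty pair list leaves the matrix unchanged.
    """
    config.validate()
    if not config.lr_pairs or fold == 1.0:
        return m
    type_names = {t.name for t in config.cell_types}
    rng = np.random.default_rng(
        np.random.SeedSequence([config.seed if seed is None else seed, 505])
    )
    counts = np.asarray(m.values.todense()).astype(np.int64)
    truth_types = truth.cells.set_index("cell_id").loc[list(m.cell_ids), "true_type"]
    profiles = type_profiles(config)
    for lig, rec, src, tgt in config.lr_pairs:
        for t in (src, tgt):
            if t not in type_names:
                raise ConfigurationError(f"lr_pairs: unknown cell type {t!r}")
        for gene, ctype in ((lig, src), (rec, tgt)):
            gi = m.gene_index([gene])[0]
            hit = (truth_types == ctype).to_numpy()
            if hit.any():
                mu = profiles.loc[ctype, gene] * (fold - 1.0)
                counts[gi, hit] += _nb_draw(
                    rng, np.full(hit.sum(), mu), config.nb_dispersion
                )
    out = CountMatrix(sp.csc_matrix(counts), m.gene_ids, m.cell_ids)
    truth.lr["log2fold"] = np.log2(fold)
    return out
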