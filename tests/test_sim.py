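"""Generator contracts: determinism, integer counts, truth coverage, and the
statistical structure downstream stages rely on."""
import numpy as np
import pytest
import scipy.stats

from xegmap.containers import ConfigurationError
from xegmap.sim import (
    SimConfig,
    generate_ambiguous_cells,
    generate_atlas,
    generate_query,
    plant_lr_signal,
    type_profiles,
)


def dense(m):
    return np.asarray(m.values.todense())


class TestValidation:
    def test_frequencies_must_sum_to_one(self, small_config):
        cfg = SimConfig(seed=1)
        cfg.cell_types[0].frequency["XEG"] += 0.1
        with pytest.raises(ConfigurationError, match="XEG"):
            cfg.validate()

    def test_nonpositive_dispersion_rejected(self):
        with pytest.raises(ConfigurationError, match="nb_dispersion"):
            SimConfig(nb_dispersion=0.0).validate()

    def test_spikein_fraction_at_one_rejected(self):
        with pytest.raises(ConfigurationError, match="spikein_fraction"):
            SimConfig(spikein_fraction=1.0).validate()

    def test_unknown_planted_gene_rejected(self):
        with pytest.raises(ConfigurationError, match="de_genes"):
            SimConfig(de_genes=[("nope", "XEG", 1.0)]).validate()


class TestAtlas:
    def test_deterministic_given_seed(self, small_config):
        m1, c1, t1 = generate_atlas(small_config)
        m2, c2, t2 = generate_atlas(small_config)
        assert (m1.values != m2.values).nnz == 0
        assert c1.equals(c2) and t1.cells.equals(t2.cells)

    def test_counts_nonnegative_integers(self, small_config):
        m, _, _ = generate_atlas(small_config)
        data = m.values.data
        assert np.all(data >= 0) and np.all(data == np.round(data))

    def test_truth_covers_every_cell_once(self, small_config):
        m, _, truth = generate_atlas(small_config)
        assert sorted(truth.cells["cell_id"]) == sorted(m.cell_ids)

    def test_every_cell_typed_and_timestamped(self, small_config):
        _, cells, _ = generate_atlas(small_config)
        assert cells["type"].notna().all()
        assert set(cells["timepoint"]) <= set(small_config.timepoints)

    def test_poisson_limit_recovers_profile_means(self):
        # theta -> inf: per-type sample mean approaches profile mean (LLN)
        cfg = SimConfig(n_genes=100, n_atlas_cells=2000, nb_dispersion=np.inf,
                        size_factor_sd=0.0, seed=3)
        m, cells, _ = generate_atlas(cfg)
        profiles = type_profiles(cfg)
        x = dense(m)
        for t in profiles.index[:2]:
            mask = (cells["type"] == t).to_numpy()
            if mask.sum() < 200:
                continue
            mu = profiles.loc[t].to_numpy()
            big = mu > 5.0
            rel = np.abs(x[:, mask].mean(axis=1)[big] - mu[big]) / mu[big]
            assert np.median(rel) < 0.05

    def test_type_counts_within_binomial_bounds(self):
        # oracle: empirical counts ~ Binomial(n, p), allow 3 SDs
        from xegmap.sim import CellType

        types = [
            CellType("A", {"XEG": 0.5, "gastruloid": 0.5}),
            CellType("B", {"XEG": 0.3, "gastruloid": 0.3}),
            CellType("C", {"XEG": 0.2, "gastruloid": 0.2}),
        ]
        cfg = SimConfig(n_genes=50, n_atlas_cells=5000, cell_types=types, seed=11)
        _, cells, _ = generate_atlas(cfg)
        counts = cells["type"].value_counts()
        for name, p in (("A", 0.5), ("B", 0.3), ("C", 0.2)):
            sd = np.sqrt(5000 * p * (1 - p))
            assert abs(counts[name] - 5000 * p) <= 3 * sd


class TestQuery:
    def test_two_conditions_two_replicates(self, small_config):
        mats, cells, _ = generate_query(small_config)
        assert set(mats) == {
            "XEG_rep1", "XEG_rep2", "gastruloid_rep1", "gastruloid_rep2"
        }
        assert set(cells["replicate"]) == {1, 2}

    def test_zero_spikein_fraction_gives_no_spikeins(self, small_config):
        cfg = SimConfig(n_genes=200, n_atlas_cells=100,
                        n_query_cells_per_sample=100, spikein_fraction=0.0, seed=2)
        _, _, truth = generate_query(cfg)
        assert (truth.cells["true_spikein"] == "none").all()

    def test_transgenes_restricted_to_designated_populations(self, small_config):
        mats, _, truth = generate_query(small_config)
        for sample, m in mats.items():
            sub = truth.cells[truth.cells["sample"] == sample]
            mch = dense(m.subset_genes(m.gene_index(["mCherry"])))[0]
            positive = sub["true_spikein"].to_numpy() == "ES_mCherry"
            assert np.all(mch[~positive] == 0)

    def test_no_batch_effect_means_matched_library_sizes(self):
        # KS test on library sizes between replicates, non-significant at
        # alpha=0.01 in >=95% of seeds when batch_effect_sd=0
        hits = 0
        n_seeds = 40
        for seed in range(n_seeds):
            cfg = SimConfig(n_genes=150, n_atlas_cells=50,
                            n_query_cells_per_sample=150, batch_effect_sd=0.0,
                            spikein_fraction=0.0, seed=seed)
            mats, _, _ = generate_query(cfg)
            ks = scipy.stats.ks_2samp(
                mats["XEG_rep1"].cell_totals(), mats["XEG_rep2"].cell_totals()
            )
            hits += ks.pvalue > 0.01
        assert hits / n_seeds >= 0.95

    def test_batch_effect_shifts_replicate_two(self):
        cfg = SimConfig(n_genes=300, n_atlas_cells=50,
                        n_query_cells_per_sample=300, batch_effect_sd=0.5,
                        spikein_fraction=0.0, seed=4)
        mats, _, _ = generate_query(cfg)
        x1 = dense(mats["XEG_rep1"]).mean(axis=1)
        x2 = dense(mats["XEG_rep2"]).mean(axis=1)
        ratio = np.log((x2 + 0.1) / (x1 + 0.1))
        assert ratio.std() > 0.2  # per-gene shifts present

    def test_antibody_separation_at_threshold(self):
        # NB tail: signal mean 200 vs background 2 split cleanly at 50
        cfg = SimConfig(n_genes=100, n_atlas_cells=50,
                        n_query_cells_per_sample=400, antibody_signal_mean=200.0,
                        antibody_background_mean=2.0, seed=6)
        _, cells, truth = generate_query(cfg)
        merged = cells.merge(truth.cells[["cell_id", "true_spikein"]], on="cell_id")
        called = merged["Ab_CD15"] > 50
        is_cd15 = merged["true_spikein"] == "E14_CD15"
        accuracy = (called == is_cd15).mean()
        assert accuracy >= 0.99


class TestPlantLR:
    def test_empty_pairs_identity(self, small_config):
        mats, _, truth = generate_query(small_config)
        m = mats["XEG_rep1"]
        out = plant_lr_signal(m, truth, small_config, fold=8.0)
        assert (out.values != m.values).nnz == 0

    def test_fold_one_identity(self):
        cfg = SimConfig(n_genes=200, n_atlas_cells=50, n_query_cells_per_sample=100,
                        lr_pairs=[("g0001", "g0002", "NMP", "Gut")], seed=9)
        mats, _, truth = generate_query(cfg)
        m = mats["XEG_rep1"]
        out = plant_lr_signal(m, truth, cfg, fold=1.0)
        assert (out.values != m.values).nnz == 0

    def test_planted_fold_elevates_means(self):
        cfg = SimConfig(n_genes=200, n_atlas_cells=50, n_query_cells_per_sample=400,
                        lr_pairs=[("g0001", "g0002", "NMP", "Gut")],
                        spikein_fraction=0.0, seed=9)
        mats, _, truth = generate_query(cfg)
        m = mats["XEG_rep1"]
        out = plant_lr_signal(m, truth, cfg, fold=8.0)
        types = truth.cells.set_index("cell_id").loc[list(m.cell_ids), "true_type"]
        src = (types == "NMP").to_numpy()
        gi = m.gene_index(["g0001"])[0]
        before = dense(m)[gi, src].mean()
        after = dense(out)[gi, src].mean()
        assert after > 4 * max(before, 0.05)


class TestAmbiguous:
    def test_unknown_type_rejected(self, small_config):
        with pytest.raises(ConfigurationError):
            generate_ambiguous_cells(small_config, 10, "NMP", "nonexistent")

    def test_truth_labels_ambiguous(self, small_config):
        m, truth = generate_ambiguous_cells(small_config, 25, "NMP", "Gut")
        assert m.n_cells == 25
        assert (truth["true_type"] == "ambiguous").all()
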