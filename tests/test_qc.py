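"""Filtering, normalization, HVG selection and signature scoring."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from xegmap.containers import EmptyOutputError
from xegmap.qc import (
    filter_cells,
    filter_genes,
    hvg_per_replicate,
    invert_normalize,
    normalize_log,
    select_hvg,
    signature_score,
    size_factors,
)

from conftest import make_counts, make_nm


class TestFilterCells:
    def test_threshold_boundary_inclusive(self):
        m = make_counts([[1000, 1300, 2000]])
        out = filter_cells(m, 1300)
        assert out.n_cells == 2 and list(out.cell_ids) == ["c1", "c2"]

    def test_zero_threshold_identity(self):
        m = make_counts([[5, 0, 3], [1, 2, 0]])
        out = filter_cells(m, 0)
        assert list(out.cell_ids) == list(m.cell_ids)

    def test_planted_low_count_cells_removed(self, rng):
        counts = rng.poisson(10.0, size=(50, 200))
        low = rng.choice(200, size=40, replace=False)
        counts[:, low] = 0
        counts[0, low] = 1  # low but nonzero
        m = make_counts(counts)
        totals = counts.sum(axis=0)  # independent summation oracle
        out = filter_cells(m, 100)
        expect = m.cell_ids[totals >= 100]
        assert list(out.cell_ids) == list(expect)

    def test_empty_result_raises(self):
        with pytest.raises(EmptyOutputError):
            filter_cells(make_counts([[1, 2]]), 100)

    def test_idempotent(self, rng):
        m = make_counts(rng.poisson(5.0, size=(30, 80)))
        once = filter_cells(m, 120)
        twice = filter_cells(once, 120)
        assert (once.values != twice.values).nnz == 0


class TestFilterGenes:
    def test_gene_in_one_cell_removed_in_two_kept(self):
        m = make_counts([[5, 0, 0], [3, 7, 0], [1, 1, 1]])
        out = filter_genes(m, min_cells=2)
        assert list(out.gene_ids) == ["g1", "g2"]

    def test_brute_force_oracle(self, rng):
        counts = (rng.random((60, 40)) < 0.05) * rng.poisson(3, size=(60, 40))
        m = make_counts(counts)
        surviving = {
            f"g{i}" for i in range(60) if int((counts[i] > 0).sum()) >= 2
        }
        out = filter_genes(m, min_cells=2)
        assert set(out.gene_ids) == surviving

    def test_commutes_with_cell_reordering(self, rng):
        counts = rng.poisson(0.5, size=(40, 30))
        m = make_counts(counts)
        perm = rng.permutation(30)
        out1 = set(filter_genes(m).gene_ids)
        out2 = set(filter_genes(m.subset_cells(perm)).gene_ids)
        assert out1 == out2


class TestNormalize:
    def test_identical_totals_give_unit_factors(self):
        m = make_counts([[2, 2], [3, 3]])
        nm = normalize_log(m)
        assert np.allclose(nm.size_factors, 1.0)

    def test_zero_count_maps_to_zero(self):
        nm = normalize_log(make_counts([[0, 4], [4, 0]]))
        x = nm.dense()
        assert x[0, 0] == 0.0 and x[1, 1] == 0.0

    def test_three_by_three_toy_hand_computed(self):
        counts = np.array([[1, 2, 4], [1, 2, 4], [2, 4, 8]])
        nm = normalize_log(make_counts(counts))
        totals = counts.sum(axis=0)  # 4, 8, 16
        sf = totals / totals.mean()
        expect = np.log2(counts / sf + 1.0)
        assert np.allclose(nm.dense(), expect)
        # doubling one cell's counts leaves other cells' values unchanged
        counts2 = counts.copy()
        counts2[:, 2] *= 2
        nm2 = normalize_log(make_counts(counts2))
        sf2 = counts2.sum(axis=0) / counts2.sum(axis=0).mean()
        assert np.allclose(nm2.dense()[:, :2], np.log2(counts[:, :2] / sf2[:2] + 1))

    def test_round_trip_recovers_counts(self, rng):
        counts = rng.poisson(3.0, size=(30, 20)) + 1
        m = make_counts(counts)
        nm = normalize_log(m)
        assert np.allclose(invert_normalize(nm), counts, atol=1e-6)

    def test_all_zero_cell_named_in_error(self):
        m = make_counts([[1, 0], [2, 0]])
        with pytest.raises(ValueError, match="c1"):
            normalize_log(m)

    def test_pooled_factors_recover_true_scaling(self, rng):
        # cells differing only by a known scale: pooled factors track it
        base = rng.poisson(20.0, size=(100,))
        scale = rng.uniform(0.5, 2.0, size=60)
        counts = rng.poisson(base[:, None] * scale[None, :])
        m = make_counts(counts)
        sf = size_factors(m, method="pooled")
        true = scale / scale.mean()
        assert np.corrcoef(sf, true)[0, 1] > 0.95


class TestHVG:
    @staticmethod
    def _poisson_nm(rng, n_genes=500, n_cells=400):
        mu = rng.lognormal(1.0, 0.7, n_genes)
        counts = rng.poisson(mu[:, None], size=(n_genes, n_cells))
        return normalize_log(filter_genes(make_counts(counts)))

    def test_poisson_null_pvalues_roughly_uniform(self):
        rng = np.random.default_rng(21)
        nm = self._poisson_nm(rng)
        res = hvg_per_replicate(nm)
        p = res.table["pvalue"].dropna()
        frac = (p < 0.05).mean()
        sd = np.sqrt(0.05 * 0.95 / len(p))
        assert abs(frac - 0.05) <= 4 * sd + 0.02  # trend fit absorbs some slack

    def test_planted_high_dispersion_genes_selected(self):
        rng = np.random.default_rng(22)
        n_genes, n_cells = 2000, 300
        mu = rng.lognormal(1.5, 0.5, n_genes)
        counts = rng.poisson(mu[:, None], size=(n_genes, n_cells)).astype(float)
        hot = rng.choice(n_genes, 100, replace=False)
        theta = 0.5  # strong overdispersion
        counts[hot] = rng.poisson(rng.gamma(theta, mu[hot, None] / theta, (100, n_cells)))
        m = make_counts(counts.astype(int))
        nm = normalize_log(m)
        res = hvg_per_replicate(nm, top_frac=0.10)
        hot_names = {f"g{i}" for i in hot}
        got = set(res.selected_genes) & hot_names
        assert len(got) >= 90

    def test_excluded_gene_never_selected(self, rng):
        counts = rng.poisson(5.0, size=(200, 100))
        counts[0] = rng.poisson(rng.gamma(0.2, 25.0 / 0.2, 100))  # extreme CV2
        nm = normalize_log(make_counts(counts))
        res = hvg_per_replicate(nm, exclude={"g0"})
        row = res.table.set_index("gene").loc["g0"]
        assert not row["selected"]

    def test_union_across_replicates(self, rng):
        a = normalize_log(make_counts(rng.poisson(5.0, size=(300, 120))))
        b = normalize_log(make_counts(rng.poisson(5.0, size=(300, 120))))
        union = set(select_hvg([a, b]))
        sa = set(hvg_per_replicate(a).selected_genes)
        sb = set(hvg_per_replicate(b).selected_genes)
        assert union == sa | sb

    def test_too_few_testable_genes_raises(self):
        m = make_counts(np.ones((20, 60), dtype=int))
        with pytest.raises(ValueError, match="testable"):
            hvg_per_replicate(normalize_log(m))


class TestSignatureScore:
    def test_single_gene_equals_zscore(self):
        nm = make_nm([[1.0, 2.0, 3.0, 6.0], [0, 0, 0, 0], [1, 1, 2, 2]])
        score = signature_score(nm, ["g0"])
        x = np.array([1.0, 2.0, 3.0, 6.0])
        assert np.allclose(score, (x - x.mean()) / x.std())

    def test_scores_mean_zero(self, rng):
        nm = make_nm(rng.lognormal(0, 1, size=(20, 50)))
        score = signature_score(nm, [f"g{i}" for i in range(10)])
        assert abs(score.mean()) < 1e-9

    def test_hand_computed_three_by_four(self):
        x = np.array([[1.0, 2, 3, 4], [2, 2, 4, 4], [0, 1, 0, 1]])
        nm = make_nm(x)
        z = (x - x.mean(axis=1, keepdims=True)) / x.std(axis=1, keepdims=True)
        assert np.allclose(signature_score(nm, ["g0", "g1", "g2"]), z.mean(axis=0))

    def test_zero_variance_genes_dropped(self):
        nm = make_nm([[1.0, 2, 3, 4], [5, 5, 5, 5]])
        score_with = signature_score(nm, ["g0", "g1"])
        score_alone = signature_score(nm, ["g0"])
        assert np.allclose(score_with, score_alone)

    def test_absent_genes_error(self):
        nm = make_nm([[1.0, 2.0]])
        with pytest.raises(ValueError):
            signature_score(nm, ["missing"])


@settings(max_examples=25, deadline=None)
@given(st.integers(min_value=0, max_value=40))
def test_filter_cells_threshold_monotone(min_count):
    """Property: raising the threshold never keeps more cells."""
    rng = np.random.default_rng(99)
    m = make_counts(rng.poisson(2.0, size=(10, 30)))
    try:
        kept_lo = filter_cells(m, min_count).n_cells
    except EmptyOutputError:
        kept_lo = 0
    try:
        kept_hi = filter_cells(m, min_count + 5).n_cells
    except EmptyOutputError:
        kept_hi = 0
    assert kept_hi <= kept_lo
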