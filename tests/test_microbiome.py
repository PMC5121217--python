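"""OTU analytics: filters, diversity, clustering, ordination, Pearson gate."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform

from mccflux.microbiome import (
    OtuTable,
    abundant_otus,
    bray_curtis,
    bray_curtis_cluster,
    correlate_otus,
    critical_pearson_r,
    pcoa,
    relative_abundance,
    shannon_index,
    shannon_per_sample,
)


def make_table(counts, sample_ids=None, otu_ids=None, productivity=None):
    counts = np.asarray(counts)
    n, m = counts.shape
    sample_ids = sample_ids or [f"S{i}" for i in range(n)]
    otu_ids = otu_ids or [f"O{j}" for j in range(m)]
    metadata = None
    if productivity is not None:
        metadata = pd.DataFrame(
            {"day": np.arange(n, dtype=float), "productivity": productivity},
            index=sample_ids,
        )
    return OtuTable(pd.DataFrame(counts, index=sample_ids, columns=otu_ids), metadata)


class TestTableBasics:
    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            make_table([[1, -1]])

    def test_singleton_removal(self):
        table = make_table([[1, 5, 0], [0, 5, 3]])
        kept = table.remove_singletons()
        assert kept.otu_ids == ["O1", "O2"]

    def test_relative_abundance_rows_sum_to_one(self):
        table = make_table([[10, 30, 60], [1, 0, 0]])
        rel = relative_abundance(table)
        assert rel.iloc[0].tolist() == pytest.approx([0.1, 0.3, 0.6])
        assert rel.sum(axis=1).tolist() == pytest.approx([1.0, 1.0], abs=1e-12)

    def test_empty_sample_rejected(self):
        table = make_table([[0, 0], [1, 1]])
        with pytest.raises(ValueError, match="zero total"):
            relative_abundance(table)


class TestAbundanceFilter:
    def test_planted_abundant_set(self):
        # 5 OTUs at >= 1% in at least one sample, 3 permanently rare
        counts = np.ones((4, 8), dtype=int)  # each 1 count
        counts[:, :5] = 200  # abundant block
        counts[:, 5:] = 1  # 1/~1000 < 1%
        table = make_table(counts)
        assert abundant_otus(table, threshold=0.01) == [f"O{j}" for j in range(5)]

    def test_threshold_zero_keeps_all_nonzero(self):
        table = make_table([[5, 0, 1]])
        assert abundant_otus(table, threshold=0.0) == ["O0", "O2"]

    def test_threshold_one_requires_monopoly(self):
        table = make_table([[10, 0], [5, 5]])
        assert abundant_otus(table, threshold=1.0) == ["O0"]

    def test_strict_vs_inclusive_boundary(self):
        table = make_table([[1, 99]])  # O0 exactly 1%
        assert "O0" in abundant_otus(table, threshold=0.01, strict=False)
        assert "O0" not in abundant_otus(table, threshold=0.01, strict=True)


class TestShannon:
    def test_point_mass_is_zero(self):
        assert shannon_index([1.0, 0.0, 0.0]) == 0.0

    def test_uniform_sixteen(self):
        assert shannon_index([1 / 16] * 16) == pytest.approx(4.0)

    def test_natural_log_base(self):
        assert shannon_index([0.5, 0.5], base=math.e) == pytest.approx(math.log(2))

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.floats(0.01, 1.0), min_size=2, max_size=20))
    def test_uniform_maximizes_entropy(self, weights):
        p = np.array(weights) / np.sum(weights)
        s = len(p)
        assert shannon_index(p) <= math.log2(s) + 1e-9

    def test_per_sample(self):
        table = make_table([[8, 8], [16, 0]])
        out = shannon_per_sample(table)
        assert out.tolist() == pytest.approx([1.0, 0.0])


class TestCriticalPearson:
    def test_published_threshold_at_n7(self):
        assert round(critical_pearson_r(7, alpha=0.05), 3) == 0.754

    def test_n3(self):
        assert critical_pearson_r(3, alpha=0.05) == pytest.approx(0.997, abs=5e-4)

    def test_monotone_in_n_and_alpha(self):
        values = [critical_pearson_r(n) for n in range(3, 200, 7)]
        assert all(a > b for a, b in zip(values, values[1:]))
        assert critical_pearson_r(10, alpha=0.01) > critical_pearson_r(10, alpha=0.05)
        assert critical_pearson_r(10_000) < 0.03  # -> 0 as n grows

    def test_requires_three_samples(self):
        with pytest.raises(ValueError):
            critical_pearson_r(2)


class TestCorrelateOtus:
    def test_perfectly_tracking_otu_flagged(self):
        prod = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0])
        counts = np.column_stack([100 * prod, 1000 - 100 * prod]).astype(int)
        table = make_table(counts, productivity=prod)
        out = correlate_otus(table).set_index("otu_id")
        assert out.loc["O0", "r"] == pytest.approx(1.0)
        assert bool(out.loc["O0", "significant"])
        # the complementary OTU is perfectly anti-correlated: never flagged
        assert not bool(out.loc["O1", "significant"])

    def test_constant_otu_undefined(self):
        prod = np.arange(1.0, 8.0)
        # constant totals so the first OTU's relative abundance is constant
        counts = np.column_stack(
            [np.full(7, 500), 250 + 10 * np.arange(7), 250 - 10 * np.arange(7)]
        ).astype(int)
        table = make_table(counts, productivity=prod)
        out = correlate_otus(table).set_index("otu_id")
        assert bool(out.loc["O0", "undefined"])
        assert not bool(out.loc["O0", "significant"])

    def test_gate_uses_positive_direction_only(self):
        prod = np.arange(1.0, 8.0)
        dec = (1000 - 100 * prod).astype(int)
        inc = (100 * prod).astype(int)
        table = make_table(np.column_stack([dec, inc]), productivity=prod)
        out = correlate_otus(table).set_index("otu_id")
        assert out.loc["O0", "r"] < -0.754
        assert not bool(out.loc["O0", "significant"])  # strong but negative

    def test_requires_three_productivity_samples(self):
        table = make_table([[1, 2], [3, 4]], productivity=[1.0, 2.0])
        with pytest.raises(ValueError):
            correlate_otus(table)


class TestBrayCurtis:
    def test_hand_example(self):
        # proportions (1,0) / (0,1) / (0.5,0.5)
        table = make_table([[10, 0], [0, 10], [5, 5]])
        dm, z, order = bray_curtis_cluster(table)
        assert dm.loc["S0", "S1"] == pytest.approx(1.0)
        assert dm.loc["S0", "S2"] == pytest.approx(0.5)
        assert dm.loc["S1", "S2"] == pytest.approx(0.5)
        # first merge at height 0.5, final UPGMA merge at (1 + 0.5)/2
        assert z[0, 2] == pytest.approx(0.5)
        assert z[1, 2] == pytest.approx(0.75)
        assert len(order) == 3

    def test_identical_and_disjoint_samples(self):
        table = make_table([[3, 3, 0], [6, 6, 0], [0, 0, 9]])
        dm = bray_curtis(table)
        assert dm.loc["S0", "S1"] == pytest.approx(0.0, abs=1e-12)
        assert dm.loc["S0", "S2"] == pytest.approx(1.0)

    @settings(derandomize=True, max_examples=30)
    @given(
        st.lists(
            st.lists(st.integers(0, 50), min_size=4, max_size=4),
            min_size=3,
            max_size=6,
        ).filter(lambda rows: all(sum(r) > 0 for r in rows))
    )
    def test_bounded_symmetric_semimetric(self, rows):
        dm = bray_curtis(make_table(rows)).to_numpy()
        assert np.allclose(dm, dm.T)
        assert np.allclose(np.diag(dm), 0.0)
        assert ((dm >= -1e-12) & (dm <= 1 + 1e-12)).all()

    def test_otu_axis_ordering_is_deterministic(self):
        rng = np.random.default_rng(5)
        counts = rng.integers(0, 100, size=(6, 10))
        counts[:, 0] += 1  # avoid empty samples
        t = make_table(counts)
        _, _, order1 = bray_curtis_cluster(t, axis="otus")
        _, _, order2 = bray_curtis_cluster(t, axis="otus")
        assert order1 == order2
        assert set(order1) == set(t.otu_ids)


class TestPCoA:
    def test_euclidean_configuration_recovered(self):
        rng = np.random.default_rng(3)
        pts = rng.normal(size=(6, 2))
        d = squareform(pdist(pts))
        res = pcoa(pd.DataFrame(d))
        coords = res.coordinates.to_numpy()[:, :2]
        d_rec = squareform(pdist(coords))
        assert np.allclose(d_rec, d, atol=1e-9)
        assert not res.has_negative_eigenvalues

    def test_two_points_single_axis(self):
        d = pd.DataFrame([[0.0, 2.0], [2.0, 0.0]])
        res = pcoa(d)
        assert res.proportion_explained.iloc[0] == pytest.approx(1.0)

    def test_equilateral_triangle_equal_eigenvalues(self):
        d = pd.DataFrame(1.0 - np.eye(3))
        res = pcoa(d)
        ev = np.sort(res.eigvals.to_numpy())[::-1]
        # centered Gram matrix of an equilateral triangle: two eigenvalues d^2/2
        assert ev[0] == pytest.approx(0.5, abs=1e-9)
        assert ev[1] == pytest.approx(0.5, abs=1e-9)
        assert ev[2] == pytest.approx(0.0, abs=1e-9)

    def test_variance_fractions_nonincreasing(self):
        rng = np.random.default_rng(9)
        pts = rng.normal(size=(8, 3))
        res = pcoa(pd.DataFrame(squareform(pdist(pts))))
        pe = res.proportion_explained.to_numpy()
        assert all(a >= b - 1e-12 for a, b in zip(pe, pe[1:]))

    def test_asymmetric_matrix_rejected(self):
        with pytest.raises(ValueError):
            pcoa(pd.DataFrame([[0.0, 1.0], [2.0, 0.0]]))


@settings(derandomize=True, max_examples=50)
@given(
    x=st.lists(st.floats(-10, 10), min_size=5, max_size=5).filter(lambda v: np.std(v) > 1e-6),
    a=st.floats(0.1, 10),
    b=st.floats(-5, 5),
)
def test_pearson_affine_invariance(x, a, b):
    from scipy.stats import pearsonr

    y = np.arange(5.0)
    r1, _ = pearsonr(np.array(x), y)
    r2, _ = pearsonr(a * np.array(x) + b, y)
    assert r1 == pytest.approx(r2, abs=1e-9)
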