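"""MSN construction: z-scoring, region-pair correlation, thresholding, strength."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from msnkit import (
    MSNMatrix,
    build_msn,
    graph_strength,
    nodal_strength,
    threshold_density,
    zscore_features,
)

from conftest import make_feature_table


def brute_force_pearson(x, y):
    """Independent Pearson oracle from the covariance formula."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    xm, ym = x - x.mean(), y - y.mean()
    return float((xm * ym).sum() / np.sqrt((xm**2).sum() * (ym**2).sum()))


class TestZscore:
    def test_columns_standardized(self, table_4x5):
        z = zscore_features(make_feature_table(table_4x5))
        assert np.all(np.abs(z.mean(axis=0)) < 1e-12)
        assert np.allclose(z.std(axis=0, ddof=1), 1.0)

    def test_closed_form_three_regions(self):
        z = zscore_features(np.array([[1.0], [2.0], [3.0]]))
        assert np.allclose(z.ravel(), [-1.0, 0.0, 1.0])

    def test_constant_feature_rejected(self):
        t = make_feature_table(np.column_stack([np.ones(4), np.arange(4.0)]))
        with pytest.raises(ValueError, match="F0"):
            zscore_features(t)


class TestBuildMSN:
    def test_identical_regions_give_unit_edge(self):
        mat = np.array([[1.0, 5.0, 2.0, 0.0], [1.0, 5.0, 2.0, 0.0], [3.0, 1.0, 9.0, 4.0]])
        msn = build_msn(mat)  # regions 0 and 1 have identical feature vectors
        assert msn.weights[0, 1] == pytest.approx(1.0)

    def test_affine_negative_region_gives_minus_one(self):
        base = np.array([0.4, -1.2, 0.8, 1.5, -0.5])
        mat = np.vstack([base, -base + 0.7, np.array([2.0, 0.1, -0.3, 0.9, 1.1])])
        msn = build_msn(mat)
        assert msn.weights[0, 1] == pytest.approx(-1.0)

    def test_edges_match_brute_force_oracle(self, table_4x5):
        z = zscore_features(make_feature_table(table_4x5))
        msn = build_msn(z)
        for i, j in itertools.combinations(range(4), 2):
            assert msn.weights[i, j] == pytest.approx(brute_force_pearson(z[i], z[j]), abs=1e-12)
        assert np.allclose(np.diag(msn.weights), 0.0)
        assert np.allclose(msn.weights, msn.weights.T)

    def test_scale_invariance_of_msn(self, table_4x5):
        """Affine rescaling of a raw feature column cannot change the network."""
        base = build_msn(zscore_features(make_feature_table(table_4x5))).weights
        scaled = table_4x5.copy()
        scaled[:, 2] = scaled[:, 2] * 1e6 + 300.0
        rescaled = build_msn(zscore_features(make_feature_table(scaled))).weights
        assert np.allclose(base, rescaled, atol=1e-10)

    def test_too_few_features_rejected(self):
        with pytest.raises(ValueError, match="3 features"):
            build_msn(np.random.default_rng(0).normal(size=(4, 2)))

    def test_constant_region_vector_rejected(self):
        z = np.array([[0.0, 0.0, 0.0], [1.0, -2.0, 0.5], [0.3, 0.9, -1.0]])
        with pytest.raises(ValueError, match="region 0"):
            build_msn(z)


class TestThreshold:
    def test_edge_count_at_40_percent_of_68_nodes(self):
        rng = np.random.default_rng(0)
        w = rng.normal(size=(68, 68))
        w = (w + w.T) / 2
        np.fill_diagonal(w, 0)
        t = threshold_density(w, 0.40)
        assert t.k_edges == 911  # round(0.4 * 2278)
        assert int(t.binary.sum()) == 2 * 911

    def test_full_density_is_identity(self, matrix_5node_a):
        t = threshold_density(matrix_5node_a, 1.0)
        assert np.array_equal(t.weighted, matrix_5node_a)
        assert np.array_equal(t.binary, (~np.eye(5, dtype=bool)).astype(float))

    def test_retained_edges_match_sort_oracle(self, matrix_5node_a):
        """Exhaustive enumeration of all 10 edges at every feasible k."""
        iu = np.triu_indices(5, 1)
        edges = sorted(
            zip(matrix_5node_a[iu], iu[0], iu[1]), key=lambda e: (-e[0], e[1], e[2])
        )
        for d in (0.1, 0.3, 0.5, 0.8, 1.0):
            k = int(np.floor(d * 10 + 0.5))
            expect = {(i, j) for _, i, j in edges[:k]}
            t = threshold_density(matrix_5node_a, d)
            got = {tuple(e) for e in np.argwhere(np.triu(t.binary, 1))}
            assert got == expect, f"d={d}"

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_edge_sets_nest_monotonically(self, seed):
        rng = np.random.default_rng(seed)
        w = rng.normal(size=(10, 10))
        w = (w + w.T) / 2
        np.fill_diagonal(w, 0)
        prev = None
        for d in (0.1, 0.2, 0.4, 0.7, 1.0):
            cur = {tuple(e) for e in np.argwhere(np.triu(threshold_density(w, d).binary, 1))}
            if prev is not None:
                assert prev <= cur
            prev = cur

    def test_magnitude_ranking_option(self, matrix_5node_a):
        t = threshold_density(matrix_5node_a, 0.2, rank_by="magnitude")
        got = {tuple(e) for e in np.argwhere(np.triu(t.binary, 1))}
        assert got == {(1, 4), (0, 1)}  # |0.71|, |0.62| beat |-0.52|

    def test_invalid_density_rejected(self, matrix_5node_a):
        for d in (0.0, -0.1, 1.2):
            with pytest.raises(ValueError, match="density"):
                threshold_density(matrix_5node_a, d)


class TestStrength:
    def test_uniform_graph_closed_form(self):
        n, w = 7, 0.3
        m = np.full((n, n), w)
        np.fill_diagonal(m, 0)
        assert np.allclose(nodal_strength(m), (n - 1) * w)
        assert graph_strength(m) == pytest.approx((n - 1) * w)

    def test_strengths_match_row_sum_oracle(self, matrix_5node_a):
        expect = [sum(matrix_5node_a[i, j] for j in range(5) if j != i) for i in range(5)]
        assert np.allclose(nodal_strength(matrix_5node_a), expect)
        assert graph_strength(matrix_5node_a) == pytest.approx(np.mean(expect))

    def test_empty_network_has_zero_strength(self):
        assert np.all(nodal_strength(np.zeros((6, 6))) == 0)
        assert graph_strength(np.zeros((6, 6))) == 0.0

    def test_thresholded_strength_uses_weighted_form(self, matrix_5node_a):
        t = threshold_density(matrix_5node_a, 0.3)
        assert np.allclose(nodal_strength(t), t.weighted.sum(axis=1))


def test_nested_model_determinism(small_cohort):
    """msn8 built from the subset of the full table equals msn8 from a fresh read."""
    from msnkit import MSN8, subset_features, write_feature_table, read_feature_table

    subject = small_cohort.subjects[0]
    direct = build_msn(zscore_features(subset_features(subject.features, MSN8)))
    import tempfile, pathlib

    with tempfile.TemporaryDirectory() as tmp:
        p = pathlib.Path(tmp) / "t.tsv"
        write_feature_table(subset_features(subject.features, MSN8), p)
        reread = build_msn(zscore_features(read_feature_table(p, spec=MSN8)))
    assert np.allclose(direct.weights, reread.weights, atol=1e-12)
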