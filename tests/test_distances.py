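"""Distance metrics: closed-form cases, independent oracles, and saturation."""

import itertools

import numpy as np
import pytest
from scipy.optimize import linprog
from scipy.stats import wasserstein_distance

import horseshoe as h
from horseshoe.exceptions import DegenerateSampleError, IdentifierError

from .conftest import random_counts, random_proportions, read_newick_string


def transport_lp(a, b, positions):
    """Minimum-cost transport between histograms a and b — brute-force LP oracle."""
    n = len(a)
    cost = np.abs(np.subtract.outer(positions, positions)).ravel()
    # flow f_kl >= 0; rows sum to a, columns sum to b
    A_eq = np.zeros((2 * n, n * n))
    for k in range(n):
        A_eq[k, k * n : (k + 1) * n] = 1
        A_eq[n + k, k::n] = 1
    res = linprog(cost, A_eq=A_eq, b_eq=np.concatenate([a, b]), method="highs")
    assert res.success
    return res.fun


class TestEuclidean:
    def test_identical_columns_zero(self):
        t = h.FeatureTable(np.ones((4, 2)), list("abcd"), ["x", "y"])
        assert h.euclidean_dm(t)["x", "y"] == 0.0

    def test_band_table_adjacent_and_disjoint(self, band30):
        table, _ = band30
        dm = h.euclidean_dm(table)
        s = table.sample_ids
        assert dm[s[0], s[1]] == pytest.approx(np.sqrt(2) / 10, abs=1e-12)
        for j in (10, 15, 29):
            assert dm[s[0], s[j]] == pytest.approx(np.sqrt(2 / 10), abs=1e-12)


class TestBandBallRadius:
    def test_closed_form_values(self):
        assert h.band_ball_radius(10) == pytest.approx(0.4472135954999579)
        assert h.band_ball_radius(1) == pytest.approx(np.sqrt(2))
        with pytest.raises(ValueError):
            h.band_ball_radius(0)

    @pytest.mark.parametrize("B", [2, 5, 10, 50])
    def test_matches_disjoint_pair_distance(self, B):
        table, _ = h.band_table(h.BandSpec(n_samples=2, band_size=B, shift=B))
        dm = h.euclidean_dm(table)
        assert dm[table.sample_ids[0], table.sample_ids[1]] == pytest.approx(
            h.band_ball_radius(B), abs=1e-12
        )


class TestChiSquared:
    def test_proportional_columns_zero(self):
        t = h.FeatureTable(
            np.array([[1.0, 2.0], [3.0, 6.0], [0.0, 0.0]]), list("abc"), ["x", "y"]
        )
        assert h.chisq_dm(t)["x", "y"] == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_two_by_two(self):
        t = h.FeatureTable(np.array([[1.0, 0.0], [0.0, 1.0]]), ["a", "b"], ["x", "y"])
        assert h.chisq_dm(t)["x", "y"] == pytest.approx(2.0, abs=1e-12)

    def test_all_zero_sample_rejected(self):
        t = h.FeatureTable(np.array([[1.0, 0.0]]), ["a"], ["x", "y"])
        with pytest.raises(DegenerateSampleError):
            h.chisq_dm(t)

    def test_matches_brute_force_double_loop(self):
        rng = np.random.default_rng(3)
        table = random_counts(rng, 12, 7)
        dm = h.chisq_dm(table)
        P = table.values / table.values.sum()
        r = P.sum(axis=0)
        c = P.sum(axis=1)
        keep = c > 0
        for i, j in itertools.combinations(range(table.n_samples), 2):
            expected = np.sqrt(
                np.sum((P[keep, i] / r[i] - P[keep, j] / r[j]) ** 2 / c[keep])
            )
            assert dm.data[i, j] == pytest.approx(expected, abs=1e-12)


class TestUniFrac:
    def test_identical_profiles_zero(self):
        tree = read_newick_string("((A:1,B:1):1,(C:1,D:1):1):0;")
        t = h.FeatureTable(np.array([[1, 1], [0, 0], [2, 2], [0, 0]], float),
                           list("ABCD"), ["x", "y"])
        assert h.unifrac_unweighted(t, tree)["x", "y"] == 0.0

    def test_disjoint_star_tree_is_one(self):
        tree = read_newick_string("(" + ",".join(f"T{i}:1" for i in range(8)) + ");")
        vals = np.zeros((8, 2))
        vals[:4, 0] = 1
        vals[4:, 1] = 1
        t = h.FeatureTable(vals, [f"T{i}" for i in range(8)], ["a", "b"])
        assert h.unifrac_unweighted(t, tree)["a", "b"] == 1.0

    def test_cherry_tree_two_thirds(self):
        tree = read_newick_string("((A:1,B:1):1,(C:1,D:1):1):0;")
        t = h.FeatureTable(np.array([[1, 0], [0, 1], [0, 0], [0, 0]], float),
                           list("ABCD"), ["s1", "s2"])
        assert h.unifrac_unweighted(t, tree)["s1", "s2"] == pytest.approx(2 / 3)

    def test_missing_feature_listed(self):
        tree = read_newick_string("(A:1,B:1);")
        t = h.FeatureTable(np.ones((3, 1)), ["A", "B", "GHOST"], ["x"])
        with pytest.raises(IdentifierError, match="GHOST"):
            h.unifrac_unweighted(t, tree)

    def test_bounded_unit_interval_and_abundance_invariant(self):
        tree = read_newick_string(
            "(((T0:0.3,(T1:0.2,T2:0.7):0.4):0.5,(T3:0.1,T4:0.9):0.2):0.3,"
            "(T5:0.5,(T6:0.2,T7:0.4):0.6):0.4);"
        )
        rng = np.random.default_rng(5)
        counts = rng.poisson(1.0, size=(8, 6)).astype(float)
        counts[:, counts.sum(axis=0) == 0] = 1.0
        t = h.FeatureTable(counts, [f"T{i}" for i in range(8)], [f"s{j}" for j in range(6)])
        dm = h.unifrac_unweighted(t, tree)
        assert np.all(dm.data >= 0) and np.all(dm.data <= 1)
        # presence/absence metric: doubling counts changes nothing
        t2 = h.FeatureTable(2 * counts, t.feature_ids, t.sample_ids)
        np.testing.assert_array_equal(dm.data, h.unifrac_unweighted(t2, tree).data)

    def test_matches_skbio_oracle(self):
        from skbio.diversity import beta_diversity

        tree = read_newick_string(
            "(((T0:0.3,(T1:0.2,T2:0.7):0.4):0.5,((T3:0.1,T4:0.9):0.2,"
            "(T5:0.3,(T6:0.4,T7:0.2):0.6):0.1):0.3):0.2,"
            "(T8:0.5,(T9:0.2,(T10:0.3,T11:0.4):0.2):0.6):0.4);"
        )
        names = [f"T{i}" for i in range(12)]
        rng = np.random.default_rng(1)
        counts = (rng.random((5, 12)) < 0.4).astype(int)
        counts[counts.sum(axis=1) == 0, 0] = 1
        expected = beta_diversity(
            "unweighted_unifrac", counts, ids=[f"s{i}" for i in range(5)],
            taxa=names, tree=tree,
        )
        ours = h.unifrac_unweighted(
            h.FeatureTable(counts.T.astype(float), names, [f"s{i}" for i in range(5)]),
            tree,
        )
        np.testing.assert_allclose(ours.data, expected.data, atol=1e-12)


class TestEmbad:
    def test_identical_columns_zero(self):
        rng = np.random.default_rng(0)
        t = random_proportions(rng, 5, 1)
        t2 = h.FeatureTable(
            np.repeat(t.values, 2, axis=1), t.feature_ids, ["x", "y"], proportions=True
        )
        order = h.FeatureOrder(tuple(t.feature_ids))
        assert h.embad(t2, order)["x", "y"] == 0.0

    def test_four_species_half_mass_flow(self):
        # all mass moves two positions: d = 2 * 1/2 + 2 * 1/2 = 2
        vals = np.array([[0.5, 0.0], [0.5, 0.0], [0.0, 0.5], [0.0, 0.5]])
        t = h.FeatureTable(vals, list("abcd"), ["s1", "s2"], proportions=True)
        order = h.FeatureOrder(("a", "b", "c", "d"))
        assert h.embad(t, order)["s1", "s2"] == pytest.approx(2.0, abs=1e-12)

    def test_band_table_distance_is_rank_gap(self, band30):
        table, _ = band30
        order = h.FeatureOrder(tuple(table.feature_ids))
        dm = h.embad(table, order)
        expected = np.abs(np.subtract.outer(np.arange(30.0), np.arange(30.0)))
        np.testing.assert_allclose(dm.data, expected, atol=1e-9)

    def test_requires_proportions(self):
        t = h.FeatureTable(np.array([[2.0], [3.0]]), ["a", "b"], ["x"])
        with pytest.raises(ValueError, match="to_proportions"):
            h.embad(t, h.FeatureOrder(("a", "b")))

    def test_incomplete_order_rejected(self):
        rng = np.random.default_rng(2)
        t = random_proportions(rng, 4, 2)
        with pytest.raises(IdentifierError):
            h.embad(t, h.FeatureOrder(("f0", "f1", "f2")))

    @pytest.mark.parametrize("n_features", [2, 4, 8])
    def test_matches_transport_lp_and_scipy(self, n_features):
        rng = np.random.default_rng(n_features)
        for _ in range(5):
            t = random_proportions(rng, n_features, 2)
            order = h.FeatureOrder(tuple(t.feature_ids))
            d = h.embad(t, order)["s0", "s1"]
            a, b = t.values[:, 0], t.values[:, 1]
            pos = np.arange(1.0, n_features + 1)
            assert d == pytest.approx(transport_lp(a, b, pos), abs=1e-9)
            assert d == pytest.approx(wasserstein_distance(pos, pos, a, b), abs=1e-9)

    def test_gradient_position_variant(self):
        rng = np.random.default_rng(9)
        t = random_proportions(rng, 5, 2)
        pos = (0.0, 0.5, 2.0, 2.5, 7.0)
        order = h.FeatureOrder(tuple(t.feature_ids), positions=pos)
        d = h.embad(t, order, use_positions=True)["s0", "s1"]
        a, b = t.values[:, 0], t.values[:, 1]
        assert d == pytest.approx(
            wasserstein_distance(np.array(pos), np.array(pos), a, b), abs=1e-9
        )

    def test_unordered_positions_rejected(self):
        with pytest.raises(ValueError):
            h.FeatureOrder(("a", "b"), positions=(1.0, 0.0))


class TestMetricAxioms:
    @pytest.mark.parametrize("metric", ["euclidean", "chisq", "embad"])
    def test_symmetry_hollow_nonnegative(self, metric):
        rng = np.random.default_rng(11)
        t = random_counts(rng, 10, 8)
        if metric == "euclidean":
            dm = h.euclidean_dm(t)
        elif metric == "chisq":
            dm = h.chisq_dm(t)
        else:
            p = h.to_proportions(t)
            dm = h.embad(p, h.FeatureOrder(tuple(p.feature_ids)))
        assert np.all(dm.data >= 0)
        np.testing.assert_allclose(dm.data, dm.data.T, atol=1e-12)
        assert np.all(np.diag(dm.data) == 0)

    @pytest.mark.parametrize("metric", ["euclidean", "embad"])
    def test_triangle_inequality_exhaustive(self, metric):
        rng = np.random.default_rng(13)
        n = 12
        t = random_proportions(rng, 6, n)
        if metric == "euclidean":
            dm = h.euclidean_dm(t)
        else:
            dm = h.embad(t, h.FeatureOrder(tuple(t.feature_ids)))
        d = dm.data
        for i, j, k in itertools.permutations(range(n), 3):
            assert d[i, j] <= d[i, k] + d[k, j] + 1e-12


class TestSaturationCurve:
    def test_euclidean_band_curve_and_plateau(self, band30):
        table, _ = band30
        dm = h.euclidean_dm(table)
        curve = h.saturation_curve(dm, table.sample_ids[0], table.sample_ids)
        assert curve.plateau_rank == 10
        rising = curve.distances[:10]
        assert np.all(np.diff(rising) > 0)
        np.testing.assert_allclose(curve.distances[9:], np.sqrt(2 / 10), atol=1e-12)

    def test_chisq_constant_over_interior_saturated_ranks(self, band30):
        # edge features occur in fewer samples, so constancy holds away
        # from the far edge of a finite band table
        table, _ = band30
        dm = h.chisq_dm(table)
        curve = h.saturation_curve(dm, table.sample_ids[0], table.sample_ids)
        interior = curve.distances[9:20]  # ranks 10..20
        np.testing.assert_allclose(interior, interior[0], atol=1e-9)
        assert np.all(np.diff(curve.distances[:10]) > 0)

    def test_embad_band_curve_strictly_increasing(self, band30):
        table, _ = band30
        order = h.FeatureOrder(tuple(table.feature_ids))
        dm = h.embad(table, order)
        curve = h.saturation_curve(dm, table.sample_ids[0], table.sample_ids)
        assert np.all(np.diff(curve.distances) > 0)
        assert curve.plateau_rank == 29  # nonsaturating: plateau only at the end

    def test_zero_matrix_flat(self):
        from skbio import DistanceMatrix

        dm = DistanceMatrix(np.zeros((4, 4)), list("abcd"))
        curve = h.saturation_curve(dm, "a", list("abcd"))
        assert curve.plateau_rank == 1
        np.testing.assert_array_equal(curve.distances, 0.0)

    def test_unknown_reference_rejected(self, band30):
        table, _ = band30
        dm = h.euclidean_dm(table)
        with pytest.raises(IdentifierError):
            h.saturation_curve(dm, "nope", table.sample_ids)
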