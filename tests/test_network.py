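"""Mutual-information estimation, permutation nulls, persistence, assembly."""

import numpy as np
import pytest

import ncbroker as nb
from ncbroker.errors import ConfigurationError, DataError
from ncbroker.network import (
    default_bins,
    discretize,
    mi_from_labels,
)

from conftest import make_matrix


class TestPairwiseMI:
    def test_self_information_is_one(self, rng):
        m = make_matrix(rng.normal(0, 1, (2, 40)), scale="log2")
        mi = nb.pairwise_mi(m)
        assert mi.iloc[0, 0] == pytest.approx(1.0)
        # duplicated profile: MI = 1, hence distance 0
        m2 = make_matrix(np.vstack([m.values.iloc[0]] * 2), scale="log2")
        assert nb.pairwise_mi(m2).iloc[0, 1] == pytest.approx(1.0)

    def test_constant_gene_convention(self, rng):
        vals = np.vstack([np.full(30, 2.0), rng.normal(0, 1, 30)])
        mi = nb.pairwise_mi(make_matrix(vals, scale="log2"))
        assert mi.iloc[0, 1] == 0.0
        assert mi.iloc[0, 0] == 0.0

    def test_matches_joint_table_enumeration(self):
        """Plug-in MI from an explicitly enumerated 3x3 joint count table."""
        joint = np.array([[4, 1, 0], [1, 4, 1], [0, 1, 4]], dtype=float)
        xs, ys = [], []
        for i in range(3):
            for j in range(3):
                xs += [i] * int(joint[i, j])
                ys += [j] * int(joint[i, j])
        xs, ys = np.array(xs), np.array(ys)
        # independent oracle: direct sum p log2(p / (px py))
        n = joint.sum()
        p = joint / n
        px, py = p.sum(axis=1), p.sum(axis=0)
        mi_direct = sum(
            p[i, j] * np.log2(p[i, j] / (px[i] * py[j]))
            for i in range(3)
            for j in range(3)
            if p[i, j] > 0
        )
        hx = -(px * np.log2(px)).sum()
        hy = -(py * np.log2(py)).sum()
        expected = mi_direct / min(hx, hy)
        assert mi_from_labels(xs, ys, 3) == pytest.approx(expected)

    def test_symmetry_and_range(self, rng):
        m = make_matrix(rng.normal(0, 1, (6, 50)), scale="log2")
        mi = nb.pairwise_mi(m).to_numpy()
        np.testing.assert_allclose(mi, mi.T)
        assert (mi >= 0).all() and (mi <= 1).all()
        np.testing.assert_allclose(np.diag(mi), 1.0)

    def test_too_few_samples_rejected(self, rng):
        m = make_matrix(rng.normal(0, 1, (2, 5)), scale="log2")
        with pytest.raises(DataError):
            nb.pairwise_mi(m)

    def test_noise_does_not_increase_mi(self, rng):
        """Data-processing sanity: corrupting one profile with independent
        noise does not raise the median normalized MI."""
        deltas = []
        for rep in range(20):
            x = rng.normal(0, 1, 60)
            y = x + rng.normal(0, 0.3, 60)
            m_clean = make_matrix(np.vstack([x, y]), scale="log2")
            m_noisy = make_matrix(
                np.vstack([x + rng.normal(0, 2.0, 60), y]), scale="log2"
            )
            deltas.append(
                nb.pairwise_mi(m_noisy).iloc[0, 1] - nb.pairwise_mi(m_clean).iloc[0, 1]
            )
        assert np.median(deltas) <= 0


class TestPairwiseCorrelation:
    def test_rank_invariance_and_symmetry(self, rng):
        x = rng.normal(0, 1, 40)
        m = make_matrix(np.vstack([x, np.exp(x)]), scale="log2")
        cor = nb.pairwise_correlation(m)
        assert cor.iloc[0, 1] == pytest.approx(1.0)
        assert cor.iloc[1, 0] == cor.iloc[0, 1]

    def test_independent_pairs_have_low_mean_rho(self, rng):
        m = make_matrix(rng.normal(0, 1, (20, 100)), scale="log2")
        cor = nb.pairwise_correlation(m).to_numpy()
        off = cor[np.triu_indices(20, k=1)]
        assert off.mean() < 0.15

    def test_constant_gene_rho_zero(self, rng):
        vals = np.vstack([np.full(30, 1.0), rng.normal(0, 1, 30)])
        cor = nb.pairwise_correlation(make_matrix(vals, scale="log2"))
        assert cor.iloc[0, 1] == 0.0


class TestPermutationNull:
    def test_duplicated_pair_reaches_minimum_p(self, rng):
        x = rng.normal(0, 1, 50)
        m = make_matrix(np.vstack([x, x]), scale="log2")
        res = nb.permutation_null(m, ("g0", "g1"), n_perm=1000, seed=1)
        assert res.null_p == pytest.approx(1 / 1001)
        assert res.observed == pytest.approx(1.0)
        assert len(res.null_samples) == 1000

    def test_constant_gene_p_one(self, rng):
        vals = np.vstack([np.full(40, 3.0), rng.normal(0, 1, 40)])
        m = make_matrix(vals, scale="log2")
        res = nb.permutation_null(m, ("g0", "g1"), n_perm=100, seed=1)
        assert res.observed == 0.0
        assert res.null_p == 1.0

    def test_tiny_n_perm_rejected(self, rng):
        m = make_matrix(rng.normal(0, 1, (2, 30)), scale="log2")
        with pytest.raises(ConfigurationError):
            nb.permutation_null(m, ("g0", "g1"), n_perm=10)


class TestPersistence:
    def test_duplicated_genes_persist_fully(self, rng):
        x = rng.normal(0, 1, 60)
        m = make_matrix(np.vstack([x, x]), scale="log2")
        pers = nb.rewiring_persistence(m, [("g0", "g1")], n_randomizations=25, seed=3)
        assert pers[("g0", "g1")] == 1.0

    def test_chance_edge_fades(self, rng):
        """Independent pairs that squeaked past the significance gate
        should reappear in well under half of the resamplings."""
        rates = []
        for rep in range(30):
            m = make_matrix(rng.normal(0, 1, (2, 60)), scale="log2")
            res = nb.permutation_null(m, ("g0", "g1"), n_perm=200, seed=rep)
            if res.null_p <= 0.2:  # a lucky-ish pair
                pers = nb.rewiring_persistence(
                    m, [("g0", "g1")], n_randomizations=20, seed=rep
                )
                rates.append(pers[("g0", "g1")])
        assert rates, "no chance pair sampled"
        assert np.mean(rates) < 0.5

    def test_deterministic_given_seed(self, rng):
        m = make_matrix(rng.normal(0, 1, (4, 40)), scale="log2")
        edges = [("g0", "g1"), ("g2", "g3")]
        a = nb.rewiring_persistence(m, edges, n_randomizations=15, seed=9)
        b = nb.rewiring_persistence(m, edges, n_randomizations=15, seed=9)
        assert a == b
        assert all(0 <= v <= 1 for v in a.values())


def correlated_block_matrix(rng, n_samples=80):
    """Two 5-gene modules + one bridging ncRNA + one noise ncRNA."""
    f1, f2 = rng.normal(0, 1, (2, n_samples))
    rows, bio = [], {}
    for k, f in enumerate([f1, f2]):
        for i in range(5):
            rows.append(1.2 * f + rng.normal(0, 1, n_samples))
    rows.append(1.2 * (f1 + f2) + rng.normal(0, 0.5, n_samples))  # broker
    rows.append(rng.normal(0, 1, n_samples))  # unrelated ncRNA
    m = make_matrix(np.array(rows), scale="log2")
    genes = [f"g{i}" for i in range(10)]
    ncrnas = ["g10", "g11"]
    for g in ncrnas:
        m.biotype[g] = "pseudogene"
    return m, genes, ncrnas


class TestBuildTemplateNetwork:
    def test_broker_edges_to_both_modules_survive(self, rng):
        m, genes, ncrnas = correlated_block_matrix(rng)
        g = nb.build_template_network(
            m, genes, ncrnas, alpha=0.05, min_persistence=0.6,
            n_perm=300, n_boot=40, seed=1,
        )
        broker_nbrs = set(g.neighbors("g10"))
        assert broker_nbrs & {f"g{i}" for i in range(5)}
        assert broker_nbrs & {f"g{i}" for i in range(5, 10)}

    def test_distance_identity_and_attributes(self, rng):
        m, genes, ncrnas = correlated_block_matrix(rng)
        g = nb.build_template_network(
            m, genes, ncrnas, alpha=0.05, min_persistence=0.0,
            n_perm=200, n_boot=10, seed=2,
        )
        assert g.number_of_edges() > 0
        for _, _, d in g.edges(data=True):
            assert d["distance"] + d["mi"] == pytest.approx(1.0, abs=1e-12)
        assert g.nodes["g10"]["is_ncrna"] and g.nodes["g10"]["biotype"] == "pseudogene"
        assert not g.nodes["g0"]["is_ncrna"]

    def test_alpha_zero_gives_empty_edge_set(self, rng):
        m, genes, ncrnas = correlated_block_matrix(rng)
        g = nb.build_template_network(m, genes, ncrnas, alpha=0.0, n_perm=50)
        assert g.number_of_edges() == 0
        assert all(g.nodes[v]["isolated"] for v in g)

    def test_edge_set_invariant_to_gene_order(self, rng):
        m, genes, ncrnas = correlated_block_matrix(rng)
        kw = dict(alpha=0.05, min_persistence=0.0, n_perm=200, n_boot=10, seed=3)
        g1 = nb.build_template_network(m, genes, ncrnas, **kw)
        g2 = nb.build_template_network(m, genes[::-1], ncrnas, **kw)
        e1 = {frozenset(e) for e in g1.edges}
        e2 = {frozenset(e) for e in g2.edges}
        assert e1 == e2

    def test_empty_gene_list_rejected(self, rng):
        m, _, ncrnas = correlated_block_matrix(rng)
        with pytest.raises(DataError):
            nb.build_template_network(m, [], ncrnas)

    def test_cor_metric_mirrors_mi_path(self, rng):
        m, genes, ncrnas = correlated_block_matrix(rng)
        g = nb.build_template_network(
            m, genes, ncrnas, metric="cor", alpha=0.05, min_persistence=0.6,
            n_perm=200, n_boot=30, seed=4,
        )
        assert g.graph["metric"] == "COR"
        assert g.number_of_edges() > 0

    def test_null_calibration_independent_pairs(self, rng):
        """Among truly independent profiles the surviving-edge fraction
        stays within twice alpha when persistence is off."""
        m = make_matrix(rng.normal(0, 1, (25, 100)), scale="log2")
        genes = [f"g{i}" for i in range(25)]
        g = nb.build_template_network(
            m, genes[:20], genes[20:], alpha=0.05, min_persistence=0.0,
            n_perm=400, seed=5,
        )
        n_pairs = 25 * 24 / 2
        assert g.number_of_edges() <= 2 * 0.05 * n_pairs


class TestDegreeSwapNull:
    def test_degrees_preserved_and_structure_randomized(self, rng):
        from ncbroker.network import degree_swap_null

        g, _ = nb.generate_broker_graph(3, 6, 2, seed=2)
        null = degree_swap_null(g, seed=4)
        assert dict(null.degree()) == dict(g.degree())
        assert {frozenset(e) for e in null.edges} != {
            frozenset(e) for e in g.edges
        }


class TestBins:
    def test_default_bins_scale(self):
        assert default_bins(124) == 5
        assert default_bins(20) == 3

    def test_discretize_equal_frequency(self):
        labels = discretize(np.array([5.0, 1.0, 3.0, 2.0, 4.0, 6.0]), 3)
        assert sorted(np.bincount(labels, minlength=3)) == [2, 2, 2]
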