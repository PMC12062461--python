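import numpy as np
import pandas as pd
import pytest
from scipy import stats

from miner.mi import adaptive_mi
from miner.network import (MetaCellConfig, NetworkConfig, Regulon, SJARACNe,
                           annotate_network, bootstrap_consensus,
                           calibrate_mi_null, dpi_filter, infer_single_network,
                           metacell_aggregate, mi_threshold_from_null,
                           null_mi_sample, to_regulons)


class TestMetacell:
    def test_gamma_one_is_identity_up_to_order(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(30, 10))
        out, members = metacell_aggregate(X, MetaCellConfig(gamma=1))
        assert out.shape == X.shape
        np.testing.assert_allclose(np.sort(out, axis=0), np.sort(X, axis=0))

    def test_identical_cells_collapse_to_common_profile(self):
        X = np.tile(np.arange(8.0), (100, 1))
        out, _ = metacell_aggregate(X, MetaCellConfig(gamma=20), seed=1)
        assert out.shape == (5, 8)
        np.testing.assert_allclose(out, np.tile(np.arange(8.0), (5, 1)))

    def test_blobs_never_mix(self):
        rng = np.random.default_rng(1)
        X = np.vstack([rng.normal(0, 0.2, (50, 20)),
                       rng.normal(5, 0.2, (50, 20))])
        blob = np.repeat([0, 1], 50)
        for seed in range(10):
            _, members = metacell_aggregate(X, MetaCellConfig(gamma=25),
                                            seed=seed)
            for c in np.unique(members):
                assert len(np.unique(blob[members == c])) == 1

    def test_gamma_exceeding_cells_errors(self):
        with pytest.raises(ValueError):
            metacell_aggregate(np.zeros((3, 4)), MetaCellConfig(gamma=10))


class TestNullCalibration:
    @pytest.fixture(scope="class")
    def gaussian_matrix(self):
        return np.random.default_rng(5).normal(size=(60, 300))

    def test_permissive_p_below_max_null(self, gaussian_matrix):
        null = null_mi_sample(gaussian_matrix, 6000, seed=1)
        thr = mi_threshold_from_null(null, pb=0.5)
        assert thr <= null.max()

    def test_threshold_monotone_in_pb(self, gaussian_matrix):
        null = null_mi_sample(gaussian_matrix, 6000, seed=1)
        assert mi_threshold_from_null(null, 1e-7) > \
            mi_threshold_from_null(null, 1e-2)

    def test_null_data_pass_rate_controlled(self, gaussian_matrix):
        # on independent genes, threshold(1e-2) should pass <= 5% of pairs
        cfg = NetworkConfig(pb=1e-2, null_pairs=6000, seed=2)
        thr = calibrate_mi_null(gaussian_matrix, cfg)
        rng = np.random.default_rng(3)
        pairs = rng.integers(0, 60, size=(500, 2))
        pairs = pairs[pairs[:, 0] != pairs[:, 1]]
        mis = np.array([adaptive_mi(gaussian_matrix[i], gaussian_matrix[j])
                        for i, j in pairs])
        assert (mis >= thr).mean() <= 0.05


class TestDPI:
    def test_weakest_triangle_edge_removed(self):
        edges = {("A", "B"): 0.9, ("B", "C"): 0.8, ("A", "C"): 0.3}
        out = dpi_filter(edges, tolerance=0.0)
        assert set(out) == {("A", "B"), ("B", "C")}

    def test_tolerance_spares_borderline_edge(self):
        edges = {("A", "B"): 0.9, ("B", "C"): 0.8, ("A", "C"): 0.75}
        assert set(dpi_filter(edges, tolerance=0.15)) == set(edges)
        assert ("A", "C") not in dpi_filter(edges, tolerance=0.0)

    def test_no_triangles_identity(self):
        edges = {("A", "B"): 0.5, ("C", "D"): 0.4}
        assert dpi_filter(edges) == edges

    def test_subset_and_idempotent(self):
        rng = np.random.default_rng(4)
        nodes = list("ABCDEFG")
        edges = {}
        for i in range(len(nodes)):
            for j in range(i + 1, len(nodes)):
                if rng.random() < 0.6:
                    edges[(nodes[i], nodes[j])] = float(rng.uniform(0.1, 1))
        once = dpi_filter(edges, 0.1)
        assert set(once) <= set(edges)
        assert dpi_filter(once, 0.1) == once


class TestSingleNetwork:
    def test_direct_target_has_top_mi(self):
        rng = np.random.default_rng(6)
        hub = rng.normal(size=400)
        X = np.vstack([hub, hub + rng.normal(scale=0.1, size=400),
                       rng.normal(size=(5, 400))])
        cfg = NetworkConfig(null_pairs=6000, seed=1)
        thr = calibrate_mi_null(X, cfg)
        net = infer_single_network(X, np.array([0]), thr, cfg)
        assert (0, 1) in net
        assert net[(0, 1)] == max(net.values())

    def test_independent_genes_give_no_edges(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(40, 500))
        cfg = NetworkConfig(pb=1e-7, null_pairs=6000, seed=2)
        thr = calibrate_mi_null(X, cfg)
        net = infer_single_network(X, np.arange(5), thr, cfg)
        assert len(net) <= max(1, int(5 * 40 * 1e-3))

    def test_chain_indirect_edge_removed_by_dpi(self):
        # chain hub1 -> mediator -> hub2: the indirect hub1-hub2 edge is the
        # weakest edge of the triangle and DPI should remove it. The MI null
        # is rank-based (distribution-free given n), so one calibration
        # serves every replicate.
        rng = np.random.default_rng(999)
        cfg = NetworkConfig(pb=1e-4, null_pairs=6000, seed=0)
        thr = calibrate_mi_null(rng.normal(size=(10, 1000)), cfg)
        removed = 0
        for rep in range(100):
            rng = np.random.default_rng(1000 + rep)
            h1 = rng.normal(size=1000)
            g = h1 + rng.normal(scale=0.4, size=1000)
            h2 = g + rng.normal(scale=0.4, size=1000)
            X = np.vstack([h1, h2, g])
            net = infer_single_network(X, np.array([0, 1]), thr, cfg)
            if (0, 1) not in net:  # the indirect hub1-hub2 edge
                removed += 1
        assert removed >= 95


class TestConsensus:
    def test_full_support_edge_retained(self):
        assert stats.poisson.sf(99, 5) < 1e-10

    def test_support_at_rate_dropped(self):
        # an edge appearing about lambda times is entirely unremarkable
        assert stats.poisson.sf(4, 5.0) > 0.5

    def test_single_bootstrap_is_single_network(self):
        rng = np.random.default_rng(8)
        hub = rng.normal(size=300)
        X = np.vstack([hub, 0.8 * hub + rng.normal(scale=0.3, size=300),
                       rng.normal(size=(3, 300))])
        cfg = NetworkConfig(n_boot=1, pc=0.99, null_pairs=6000, seed=3)
        thr = calibrate_mi_null(X, cfg)
        df = bootstrap_consensus(X, np.array([0]), thr, cfg)
        assert (df["support"] == 1).all()

    def test_fixed_seed_bit_identical(self, grn_fixture):
        fx = grn_fixture
        kw = dict(hubs=fx.hubs[:3], n_boot=5, pc=0.9, null_pairs=6000,
                  random_state=9)
        a = SJARACNe(**kw).fit(fx.matrix).network_
        b = SJARACNe(**kw).fit(fx.matrix).network_
        assert len(a) > 0
        pd.testing.assert_frame_equal(a, b)


class TestAnnotation:
    def _net(self):
        return pd.DataFrame({"source_idx": [0, 0], "target_idx": [1, 2],
                             "mi": [1.0, 0.8], "support": [10, 10],
                             "p_consensus": [1e-5, 1e-5]})

    def test_linear_relationship_stats(self):
        x = np.linspace(0, 1, 50)
        X = np.vstack([x, 2 * x, -x + np.random.default_rng(0).normal(
            scale=0.05, size=50)])
        out = annotate_network(self._net(), X, ["H", "A", "B"], {0})
        row = out[out.target == "A"].iloc[0]
        assert row.pearson == pytest.approx(1.0)
        assert row.slope == pytest.approx(2.0)
        assert row.sign == 1
        assert out[out.target == "B"].iloc[0].sign == -1

    def test_spearman_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=80)
        y = x + rng.normal(scale=0.5, size=80)
        net = self._net().iloc[:1]
        a = annotate_network(net, np.vstack([x, y, y]), ["H", "A", "B"], {0})
        b = annotate_network(net, np.vstack([x, np.exp(y), y]),
                             ["H", "A", "B"], {0})
        assert a.iloc[0].spearman == pytest.approx(b.iloc[0].spearman)

    def test_constant_gene_flagged_zero(self):
        X = np.vstack([np.linspace(0, 1, 20), np.full(20, 3.0),
                       np.zeros(20)])
        with pytest.warns(UserWarning):
            out = annotate_network(self._net().iloc[:1], X,
                                   ["H", "A", "B"], {0})
        assert out.iloc[0].spearman == 0.0 and out.iloc[0].sign == 0


class TestRegulons:
    def test_split_by_sign(self):
        net = pd.DataFrame({"source": ["H", "H", "H"],
                            "target": ["A", "B", "C"],
                            "sign": [1, 1, -1]})
        regs = to_regulons(net)
        assert regs["H"].positive == ["A", "B"]
        assert regs["H"].negative == ["C"]

    def test_empty_network(self):
        assert to_regulons(pd.DataFrame(columns=["source", "target",
                                                 "sign"])) == {}

    def test_overlapping_signs_rejected(self):
        with pytest.raises(ValueError):
            Regulon("H", ["A"], ["A"])


class TestPlantedRecovery:
    @pytest.fixture(scope="class")
    def fitted(self, grn_fixture):
        return SJARACNe(hubs=grn_fixture.hubs, n_boot=30, null_pairs=6000,
                        random_state=1).fit(grn_fixture.matrix)

    def test_edge_ranking_auroc(self, grn_fixture, fitted):
        from sklearn.metrics import roc_auc_score

        truth = set(zip(grn_fixture.edges.source, grn_fixture.edges.target))
        mi_map = {}
        for r in fitted.network_.itertuples():
            mi_map[(r.source, r.target)] = r.mi
            mi_map[(r.target, r.source)] = r.mi
        scores, labels = [], []
        for h in grn_fixture.hubs:
            for g in grn_fixture.matrix.gene_ids:
                if g == h:
                    continue
                scores.append(mi_map.get((h, g), 0.0))
                labels.append((h, g) in truth)
        assert roc_auc_score(labels, scores) >= 0.9

    def test_planted_signs_recovered(self, grn_fixture, fitted):
        planted = {(r.source, r.target): r.sign
                   for r in grn_fixture.edges.itertuples()}
        retained = [(r.source, r.target, r.sign)
                    for r in fitted.network_.itertuples()
                    if (r.source, r.target) in planted]
        assert retained, "no planted edge retained"
        agreement = np.mean([s == planted[(a, b)] for a, b, s in retained])
        assert agreement >= 0.9

    def test_stricter_thresholds_never_add_edges(self, grn_fixture, fitted):
        loose = fitted.network_
        strict = SJARACNe(hubs=grn_fixture.hubs, n_boot=30, null_pairs=6000,
                          pc=1e-4, random_state=1).fit(grn_fixture.matrix)
        loose_edges = set(zip(loose.source, loose.target))
        strict_edges = set(zip(strict.network_.source,
                               strict.network_.target))
        assert strict_edges <= loose_edges

    def test_missing_hub_dropped_with_warning(self, grn_fixture):
        est = SJARACNe(hubs=[grn_fixture.hubs[0], "NOTAGENE"], n_boot=2,
                       null_pairs=6000, random_state=0)
        with pytest.warns(UserWarning, match="NOTAGENE"):
            est.fit(grn_fixture.matrix)

    def test_no_hub_at_all_errors(self, grn_fixture):
        with pytest.raises(ValueError, match="hub"):
            SJARACNe(hubs=["NOPE"], null_pairs=6000).fit(grn_fixture.matrix)
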