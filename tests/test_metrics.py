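import numpy as np
import pandas as pd
import pytest
from scipy import stats

from miner.metrics import (assign_drivers, clustering_scores, early_precision,
                           fisher_combine, gsea_ks, random_network, roc_prc)


class TestClusteringScores:
    def test_perfect_prediction(self, blob_embedding):
        E, truth = blob_embedding
        s = clustering_scores(truth, truth, representation_for_asw(E))
        assert (s.ari, s.ami, s.nmi) == (1.0, 1.0, 1.0)
        assert s.accuracy_score == 1.0 and s.purity_score == 1.0

    def test_single_cluster_prediction_has_zero_ari(self):
        truth = np.repeat([0, 1], 10)
        s = clustering_scores(np.zeros(20), truth)
        assert s.ari == 0.0

    def test_hand_computed_purity(self):
        # P1 = {8 A, 2 B}, P2 = {10 B}: purity = (10*0.8 + 10*1.0)/20
        pred = np.repeat([1, 2], 10)
        truth = np.array(["A"] * 8 + ["B"] * 2 + ["B"] * 10)
        s = clustering_scores(pred, truth)
        assert s.purity_score == pytest.approx(0.9)

    def test_hand_computed_accuracy(self):
        # true cluster A = {8 P1, 2 P2}, B = {10 P2}
        truth = np.array(["A"] * 10 + ["B"] * 10)
        pred = np.array([1] * 8 + [2] * 2 + [2] * 10)
        s = clustering_scores(pred, truth)
        assert s.accuracy_score == pytest.approx(0.9)

    def test_symmetry_and_label_permutation(self):
        rng = np.random.default_rng(0)
        a = rng.integers(0, 3, 50)
        b = rng.integers(0, 4, 50)
        s1, s2 = clustering_scores(a, b), clustering_scores(b, a)
        assert s1.ari == pytest.approx(s2.ari)
        assert s1.nmi == pytest.approx(s2.nmi)
        relabeled = np.array([{0: 7, 1: 5, 2: 9}[x] for x in a])
        assert clustering_scores(relabeled, b).ari == pytest.approx(s1.ari)

    def test_avgbio_uses_scaled_asw(self, blob_embedding):
        E, truth = blob_embedding
        s = clustering_scores(truth, truth, E)
        assert s.avgbio == pytest.approx(
            np.mean([s.ari, s.nmi, (s.asw + 1) / 2]))

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            clustering_scores([1, 2], [1, 2, 3])


def representation_for_asw(E):
    return E


class TestEarlyPrecision:
    def test_fraction_of_topk(self):
        ranked = list(range(10))
        truth = {0, 2, 4, 6}
        ep, _ = early_precision(ranked, truth, k=10)
        assert ep == 0.4

    def test_perfect_ranking(self):
        truth = set(range(5))
        ep, epr = early_precision(list(range(20)), truth, k=5)
        assert ep == 1.0
        assert epr == pytest.approx(1.0 / (5 / 20))

    def test_random_ranking_epr_near_one(self):
        rng = np.random.default_rng(1)
        universe = list(range(200))
        truth = set(range(50))
        eprs = []
        for _ in range(100):
            ranked = list(rng.permutation(universe))
            eprs.append(early_precision(ranked, truth, k=40)[1])
        assert np.mean(eprs) == pytest.approx(1.0, abs=0.2)

    def test_perfect_epr_dominates(self):
        rng = np.random.default_rng(2)
        universe = list(range(100))
        truth = set(range(20))
        perfect = sorted(universe, key=lambda e: e not in truth)
        best = early_precision(perfect, truth, k=20)[1]
        for _ in range(50):
            other = list(rng.permutation(universe))
            assert early_precision(other, truth, k=20)[1] <= best

    def test_empty_truth_errors(self):
        with pytest.raises(ValueError):
            early_precision([1, 2], set(), k=1)


class TestRocPrc:
    def test_perfect_separation(self):
        auroc, auprc, _ = roc_prc([3, 2, 1, 0], [1, 1, 0, 0])
        assert auroc == 1.0 and auprc == 1.0

    def test_uninformative_scores(self):
        rng = np.random.default_rng(3)
        auroc, _, _ = roc_prc(rng.normal(size=2000),
                              rng.integers(0, 2, 2000))
        assert auroc == pytest.approx(0.5, abs=0.05)

    def test_auroc_equals_mann_whitney_identity(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            s = rng.normal(size=30)
            y = rng.integers(0, 2, 30)
            if len(np.unique(y)) < 2:
                continue
            auroc = roc_prc(s, y)[0]
            u = stats.mannwhitneyu(s[y == 1], s[y == 0]).statistic
            assert auroc == pytest.approx(u / ((y == 1).sum() *
                                               (y == 0).sum()))

    def test_single_class_errors(self):
        with pytest.raises(ValueError):
            roc_prc([1, 2], [1, 1])


class TestGseaKS:
    def test_top_ranked_targets_enrich(self):
        ranking = pd.Series(np.linspace(3, -3, 100),
                            index=[f"g{i}" for i in range(100)])
        es, p = gsea_ks([f"g{i}" for i in range(10)], ranking)
        assert es > 0 and p < 1e-4

    def test_single_target_at_top(self):
        n = 50
        ranking = pd.Series(np.arange(n, 0, -1.0),
                            index=[f"g{i}" for i in range(n)])
        es, _ = gsea_ks(["g0"], ranking)
        assert es == pytest.approx(1 - 1 / n)

    def test_null_p_values_uniform(self):
        rng = np.random.default_rng(5)
        features = [f"g{i}" for i in range(200)]
        ps = []
        for _ in range(200):
            ranking = pd.Series(rng.normal(size=200), index=features)
            targets = rng.choice(features, 20, replace=False)
            ps.append(gsea_ks(targets, ranking)[1])
        # approximate uniformity: the exact two-sample KS p is discrete, so
        # check the moments and the type-I rate rather than a strict KS test
        ps = np.asarray(ps)
        assert np.mean(ps) == pytest.approx(0.5, abs=0.06)
        assert (ps < 0.05).mean() == pytest.approx(0.05, abs=0.04)

    def test_p_matches_permutation_ks(self):
        rng = np.random.default_rng(6)
        features = [f"g{i}" for i in range(60)]
        ranking = pd.Series(rng.normal(size=60), index=features)
        ranking.iloc[:10] += 1.5
        targets = features[:10]
        _, p = gsea_ks(targets, ranking)
        # permutation oracle for the two-sample KS statistic
        obs = stats.ks_2samp(ranking[targets],
                             ranking[features[10:]]).statistic
        count = 0
        n_perm = 10_000
        vals = ranking.to_numpy()
        for _ in range(n_perm):
            perm = rng.permutation(vals)
            d = stats.ks_2samp(perm[:10], perm[10:]).statistic
            count += d >= obs
        p_perm = (count + 1) / (n_perm + 1)
        mc_err = 3 * np.sqrt(max(p_perm, 1e-4) / n_perm)
        assert abs(p - p_perm) <= max(0.01, mc_err * 10)

    def test_all_targets_rejected(self):
        ranking = pd.Series([1.0, 2.0], index=["a", "b"])
        with pytest.raises(ValueError):
            gsea_ks(["a", "b"], ranking)


class TestFisher:
    def test_unit_pvalues(self):
        assert fisher_combine(1.0, 1.0) == pytest.approx(1.0)

    def test_known_value(self):
        assert fisher_combine(0.05, 0.05) == pytest.approx(0.0175, abs=5e-5)

    def test_symmetry(self):
        assert fisher_combine(0.01, 0.6) == fisher_combine(0.6, 0.01)

    def test_invalid_input(self):
        with pytest.raises(ValueError):
            fisher_combine(0.0, 0.5)


class TestRandomNetwork:
    def test_fixed_size_range(self):
        net = random_network(["H1", "H2"], [f"g{i}" for i in range(20)],
                             (5, 5), seed=1)
        assert (net.groupby("source").size() == 5).all()

    def test_seed_reproducibility(self):
        args = (["H"], list("abcdefghij"), (2, 6))
        pd.testing.assert_frame_equal(random_network(*args, seed=3),
                                      random_network(*args, seed=3))

    def test_random_network_auroc_near_half(self):
        rng = np.random.default_rng(7)
        candidates = [f"g{i}" for i in range(100)]
        truth = {("H", g) for g in candidates[:30]}
        aurocs = []
        for seed in range(50):
            net = random_network(["H"], candidates, (20, 60), seed=seed)
            edges = set(zip(net.source, net.target))
            labels = [("H", g) in truth for g in candidates]
            scores = [("H", g) in edges for g in candidates]
            from sklearn.metrics import roc_auc_score

            aurocs.append(roc_auc_score(labels, scores))
        assert np.mean(aurocs) == pytest.approx(0.5, abs=0.05)


class TestAssignDrivers:
    def _activity(self, shift):
        rng = np.random.default_rng(8)
        labels = np.repeat(["x", "y", "z"], 30)
        A = rng.normal(size=(2, 90))
        A[0, labels == "y"] += shift
        return pd.DataFrame(A, index=["D1", "D2"]), labels

    def test_shifted_driver_assigned(self):
        act, labels = self._activity(3.0)
        assignment, tpr = assign_drivers(act, labels,
                                         known_truth={"D1": "y"})
        assert assignment["D1"] == "y"
        assert tpr == 1.0

    def test_flat_driver_unassigned(self):
        act, labels = self._activity(3.0)
        assignment, _ = assign_drivers(act, labels, known_truth={})
        assert "D2" not in assignment

    def test_tpr_ratio(self):
        act, labels = self._activity(3.0)
        _, tpr = assign_drivers(act, labels,
                                known_truth={"D1": "y", "D2": "x"})
        assert tpr == pytest.approx(0.5)

    def test_small_cell_type_errors(self):
        act = pd.DataFrame(np.ones((1, 3)), index=["D"])
        with pytest.raises(ValueError):
            assign_drivers(act, ["a", "a", "b"])
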