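"""Clustering and network evaluation metrics.

Clustering: ARI / AMI / NMI, average silhouette width on a supplied
representation, size-weighted accuracy (major predicted label per true
cluster) and purity (major true label per predicted cluster), and AvgBIO —
the mean of ARI, NMI and the [0, 1]-rescaled ASW.

Networks: early precision (and its ratio against the analytic
random-network baseline), rank-based AUROC / step-interpolated AUPRC,
unweighted KS-style gene-set enrichment with Fisher combination of the
positive- and negative-target p-values, uniform random networks as a null,
and activity-based driver-to-cell-type assignment with all-pairwise
one-tailed t-tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn import metrics as skm

__all__ = [
    "clustering_scores",
    "early_precision",
    "roc_prc",
    "gsea_ks",
    "fisher_combine",
    "random_network",
    "assign_drivers",
    "ClusteringScore",
]


@dataclass
class ClusteringScore:
    ari: float
    ami: float
    nmi: float
    asw: float
    accuracy_score: float
    purity_score: float
    avgbio: float


def _confusion_weighted_max(labels_a, labels_b) -> float:
    """Size-weighted mean over a-clusters of the majority fraction of b labels."""
    labels_a, labels_b = np.asarray(labels_a), np.asarray(labels_b)
    n = labels_a.size
    total = 0.0
    for a in pd.unique(labels_a):
        mask = labels_a == a
        counts = pd.Series(labels_b[mask]).value_counts()
        total += (mask.sum() / n) * (counts.iloc[0] / mask.sum())
    return total


def clustering_scores(pred, truth, representation=None) -> ClusteringScore:
    """All clustering metrics for predicted vs true labels.

    ``representation`` (cells x d) is required for the silhouette (ASW);
    without it ASW and AvgBIO are NaN.
    """
    pred, truth = np.asarray(pred), np.asarray(truth)
    if pred.size != truth.size:
        raise ValueError("label vectors differ in length")
    ari = skm.adjusted_rand_score(truth, pred)
    ami = skm.adjusted_mutual_info_score(truth, pred)
    nmi = skm.normalized_mutual_info_score(truth, pred)
    accuracy = _confusion_weighted_max(truth, pred)
    purity = _confusion_weighted_max(pred, truth)
    if representation is not None and len(np.unique(pred)) > 1:
        asw = float(skm.silhouette_score(np.asarray(representation), pred))
        avgbio = float(np.mean([ari, nmi, (asw + 1) / 2]))
    else:
        asw = float("nan")
        avgbio = float("nan")
    return ClusteringScore(ari=float(ari), ami=float(ami), nmi=float(nmi),
                           asw=asw, accuracy_score=float(accuracy),
                           purity_score=float(purity), avgbio=avgbio)


def early_precision(ranked_edges, truth_edges, k: int,
                    n_candidates: int | None = None) -> tuple[float, float]:
    """Early precision of the top-k ranked edges and its random-network ratio.

    ``ep`` is the fraction of the top-k edges found in ``truth_edges``;
    ``epr`` divides it by the expected precision of a random ranking,
    ``|truth| / n_candidates`` (``n_candidates`` defaults to the ranked
    list's length).
    """
    ranked_edges = list(ranked_edges)
    truth_edges = set(truth_edges)
    if not truth_edges:
        raise ValueError("empty ground-truth edge set")
    if k > len(ranked_edges):
        raise ValueError("k exceeds the ranked list")
    ep = sum(1 for e in ranked_edges[:k] if e in truth_edges) / k
    n_candidates = n_candidates or len(ranked_edges)
    baseline = len(truth_edges) / n_candidates
    return float(ep), float(ep / baseline)


def roc_prc(scores, labels):
    """Rank-based AUROC and step-interpolated AUPRC with both curves.

    Returns ``(auroc, auprc, curves)`` where curves holds the ROC
    (fpr, tpr) and precision-recall (precision, recall) points.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    if len(np.unique(labels)) < 2:
        raise ValueError("need both classes present")
    auroc = float(skm.roc_auc_score(labels, scores))
    auprc = float(skm.average_precision_score(labels, scores))
    fpr, tpr, _ = skm.roc_curve(labels, scores)
    prec, rec, _ = skm.precision_recall_curve(labels, scores)
    return auroc, auprc, {"roc": (fpr, tpr), "prc": (prec, rec)}


def gsea_ks(target_set, ranking) -> tuple[float, float]:
    """Unweighted (KS-style) gene-set enrichment of targets in a ranking.

    ``ranking`` maps feature -> statistic (e.g. log2FC); features are sorted
    in decreasing order. The enrichment score is the signed maximum deviation
    of the running sum (hits step up by 1/n_targets, every position steps
    down by 1/n_total) — the KS statistic of the target ranks against
    uniform. The p-value is a two-sample KS test between target and
    non-target statistic values.
    """
    if isinstance(ranking, dict):
        ranking = pd.Series(ranking)
    ranking = ranking.sort_values(ascending=False)
    targets = set(target_set) & set(ranking.index)
    if not targets:
        raise ValueError("no target present in the ranking")
    n = len(ranking)
    n_hit = len(targets)
    if n_hit == n:
        raise ValueError("all ranked features are targets")
    is_hit = np.array([f in targets for f in ranking.index])
    running = np.cumsum(np.where(is_hit, 1.0 / n_hit, 0.0)) - \
        np.arange(1, n + 1) / n
    es = running[np.argmax(np.abs(running))]
    ks = stats.ks_2samp(ranking[is_hit].to_numpy(),
                        ranking[~is_hit].to_numpy())
    return float(es), float(ks.pvalue)


def fisher_combine(p1: float, p2: float) -> float:
    """Fisher's method for two p-values: chi-square with 4 df on -2*sum(ln p)."""
    for p in (p1, p2):
        if not 0 < p <= 1:
            raise ValueError("p-values must be in (0, 1]")
    x = -2.0 * (np.log(p1) + np.log(p2))
    return float(stats.chi2.sf(x, df=4))


def random_network(hubs, candidate_targets, size_range: tuple,
                   seed: int = 0) -> pd.DataFrame:
    """Null network: per hub, a uniform regulon size and random targets."""
    lo, hi = size_range
    candidates = list(candidate_targets)
    if hi > len(candidates):
        raise ValueError("size_range exceeds the candidate pool")
    rng = np.random.default_rng(seed)
    rows = []
    for h in hubs:
        size = int(rng.integers(lo, hi + 1))
        for t in rng.choice(len(candidates), size=size, replace=False):
            rows.append((h, candidates[t]))
    return pd.DataFrame(rows, columns=["source", "target"])


def assign_drivers(activity: pd.DataFrame, labels, alpha: float = 1e-4,
                   known_truth: dict | None = None):
    """Assign each driver to the cell type where its activity dominates.

    For every driver and cell type, one-tailed Welch t-tests ("activity is
    greater in this type") against every other type; the driver is assigned
    iff all pairwise p-values fall below ``alpha``. With ``known_truth``
    (driver -> true type) the true positive rate of the assignment is
    returned as well.
    """
    labels = np.asarray(labels)
    types = pd.unique(labels)
    if len(types) < 2:
        raise ValueError("need at least 2 cell types")
    for t in types:
        if (labels == t).sum() < 2:
            raise ValueError(f"cell type {t!r} has fewer than 2 cells")
    A = activity.to_numpy(dtype=float)
    assignment: dict = {}
    for di, driver in enumerate(activity.index):
        for t in types:
            ok = True
            a = A[di, labels == t]
            for other in types:
                if other == t:
                    continue
                b = A[di, labels == other]
                p = stats.ttest_ind(a, b, equal_var=False,
                                    alternative="greater").pvalue
                if not p < alpha:
                    ok = False
                    break
            if ok:
                assignment[driver] = t
                break
    if known_truth is None:
        return assignment, None
    hits = sum(1 for d, t in known_truth.items() if assignment.get(d) == t)
    tpr = hits / len(known_truth) if known_truth else float("nan")
    return assignment, float(tpr)
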