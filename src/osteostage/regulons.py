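"""Regulatory-influence inference and TF-TF network construction.

Starting from z-scored expression profiles of the response genes, the
up- and downregulated sets are each partitioned by agglomerative
clustering with the cluster number selected by consensus over three
internal quality indices. Clusters are probed for enrichment of prior
regulator target sets (hypergeometric tests, BH-corrected), enriched
gene sets sharing a regulator are merged, and a candidate is retained as
a *regulon* only if the regulator's own expression profile correlates
(Pearson r above a threshold) with the mean profile of its targets.
Regulon activity per condition is the mean target z-score; its temporal
profile is classified as an up-, down- or transient switch. Finally a
directed TF-TF influence network links each retained regulator to the
transcription factors among its targets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import networkx as nx
from scipy.stats import hypergeom, rankdata
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.cluster import AgglomerativeClustering
from sklearn.metrics import (calinski_harabasz_score, davies_bouldin_score,
                             silhouette_score)
from sklearn.utils.validation import check_is_fitted
from statsmodels.stats.multitest import multipletests

__all__ = [
    "Regulon", "ClusterQuality", "ConsensusKAgglomerative",
    "RegulonInference", "zscore_genes", "cluster_quality_scores",
    "select_partition", "hypergeom_pvalue", "bh_adjust", "infer_regulons",
    "classify_switch", "build_tf_network", "name_regulon",
]


def zscore_genes(expression: pd.DataFrame):
    """Per-gene z-scores across conditions.

    Each row is standardized to mean 0 and unit sample SD (ddof=1).
    Zero-variance genes cannot be standardized; they are dropped from the
    returned matrix and reported separately.

    Returns ``(z, degenerate)`` where ``degenerate`` is the Index of
    excluded constant genes.
    """
    if expression.shape[1] < 2:
        raise ValueError("z-scoring requires >= 2 conditions")
    values = expression.to_numpy(dtype=float)
    mean = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, ddof=1, keepdims=True)
    degenerate = expression.index[(sd == 0).ravel()]
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (values - mean) / sd
    zdf = pd.DataFrame(z, index=expression.index, columns=expression.columns)
    return zdf.drop(index=degenerate), degenerate


@dataclass
class ClusterQuality:
    silhouette: float
    calinski_harabasz: float
    davies_bouldin: float


def cluster_quality_scores(X, labels) -> ClusterQuality:
    """Silhouette, Calinski-Harabasz and Davies-Bouldin for one partition."""
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("quality scores require k >= 2 clusters")
    return ClusterQuality(
        silhouette=float(silhouette_score(X, labels, metric="euclidean")),
        calinski_harabasz=float(calinski_harabasz_score(X, labels)),
        davies_bouldin=float(davies_bouldin_score(X, labels)),
    )


class ConsensusKAgglomerative(ClusterMixin, BaseEstimator):
    """Agglomerative clustering with consensus selection of k.

    Ward-linkage agglomerative clustering is run for every candidate k in
    ``[k_min, k_max]``; each partition is scored by silhouette (higher
    better), Calinski-Harabasz (higher better) and Davies-Bouldin (lower
    better). The k with the best (lowest) mean rank across the three
    indices wins; ties break toward the smallest k.

    Attributes
    ----------
    k_ : selected number of clusters.
    labels_ : cluster labels under the selected k.
    scores_ : DataFrame of the three indices and mean rank per candidate k.
    """

    def __init__(self, k_min: int = 3, k_max: int | None = None,
                 linkage: str = "ward"):
        self.k_min = k_min
        self.k_max = k_max
        self.linkage = linkage

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        n = X.shape[0]
        k_max = self.k_max if self.k_max is not None else min(114, n - 1)
        k_max = min(k_max, n - 1)
        if n < self.k_min + 1:
            raise ValueError(
                f"need at least k_min + 1 = {self.k_min + 1} samples, got {n}"
            )
        ks = list(range(self.k_min, k_max + 1))
        rows, labelings = [], {}
        for k in ks:
            labels = AgglomerativeClustering(
                n_clusters=k, linkage=self.linkage
            ).fit_predict(X)
            q = cluster_quality_scores(X, labels)
            labelings[k] = labels
            rows.append((k, q.silhouette, q.calinski_harabasz,
                         q.davies_bouldin))
        scores = pd.DataFrame(
            rows, columns=["k", "silhouette", "calinski_harabasz",
                           "davies_bouldin"]
        ).set_index("k")
        # lower rank = better partition under each index
        ranks = np.column_stack([
            rankdata(-scores["silhouette"]),
            rankdata(-scores["calinski_harabasz"]),
            rankdata(scores["davies_bouldin"]),
        ])
        scores["mean_rank"] = ranks.mean(axis=1)
        best = scores["mean_rank"].idxmin()  # idxmin takes the smallest k on ties
        self.k_ = int(best)
        self.labels_ = labelings[self.k_]
        self.scores_ = scores
        self.n_features_in_ = X.shape[1]
        return self


def select_partition(z: pd.DataFrame, k_min: int = 3,
                     k_max: int | None = None) -> dict:
    """Cluster genes and return ``{gene: cluster_id}`` for the consensus k."""
    est = ConsensusKAgglomerative(k_min=k_min, k_max=k_max).fit(z.to_numpy())
    return dict(zip(z.index, est.labels_))


def hypergeom_pvalue(N: int, K: int, n: int, k: int) -> float:
    """Upper-tail hypergeometric P(X >= k) for overlap k of a size-n draw
    from a population of N containing K successes."""
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError("require K <= N and n <= N")
    if not 0 <= k <= min(K, n):
        raise ValueError("require 0 <= k <= min(K, n)")
    return float(hypergeom.sf(k - 1, N, K, n))


def bh_adjust(pvalues, alpha: float = 0.1):
    """Benjamini-Hochberg step-up adjustment.

    Returns ``(adjusted, significant)`` where ``significant`` flags
    adjusted p-values <= alpha.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    _, adjusted, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    return adjusted, adjusted <= alpha


def classify_switch(activity, delta: float = 0.5) -> str:
    """Classify a temporal activity profile as up, down, transient or flat.

    ``up``/``down`` if the last time point exceeds/undershoots the first
    by more than ``delta`` (z-units); otherwise ``transient`` if an
    interior maximum exceeds both endpoints by more than ``delta``;
    ``flat`` if none of the rules fire.
    """
    a = np.asarray(activity, dtype=float)
    if a.size < 3:
        raise ValueError("switch classification requires >= 3 time points")
    span = a[-1] - a[0]
    if span > delta:
        return "up"
    if span < -delta:
        return "down"
    interior = a[1:-1].max()
    if interior > a[0] + delta and interior > a[-1] + delta:
        return "transient"
    return "flat"


def name_regulon(regulator: str, n_targets: int) -> str:
    """Regulon identifier ``<regulator>.<n_targets>`` (e.g. ``E2F8.123``)."""
    if not regulator:
        raise ValueError("regulator name must be non-empty")
    if n_targets < 1:
        raise ValueError("a regulon needs at least one target")
    return f"{regulator}.{n_targets}"


@dataclass
class Regulon:
    """A regulator with its gated target set and activity profile."""

    regulator: str
    targets: list
    correlation: float
    activity: pd.Series            # per condition (time x donor)
    activity_by_time: pd.Series    # donor-averaged per time point
    direction: str
    name: str = field(init=False)

    def __post_init__(self) -> None:
        self.name = name_regulon(self.regulator, len(self.targets))


class RegulonInference(BaseEstimator):
    """End-to-end regulon inference over z-scored response-gene profiles.

    Parameters
    ----------
    r_threshold : Pearson correlation gate between a regulator's profile
        and its targets' mean profile (candidates at or below are dropped;
        negative correlates are excluded, matching the positive gate).
    alpha : BH significance level for the enrichment tests.
    k_min, k_max : candidate cluster-number range per direction.
    delta : z-unit threshold of the switch classifier.
    keep_repressors : if True, candidates with r < -r_threshold are kept
        and flagged instead of discarded.

    ``fit(z, response, prior, times=...)`` takes the full z-score matrix
    (genes x conditions; must include regulator rows), a
    :class:`~osteostage.filtering.ResponseGeneSet` (or any object with
    ``up``/``down`` gene lists), and a mapping ``regulator -> target set``.
    ``times`` assigns a time point to every condition column (defaults to
    the text before the first ``_`` in each column label).

    Attributes
    ----------
    regulons_ : list of retained :class:`Regulon`.
    partitions_ : per-direction ``{gene: cluster}`` maps.
    selected_k_ : per-direction selected cluster count.
    enrichment_ : DataFrame of all hypergeometric tests with BH columns.
    """

    def __init__(self, r_threshold: float = 0.8, alpha: float = 0.1,
                 k_min: int = 3, k_max: int | None = None,
                 delta: float = 0.5, keep_repressors: bool = False):
        self.r_threshold = r_threshold
        self.alpha = alpha
        self.k_min = k_min
        self.k_max = k_max
        self.delta = delta
        self.keep_repressors = keep_repressors

    def _condition_times(self, columns, times):
        if times is not None:
            return list(times)
        return [str(c).split("_")[0] for c in columns]

    def fit(self, z: pd.DataFrame, response, prior: dict, times=None):
        cond_times = self._condition_times(z.columns, times)
        if len(cond_times) != z.shape[1]:
            raise ValueError("times must match the number of conditions")
        self.partitions_ = {}
        self.selected_k_ = {}
        tests = []
        candidates: dict[str, set] = {}
        for direction, genes in (("up", list(response.up)),
                                 ("down", list(response.down))):
            genes = [g for g in genes if g in z.index]
            if len(genes) < self.k_min + 1:
                warnings.warn(
                    f"{direction}: only {len(genes)} genes, skipping direction"
                )
                continue
            sub = z.loc[genes]
            est = ConsensusKAgglomerative(
                k_min=self.k_min, k_max=self.k_max
            ).fit(sub.to_numpy())
            partition = dict(zip(sub.index, est.labels_))
            self.partitions_[direction] = partition
            self.selected_k_[direction] = est.k_
            population = set(genes)
            N = len(population)
            clusters: dict[int, set] = {}
            for g, c in partition.items():
                clusters.setdefault(c, set()).add(g)
            dir_tests = []
            for regulator, targets in prior.items():
                K_set = set(targets) & population
                if not K_set:
                    continue
                for c, members in sorted(clusters.items()):
                    overlap = members & K_set
                    p = hypergeom_pvalue(N, len(K_set), len(members),
                                         len(overlap))
                    dir_tests.append({
                        "direction": direction, "regulator": regulator,
                        "cluster": c, "N": N, "K": len(K_set),
                        "n": len(members), "k": len(overlap), "pvalue": p,
                        "overlap": overlap,
                    })
            if not dir_tests:
                continue
            # BH family: all cluster x regulator tests within one direction
            adj, sig = bh_adjust([t["pvalue"] for t in dir_tests], self.alpha)
            for t, a, s in zip(dir_tests, adj, sig):
                t["adj_pvalue"], t["significant"] = float(a), bool(s)
                if s and t["k"] > 0:
                    candidates.setdefault(t["regulator"], set()).update(
                        t["overlap"]
                    )
            tests.extend(dir_tests)
        self.enrichment_ = pd.DataFrame(
            [{k: v for k, v in t.items() if k != "overlap"} for t in tests]
        )

        time_index = pd.Index(cond_times)
        regulons = []
        for regulator, targets in sorted(candidates.items()):
            targets = targets - {regulator}
            if not targets:
                continue
            if regulator not in z.index:
                warnings.warn(
                    f"regulator {regulator} absent from expression matrix; "
                    "candidate dropped"
                )
                continue
            target_list = sorted(targets)
            mean_profile = z.loc[target_list].mean(axis=0)
            r = float(np.corrcoef(z.loc[regulator].to_numpy(),
                                  mean_profile.to_numpy())[0, 1])
            keep = r > self.r_threshold or (
                self.keep_repressors and r < -self.r_threshold
            )
            if not keep:
                continue
            activity = mean_profile
            by_time = activity.groupby(time_index).mean()
            # preserve temporal order of appearance of the condition labels
            order = list(dict.fromkeys(cond_times))
            by_time = by_time.reindex(order)
            direction = classify_switch(by_time.to_numpy(), self.delta)
            regulons.append(Regulon(
                regulator=regulator, targets=target_list, correlation=r,
                activity=activity, activity_by_time=by_time,
                direction=direction,
            ))
        assert all(
            abs(r.correlation) > self.r_threshold for r in regulons
        ), "retained regulon violates the correlation gate"
        self.regulons_ = regulons
        return self

    def activity_table(self) -> pd.DataFrame:
        check_is_fitted(self, "regulons_")
        return pd.DataFrame({r.name: r.activity for r in self.regulons_}).T


def infer_regulons(z: pd.DataFrame, response, prior: dict,
                   r_threshold: float = 0.8, alpha: float = 0.1,
                   times=None, k_min: int = 3,
                   k_max: int | None = None) -> list:
    """Functional wrapper over :class:`RegulonInference`; returns the regulons."""
    est = RegulonInference(r_threshold=r_threshold, alpha=alpha,
                           k_min=k_min, k_max=k_max)
    est.fit(z, response, prior, times=times)
    return est.regulons_


def build_tf_network(regulons, tf_list) -> nx.DiGraph:
    """Directed regulator -> TF influence graph from retained regulons.

    An edge A -> B exists iff B is a target of A's regulon and B is a
    transcription factor. Regulator nodes carry their regulon size
    (``n_targets``) and switch direction; an empty network is valid.
    """
    tfs = set(tf_list)
    G = nx.DiGraph()
    for reg in regulons:
        tf_targets = [t for t in reg.targets if t in tfs]
        if not tf_targets and reg.regulator not in tfs:
            continue
        G.add_node(reg.regulator, n_targets=len(reg.targets),
                   direction=reg.direction)
        for t in tf_targets:
            if t not in G:
                G.add_node(t)
            G.add_edge(reg.regulator, t)
    return G
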