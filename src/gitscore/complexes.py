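"""Co-functional module discovery from score profiles.

Genes with similar score profiles across compounds tend to act in the same
complex or pathway: compounds hitting a complex perturb all of its members
coherently.  We cluster genes by k-means on their per-compound scores and
test each cluster for over-representation of annotated gene sets with a
one-sided Fisher's exact test (hypergeometric upper tail), controlling the
false discovery rate across all (cluster, set) pairs by Benjamini-Hochberg.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans
from statsmodels.stats.multitest import multipletests

from .screen_io import GeneSetCollection
from .scoring import ScoreMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "ClusterAssignment",
    "EnrichmentResult",
    "cluster_genes",
    "enrich",
    "enriched_cluster_counts",
]


@dataclass
class ClusterAssignment:
    """Gene -> cluster id (1-based) from k-means on score profiles."""

    labels: pd.Series
    n_clusters: int
    rng_seed: int
    feature_desc: str = ""

    def members(self, cluster: int) -> set[str]:
        return set(self.labels.index[self.labels == cluster])

    @property
    def clusters(self) -> list[int]:
        return list(range(1, self.n_clusters + 1))

    def empty_clusters(self) -> list[int]:
        present = set(self.labels)
        return [c for c in self.clusters if c not in present]


@dataclass
class EnrichmentResult:
    """Per (cluster, gene set) Fisher tests with BH-adjusted q-values.

    ``table`` columns: cluster, gene_set, a (in cluster & in set), b (in
    cluster only), c (in set only), d (neither), p, q, enriched.
    """

    table: pd.DataFrame
    fdr_threshold: float
    universe_size: int

    def enriched_clusters(self, fdr: float | None = None) -> set[int]:
        fdr = self.fdr_threshold if fdr is None else fdr
        hit = self.table[self.table["q"] <= fdr]
        return set(hit["cluster"])


def cluster_genes(
    scores: ScoreMatrix,
    n_clusters: int,
    rng_seed: int = 0,
    missing_fill: float = 0.0,
    standardize: bool = False,
) -> ClusterAssignment:
    """k-means cluster genes on their per-compound score profiles.

    All-missing compound columns are dropped with a warning; remaining
    missing entries are imputed with ``missing_fill`` before clustering.
    ``standardize`` optionally z-scores each compound column first.
    """
    df = scores.scores
    if n_clusters > len(df.index):
        raise ValueError("n_clusters cannot exceed the number of genes")
    all_missing = df.isna().all(axis=0)
    if all_missing.any():
        logger.warning(
            "dropping %d all-missing compound column(s) from features",
            int(all_missing.sum()),
        )
        df = df.loc[:, ~all_missing]
    if standardize:
        df = (df - df.mean(axis=0)) / df.std(axis=0, ddof=1)
    X = df.fillna(missing_fill).to_numpy()
    km = KMeans(n_clusters=n_clusters, random_state=rng_seed, n_init=10)
    labels = km.fit_predict(X) + 1  # 1-based cluster ids
    assign = ClusterAssignment(
        labels=pd.Series(labels, index=df.index, dtype=int),
        n_clusters=n_clusters,
        rng_seed=rng_seed,
        feature_desc=f"{scores.method} scores over {df.shape[1]} compounds",
    )
    if assign.empty_clusters():
        logger.warning("%d empty cluster(s)", len(assign.empty_clusters()))
    return assign


def _fisher_upper(a: int, b: int, c: int, d: int) -> float:
    # one-sided (enrichment) Fisher's exact test = hypergeometric upper tail
    return float(stats.fisher_exact([[a, b], [c, d]], alternative="greater")[1])


def enrich(
    assign: ClusterAssignment,
    sets: GeneSetCollection,
    universe: set[str] | None = None,
    fdr_threshold: float = 0.005,
) -> EnrichmentResult:
    """Test every (cluster, gene set) pair for enrichment.

    The universe defaults to the clustered genes; gene sets are intersected
    with the universe and empty intersections are skipped.  q-values come
    from Benjamini-Hochberg across all tested pairs.
    """
    if universe is None:
        universe = set(assign.labels.index)
    else:
        universe = set(universe)
    if not universe:
        raise ValueError("empty enrichment universe")
    n_u = len(universe)
    rows = []
    for cluster in assign.clusters:
        members = assign.members(cluster) & universe
        if not members:
            continue
        for name in sets.names():
            in_set = sets[name] & universe
            if not in_set:
                continue
            a = len(members & in_set)
            b = len(members) - a
            c = len(in_set) - a
            d = n_u - a - b - c
            rows.append((cluster, name, a, b, c, d, _fisher_upper(a, b, c, d)))
    table = pd.DataFrame(
        rows, columns=["cluster", "gene_set", "a", "b", "c", "d", "p"]
    )
    if len(table):
        table["q"] = multipletests(table["p"].to_numpy(), method="fdr_bh")[1]
    else:
        table["q"] = pd.Series(dtype=float)
    table["enriched"] = table["q"] <= fdr_threshold
    return EnrichmentResult(table, fdr_threshold, n_u)


def enriched_cluster_counts(result: EnrichmentResult, r_grid) -> pd.DataFrame:
    """Number of clusters with >=1 enriched set at each FDR threshold.

    This is the curve used to compare methods on module discovery: a better
    score matrix groups more genes into annotatable complexes at a stringent
    threshold.  Counts are non-decreasing in the threshold.
    """
    rows = [
        (float(r), len(result.enriched_clusters(float(r)))) for r in r_grid
    ]
    return pd.DataFrame(rows, columns=["fdr_threshold", "n_enriched_clusters"])
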