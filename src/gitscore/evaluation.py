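"""Ranking, top-k recovery curves, nAUC, and the random-network test.

A scoring method is judged by how early it recovers known compound-target
pairs when genes are ranked per compound: counts_t(k) is the number of
benchmark pairs whose target ranks in the top k, counts_d(k) the number of
compounds with at least one target in the top k.  The area under either
curve, normalized by a reference method's area (by default the raw
FD-score), gives the nAUC; values above 1 mean the method beats the
reference.  Statistical significance of a network-assisted score is
assessed against signed-degree-preserving random networks: the empirical
p-value is the add-one-smoothed fraction of random networks that do at
least as well.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

from . import ginet, scoring
from .ginet import GINetwork
from .screen_io import BenchmarkSet, FitnessMatrix
from .scoring import ScoreMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "RankTable",
    "EvaluationCurve",
    "rank_genes",
    "recovery_curves",
    "auc_nauc",
    "empirical_pvalue",
]


@dataclass
class RankTable:
    """Per-compound 1-based gene ranks (best = 1) under a method's orientation."""

    ranks: pd.DataFrame  # genes x compounds, int ranks
    n_scored: pd.Series  # finite scores per compound
    method: str = ""

    @property
    def gene_ids(self) -> list[str]:
        return list(self.ranks.index)

    @property
    def compound_ids(self) -> list[str]:
        return list(self.ranks.columns)


@dataclass
class EvaluationCurve:
    """Recovery counts over the top-k grid plus bookkeeping."""

    k: np.ndarray
    counts_t: np.ndarray  # benchmark pairs recovered in top k
    counts_d: np.ndarray  # compounds with >=1 target in top k
    n_pairs: int
    n_compounds: int
    n_excluded_pairs: int = 0
    method: str = ""

    def counts(self, criterion: str = "interactions") -> np.ndarray:
        if criterion == "interactions":
            return self.counts_t
        if criterion == "drugs":
            return self.counts_d
        raise ValueError(f"unknown criterion {criterion!r}")


def rank_genes(scores: ScoreMatrix) -> RankTable:
    """Rank genes best-to-worst per compound.

    Low-is-hit methods sort ascending, high-is-hit descending.  Ties are
    broken by lexicographic gene id; genes with missing scores are placed
    after all finite scores.  Compounds with no finite score are omitted
    with a warning.
    """
    df = scores.scores
    genes = np.array(df.index, dtype=object)
    keep_cols = []
    rank_cols = {}
    n_scored = {}
    for comp in df.columns:
        col = df[comp].to_numpy(dtype=float)
        finite = np.isfinite(col)
        if not finite.any():
            logger.warning("compound %s has no finite score; omitted from ranking", comp)
            continue
        key = col if scores.orientation == scoring.LOW_IS_HIT else -col
        key = np.where(finite, key, np.inf)
        order = np.lexsort((genes, key))
        ranks = np.empty(len(genes), dtype=int)
        ranks[order] = np.arange(1, len(genes) + 1)
        keep_cols.append(comp)
        rank_cols[comp] = ranks
        n_scored[comp] = int(finite.sum())
    rank_df = pd.DataFrame(rank_cols, index=df.index)[keep_cols]
    return RankTable(rank_df, pd.Series(n_scored, dtype=int), method=scores.method)


def recovery_curves(
    ranks: RankTable, bench: BenchmarkSet, K: int | None = None
) -> EvaluationCurve:
    """Count benchmark recoveries in the top k for k = 1..K.

    Benchmark pairs whose gene or compound is absent from the ranked
    universe are excluded from the denominator (and counted in
    ``n_excluded_pairs``).  K defaults to the full gene universe.
    """
    n_genes = len(ranks.gene_ids)
    if K is None:
        K = n_genes
    if K < 1 or K > n_genes:
        raise ValueError(f"K must be in 1..{n_genes}")
    gene_set = set(ranks.gene_ids)
    comp_set = set(ranks.compound_ids)
    pair_ranks: list[int] = []
    per_comp_best: dict[str, int] = {}
    n_excluded = 0
    for row in ranks_pairs(bench):
        comp, gene = row
        if comp not in comp_set or gene not in gene_set:
            n_excluded += 1
            continue
        r = int(ranks.ranks.loc[gene, comp])
        pair_ranks.append(r)
        per_comp_best[comp] = min(per_comp_best.get(comp, r), r)
    if not pair_ranks:
        raise ValueError("benchmark has no pair within the scored universe")
    if n_excluded:
        logger.info("excluded %d benchmark pair(s) outside the scored universe", n_excluded)
    kgrid = np.arange(1, K + 1)
    counts_t = np.searchsorted(np.sort(pair_ranks), kgrid, side="right")
    best = np.sort(list(per_comp_best.values()))
    counts_d = np.searchsorted(best, kgrid, side="right")
    return EvaluationCurve(
        k=kgrid,
        counts_t=counts_t.astype(int),
        counts_d=counts_d.astype(int),
        n_pairs=len(pair_ranks),
        n_compounds=len(per_comp_best),
        n_excluded_pairs=n_excluded,
    )


def ranks_pairs(bench: BenchmarkSet):
    for _, row in bench.pairs.iterrows():
        yield row["compound"], row["gene"]


def auc_nauc(
    curve: EvaluationCurve,
    reference: EvaluationCurve,
    criterion: str = "interactions",
) -> tuple[float, float]:
    """Area under the top-k recovery curve and its ratio to a reference.

    The area is the sum of counts over the integer k grid (unit-width
    rectangles); any monotone-equivalent area definition rescales numerator
    and denominator alike, so the normalized value is insensitive to the
    convention.  The reference is conventionally the FD-score.
    """
    if len(curve.k) != len(reference.k) or curve.k[0] != reference.k[0]:
        raise ValueError("curve and reference must share the same k grid")
    auc = float(curve.counts(criterion).sum())
    auc_ref = float(reference.counts(criterion).sum())
    if auc_ref == 0:
        raise ValueError("reference AUC is zero; nAUC undefined")
    return auc, auc / auc_ref


METHODS: dict[str, Callable] = {
    "git_hip": lambda fd, nbh: scoring.git_hip(fd, nbh),
    "git_hop": lambda fd, nbh: scoring.git_hop(fd, nbh),
    "rho": lambda fd, nbh: scoring.rho(fd, nbh),
    "fd": lambda fd, nbh: scoring.as_fd_scores(fd),
}


def nauc_for_method(
    fd: FitnessMatrix,
    nbh,
    bench: BenchmarkSet,
    method: str,
    criterion: str = "interactions",
    K: int | None = None,
    reference_curve: EvaluationCurve | None = None,
) -> float:
    """Convenience: score -> rank -> curve -> nAUC against the FD reference."""
    if reference_curve is None:
        reference_curve = recovery_curves(
            rank_genes(scoring.as_fd_scores(fd)), bench, K=K
        )
    sm = METHODS[method](fd, nbh)
    curve = recovery_curves(rank_genes(sm), bench, K=K)
    return auc_nauc(curve, reference_curve, criterion)[1]


def empirical_pvalue(
    observed_nauc: float,
    fd: FitnessMatrix,
    net: GINetwork,
    bench: BenchmarkSet,
    method: str = "git_hip",
    n_random: int = 99,
    rng_seed: int = 0,
    q: int | None = 100,
    criterion: str = "interactions",
    K: int | None = None,
) -> tuple[float, np.ndarray]:
    """Random-network significance test for a network-assisted score.

    Rebuilds ``n_random`` signed-degree-preserving random networks, recomputes
    the method's nAUC on each, and returns the add-one empirical p-value
    p = (1 + #{random nAUC >= observed}) / (1 + n_random) together with the
    vector of random nAUCs.  Because every random network preserves each
    gene's positive/negative neighbor counts and incident weights, a small p
    shows the improvement comes from the neighbors' fitness values rather
    than from network degree alone.
    """
    if n_random < 1:
        raise ValueError("n_random must be >= 1")
    rng = np.random.default_rng(rng_seed)
    seeds = rng.integers(0, 2**31 - 1, size=n_random)
    reference_curve = recovery_curves(rank_genes(scoring.as_fd_scores(fd)), bench, K=K)
    random_naucs = np.empty(n_random)
    for i, s in enumerate(seeds):
        rnet = ginet.randomize(net, int(s))
        nbh = ginet.truncate(rnet, q)
        random_naucs[i] = nauc_for_method(
            fd, nbh, bench, method, criterion=criterion, K=K,
            reference_curve=reference_curve,
        )
    p = (1 + int((random_naucs >= observed_nauc).sum())) / (1 + n_random)
    return p, random_naucs
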