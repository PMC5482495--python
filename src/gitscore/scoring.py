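"""Target scores for HIP/HOP screens.

The one-hop score corrects a gene's own fitness defect by the signed,
weighted fitness defects of its genetic-interaction neighbors::

    GIT_hip[i, c] = FD[i, c] - sum_j FD[j, c] * g_ij

If an inhibited gene's positive neighbors grow well (high FD) and its
negative neighbors grow poorly (low FD), the subtraction drives the score
strongly negative — the signature of a direct target in a HIP assay.  For
HOP assays the sensitive strains buffer the target pathway rather than
carry the target, so the correction is applied twice (two hops)::

    GIT_hop[i, c] = FD[i, c] - sum_j GIT_first[j, c] * g_ij

with GIT_first identical to the one-hop score.  Both are instances of the
order-k recursion ``S_k = FD - G S_{k-1}``, ``S_0 = FD``, whose closed form
on complete data is ``sum_{m<=k} (-G)^m FD`` with the row-truncated
adjacency G.  Low GIT scores flag candidate targets; the rho baseline
(Pearson correlation of a gene's interaction profile with the compound's FD
profile over its neighbors) flags candidates with *high* scores instead.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ginet import TruncatedNeighborhood
from .screen_io import FitnessMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "ScoreMatrix",
    "ContributionReport",
    "git_hip",
    "git_first",
    "git_hop",
    "git_k",
    "rho",
    "combine_hip_hop",
    "explain",
]

LOW_IS_HIT = "low_is_hit"
HIGH_IS_HIT = "high_is_hit"


@dataclass
class ScoreMatrix:
    """Genes x compounds scores with a hit orientation and a method tag."""

    scores: pd.DataFrame
    orientation: str
    method: str

    def __post_init__(self) -> None:
        if self.orientation not in (LOW_IS_HIT, HIGH_IS_HIT):
            raise ValueError(f"unknown orientation {self.orientation!r}")
        self.scores = self.scores.astype(float)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.scores.index)

    @property
    def compound_ids(self) -> list[str]:
        return list(self.scores.columns)


@dataclass
class ContributionReport:
    """Decomposition of one (gene, compound) GIT score into neighbor terms.

    ``terms`` rows are (neighbor, g_ij, neighbor score used, product); the
    reconstruction identity own_fd - sum(products) == score holds to
    numerical tolerance.
    """

    gene: str
    compound: str
    method: str
    own_fd: float
    terms: list[tuple[str, float, float, float]]
    score: float


def _g_matrix(fd: FitnessMatrix, nbh: TruncatedNeighborhood):
    gene_index = {g: i for i, g in enumerate(fd.gene_ids)}
    return nbh.to_sparse(gene_index)


def as_fd_scores(fd: FitnessMatrix) -> ScoreMatrix:
    """Wrap the raw FD matrix as a low-is-hit score (the baseline method)."""
    return ScoreMatrix(fd.fd.copy(), LOW_IS_HIT, "fd")


def git_k(fd: FitnessMatrix, nbh: TruncatedNeighborhood, k: int) -> ScoreMatrix:
    """Order-k network-corrected score: S_k = FD - G @ S_{k-1}, S_0 = FD.

    Missing neighbor scores contribute 0 to the correction sum; a missing
    own FD yields a missing score.  k=1 is the one-hop (HIP) score, k=2 the
    two-hop (HOP) score.
    """
    if k < 0:
        raise ValueError("k must be >= 0")
    if k == 0:
        logger.warning("git_k with k=0 returns the FD-score unchanged")
        return ScoreMatrix(fd.fd.copy(), LOW_IS_HIT, "git_k0")
    G = _g_matrix(fd, nbh)
    if G.nnz == 0:
        logger.warning("empty neighborhood structure: GIT score equals the FD-score")
    F = fd.fd.to_numpy()
    S = F
    for _ in range(k):
        S = F - G @ np.nan_to_num(S, nan=0.0)
    # missing own FD stays missing
    S = np.where(np.isnan(F), np.nan, S)
    out = pd.DataFrame(S, index=fd.gene_ids, columns=fd.compound_ids)
    return ScoreMatrix(out, LOW_IS_HIT, f"git_k{k}")


def git_hip(fd: FitnessMatrix, nbh: TruncatedNeighborhood) -> ScoreMatrix:
    """One-hop score for HIP assays (low score = candidate direct target)."""
    sm = git_k(fd, nbh, 1)
    return ScoreMatrix(sm.scores, LOW_IS_HIT, "git_hip")


def git_first(fd: FitnessMatrix, nbh: TruncatedNeighborhood) -> ScoreMatrix:
    """First-order score, the inner term of the two-hop recursion.

    Identical to :func:`git_hip`; kept as a named intermediate because the
    two-hop score corrects the FD by *these* values rather than raw FDs.
    """
    sm = git_k(fd, nbh, 1)
    return ScoreMatrix(sm.scores, LOW_IS_HIT, "git_first")


def git_hop(fd: FitnessMatrix, nbh: TruncatedNeighborhood) -> ScoreMatrix:
    """Two-hop score for HOP assays (captures the pathway-buffer effect)."""
    sm = git_k(fd, nbh, 2)
    return ScoreMatrix(sm.scores, LOW_IS_HIT, "git_hop")


def rho(fd: FitnessMatrix, nbh: TruncatedNeighborhood, min_pairs: int = 3) -> ScoreMatrix:
    """Pearson correlation between a gene's interaction profile and the
    compound's FD profile over that gene's retained neighbors.

    Neighbor/compound pairs with missing FD are excluded.  Fewer than
    ``min_pairs`` usable pairs, or zero variance on either side, yields a
    missing score.  High positive values flag candidate targets.
    """
    genes = fd.gene_ids
    gene_pos = {g: i for i, g in enumerate(genes)}
    F = fd.fd.to_numpy()
    n_comp = F.shape[1]
    out = np.full((len(genes), n_comp), np.nan)
    for gi, gene in enumerate(genes):
        nbrs = [(j, w) for j, w in nbh.neighbors.get(gene, []) if j in gene_pos]
        if len(nbrs) < min_pairs:
            continue
        idx = np.array([gene_pos[j] for j, _ in nbrs])
        w = np.array([wt for _, wt in nbrs])
        sub = F[idx, :]  # m x C
        valid = ~np.isnan(sub)
        n = valid.sum(axis=0)
        ok = n >= min_pairs
        if not ok.any():
            continue
        sub0 = np.where(valid, sub, 0.0)
        wcol = w[:, None] * valid
        with np.errstate(invalid="ignore", divide="ignore"):
            f_mean = sub0.sum(axis=0) / n
            w_mean = wcol.sum(axis=0) / n
            df = np.where(valid, sub0 - f_mean, 0.0)
            dw = np.where(valid, w[:, None] - w_mean, 0.0)
            num = (df * dw).sum(axis=0)
            den = np.sqrt((df * df).sum(axis=0) * (dw * dw).sum(axis=0))
            r = num / den
        r[~ok | (den <= 0) | ~np.isfinite(r)] = np.nan
        out[gi, :] = r
    df_out = pd.DataFrame(out, index=genes, columns=fd.compound_ids)
    return ScoreMatrix(df_out, HIGH_IS_HIT, "rho")


def zscore_columns(df: pd.DataFrame) -> pd.DataFrame:
    """Standardize each column to mean 0, sample (ddof=1) SD 1, NaN-aware."""
    mean = df.mean(axis=0, skipna=True)
    std = df.std(axis=0, ddof=1, skipna=True)
    return (df - mean) / std


def combine_hip_hop(
    hip_scores: ScoreMatrix,
    hop_scores: ScoreMatrix,
    gene_policy: str = "union",
) -> ScoreMatrix:
    """Average of per-compound z-scores of the HIP and HOP scores.

    Each input is standardized per compound across genes (mean 0, sample SD
    1, missing excluded) before averaging; the boosted score remains
    low-is-hit.  Under ``gene_policy='intersection'`` only genes scored in
    both assays are kept; under ``'union'`` a gene present in one assay
    receives that assay's z-score.
    """
    if hip_scores.orientation != LOW_IS_HIT or hop_scores.orientation != LOW_IS_HIT:
        raise ValueError("combine_hip_hop expects low-is-hit inputs")
    if gene_policy not in ("union", "intersection"):
        raise ValueError(f"unknown gene_policy {gene_policy!r}")
    z_hip = zscore_columns(hip_scores.scores)
    z_hop = zscore_columns(hop_scores.scores)
    if gene_policy == "intersection":
        genes = [g for g in z_hip.index if g in set(z_hop.index)]
    else:
        genes = list(dict.fromkeys(list(z_hip.index) + list(z_hop.index)))
    compounds = list(dict.fromkeys(list(z_hip.columns) + list(z_hop.columns)))
    only_hip = set(z_hip.columns) - set(z_hop.columns)
    only_hop = set(z_hop.columns) - set(z_hip.columns)
    for missing_side, comps in (("HOP", only_hip), ("HIP", only_hop)):
        if comps:
            logger.warning(
                "%d compound(s) absent from the %s assay scored from one assay only",
                len(comps), missing_side,
            )
    a = z_hip.reindex(index=genes, columns=compounds)
    b = z_hop.reindex(index=genes, columns=compounds)
    combined = pd.concat([a, b]).groupby(level=0).mean()
    combined = combined.reindex(index=genes, columns=compounds)
    return ScoreMatrix(combined, LOW_IS_HIT, "git_combined")


def explain(
    fd: FitnessMatrix,
    nbh: TruncatedNeighborhood,
    gene: str,
    compound: str,
    method: str = "hip",
) -> ContributionReport:
    """Decompose a gene/compound GIT score into per-neighbor contributions.

    For ``method='hip'`` the neighbor score used is the neighbor's FD; for
    ``method='hop'`` it is the neighbor's first-order GIT score.  Terms are
    sorted by absolute product, largest first.
    """
    if gene not in set(fd.gene_ids):
        raise KeyError(f"unknown gene {gene!r}")
    if compound not in set(fd.compound_ids):
        raise KeyError(f"unknown compound {compound!r}")
    if method not in ("hip", "hop"):
        raise ValueError(f"unknown method {method!r}")
    if method == "hip":
        nbr_scores = fd.fd
    else:
        nbr_scores = git_first(fd, nbh).scores
    own_fd = float(fd.fd.loc[gene, compound])
    gene_set = set(fd.gene_ids)
    terms = []
    for j, w in nbh.neighbors.get(gene, []):
        if j not in gene_set:
            continue
        s = nbr_scores.loc[j, compound]
        s = 0.0 if np.isnan(s) else float(s)
        terms.append((j, float(w), s, float(w) * s))
    terms.sort(key=lambda t: (-abs(t[3]), t[0]))
    score = own_fd - sum(t[3] for t in terms)
    return ContributionReport(gene, compound, method, own_fd, terms, score)
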