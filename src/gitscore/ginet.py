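"""The signed, weighted genetic-interaction network.

An edge weight is the deviation of the measured double-mutant fitness from
the multiplicative expectation of the two single-mutant fitnesses::

    g_ij = f_ij - f_i * f_j

Negative weights are aggravating interactions (extreme case: synthetic
lethality), positive weights are alleviating.  Scoring consumes the network
row-wise: for each gene we keep at most the top ``q`` positive neighbors by
weight and the top ``q`` negative neighbors by absolute weight.  The
degree-preserving randomization used for significance testing reassigns each
gene's neighbor slots to random other genes while keeping every incident
weight (and hence its sign), which yields a directed row-wise relation — it
is consumed exactly like the truncated neighborhoods.
"""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse

logger = logging.getLogger(__name__)

__all__ = [
    "FitnessProfiles",
    "GINetwork",
    "TruncatedNeighborhood",
    "build_network",
    "truncate",
    "randomize",
    "read_edges",
    "write_edges",
]


@dataclass
class FitnessProfiles:
    """Single- and double-mutant fitness values; doubles keyed on unordered pairs."""

    singles: dict[str, float]
    doubles: dict[tuple[str, str], float]

    def __post_init__(self) -> None:
        normalized: dict[tuple[str, str], float] = {}
        for (i, j), f in self.doubles.items():
            if i == j:
                raise ValueError(f"double-mutant pair with identical genes: {i}")
            key = (i, j) if i < j else (j, i)
            if key in normalized and not math.isclose(normalized[key], f):
                raise ValueError(f"conflicting double-mutant fitness for pair {key}")
            normalized[key] = float(f)
        self.doubles = normalized
        for g, f in self.singles.items():
            if not math.isfinite(f):
                raise ValueError(f"non-finite single-mutant fitness for {g}")


@dataclass
class GINetwork:
    """Gene-gene interaction network stored as per-gene neighbor maps.

    For an undirected network (``directed=False``) the adjacency is kept
    symmetric: ``adj[i][j] == adj[j][i]``.  Randomized networks are directed
    row-wise relations (``directed=True``) and are consumed per row, the same
    way truncated neighborhoods are.  ``signed=False`` marks unsigned
    (e.g. physical-interaction) networks whose weights are all positive.
    """

    adj: dict[str, dict[str, float]]
    signed: bool = True
    directed: bool = False

    def __post_init__(self) -> None:
        for i, nbrs in self.adj.items():
            if i in nbrs:
                raise ValueError(f"self-edge on gene {i}")
            for j, w in nbrs.items():
                if w == 0.0:
                    raise ValueError(f"zero-weight edge {i}-{j}")
                if not self.signed and w < 0:
                    raise ValueError(f"negative weight {w} in unsigned network ({i}-{j})")
        if not self.directed:
            for i, nbrs in self.adj.items():
                for j, w in nbrs.items():
                    if self.adj.get(j, {}).get(i) != w:
                        raise ValueError(f"asymmetric edge {i}-{j} in undirected network")

    @classmethod
    def from_edges(cls, edges, signed: bool = True) -> "GINetwork":
        """Build an undirected network from (i, j, weight) triples."""
        adj: dict[str, dict[str, float]] = {}
        for i, j, w in edges:
            if i == j:
                raise ValueError(f"self-edge on gene {i}")
            adj.setdefault(i, {})[j] = float(w)
            adj.setdefault(j, {})[i] = float(w)
        return cls(adj, signed=signed, directed=False)

    @property
    def genes(self) -> list[str]:
        return sorted(self.adj)

    @property
    def n_edges(self) -> int:
        total = sum(len(nbrs) for nbrs in self.adj.values())
        return total if self.directed else total // 2

    def neighbors(self, gene: str) -> dict[str, float]:
        return self.adj.get(gene, {})

    def degree(self, gene: str) -> int:
        return len(self.adj.get(gene, {}))

    def signed_degrees(self, gene: str) -> tuple[int, int]:
        """(positive-neighbor count, negative-neighbor count) of a gene's row."""
        nbrs = self.adj.get(gene, {})
        pos = sum(1 for w in nbrs.values() if w > 0)
        return pos, len(nbrs) - pos

    def edge_list(self) -> list[tuple[str, str, float]]:
        if self.directed:
            return sorted(
                (i, j, w) for i, nbrs in self.adj.items() for j, w in nbrs.items()
            )
        seen = []
        for i, nbrs in self.adj.items():
            for j, w in nbrs.items():
                if i < j:
                    seen.append((i, j, w))
        return sorted(seen)

    def to_networkx(self):
        """Export to a networkx graph (DiGraph when directed)."""
        import networkx as nx

        g = nx.DiGraph() if self.directed else nx.Graph()
        g.add_nodes_from(self.genes)
        for i, nbrs in self.adj.items():
            for j, w in nbrs.items():
                g.add_edge(i, j, weight=w)
        return g


@dataclass
class TruncatedNeighborhood:
    """Per-gene retained neighbors: top-q positive and top-q negative by |weight|."""

    neighbors: dict[str, list[tuple[str, float]]]
    q: int | None = None

    def to_sparse(self, gene_index: dict[str, int]) -> sparse.csr_matrix:
        """Row-truncated adjacency over a gene ordering (genes outside dropped)."""
        n = len(gene_index)
        rows, cols, vals = [], [], []
        for gene, nbrs in self.neighbors.items():
            i = gene_index.get(gene)
            if i is None:
                continue
            for j_gene, w in nbrs:
                j = gene_index.get(j_gene)
                if j is None:
                    continue
                rows.append(i)
                cols.append(j)
                vals.append(w)
        return sparse.csr_matrix((vals, (rows, cols)), shape=(n, n))


def build_network(profiles: FitnessProfiles, magnitude_cutoff: float = 0.0) -> GINetwork:
    """Derive interaction weights g_ij = f_ij - f_i*f_j from fitness tables.

    Pairs whose |g_ij| does not exceed ``magnitude_cutoff`` are dropped
    (with the default cutoff 0 this removes exactly the zero-interaction
    pairs, i.e. double mutants at the multiplicative expectation).
    """
    missing = sorted(
        {g for pair in profiles.doubles for g in pair if g not in profiles.singles}
    )
    if missing:
        raise ValueError(f"single-mutant fitness missing for genes: {missing}")
    edges = []
    for (i, j), f_ij in profiles.doubles.items():
        g = f_ij - profiles.singles[i] * profiles.singles[j]
        if abs(g) > magnitude_cutoff:
            edges.append((i, j, g))
    return GINetwork.from_edges(edges)


def _top_q(items: list[tuple[str, float]], q: int, key) -> list[tuple[str, float]]:
    # ties at the q-th slot broken toward the lexicographically smaller gene id
    return sorted(items, key=lambda t: (-key(t[1]), t[0]))[:q]


def truncate(net: GINetwork, q: int | None) -> TruncatedNeighborhood:
    """Keep, per gene, the top-q positive neighbors by weight and the top-q
    negative neighbors by absolute weight.

    Truncation is row-wise, so the retained relation may be asymmetric even
    on an undirected network.  ``q=None`` keeps everything.
    """
    if q is not None and q < 1:
        raise ValueError("q must be >= 1 (or None for no truncation)")
    out: dict[str, list[tuple[str, float]]] = {}
    for gene in net.adj:
        nbrs = list(net.adj[gene].items())
        pos = [(j, w) for j, w in nbrs if w > 0]
        neg = [(j, w) for j, w in nbrs if w < 0]
        if q is not None:
            pos = _top_q(pos, q, key=lambda w: w)
            neg = _top_q(neg, q, key=abs)
        out[gene] = sorted(pos + neg)
    return TruncatedNeighborhood(out, q=q)


def randomize(net: GINetwork, rng_seed) -> GINetwork:
    """Signed-degree-preserving randomization by neighbor-slot reassignment.

    Every gene's neighbor slots are redirected to uniformly drawn distinct
    other genes while each slot keeps its weight (and hence sign).  Per gene,
    the positive/negative neighbor counts and the multiset of incident
    weights are exactly preserved.  The result is a directed row-wise
    relation and must be consumed per row (as scoring does).
    """
    if not net.signed:
        raise ValueError("randomize is defined for signed networks")
    genes = net.genes
    n = len(genes)
    if n < 3:
        raise ValueError("randomization requires at least 3 genes")
    rng = np.random.default_rng(rng_seed)
    idx_of = {g: k for k, g in enumerate(genes)}
    adj: dict[str, dict[str, float]] = {g: {} for g in genes}
    for gene in genes:
        slots = sorted(net.adj[gene].items())  # deterministic slot order
        weights = [w for _, w in slots]
        # distinct uniform targets among the other n-1 genes
        draws = rng.choice(n - 1, size=len(weights), replace=False)
        self_i = idx_of[gene]
        for d, w in zip(draws, weights):
            j = int(d) if d < self_i else int(d) + 1
            adj[gene][genes[j]] = w
    return GINetwork(adj, signed=True, directed=True)


def read_edges(path, signed: bool = True) -> GINetwork:
    """Read an undirected edge-list TSV: gene_i TAB gene_j TAB weight.

    Self-edges are dropped with a warning; duplicate (i,j)/(j,i) entries are
    averaged with a warning.
    """
    pair_weights: dict[tuple[str, str], list[float]] = {}
    n_self = 0
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        for lineno, fields in enumerate(reader, start=1):
            if not fields or fields[0].startswith("#"):
                continue
            if len(fields) < 3:
                raise ValueError(f"{path}: line {lineno}: expected 3 fields")
            i, j = fields[0], fields[1]
            try:
                w = float(fields[2])
            except ValueError:
                if lineno == 1:
                    continue  # header line
                raise ValueError(
                    f"{path}: line {lineno}: non-numeric weight {fields[2]!r}"
                ) from None
            if i == j:
                n_self += 1
                continue
            key = (i, j) if i < j else (j, i)
            pair_weights.setdefault(key, []).append(w)
    if n_self:
        logger.warning("%s: dropped %d self-edge(s)", path, n_self)
    n_dup = sum(1 for ws in pair_weights.values() if len(ws) > 1)
    if n_dup:
        logger.warning("%s: averaged %d duplicated edge(s)", path, n_dup)
    edges = [
        (i, j, float(np.mean(ws))) for (i, j), ws in pair_weights.items()
        if float(np.mean(ws)) != 0.0
    ]
    return GINetwork.from_edges(edges, signed=signed)


def write_edges(net: GINetwork, path) -> None:
    with open(path, "w", newline="") as fh:
        fh.write("gene_i\tgene_j\tweight\n")
        for i, j, w in net.edge_list():
            fh.write(f"{i}\t{j}\t{repr(float(w))}\n")
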