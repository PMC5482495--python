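"""Synthetic screens with planted compound-target structure.

Every stage of the pipeline is testable without external data by simulating
(i) a signed weighted interaction network, (ii) HIP- and HOP-style fitness
matrices whose signal geometry matches the two assays, and (iii) a
benchmark of the planted pairs.

HIP geometry (direct-target signal): the target strain itself is sensitized
(its FD is ``attenuation * target_fd``; attenuation < 1 models the
neighboring-gene effect that hides targets from the raw FD-score), while
each one-hop neighbor j moves opposite to the inhibited target according to
its interaction sign: negative neighbors become hypersensitive (low FD),
positive neighbors grow relatively well (high FD).

HOP geometry (pathway-buffer signal): the target's own FD stays near zero;
instead the *two-hop* genes around it — neighbors of its pathway genes —
carry the fitness signal, arranged so that the pathway genes' first-order
scores take the HIP-like pattern and only the two-hop score pulls the
target to the top.  Everything else is i.i.d. Gaussian noise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .ginet import GINetwork
from .screen_io import BenchmarkSet, FitnessMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "SimulationSpec",
    "GroundTruth",
    "simulate_network",
    "plant_targets",
    "simulate_hip",
    "simulate_hop",
    "make_benchmark",
]

# independent rng streams derived from the user seed
_STREAM_NETWORK = 0
_STREAM_TRUTH = 1
_STREAM_HIP = 2
_STREAM_HOP = 3


@dataclass(frozen=True)
class SimulationSpec:
    """Study conditions for the synthetic screens.

    Defaults give a 500-gene network with ~30 positive and ~30 negative
    neighbors per gene (half-normal weights, scale 0.2), 50 compounds with
    one planted target each, unit Gaussian screen noise, and signal sizes
    such that the raw FD-score recovers roughly half of the planted targets
    in the top 10 — strong enough to be a serious baseline, weak enough
    that network correction has headroom.
    """

    n_genes: int = 500
    mean_pos_degree: float = 30.0
    mean_neg_degree: float = 30.0
    weight_scale: float = 0.2
    n_compounds: int = 50
    targets_per_compound: int = 1
    target_fd: float = -4.0
    attenuation: float = 0.5
    neighbor_gain: float = 0.3
    buffer_gain: float = 0.3
    noise_sd: float = 1.0
    seed: int = 1

    def __post_init__(self) -> None:
        if not 0.0 <= self.attenuation <= 1.0:
            raise ValueError("attenuation must be in [0, 1]")
        for name in ("mean_pos_degree", "mean_neg_degree", "weight_scale",
                     "neighbor_gain", "buffer_gain", "noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.mean_pos_degree + self.mean_neg_degree >= self.n_genes:
            raise ValueError("requested mean degree must be below n_genes")

    def with_(self, **kwargs) -> "SimulationSpec":
        return replace(self, **kwargs)


@dataclass
class GroundTruth:
    """Planted (compound, target) pairs and the affected gene sets."""

    pairs: list[tuple[str, str]]
    one_hop: dict[str, set[str]] = field(default_factory=dict)
    two_hop: dict[str, set[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.pairs:
            raise ValueError("ground truth must contain at least one pair")

    def targets_of(self, compound: str) -> list[str]:
        return [g for c, g in self.pairs if c == compound]

    @property
    def compounds(self) -> list[str]:
        return list(dict.fromkeys(c for c, _ in self.pairs))


def _rng(spec: SimulationSpec, stream: int) -> np.random.Generator:
    return np.random.default_rng([spec.seed, stream])


def _gene_names(n: int) -> list[str]:
    width = len(str(n))
    return [f"G{i:0{width}d}" for i in range(1, n + 1)]


def simulate_network(spec: SimulationSpec) -> GINetwork:
    """Random signed network: independent positive/negative edges, weights
    sign * |N(0, weight_scale)|; bit-reproducible under the simulation seed."""
    rng = _rng(spec, _STREAM_NETWORK)
    n = spec.n_genes
    genes = _gene_names(n)
    p_pos = spec.mean_pos_degree / (n - 1)
    p_neg = spec.mean_neg_degree / (n - 1)
    iu, ju = np.triu_indices(n, k=1)
    u = rng.random(len(iu))
    is_pos = u < p_pos
    is_neg = (u >= p_pos) & (u < p_pos + p_neg)
    sel = is_pos | is_neg
    mags = np.abs(rng.normal(0.0, spec.weight_scale, size=int(sel.sum())))
    signs = np.where(is_pos[sel], 1.0, -1.0)
    weights = signs * mags
    edges = [
        (genes[i], genes[j], w)
        for i, j, w in zip(iu[sel], ju[sel], weights)
        if w != 0.0
    ]
    return GINetwork.from_edges(edges)


def plant_targets(net: GINetwork, spec: SimulationSpec) -> GroundTruth:
    """Pick target genes (with at least one neighbor) for each compound and
    record their one- and two-hop gene sets."""
    rng = _rng(spec, _STREAM_TRUTH)
    eligible = np.array([g for g in net.genes if net.degree(g) >= 1], dtype=object)
    need = spec.n_compounds * spec.targets_per_compound
    if len(eligible) == 0:
        raise ValueError("network has no gene with neighbors")
    targets = rng.choice(eligible, size=need, replace=need > len(eligible))
    width = len(str(spec.n_compounds))
    pairs = []
    one_hop: dict[str, set[str]] = {}
    two_hop: dict[str, set[str]] = {}
    it = iter(targets)
    for ci in range(1, spec.n_compounds + 1):
        comp = f"C{ci:0{width}d}"
        hop1: set[str] = set()
        hop2: set[str] = set()
        for _ in range(spec.targets_per_compound):
            t = str(next(it))
            pairs.append((comp, t))
            nbrs = set(net.neighbors(t))
            hop1 |= nbrs
            for p in nbrs:
                hop2 |= set(net.neighbors(p)) - {t}
        one_hop[comp] = hop1
        two_hop[comp] = hop2 - hop1
    return GroundTruth(pairs, one_hop, two_hop)


def _noise_matrix(spec: SimulationSpec, stream: int) -> np.ndarray:
    rng = _rng(spec, stream)
    return rng.normal(0.0, spec.noise_sd, size=(spec.n_genes, spec.n_compounds))


def simulate_hip(net: GINetwork, truth: GroundTruth, spec: SimulationSpec) -> FitnessMatrix:
    """HIP-style screen: direct signal on the target, signed one-hop echo.

    For compound c with target t: FD[t,c] = attenuation*target_fd + noise;
    each neighbor j of t gets neighbor_gain*sign(g_tj)*(-target_fd)*|g_tj|
    (low FD on negative neighbors of an inhibited target, high on positive
    ones); all other entries are pure noise.
    """
    genes = _gene_names(spec.n_genes)
    gene_pos = {g: i for i, g in enumerate(genes)}
    comps = truth.compounds
    signal = np.zeros((spec.n_genes, len(comps)))
    for ci, comp in enumerate(comps):
        for t in truth.targets_of(comp):
            signal[gene_pos[t], ci] += spec.attenuation * spec.target_fd
            for j, g_tj in net.neighbors(t).items():
                signal[gene_pos[j], ci] += (
                    spec.neighbor_gain * np.sign(g_tj) * (-spec.target_fd) * abs(g_tj)
                )
    fdvals = signal + _noise_matrix(spec, _STREAM_HIP)[:, : len(comps)]
    return FitnessMatrix(pd.DataFrame(fdvals, index=genes, columns=comps))


def simulate_hop(net: GINetwork, truth: GroundTruth, spec: SimulationSpec) -> FitnessMatrix:
    """HOP-style screen: pathway-buffer signal on two-hop genes only.

    The target's own FD carries no signal.  For each pathway gene p (a
    neighbor of target t) and each buffer gene b adjacent to p, FD[b,c]
    gets buffer_gain*sign(g_tp)*sign(g_pb)*target_fd*|g_pb|, which makes the
    first-order score of positive-side pathway genes high and of
    negative-side pathway genes low — recoverable by the two-hop score but
    invisible to the FD-score and largely to the one-hop score.
    """
    genes = _gene_names(spec.n_genes)
    gene_pos = {g: i for i, g in enumerate(genes)}
    comps = truth.compounds
    signal = np.zeros((spec.n_genes, len(comps)))
    for ci, comp in enumerate(comps):
        for t in truth.targets_of(comp):
            for p, g_tp in net.neighbors(t).items():
                for b, g_pb in net.neighbors(p).items():
                    if b == t:
                        continue
                    signal[gene_pos[b], ci] += (
                        spec.buffer_gain
                        * np.sign(g_tp) * np.sign(g_pb)
                        * spec.target_fd * abs(g_pb)
                    )
    fdvals = signal + _noise_matrix(spec, _STREAM_HOP)[:, : len(comps)]
    return FitnessMatrix(pd.DataFrame(fdvals, index=genes, columns=comps))


def make_benchmark(
    truth: GroundTruth,
    n_decoys: int = 0,
    decoy_confidence: float = 0.3,
    rng_seed: int = 0,
) -> BenchmarkSet:
    """Benchmark of the planted pairs at confidence 1.0, plus optional decoy
    pairs at sub-threshold confidence to exercise the benchmark filter."""
    rows = [(c, g, 1.0) for c, g in truth.pairs]
    if n_decoys > 0:
        rng = np.random.default_rng(rng_seed)
        planted = set(truth.pairs)
        comps = truth.compounds
        made = 0
        while made < n_decoys:
            c = comps[int(rng.integers(len(comps)))]
            g = f"DECOY{int(rng.integers(10 ** 6)):06d}"
            if (c, g) not in planted:
                rows.append((c, g, decoy_confidence))
                made += 1
    df = pd.DataFrame(rows, columns=["compound", "gene", "confidence"])
    return BenchmarkSet(df.drop_duplicates(subset=["compound", "gene"]).reset_index(drop=True))
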