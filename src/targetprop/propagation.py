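"""Insulated heat diffusion (random walk with restart) and network modules.

Genetic evidence is converted to "heat" h = -log2(1 - p12) and diffused over
the interactome with the insulated diffusion operator

    F = beta * (I - (1 - beta) * W)^(-1)

where W is the column-normalized adjacency matrix and beta the restart
probability. Columns of F sum to one, so heat is conserved. The exchanged
heat matrix E = F @ diag(h) records how much heat node j delivers to node i;
thresholding E at delta (edge j -> i iff E[i, j] >= delta) and taking
strongly connected components of size >= k_min yields disease modules.
Module genes minus the seed hits are the propagation proxy set.

delta is chosen by permutation: the smallest threshold at which randomly
reassigned heat yields (almost) no modules, so surviving modules reflect
heat concentrated on topologically coherent gene sets rather than diffusion
reach alone.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Set, Tuple

import networkx as nx
import numpy as np

from .knowledge import Interactome, ProxySet

__all__ = [
    "P12_MAX_DEFAULT",
    "heat_score",
    "HeatVector",
    "DiffusionResult",
    "NetworkModule",
    "InsulatedDiffusion",
    "diffuse",
    "extract_modules",
    "select_delta",
    "consensus_modules",
    "propagation_proxies",
]

#: p12 = 1 would give infinite heat; clip just below 1.
P12_MAX_DEFAULT = 1.0 - 2.0 ** -20


def heat_score(p12, p12_max: float = P12_MAX_DEFAULT):
    """Heat transform h = -log2(1 - p12); strictly increasing, h(0) = 0.

    Values at or above ``p12_max`` (including p12 = 1) are clipped with a
    warning so the heat stays finite.
    """
    arr = np.asarray(p12, dtype=float)
    if np.any((arr < 0) | (arr > 1)):
        raise ValueError("p12 must lie in [0, 1]")
    if np.any(arr > p12_max):
        warnings.warn(
            f"p12 value(s) above {p12_max} clipped to keep heat finite",
            stacklevel=2,
        )
        arr = np.minimum(arr, p12_max)
    out = -np.log2(1.0 - arr)
    return float(out) if np.isscalar(p12) else out


@dataclass
class HeatVector:
    """Non-negative heat per gene; genes absent carry no heat."""

    heat: Dict[str, float]

    def __post_init__(self):
        bad = {g: h for g, h in self.heat.items() if h < 0}
        if bad:
            raise ValueError(f"negative heat: {bad}")

    @classmethod
    def from_p12(cls, p12_by_gene: Mapping[str, float]) -> "HeatVector":
        return cls({g: heat_score(p) for g, p in p12_by_gene.items()})

    def total(self) -> float:
        return float(sum(self.heat.values()))


@dataclass(frozen=True)
class NetworkModule:
    genes: frozenset
    trait_id: str = ""
    network: str = ""
    delta: float = float("nan")


class InsulatedDiffusion:
    """Diffusion operator for one (network, beta); reusable across traits.

    The operator is built on the largest connected component (isolated or
    out-of-component genes never become module members). Dense inversion is
    used up to ``dense_limit`` nodes, an iterative per-column solve above.
    """

    def __init__(self, net: Interactome, beta: float = 0.4, dense_limit: int = 5000):
        if not (0.0 < beta < 1.0):
            raise ValueError("beta must lie in (0, 1)")
        self.beta = beta
        self.network_name = net.name
        g = net.graph
        n_iso = sum(1 for v in g.nodes if g.degree(v) == 0)
        if n_iso:
            warnings.warn(
                f"{n_iso} isolated node(s) removed before diffusion", stacklevel=2
            )
        comps = list(nx.connected_components(g))
        comps = [c for c in comps if len(c) >= 2]
        if not comps:
            raise ValueError("network has no connected component of size >= 2")
        lcc = max(comps, key=lambda c: (len(c), min(c)))
        self.genes: List[str] = sorted(lcc)
        self.index = {gene: i for i, gene in enumerate(self.genes)}
        A = nx.to_numpy_array(g.subgraph(self.genes), nodelist=self.genes, weight=None)
        colsum = A.sum(axis=0)
        W = A / colsum  # column-stochastic walk matrix
        self.W = W
        n = len(self.genes)
        M = np.eye(n) - (1.0 - beta) * W
        if n <= dense_limit:
            self.F = beta * np.linalg.inv(M)
        else:
            from scipy.sparse import csc_matrix
            from scipy.sparse.linalg import splu

            lu = splu(csc_matrix(M))
            self.F = beta * lu.solve(np.eye(n))

    def heat_array(self, heat: HeatVector) -> np.ndarray:
        h = np.zeros(len(self.genes))
        for gene, value in heat.heat.items():
            i = self.index.get(gene)
            if i is not None:
                h[i] = value
        return h

    def exchanged_heat(self, heat: HeatVector) -> np.ndarray:
        """E = F @ diag(h)."""
        return self.F * self.heat_array(heat)[np.newaxis, :]


@dataclass
class DiffusionResult:
    """Walk matrix, diffusion matrix, exchanged heat and the node order."""

    genes: List[str]
    W: np.ndarray
    F: np.ndarray
    E: np.ndarray
    beta: float
    network: str = ""
    _operator: Optional[InsulatedDiffusion] = field(default=None, repr=False)


def diffuse(net: Interactome, heat: HeatVector, beta: float = 0.4) -> DiffusionResult:
    """One-shot diffusion of a heat vector over a network."""
    op = InsulatedDiffusion(net, beta=beta)
    return DiffusionResult(
        genes=op.genes,
        W=op.W,
        F=op.F,
        E=op.exchanged_heat(heat),
        beta=beta,
        network=net.name,
        _operator=op,
    )


def _scc_modules(
    E: np.ndarray, genes: Sequence[str], delta: float, k_min: int
) -> List[frozenset]:
    """Strongly connected components of the delta-thresholded exchanged-heat
    graph (edge j -> i iff E[i, j] >= delta), size >= k_min.

    Vectorized: the thresholded adjacency goes straight into
    scipy.sparse.csgraph on the involved nodes only.
    """
    if delta <= 0:
        raise ValueError("delta must be positive")
    mask = E >= delta
    np.fill_diagonal(mask, False)
    rows, cols = np.nonzero(mask)
    if rows.size == 0:
        return []
    from scipy.sparse import csr_matrix
    from scipy.sparse.csgraph import connected_components

    nodes = np.unique(np.concatenate([rows, cols]))
    remap = np.full(E.shape[0], -1, dtype=np.int64)
    remap[nodes] = np.arange(nodes.size)
    adj = csr_matrix(
        (np.ones(rows.size, dtype=bool), (remap[cols], remap[rows])),
        shape=(nodes.size, nodes.size),
    )
    n_comp, labels = connected_components(adj, directed=True, connection="strong")
    counts = np.bincount(labels)
    out = []
    for comp in np.flatnonzero(counts >= k_min):
        idx = nodes[labels == comp]
        out.append(frozenset(genes[i] for i in idx))
    return out


def extract_modules(
    E: np.ndarray,
    genes: Sequence[str],
    delta: float,
    k_min: int = 3,
    trait_id: str = "",
    network: str = "",
) -> List[NetworkModule]:
    """Modules = SCCs of the thresholded exchanged-heat graph, size >= k_min."""
    if k_min < 2:
        raise ValueError("k_min must be >= 2")
    comps = _scc_modules(E, list(genes), delta, k_min)
    comps.sort(key=lambda c: (-len(c), min(c)))
    return [
        NetworkModule(genes=c, trait_id=trait_id, network=network, delta=delta)
        for c in comps
    ]


def select_delta(
    op: InsulatedDiffusion,
    heat: HeatVector,
    n_perm: int = 30,
    seed: int = 0,
    k_min: int = 3,
    n_candidates: int = 24,
    expected_modules: float = 0.05,
) -> float:
    """Permutation-based choice of the exchanged-heat threshold delta.

    Candidate deltas are quantiles of the positive exchanged-heat entries.
    Heat values are reassigned to random genes ``n_perm`` times; delta is the
    smallest candidate for which the mean number of size->=k_min modules per
    permutation falls below ``expected_modules``. Degenerate heat (all equal
    or all zero) gets a sentinel above max(E).
    """
    if n_perm < 10:
        raise ValueError("n_perm must be >= 10")
    values = np.array(sorted(heat.heat.values(), reverse=True), dtype=float)
    values = values[values > 0]
    E = op.exchanged_heat(heat)
    emax = float(E.max(initial=0.0))
    if values.size == 0:
        warnings.warn("heat is all zero; returning sentinel delta", stacklevel=2)
        return np.inf
    if np.allclose(values, values[0]) and len(values) == len(op.genes):
        warnings.warn("degenerate (uniform) heat; returning max(E)+eps", stacklevel=2)
        return emax * (1 + 1e-9) + 1e-300

    # candidate thresholds taken at geometrically spaced ranks from the top
    # of the positive exchanged-heat distribution: module-bearing deltas live
    # in the extreme upper tail, far beyond any fixed quantile grid
    pos = np.sort(E[E > 0])[::-1]
    ranks = np.unique(
        np.geomspace(2, pos.size, num=n_candidates).astype(int)
    )
    candidates = np.unique(pos[ranks - 1])  # ascending after unique
    candidates = candidates[candidates > 0]

    rng = np.random.default_rng(seed)
    gene_arr = np.arange(len(op.genes))
    perm_E = []
    for _ in range(n_perm):
        idx = rng.choice(gene_arr, size=values.size, replace=False)
        hp = np.zeros(len(op.genes))
        hp[idx] = rng.permutation(values)
        perm_E.append(op.F * hp[np.newaxis, :])

    max_total = n_perm * expected_modules
    for delta in candidates:
        total = 0
        for Ep in perm_E:
            total += len(_scc_modules(Ep, op.genes, float(delta), k_min))
            if total >= max_total:
                break
        if total < max_total:
            return float(delta)
    warnings.warn(
        "no candidate delta suppressed permutation modules; returning max(E)+eps",
        stacklevel=2,
    )
    return emax * (1 + 1e-9) + 1e-300


def consensus_modules(
    net: Interactome,
    heat: HeatVector,
    betas: Sequence[float] = (0.25, 0.4, 0.55),
    min_votes: int = 2,
    k_min: int = 3,
    n_perm: int = 30,
    seed: int = 0,
    trait_id: str = "",
) -> List[NetworkModule]:
    """Across-restart consensus (a reconstruction, not the original
    procedure): run diffusion at each beta with its own permutation-selected
    delta, and keep genes appearing in modules in >= ``min_votes`` runs.

    Consensus genes are grouped into modules as connected components of the
    interactome restricted to them.
    """
    votes: Dict[str, int] = {}
    for i, beta in enumerate(betas):
        op = InsulatedDiffusion(net, beta=beta)
        delta = select_delta(op, heat, n_perm=n_perm, seed=seed + i, k_min=k_min)
        if not np.isfinite(delta):
            continue
        genes: Set[str] = set()
        for m in extract_modules(op.exchanged_heat(heat), op.genes, delta, k_min):
            genes |= m.genes
        for g in genes:
            votes[g] = votes.get(g, 0) + 1
    kept = {g for g, v in votes.items() if v >= min_votes}
    if not kept:
        return []
    sub = net.graph.subgraph(kept)
    comps = sorted(nx.connected_components(sub), key=lambda c: (-len(c), min(c)))
    return [
        NetworkModule(genes=frozenset(c), trait_id=trait_id, network=net.name)
        for c in comps
        if len(c) >= k_min
    ]


def propagation_proxies(
    modules: Sequence[NetworkModule], seeds: Set[str], trait_id: str = ""
) -> ProxySet:
    """Union of module genes minus the seed hits."""
    genes: Set[str] = set()
    for m in modules:
        genes |= m.genes
    return ProxySet(trait_id, "hotnet", frozenset(seeds), frozenset(genes - seeds))
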