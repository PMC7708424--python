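"""Prior-knowledge containers and naive proxy-gene expansion methods.

Genetic disease associations rarely land on every gene relevant to a disease.
A standard remedy is guilt-by-association: expand a seed set of genetically
supported genes ("seeds", here high-confidence genetic hits) into *proxy*
genes through curated functional linkages — protein complexes, ligand–receptor
pairs, interactome neighborhoods, and pathway membership or wiring.

Every expansion returns a :class:`ProxySet` whose proxies exclude the seeds:
enrichment downstream is always measured on the newly implicated genes only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import FrozenSet, Iterable, List, Sequence, Set, Tuple

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "KnowledgeBase",
    "GeneUniverse",
    "Interactome",
    "ComplexSet",
    "LigandReceptorMap",
    "PathwaySet",
    "ProxySet",
    "complex_proxies",
    "ligand_receptor_proxies",
    "network_neighbors",
    "pathway_clique_proxies",
    "pathway_neighbors",
    "random_proxies",
    "RANDOM_SAMPLING_FRACTION",
]

#: The reference analysis drew 10,000 random protein-coding genes from a
#: 22,758-gene background; the random negative control preserves this fraction
#: when scaled to a smaller universe.
RANDOM_SAMPLING_FRACTION = 10_000 / 22_758


@dataclass(frozen=True)
class GeneUniverse:
    """Ordered gene universe with protein-coding and HLA flags.

    The *background* for all enrichment statistics is the protein-coding
    subset; non-coding genes may appear in expansions but never in the
    counted population.
    """

    genes: Tuple[str, ...]
    is_coding: Tuple[bool, ...]
    is_hla: Tuple[bool, ...]

    def __post_init__(self):
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("gene identifiers must be unique")
        if not (len(self.genes) == len(self.is_coding) == len(self.is_hla)):
            raise ValueError("flag vectors must match gene list length")

    @property
    def gene_set(self) -> FrozenSet[str]:
        return frozenset(self.genes)

    @property
    def coding(self) -> FrozenSet[str]:
        return frozenset(g for g, c in zip(self.genes, self.is_coding) if c)

    @property
    def hla(self) -> FrozenSet[str]:
        return frozenset(g for g, h in zip(self.genes, self.is_hla) if h)

    def __contains__(self, gene: str) -> bool:
        return gene in self.gene_set

    def __len__(self) -> int:
        return len(self.genes)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "GeneUniverse":
        return cls(
            genes=tuple(df["gene_id"].astype(str)),
            is_coding=tuple(df["is_coding"].astype(int).astype(bool)),
            is_hla=tuple(df["is_hla"].astype(int).astype(bool)),
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene_id": self.genes,
                "is_coding": np.asarray(self.is_coding, dtype=int),
                "is_hla": np.asarray(self.is_hla, dtype=int),
            }
        )


@dataclass
class Interactome:
    """Undirected protein–protein interaction network over universe genes."""

    graph: nx.Graph
    name: str = "interactome"

    def __post_init__(self):
        loops = list(nx.selfloop_edges(self.graph))
        if loops:
            raise ValueError(f"interactome contains self-loops: {loops[:3]}")

    @classmethod
    def from_edges(
        cls,
        edges: Iterable[Tuple[str, str, float]],
        name: str = "interactome",
        min_weight: float | None = None,
    ) -> "Interactome":
        """Build from (gene_a, gene_b, weight) triples.

        Duplicate edges collapse (last weight wins); self-loops are dropped.
        ``min_weight`` applies a STRING-style confidence threshold on load.
        """
        g = nx.Graph()
        for a, b, w in edges:
            if a == b:
                continue
            if min_weight is not None and w < min_weight:
                continue
            g.add_edge(a, b, weight=float(w))
        return cls(graph=g, name=name)

    def to_dataframe(self) -> pd.DataFrame:
        rows = sorted(
            (min(a, b), max(a, b), d.get("weight", 1.0))
            for a, b, d in self.graph.edges(data=True)
        )
        return pd.DataFrame(rows, columns=["gene_a", "gene_b", "weight"])


@dataclass
class ComplexSet:
    """Stable protein complexes, each modeled as a fully connected clique."""

    complexes: List[FrozenSet[str]]
    ids: List[str] = field(default_factory=list)

    def __post_init__(self):
        if not self.ids:
            self.ids = [f"CPX{i:04d}" for i in range(len(self.complexes))]
        for cid, members in zip(self.ids, self.complexes):
            if len(members) < 2:
                raise ValueError(f"complex {cid} has fewer than 2 members")


@dataclass
class LigandReceptorMap:
    """Many-to-many ligand–receptor pairing (not a simple 1:1 mapping)."""

    pairs: FrozenSet[Tuple[str, str]]

    @classmethod
    def from_pairs(cls, pairs: Iterable[Tuple[str, str]]) -> "LigandReceptorMap":
        return cls(pairs=frozenset((str(a), str(b)) for a, b in pairs))


@dataclass
class PathwaySet:
    """Pathways with both membership and internal directed wiring.

    ``edges`` holds (pathway_id, source, target) directed interactions; they
    must connect pathway members only.
    """

    pathways: List[Tuple[str, FrozenSet[str]]]
    edges: List[Tuple[str, str, str]] = field(default_factory=list)

    def __post_init__(self):
        members = {pid: genes for pid, genes in self.pathways}
        for pid, s, t in self.edges:
            if pid not in members:
                raise ValueError(f"edge references unknown pathway {pid}")
            if s not in members[pid] or t not in members[pid]:
                raise ValueError(
                    f"pathway {pid} edge {s}->{t} leaves pathway membership"
                )

    def membership(self) -> dict:
        return {pid: genes for pid, genes in self.pathways}

    def edge_graph(self) -> nx.Graph:
        """Union of pathway wiring as an undirected graph (upstream and
        downstream interactors are treated symmetrically); cached."""
        cached = getattr(self, "_edge_graph", None)
        if cached is None:
            cached = nx.Graph()
            for _, s, t in self.edges:
                if s != t:
                    cached.add_edge(s, t)
            self._edge_graph = cached
        return cached


@dataclass(frozen=True)
class ProxySet:
    """Expanded gene set for one (trait, method), seeds excluded."""

    trait_id: str
    method: str
    seeds: FrozenSet[str]
    proxies: FrozenSet[str]

    def __post_init__(self):
        if self.proxies & self.seeds:
            raise ValueError("proxies must be disjoint from seeds")

    def __len__(self) -> int:
        return len(self.proxies)


@dataclass
class KnowledgeBase:
    """Bundle of prior knowledge: universe, interactome, complexes,
    ligand–receptor pairs and pathway maps (with topology)."""

    universe: GeneUniverse
    interactome: Interactome
    complexes: ComplexSet
    lr: LigandReceptorMap
    pathways: PathwaySet


# ---------------------------------------------------------------------------
# Expansion methods
# ---------------------------------------------------------------------------


def complex_proxies(
    seeds: Set[str], complexes: ComplexSet, trait_id: str = ""
) -> ProxySet:
    """All genes sharing a protein complex with a seed, seeds removed."""
    seeds = frozenset(seeds)
    out: Set[str] = set()
    for members in complexes.complexes:
        if members & seeds:
            out |= members
    return ProxySet(trait_id, "complex", seeds, frozenset(out - seeds))


def ligand_receptor_proxies(
    seeds: Set[str], lr: LigandReceptorMap, trait_id: str = ""
) -> ProxySet:
    """Partners of seeds across ligand–receptor pairs, strictly first-neighbor.

    A seed ligand's receptors are returned, but NOT those receptors' other
    ligands: expanding to second neighbors would propagate evidence from a
    ligand to *all* ligands of its receptor, which is deliberately avoided.
    """
    seeds = frozenset(seeds)
    out: Set[str] = set()
    for ligand, receptor in lr.pairs:
        if ligand in seeds:
            out.add(receptor)
        if receptor in seeds:
            out.add(ligand)
    return ProxySet(trait_id, "ligand_receptor", seeds, frozenset(out - seeds))


def network_neighbors(
    seeds: Set[str], net: Interactome, order: int, trait_id: str = ""
) -> ProxySet:
    """First (order=1) or first-and-second (order=2) degree interactors."""
    if order not in (1, 2):
        raise ValueError("order must be 1 or 2")
    seeds = frozenset(seeds)
    g = net.graph
    present = [s for s in seeds if s in g]
    missing = seeds - set(present)
    if missing:
        warnings.warn(
            f"{len(missing)} seed(s) absent from network '{net.name}'; "
            "treated as isolated",
            stacklevel=2,
        )
    out: Set[str] = set()
    for s in present:
        nbrs = set(g.neighbors(s))
        out |= nbrs
        if order == 2:
            for n in nbrs:
                out |= set(g.neighbors(n))
    method = f"net_neighbor{order}"
    return ProxySet(trait_id, method, seeds, frozenset(out - seeds))


def pathway_clique_proxies(
    seeds: Set[str], pathways: PathwaySet, trait_id: str = ""
) -> ProxySet:
    """All genes in any pathway containing a seed (pathway as a clique)."""
    seeds = frozenset(seeds)
    out: Set[str] = set()
    for _, members in pathways.pathways:
        if members & seeds:
            out |= members
    return ProxySet(trait_id, "pathway_clique", seeds, frozenset(out - seeds))


def pathway_neighbors(
    seeds: Set[str], pathways: PathwaySet, order: int, trait_id: str = ""
) -> ProxySet:
    """Direct pathway-wiring interactors of seeds (order=1), or the union of
    first and second interactors (order=2).

    First interactors are all upstream and downstream direct partners across
    all pathways; second interactors repeat the process starting from the
    first interactors. Edge direction is ignored (undirected reachability).
    """
    if order not in (1, 2):
        raise ValueError("order must be 1 or 2")
    seeds = frozenset(seeds)
    g = pathways.edge_graph()
    first: Set[str] = set()
    for s in seeds:
        if s in g:
            first |= set(g.neighbors(s))
    out = set(first)
    if order == 2:
        for f in first:
            out |= set(g.neighbors(f))
    method = f"pathway_neighbor{order}"
    return ProxySet(trait_id, method, seeds, frozenset(out - seeds))


def random_proxies(
    universe: GeneUniverse,
    n: int | None = None,
    seed: int = 0,
    trait_id: str = "",
    exclude_seeds: Set[str] | None = None,
) -> ProxySet:
    """Uniform sample of protein-coding genes — the negative control.

    With ``n=None`` the sample size preserves the reference sampling fraction
    (10,000 of 22,758 coding genes) at the current universe size.
    """
    coding = sorted(universe.coding)
    if n is None:
        n = int(round(RANDOM_SAMPLING_FRACTION * len(coding)))
    if n > len(coding):
        raise ValueError(f"cannot sample {n} genes from {len(coding)} coding genes")
    rng = np.random.default_rng(seed)
    sample = frozenset(rng.choice(np.asarray(coding, dtype=object), size=n, replace=False))
    seeds = frozenset(exclude_seeds or ())
    return ProxySet(trait_id, "random", seeds, frozenset(sample - seeds))


def proxy_sets_to_frame(proxy_sets: Sequence[ProxySet]) -> pd.DataFrame:
    """Flatten proxy sets to a (trait_id, method, gene_id) table."""
    rows = [
        (ps.trait_id, ps.method, g)
        for ps in proxy_sets
        for g in sorted(ps.proxies)
    ]
    return pd.DataFrame(rows, columns=["trait_id", "method", "gene_id"])
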