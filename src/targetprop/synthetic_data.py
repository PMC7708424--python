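"""Synthetic world generator for the full expansion/enrichment analysis.

The real analysis consumes proprietary inputs (large GWAS–eQTL
colocalization panels, historical trial records, licensed interactomes).
This module generates a self-contained world with the same statistical
structure, so every downstream stage can be exercised and validated:

* a scale-free interactome (preferential attachment — the hub-dominated
  topology that drives the failed-target effect in global networks), with an
  Erdős–Rényi alternative for contrast;
* complexes and pathways as random *connected subgraphs* of the interactome
  (real complexes/pathways are locally connected within it);
* per-trait planted disease modules (connected subgraphs) whose genes emit
  high-confidence colocalization records (p12 concentrated above 0.8,
  genome-wide significant GWAS p, passing eQTL p) among decoy loci and decoy
  candidate eGenes;
* trial outcomes with hub-biased target testing (probability of being tested
  scales with degree^exponent), a configurable success-odds multiplier for
  genes near the planted module (graph neighborhood or shared complex), and
  an optional degree-dependent failure accumulation for hubs;
* an LD-correlated variant panel: per gene, z ~ MVN(mu, R) with AR(1) LD and
  a mean shift for genes in (or near) planted modules, on synthetic genomic
  windows that allow gene fusion.

A fixed seed makes the world bit-reproducible, including its on-disk
serialization.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path
from typing import Dict, FrozenSet, List, Mapping, Optional, Sequence, Set, Tuple

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from .clinical import AssetRecord, assets_from_frame
from .genescore import GeneWindow, VariantBlock, WINDOW_BP
from .hcgh import ColocRecord
from .knowledge import (
    ComplexSet,
    GeneUniverse,
    Interactome,
    KnowledgeBase,
    LigandReceptorMap,
    PathwaySet,
)

__all__ = [
    "SimulationConfig",
    "SyntheticWorld",
    "generate_world",
    "variant_panel_for_trait",
    "write_world",
    "read_world",
    "WORLD_FILES",
]

_FMT = "%.17g"  # lossless float round-trip in text


class WorldIOError(RuntimeError):
    """Missing or malformed world file."""


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic world.

    Distribution parameters: ``p12_*_dist`` are (alpha, beta, lo, hi) —
    a Beta(alpha, beta) draw rescaled to [lo, hi]; ``*_p_*_dist`` are
    (lo, hi) bounds of a log-uniform draw.
    """

    # universe & networks
    n_genes: int = 2000
    coding_fraction: float = 0.95
    hla_fraction: float = 0.01
    topology: str = "scale_free"  # or "erdos_renyi"
    pa_edges: int = 3
    n_complexes: int = 300
    complex_size_range: Tuple[int, int] = (2, 10)
    n_lr_pairs: int = 200
    n_pathways: int = 150
    pathway_size_range: Tuple[int, int] = (10, 100)
    # traits & genetics
    n_traits: int = 100
    loci_per_trait: Tuple[int, int] = (15, 30)
    module_size: Tuple[int, int] = (15, 35)
    hcgh_detect_prob: float = 0.85
    decoy_pass_prob: float = 0.15
    p12_hit_dist: Tuple[float, float, float, float] = (2.0, 2.0, 0.8, 1.0)
    p12_null_dist: Tuple[float, float, float, float] = (2.0, 2.0, 0.0, 0.5)
    gwas_p_hit_dist: Tuple[float, float] = (1e-30, 5e-8)
    gwas_p_null_dist: Tuple[float, float] = (1e-7, 1.0)
    eqtl_p_hit_dist: Tuple[float, float] = (1e-12, 1e-4)
    eqtl_p_null_dist: Tuple[float, float] = (2e-4, 1.0)
    # trial outcomes
    target_sampling_degree_exponent: float = 1.0
    targets_tested_per_trait: int = 100
    baseline_success_prob: float = 0.1
    planted_success_or: float = 3.0
    success_neighborhood: str = "network"  # or "complex"
    neighborhood_radius: int = 1
    hub_failure_exponent: float = 0.0
    clinical_failure_frac: float = 0.7
    nonselective_frac: float = 0.15
    in_progress_frac: float = 0.1
    # variant panel
    with_variants: bool = True
    variants_per_gene: int = 8
    ld_rho: float = 0.5
    causal_effect_mu: float = 2.0
    causal_decay: float = 0.5
    focal_trait_index: int = 0
    seed: int = 0

    def validate(self) -> None:
        for name in (
            "coding_fraction",
            "hla_fraction",
            "hcgh_detect_prob",
            "decoy_pass_prob",
            "baseline_success_prob",
            "clinical_failure_frac",
            "nonselective_frac",
            "in_progress_frac",
        ):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if not (0.0 <= self.ld_rho < 1.0):
            raise ValueError("ld_rho must lie in [0, 1)")
        if self.planted_success_or <= 0:
            raise ValueError("planted_success_or must be positive")
        if self.target_sampling_degree_exponent < 0:
            raise ValueError("target_sampling_degree_exponent must be >= 0")
        for name in ("complex_size_range", "pathway_size_range", "module_size", "loci_per_trait"):
            lo, hi = getattr(self, name)
            if lo < 1 or hi < lo:
                raise ValueError(f"{name} must be a non-degenerate positive range")
        for name, count in (
            ("complex_size_range", self.n_complexes),
            ("pathway_size_range", self.n_pathways),
            ("module_size", self.n_traits),
        ):
            if count and getattr(self, name)[1] > self.n_genes:
                raise ValueError(
                    f"{name} upper bound exceeds n_genes={self.n_genes}"
                )
        if self.topology not in ("scale_free", "erdos_renyi"):
            raise ValueError(f"unknown topology {self.topology!r}")
        if self.success_neighborhood not in ("network", "complex"):
            raise ValueError(
                f"unknown success_neighborhood {self.success_neighborhood!r}"
            )


@dataclass
class SyntheticWorld:
    """Complete generated world; the ground truth stays attached."""

    config: SimulationConfig
    knowledge_base: KnowledgeBase
    windows: Dict[str, GeneWindow]
    trait_coloc: Dict[str, List[ColocRecord]]
    trait_truth: Dict[str, FrozenSet[str]]
    trait_detected: Dict[str, FrozenSet[str]]
    trait_indications: Dict[str, str]
    assets: List[AssetRecord]
    variant_stats: Dict[str, VariantBlock]

    def indication_map(self) -> Dict[str, Set[str]]:
        """trait -> set of matched indications (one per trait here)."""
        return {t: {i} for t, i in self.trait_indications.items()}

    def equals(self, other: "SyntheticWorld") -> bool:
        if self.config != other.config:
            return False
        kb, okb = self.knowledge_base, other.knowledge_base
        if kb.universe != okb.universe:
            return False
        if set(map(frozenset, kb.interactome.graph.edges)) != set(
            map(frozenset, okb.interactome.graph.edges)
        ):
            return False
        if sorted(kb.complexes.complexes, key=sorted) != sorted(
            okb.complexes.complexes, key=sorted
        ):
            return False
        if kb.lr.pairs != okb.lr.pairs:
            return False
        if dict(kb.pathways.pathways) != dict(okb.pathways.pathways):
            return False
        if sorted(kb.pathways.edges) != sorted(okb.pathways.edges):
            return False
        if self.windows != other.windows:
            return False
        if self.trait_truth != other.trait_truth:
            return False
        if self.trait_detected != other.trait_detected:
            return False
        if self.trait_indications != other.trait_indications:
            return False
        if {t: sorted(rs, key=str) for t, rs in self.trait_coloc.items()} != {
            t: sorted(rs, key=str) for t, rs in other.trait_coloc.items()
        }:
            return False
        if sorted(self.assets, key=str) != sorted(other.assets, key=str):
            return False
        if set(self.variant_stats) != set(other.variant_stats):
            return False
        for g, b in self.variant_stats.items():
            ob = other.variant_stats[g]
            if b.variant_ids != ob.variant_ids:
                return False
            if not (np.array_equal(b.z, ob.z) and np.array_equal(b.R, ob.R)):
                return False
        return True


# ---------------------------------------------------------------------------
# generation helpers
# ---------------------------------------------------------------------------


def _connected_subgraph(
    g: nx.Graph, size: int, rng: np.random.Generator, nodes: Sequence[str]
) -> FrozenSet[str]:
    """Randomly grown connected subgraph of ``size`` nodes (or as many as the
    component allows)."""
    start = nodes[rng.integers(len(nodes))]
    chosen = {start}
    frontier = set(g.neighbors(start)) - chosen
    while len(chosen) < size and frontier:
        pick = sorted(frontier)[rng.integers(len(frontier))]
        chosen.add(pick)
        frontier |= set(g.neighbors(pick))
        frontier -= chosen
    return frozenset(chosen)


def _loguniform(rng, lo: float, hi: float, size=None):
    return np.exp(rng.uniform(np.log(lo), np.log(hi), size=size))


def _scaled_beta(rng, params: Tuple[float, float, float, float], size=None):
    a, b, lo, hi = params
    return lo + (hi - lo) * rng.beta(a, b, size=size)


def _distance_to_set(g: nx.Graph, sources: Set[str], cutoff: int) -> Dict[str, int]:
    """Multi-source BFS distances up to ``cutoff`` hops."""
    dist = {s: 0 for s in sources if s in g}
    frontier = list(dist)
    for d in range(1, cutoff + 1):
        nxt = []
        for u in frontier:
            for v in g.neighbors(u):
                if v not in dist:
                    dist[v] = d
                    nxt.append(v)
        frontier = nxt
        if not frontier:
            break
    return dist


def _panel_seed(config: SimulationConfig, trait: str) -> int:
    """Deterministic, trait-specific sub-seed below 2**31."""
    t = int(trait.lstrip("T"))
    return int((config.seed * 1_000_003 + 7919 * (t + 1)) % (2**31 - 1))


def _variant_panel(
    genes: Sequence[str],
    graph: nx.Graph,
    module: FrozenSet[str],
    config: SimulationConfig,
    seed: int,
) -> Dict[str, VariantBlock]:
    """Per-gene variant z-scores for one GWAS trait.

    z ~ MVN(mu, R) with AR(1) LD; mu = causal_effect_mu * causal_decay^d per
    variant, where d is the graph distance to the trait's planted module
    (genes beyond two hops carry no signal). The decay mimics the real
    pattern that genes interacting with true disease genes carry weak but
    real association signal.
    """
    rng = np.random.default_rng(seed)
    m = config.variants_per_gene
    idx = np.arange(m)
    R = config.ld_rho ** np.abs(idx[:, None] - idx[None, :])
    L = np.linalg.cholesky(R + 1e-12 * np.eye(m))
    dist = _distance_to_set(graph, set(module), cutoff=2)
    panel: Dict[str, VariantBlock] = {}
    for gene in genes:
        d = dist.get(gene)
        mu = config.causal_effect_mu * config.causal_decay**d if d is not None else 0.0
        z = mu + L @ rng.standard_normal(m)
        panel[gene] = VariantBlock(
            gene_id=gene, z=z, R=R.copy(),
            variant_ids=tuple(f"{gene}:v{j}" for j in range(m)),
        )
    return panel


def variant_panel_for_trait(
    world: "SyntheticWorld", trait: str
) -> Dict[str, VariantBlock]:
    """Regenerate the (deterministic) variant panel for any trait's GWAS.

    The stored ``variant_stats`` is the panel of the focal trait; panels for
    other traits are reproduced on demand from the world's seed, so per-trait
    gene scores never require storing n_traits x n_genes files.
    """
    if trait not in world.trait_truth:
        raise KeyError(f"unknown trait {trait}")
    cfg = world.config
    focal = f"T{cfg.focal_trait_index:03d}"
    if trait == focal and world.variant_stats:
        return world.variant_stats
    genes = list(world.knowledge_base.universe.genes)
    return _variant_panel(
        genes,
        world.knowledge_base.interactome.graph,
        world.trait_truth[trait],
        cfg,
        _panel_seed(cfg, trait),
    )


# ---------------------------------------------------------------------------
# main generator
# ---------------------------------------------------------------------------


def generate_world(config: SimulationConfig) -> SyntheticWorld:
    """Generate a complete synthetic world; deterministic per config.seed."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_genes
    genes = [f"G{i:04d}" for i in range(n)]

    n_coding = int(round(config.coding_fraction * n))
    perm = rng.permutation(n)
    coding_idx = set(perm[:n_coding].tolist())
    n_hla = int(round(config.hla_fraction * n))
    hla_idx = set(perm[:n_hla].tolist())  # HLA genes are coding
    universe = GeneUniverse(
        genes=tuple(genes),
        is_coding=tuple(i in coding_idx for i in range(n)),
        is_hla=tuple(i in hla_idx for i in range(n)),
    )

    # interactome
    gseed = int(rng.integers(2**31 - 1))
    if config.topology == "scale_free":
        raw = nx.barabasi_albert_graph(n, config.pa_edges, seed=gseed)
    else:
        p = 2.0 * config.pa_edges / (n - 1)
        raw = nx.gnp_random_graph(n, p, seed=gseed)
    graph = nx.relabel_nodes(raw, {i: genes[i] for i in range(n)})
    nx.set_edge_attributes(graph, 1.0, "weight")
    interactome = Interactome(graph=graph, name=config.topology)
    degree = dict(graph.degree())

    # complexes / pathways as connected subgraphs; LR pairs as oriented edges
    complexes = []
    for _ in range(config.n_complexes):
        size = int(rng.integers(config.complex_size_range[0], config.complex_size_range[1] + 1))
        members = _connected_subgraph(graph, max(size, 2), rng, genes)
        if len(members) >= 2:
            complexes.append(members)
    complex_set = ComplexSet(complexes=complexes)

    pathways, pathway_edges = [], []
    for k in range(config.n_pathways):
        size = int(rng.integers(config.pathway_size_range[0], config.pathway_size_range[1] + 1))
        members = _connected_subgraph(graph, size, rng, genes)
        pid = f"PW{k:04d}"
        pathways.append((pid, members))
        for a, b in sorted(graph.subgraph(members).edges()):
            if rng.random() < 0.5:
                a, b = b, a
            pathway_edges.append((pid, a, b))
    pathway_set = PathwaySet(pathways=pathways, edges=pathway_edges)

    all_edges = sorted(tuple(sorted(e)) for e in graph.edges())
    k_lr = min(config.n_lr_pairs, len(all_edges))
    lr_idx = rng.choice(len(all_edges), size=k_lr, replace=False)
    lr_pairs = set()
    for i in sorted(lr_idx):
        a, b = all_edges[i]
        lr_pairs.add((a, b) if rng.random() < 0.5 else (b, a))
    lr_map = LigandReceptorMap(pairs=frozenset(lr_pairs))

    # planted disease modules and colocalization records
    trait_truth: Dict[str, FrozenSet[str]] = {}
    trait_coloc: Dict[str, List[ColocRecord]] = {}
    trait_indications: Dict[str, str] = {}
    trait_detected: Dict[str, List[str]] = {}
    coding_set = universe.coding
    tissues = [f"tissue{j}" for j in range(3)]
    neighbors = {g_: sorted(graph.neighbors(g_)) for g_ in genes}
    for t in range(config.n_traits):
        trait = f"T{t:03d}"
        trait_indications[trait] = f"IND{t:03d}"
        msize = int(rng.integers(config.module_size[0], config.module_size[1] + 1))
        module = _connected_subgraph(graph, msize, rng, genes)
        trait_truth[trait] = module
        records: List[ColocRecord] = []
        n_loci = int(rng.integers(config.loci_per_trait[0], config.loci_per_trait[1] + 1))
        # hit loci are emitted for coding module genes only: a non-coding
        # eGene could never survive the HCGH filter, so planting signal
        # there would decouple the planted world from its recoverable seeds
        detected = [
            g_
            for g_ in sorted(module)
            if g_ in coding_set and rng.random() < config.hcgh_detect_prob
        ]
        trait_detected[trait] = detected
        locus_no = 0
        for gene in detected:
            locus = f"{trait}_L{locus_no:03d}"
            locus_no += 1
            gwas_p = float(_loguniform(rng, *config.gwas_p_hit_dist))
            # the causal eGene
            n_tiss = int(rng.integers(1, 3))
            best = 0.0
            for j in range(n_tiss):
                p12 = float(_scaled_beta(rng, config.p12_hit_dist))
                best = max(best, p12)
                records.append(
                    ColocRecord(
                        trait, locus, gene, tissues[j],
                        gwas_p=gwas_p,
                        eqtl_p=float(_loguniform(rng, *config.eqtl_p_hit_dist)),
                        p12=p12,
                    )
                )
            # decoy candidate eGenes at the same locus (neighbors in the
            # interactome stand in for physical locus neighbors)
            cands = neighbors[gene][: int(rng.integers(1, 4))]
            for c in cands:
                passing_decoy = rng.random() < config.decoy_pass_prob
                records.append(
                    ColocRecord(
                        trait, locus, c, tissues[int(rng.integers(3))],
                        gwas_p=gwas_p,
                        eqtl_p=float(
                            _loguniform(rng, *config.eqtl_p_hit_dist)
                            if passing_decoy
                            else _loguniform(rng, *config.eqtl_p_null_dist)
                        ),
                        p12=float(
                            _scaled_beta(rng, config.p12_hit_dist)
                            if passing_decoy
                            else _scaled_beta(rng, config.p12_null_dist)
                        ),
                    )
                )
        for _ in range(max(0, n_loci - len(detected))):
            locus = f"{trait}_L{locus_no:03d}"
            locus_no += 1
            gene = genes[int(rng.integers(n))]
            records.append(
                ColocRecord(
                    trait, locus, gene, tissues[int(rng.integers(3))],
                    gwas_p=float(_loguniform(rng, *config.gwas_p_null_dist)),
                    eqtl_p=float(_loguniform(rng, *config.eqtl_p_null_dist)),
                    p12=float(_scaled_beta(rng, config.p12_null_dist)),
                )
            )
        trait_coloc[trait] = records

    # trial outcomes: hub-biased testing, planted success odds near modules
    coding_genes = sorted(universe.coding)
    deg_arr = np.array([degree[g_] for g_ in coding_genes], dtype=float)
    w = (deg_arr + 1.0) ** config.target_sampling_degree_exponent
    w /= w.sum()
    mean_deg = float(np.mean([degree[g_] for g_ in genes]))
    base_odds = config.baseline_success_prob / (1.0 - config.baseline_success_prob)
    complex_membership: Dict[str, List[int]] = {}
    for ci, members in enumerate(complexes):
        for g_ in members:
            complex_membership.setdefault(g_, []).append(ci)

    assets: List[AssetRecord] = []
    asset_no = 0
    n_tested = min(config.targets_tested_per_trait, len(coding_genes))
    failed_statuses = ["No Development Reported", "Discontinued", "Withdrawn", "Suspended"]
    failed_probs = [0.755, 0.235, 0.005, 0.005]
    for t in range(config.n_traits):
        trait = f"T{t:03d}"
        module = trait_truth[trait]
        indication = trait_indications[trait]
        if config.success_neighborhood == "network":
            near = set(
                _distance_to_set(graph, set(module), config.neighborhood_radius)
            )
        else:
            # success boost concentrated in complexes containing the seed
            # (signal-carrying) genes, plus the seeds themselves
            seeds_ = trait_detected[trait]
            near = set(seeds_)
            for g_ in seeds_:
                for ci in complex_membership.get(g_, ()):
                    near |= complexes[ci]
        tested = rng.choice(len(coding_genes), size=n_tested, replace=False, p=w)
        for gi in sorted(tested):
            gene = coding_genes[gi]
            odds = base_odds
            if gene in near:
                odds *= config.planted_success_or
            if config.hub_failure_exponent > 0:
                odds *= ((degree[gene] + 1.0) / (mean_deg + 1.0)) ** (
                    -config.hub_failure_exponent
                )
            success = rng.random() < odds / (1.0 + odds)
            targets = {gene}
            if rng.random() < config.nonselective_frac:
                # non-selective assets bind a complex of targets (or a close
                # interactor), not an arbitrary unrelated gene
                partners: List[str] = sorted(
                    {
                        p
                        for ci in complex_membership.get(gene, ())
                        for p in complexes[ci]
                        if p != gene
                    }
                ) or neighbors[gene]
                if partners:
                    targets.add(partners[int(rng.integers(len(partners)))])
            if success:
                status, phase = "Launched", "Launched"
            elif rng.random() < config.clinical_failure_frac:
                status = failed_statuses[
                    int(rng.choice(4, p=failed_probs))
                ]
                phase = ["PhaseI", "PhaseII", "PhaseIII"][int(rng.choice(3, p=[0.4, 0.4, 0.2]))]
            else:
                status = failed_statuses[int(rng.choice(4, p=failed_probs))]
                phase = "Preclinical"
            assets.append(
                AssetRecord(
                    asset_id=f"A{asset_no:06d}",
                    target_genes=frozenset(targets),
                    indication_id=indication,
                    status_text=status,
                    phase_reached=phase,
                )
            )
            asset_no += 1
            if rng.random() < config.in_progress_frac:
                assets.append(
                    AssetRecord(
                        asset_id=f"A{asset_no:06d}",
                        target_genes=frozenset({gene}),
                        indication_id=indication,
                        status_text="Phase II Clinical Trial",
                        phase_reached="PhaseII",
                    )
                )
                asset_no += 1

    # synthetic genomic windows and the LD-correlated variant panel
    windows: Dict[str, GeneWindow] = {}
    n_chrom = 20
    per_chrom = int(np.ceil(n / n_chrom))
    gi = 0
    for c in range(n_chrom):
        pos = 0
        for _ in range(per_chrom):
            if gi >= n:
                break
            gene = genes[gi]
            pos += int(rng.integers(20_000, 200_000))
            body = int(rng.integers(5_000, 100_000))
            windows[gene] = GeneWindow(
                gene_id=gene,
                chrom=f"chr{c + 1}",
                start=pos - WINDOW_BP,
                end=pos + body + WINDOW_BP,
            )
            pos += body
            gi += 1

    variant_stats: Dict[str, VariantBlock] = {}
    if config.with_variants and config.n_traits > 0:
        focal = f"T{config.focal_trait_index:03d}"
        if focal not in trait_truth:
            raise ValueError(f"focal_trait_index out of range: {focal}")
        variant_stats = _variant_panel(
            genes, graph, trait_truth[focal], config, _panel_seed(config, focal)
        )

    return SyntheticWorld(
        config=config,
        knowledge_base=KnowledgeBase(
            universe=universe,
            interactome=interactome,
            complexes=complex_set,
            lr=lr_map,
            pathways=pathway_set,
        ),
        windows=windows,
        trait_coloc=trait_coloc,
        trait_truth=trait_truth,
        trait_detected={t: frozenset(v) for t, v in trait_detected.items()},
        trait_indications=trait_indications,
        assets=assets,
        variant_stats=variant_stats,
    )


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

WORLD_FILES = [
    "config.yaml",
    "universe.tsv",
    "network.tsv",
    "complexes.gmt",
    "pathways.gmt",
    "pathway_edges.tsv",
    "lr_pairs.tsv",
    "coloc.tsv",
    "assets.tsv",
    "traits.tsv",
    "truth.tsv",
    "detected.tsv",
    "windows.tsv",
]


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=_FMT)


def write_world(world: SyntheticWorld, directory: os.PathLike) -> List[Path]:
    """Serialize a world to plain-text files; deterministic ordering."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    written: List[Path] = []

    cfg = asdict(world.config)
    with open(d / "config.yaml", "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)
    written.append(d / "config.yaml")

    kb = world.knowledge_base
    _write_tsv(kb.universe.to_dataframe(), d / "universe.tsv")
    _write_tsv(kb.interactome.to_dataframe(), d / "network.tsv")

    with open(d / "complexes.gmt", "w") as fh:
        for cid, members in zip(kb.complexes.ids, kb.complexes.complexes):
            fh.write("\t".join([cid, "synthetic_complex", *sorted(members)]) + "\n")
    with open(d / "pathways.gmt", "w") as fh:
        for pid, members in kb.pathways.pathways:
            fh.write("\t".join([pid, "synthetic_pathway", *sorted(members)]) + "\n")
    _write_tsv(
        pd.DataFrame(sorted(kb.pathways.edges), columns=["pathway_id", "source", "target"]),
        d / "pathway_edges.tsv",
    )
    _write_tsv(
        pd.DataFrame(sorted(kb.lr.pairs), columns=["ligand_gene", "receptor_gene"]),
        d / "lr_pairs.tsv",
    )

    coloc_rows = [
        (r.trait_id, r.locus_id, r.gene_id, r.tissue, r.gwas_p, r.eqtl_p, r.p12)
        for t in sorted(world.trait_coloc)
        for r in world.trait_coloc[t]
    ]
    _write_tsv(
        pd.DataFrame(
            coloc_rows,
            columns=["trait_id", "locus_id", "gene_id", "tissue", "gwas_p", "eqtl_p", "p12"],
        ),
        d / "coloc.tsv",
    )

    asset_rows = [
        (a.asset_id, g, a.indication_id, a.status_text, a.phase_reached or "")
        for a in world.assets
        for g in sorted(a.target_genes)
    ]
    _write_tsv(
        pd.DataFrame(
            asset_rows,
            columns=["asset_id", "gene_id", "indication_id", "status_text", "phase_reached"],
        ),
        d / "assets.tsv",
    )

    _write_tsv(
        pd.DataFrame(
            sorted(world.trait_indications.items()), columns=["trait_id", "indication_id"]
        ),
        d / "traits.tsv",
    )
    _write_tsv(
        pd.DataFrame(
            [(t, g) for t in sorted(world.trait_truth) for g in sorted(world.trait_truth[t])],
            columns=["trait_id", "gene_id"],
        ),
        d / "truth.tsv",
    )
    _write_tsv(
        pd.DataFrame(
            [(t, g) for t in sorted(world.trait_detected) for g in sorted(world.trait_detected[t])],
            columns=["trait_id", "gene_id"],
        ),
        d / "detected.tsv",
    )
    _write_tsv(
        pd.DataFrame(
            [
                (w.gene_id, w.chrom, w.start, w.end)
                for w in (world.windows[g] for g in sorted(world.windows))
            ],
            columns=["gene_id", "chrom", "start", "end"],
        ),
        d / "windows.tsv",
    )
    written += [d / f for f in WORLD_FILES[1:]]

    if world.variant_stats:
        (d / "variants").mkdir(exist_ok=True)
        (d / "ld").mkdir(exist_ok=True)
        for g in sorted(world.variant_stats):
            b = world.variant_stats[g]
            _write_tsv(
                pd.DataFrame({"variant_id": b.variant_ids, "z": b.z}),
                d / "variants" / f"{g}.tsv",
            )
            np.savetxt(d / "ld" / f"{g}.tsv", b.R, delimiter="\t", fmt=_FMT)
            written += [d / "variants" / f"{g}.tsv", d / "ld" / f"{g}.tsv"]
    return written


def read_gmt(path: Path) -> List[Tuple[str, FrozenSet[str]]]:
    """Standard GMT: set_id TAB description TAB members...; duplicate members
    are deduplicated with a warning."""
    sets = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                raise WorldIOError(f"{path}:{ln}: GMT line has fewer than 3 fields")
            members = parts[2:]
            unique = frozenset(members)
            if len(unique) < len(members):
                warnings.warn(
                    f"{path.name}:{ln}: duplicate genes in set {parts[0]}; deduplicated",
                    stacklevel=2,
                )
            sets.append((parts[0], unique))
    return sets


def read_world(directory: os.PathLike) -> SyntheticWorld:
    """Read a world back; raises :class:`WorldIOError` naming missing files."""
    d = Path(directory)
    missing = [f for f in WORLD_FILES if not (d / f).exists()]
    if missing:
        raise WorldIOError(f"missing world files in {d}: {', '.join(missing)}")

    with open(d / "config.yaml") as fh:
        raw = yaml.safe_load(fh)
    for key in (
        "complex_size_range",
        "pathway_size_range",
        "module_size",
        "loci_per_trait",
        "p12_hit_dist",
        "p12_null_dist",
        "gwas_p_hit_dist",
        "gwas_p_null_dist",
        "eqtl_p_hit_dist",
        "eqtl_p_null_dist",
    ):
        raw[key] = tuple(raw[key])
    config = SimulationConfig(**raw)

    try:
        universe = GeneUniverse.from_dataframe(pd.read_csv(d / "universe.tsv", sep="\t"))
        net_df = pd.read_csv(d / "network.tsv", sep="\t", float_precision="round_trip")
        interactome = Interactome.from_edges(
            net_df.itertuples(index=False, name=None), name=config.topology
        )
        cx = read_gmt(d / "complexes.gmt")
        complex_set = ComplexSet(
            complexes=[m for _, m in cx], ids=[cid for cid, _ in cx]
        )
        pw = read_gmt(d / "pathways.gmt")
        pe_df = pd.read_csv(d / "pathway_edges.tsv", sep="\t")
        pathway_set = PathwaySet(
            pathways=pw, edges=[tuple(r) for r in pe_df.itertuples(index=False, name=None)]
        )
        lr_df = pd.read_csv(d / "lr_pairs.tsv", sep="\t")
        lr_map = LigandReceptorMap.from_pairs(
            lr_df.itertuples(index=False, name=None)
        )

        coloc_df = pd.read_csv(d / "coloc.tsv", sep="\t", float_precision="round_trip")
        trait_coloc: Dict[str, List[ColocRecord]] = {}
        for row in coloc_df.itertuples(index=False):
            trait_coloc.setdefault(row.trait_id, []).append(
                ColocRecord(
                    row.trait_id, row.locus_id, row.gene_id, row.tissue,
                    gwas_p=float(row.gwas_p), eqtl_p=float(row.eqtl_p), p12=float(row.p12),
                )
            )
        assets = assets_from_frame(
            pd.read_csv(d / "assets.tsv", sep="\t"), indication_blacklist=frozenset()
        )
        traits_df = pd.read_csv(d / "traits.tsv", sep="\t")
        trait_indications = dict(
            zip(traits_df["trait_id"], traits_df["indication_id"])
        )
        truth_df = pd.read_csv(d / "truth.tsv", sep="\t")
        trait_truth = {
            t: frozenset(sub["gene_id"]) for t, sub in truth_df.groupby("trait_id")
        }
        det_df = pd.read_csv(d / "detected.tsv", sep="\t")
        trait_detected = {
            t: frozenset(sub["gene_id"]) for t, sub in det_df.groupby("trait_id")
        }
        for t in trait_truth:
            trait_detected.setdefault(t, frozenset())
        win_df = pd.read_csv(d / "windows.tsv", sep="\t")
        windows = {
            row.gene_id: GeneWindow(row.gene_id, row.chrom, int(row.start), int(row.end))
            for row in win_df.itertuples(index=False)
        }
    except WorldIOError:
        raise
    except Exception as exc:  # surface the offending file
        raise WorldIOError(f"malformed world file in {d}: {exc}") from exc

    variant_stats: Dict[str, VariantBlock] = {}
    vdir = d / "variants"
    if vdir.is_dir():
        for path in sorted(vdir.glob("*.tsv")):
            gene = path.stem
            vdf = pd.read_csv(path, sep="\t", float_precision="round_trip")
            ld_path = d / "ld" / f"{gene}.tsv"
            if not ld_path.exists():
                raise WorldIOError(f"missing LD matrix for gene {gene}: {ld_path}")
            R = np.loadtxt(ld_path, delimiter="\t", ndmin=2)
            variant_stats[gene] = VariantBlock(
                gene_id=gene,
                z=vdf["z"].to_numpy(),
                R=R,
                variant_ids=tuple(vdf["variant_id"]),
            )

    return SyntheticWorld(
        config=config,
        knowledge_base=KnowledgeBase(
            universe=universe,
            interactome=interactome,
            complexes=complex_set,
            lr=lr_map,
            pathways=pathway_set,
        ),
        windows=windows,
        trait_coloc=trait_coloc,
        trait_truth=trait_truth,
        trait_detected=trait_detected,
        trait_indications=trait_indications,
        assets=assets,
        variant_stats=variant_stats,
    )
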