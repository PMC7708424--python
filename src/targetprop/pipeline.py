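"""End-to-end orchestration: simulate -> HCGH -> expand/propagate/score ->
stratified enrichment -> gene-score distributions.

``run_all`` executes the whole analysis on a synthetic (or loaded) world and
returns a :class:`RunResult` bundling every intermediate product; with an
output directory it also writes the tab-separated result tables and a run
manifest recording all seeds and parameters.
"""

from __future__ import annotations

import logging
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
import yaml

from . import clinical, enrichment, genescore, hcgh, knowledge, propagation
from .clinical import Outcome, TargetIndicationOutcome
from .enrichment import ContingencyTable, EnrichmentResult
from .genescore import GeneScore
from .hcgh import HcghSet
from .knowledge import ProxySet
from .propagation import HeatVector, InsulatedDiffusion
from .synthetic_data import SimulationConfig, SyntheticWorld, generate_world, read_world

logger = logging.getLogger("targetprop")

ALL_METHODS = [
    "hcgh",
    "complex",
    "ligand_receptor",
    "net_neighbor1",
    "net_neighbor2",
    "pathway_clique",
    "pathway_neighbor1",
    "pathway_neighbor2",
    "random",
    "hotnet",
    "pascal",
]


@dataclass
class RunConfig:
    """Configuration of one end-to-end run."""

    simulation: Optional[SimulationConfig] = None
    world_dir: Optional[str] = None
    methods: List[str] = field(default_factory=lambda: list(ALL_METHODS))
    beta: float = 0.4
    k_min: int = 3
    delta_n_perm: int = 10
    delta_candidates: int = 12
    pathway_n_perm: int = 10_000
    score_traits: Optional[int] = 10  # max traits given per-trait gene scores
    random_n: Optional[int] = None  # None -> reference sampling fraction
    seed: int = 0
    out_dir: Optional[str] = None

    def __post_init__(self):
        if self.simulation is None and self.world_dir is None:
            self.simulation = SimulationConfig()
        unknown = set(self.methods) - set(ALL_METHODS)
        if unknown:
            raise ValueError(f"unknown methods: {sorted(unknown)}")


@dataclass
class RunResult:
    world: SyntheticWorld
    hcgh_sets: Dict[str, HcghSet]
    retained_traits: List[str]
    outcomes: List[TargetIndicationOutcome]
    proxy_sets: List[ProxySet]
    tables: List[ContingencyTable]
    enrichment: Dict[str, Optional[EnrichmentResult]]
    summary: pd.DataFrame
    scores_by_trait: Dict[str, Dict[str, GeneScore]]
    score_distributions: pd.DataFrame
    manifest: Dict
    modules: List = field(default_factory=list)
    heats: Dict[str, HeatVector] = field(default_factory=dict)


def outcome_genes_by_trait(
    outcomes: Sequence[TargetIndicationOutcome],
    indication_map: Mapping[str, Set[str]],
) -> Dict[str, Set[str]]:
    """Genes with a Succeeded/ClinicalFailure outcome per matched trait."""
    by_ind: Dict[str, Set[str]] = {}
    for o in outcomes:
        if o.outcome in (Outcome.SUCCEEDED, Outcome.CLINICAL_FAILURE):
            by_ind.setdefault(o.indication_id, set()).add(o.gene_id)
    return {
        t: set().union(*(by_ind.get(i, set()) for i in inds))
        for t, inds in indication_map.items()
    }


def best_p12_heat(records: Sequence[hcgh.ColocRecord]) -> HeatVector:
    """Heat from the best colocalization record of every gene with any
    record for the trait (seeds are simply the hottest genes)."""
    best: Dict[str, float] = {}
    for r in records:
        if r.p12 > best.get(r.gene_id, -1.0):
            best[r.gene_id] = r.p12
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # p12 ~ 1 clipping is routine here
        return HeatVector.from_p12(best)


def pathway_enrichment_analysis(
    world: SyntheticWorld,
    n_perm: int = 1000,
    seed: int = 0,
    panel: Optional[Mapping[str, genescore.VariantBlock]] = None,
    fusion_groups: Optional[Dict[str, List[List[str]]]] = None,
) -> Tuple[Dict[str, GeneScore], List[genescore.PathwayEnrichmentResult]]:
    """Gene scores plus fused, BH-adjusted pathway enrichment for one
    variant panel (default: the world's stored focal-trait panel)."""
    panel = dict(panel) if panel is not None else world.variant_stats
    scores = genescore.score_genes(list(panel.values()))
    if fusion_groups is None:
        fusion_groups = pathway_fusion_groups(world, set(panel))
    results = []
    rng = np.random.default_rng(seed)
    screen_n = min(500, n_perm)
    for pid, _ in world.knowledge_base.pathways.pathways:
        fused_scores: Dict[str, GeneScore] = {}
        for group in fusion_groups.get(pid, []):
            if len(group) == 1:
                fused_scores[group[0]] = scores[group[0]]
            else:
                block = genescore.merge_blocks(panel, group)
                fused_scores[block.gene_id] = genescore.sum_gene_score(block)
        if not fused_scores:
            continue
        # adaptive permutation: cheap screen, then full depth only where the
        # screen suggests significance (the add-one floor must be able to
        # survive BH across the collection)
        pseed = int(rng.integers(2**31 - 1))
        res = genescore.pathway_empirical_p(
            fused_scores,
            pid,
            set(fused_scores),
            universe_scores=scores,
            n_perm=screen_n,
            seed=pseed,
        )
        if res is not None and res.p_value <= 0.05 and n_perm > screen_n:
            res = genescore.pathway_empirical_p(
                fused_scores,
                pid,
                set(fused_scores),
                universe_scores=scores,
                n_perm=n_perm,
                seed=pseed,
            )
        if res is not None:
            results.append(res)
    return scores, genescore.adjust_pathway_results(results)


def pathway_fusion_groups(
    world: SyntheticWorld, available: Set[str]
) -> Dict[str, List[List[str]]]:
    """Window-overlap fusion groups per pathway (panel-independent)."""
    return {
        pid: genescore.window_fusion_groups(set(members), world.windows, available)
        for pid, members in world.knowledge_base.pathways.pathways
    }


def expand_trait(
    world: SyntheticWorld,
    trait: str,
    seeds: Set[str],
    methods: Sequence[str],
    config: RunConfig,
    diffusion_op: Optional[InsulatedDiffusion] = None,
    pathway_results: Optional[Sequence[genescore.PathwayEnrichmentResult]] = None,
    gene_scores: Optional[Mapping[str, GeneScore]] = None,
    rng: Optional[np.random.Generator] = None,
    module_sink: Optional[List] = None,
    heat_sink: Optional[Dict[str, HeatVector]] = None,
) -> List[ProxySet]:
    """All requested proxy sets for one trait."""
    kb = world.knowledge_base
    rng = rng or np.random.default_rng(config.seed)
    out: List[ProxySet] = []
    for m in methods:
        if m == "hcgh":
            out.append(ProxySet(trait, "hcgh", frozenset(), frozenset(seeds)))
        elif m == "complex":
            out.append(knowledge.complex_proxies(seeds, kb.complexes, trait))
        elif m == "ligand_receptor":
            out.append(knowledge.ligand_receptor_proxies(seeds, kb.lr, trait))
        elif m in ("net_neighbor1", "net_neighbor2"):
            out.append(
                knowledge.network_neighbors(seeds, kb.interactome, int(m[-1]), trait)
            )
        elif m == "pathway_clique":
            out.append(knowledge.pathway_clique_proxies(seeds, kb.pathways, trait))
        elif m in ("pathway_neighbor1", "pathway_neighbor2"):
            out.append(
                knowledge.pathway_neighbors(seeds, kb.pathways, int(m[-1]), trait)
            )
        elif m == "random":
            out.append(
                knowledge.random_proxies(
                    kb.universe,
                    n=config.random_n,
                    seed=int(rng.integers(2**31 - 1)),
                    trait_id=trait,
                    exclude_seeds=seeds,
                )
            )
        elif m == "hotnet":
            if diffusion_op is None:
                diffusion_op = InsulatedDiffusion(kb.interactome, beta=config.beta)
            heat = best_p12_heat(world.trait_coloc.get(trait, []))
            delta = propagation.select_delta(
                diffusion_op,
                heat,
                n_perm=config.delta_n_perm,
                seed=int(rng.integers(2**31 - 1)),
                k_min=config.k_min,
                n_candidates=config.delta_candidates,
            )
            if np.isfinite(delta):
                E = diffusion_op.exchanged_heat(heat)
                modules = propagation.extract_modules(
                    E, diffusion_op.genes, delta, config.k_min, trait,
                    diffusion_op.network_name,
                )
            else:
                modules = []
            if module_sink is not None:
                module_sink.extend(modules)
            if heat_sink is not None:
                heat_sink[trait] = heat
            out.append(propagation.propagation_proxies(modules, seeds, trait))
        elif m == "pascal":
            if pathway_results is None or gene_scores is None:
                raise ValueError("pascal method requires pathway enrichment inputs")
            out.append(
                genescore.select_pathway_proxies(
                    pathway_results,
                    gene_scores,
                    world.knowledge_base.pathways.membership(),
                    hla_genes=set(kb.universe.hla),
                    seeds=seeds,
                    trait_id=trait,
                )
            )
    return out


def proxy_score_distributions(
    proxy_sets: Sequence[ProxySet],
    scores_by_trait: Mapping[str, Mapping[str, GeneScore]],
) -> pd.DataFrame:
    """Per-method distribution of -log10 gene-score p for proxy genes,
    scored against the proxy's own trait (seeds are already excluded from
    every proxy set). Proxy sets for unscored traits are skipped."""
    rows = []
    by_method: Dict[str, List[float]] = {}
    for ps in proxy_sets:
        gene_scores = scores_by_trait.get(ps.trait_id)
        if gene_scores is None:
            continue
        vals = [
            -np.log10(gene_scores[g].p_value)
            for g in ps.proxies
            if g in gene_scores
        ]
        by_method.setdefault(ps.method, []).extend(vals)
    for m in sorted(by_method):
        v = np.array(by_method[m])
        if v.size == 0:
            continue
        q = np.percentile(v, [5, 25, 50, 75, 95])
        rows.append((m, v.size, *q, float(v.mean())))
    return pd.DataFrame(
        rows,
        columns=["method", "n_genes", "q05", "q25", "median", "q75", "q95", "mean"],
    )


def run_all(config: RunConfig) -> RunResult:
    """Execute the full analysis; every stage logs its counts."""
    t0 = time.time()
    rng = np.random.default_rng(config.seed)

    if config.world_dir is not None:
        world = read_world(config.world_dir)
    else:
        world = generate_world(config.simulation)
    kb = world.knowledge_base
    logger.info(
        "world: %d genes, %d interactions, %d traits",
        len(kb.universe), kb.interactome.graph.number_of_edges(), len(world.trait_coloc),
    )

    outcomes = clinical.classify_target_indication(world.assets)
    logger.info("outcomes: %d target-indication pairs", len(outcomes))

    hcgh_sets: Dict[str, HcghSet] = {}
    for trait, records in world.trait_coloc.items():
        if not records:
            continue
        hs = hcgh.define_hcghs(records, kb.universe)
        if len(hs):
            hcgh_sets[trait] = hs
    indication_map = world.indication_map()
    outcome_genes = outcome_genes_by_trait(outcomes, indication_map)
    retained = hcgh.retain_traits(hcgh_sets, outcome_genes)
    logger.info("traits: %d with >=1 HCGH, %d retained", len(hcgh_sets), len(retained))

    # per-trait variant panels, gene scores and pathway enrichment: each
    # trait's GWAS carries signal around its own planted module
    needs_scores = "pascal" in config.methods
    scores_by_trait: Dict[str, Dict[str, GeneScore]] = {}
    results_by_trait: Dict[str, List[genescore.PathwayEnrichmentResult]] = {}
    if needs_scores and world.variant_stats:
        scored_traits = (
            retained
            if config.score_traits is None
            else retained[: config.score_traits]
        )
        fusion_groups = pathway_fusion_groups(world, set(world.variant_stats))
        from .synthetic_data import variant_panel_for_trait

        for trait in scored_traits:
            panel = variant_panel_for_trait(world, trait)
            scores_by_trait[trait], results_by_trait[trait] = (
                pathway_enrichment_analysis(
                    world,
                    n_perm=config.pathway_n_perm,
                    seed=int(rng.integers(2**31 - 1)),
                    panel=panel,
                    fusion_groups=fusion_groups,
                )
            )
        logger.info("gene scores computed for %d traits", len(scores_by_trait))

    diffusion_op = None
    if "hotnet" in config.methods:
        diffusion_op = InsulatedDiffusion(kb.interactome, beta=config.beta)

    proxy_sets: List[ProxySet] = []
    modules: List[propagation.NetworkModule] = []
    heats: Dict[str, HeatVector] = {}
    for trait in retained:
        seeds = set(hcgh_sets[trait].genes)
        methods = [
            m
            for m in config.methods
            if m != "pascal" or trait in scores_by_trait
        ]
        proxy_sets.extend(
            expand_trait(
                world, trait, seeds, methods, config,
                diffusion_op=diffusion_op,
                pathway_results=results_by_trait.get(trait),
                gene_scores=scores_by_trait.get(trait),
                rng=rng,
                module_sink=modules,
                heat_sink=heats,
            )
        )

    tables: List[ContingencyTable] = []
    results: Dict[str, Optional[EnrichmentResult]] = {}
    n_removed = 0
    by_method: Dict[str, List[ContingencyTable]] = {m: [] for m in config.methods}
    sizes: Dict[str, List[int]] = {m: [] for m in config.methods}
    outcomes_by_ind: Dict[str, List[TargetIndicationOutcome]] = {}
    for o in outcomes:
        outcomes_by_ind.setdefault(o.indication_id, []).append(o)
    for ps in proxy_sets:
        sizes[ps.method].append(len(ps.proxies))
        relevant = [
            o
            for ind in indication_map.get(ps.trait_id, ())
            for o in outcomes_by_ind.get(ind, ())
        ]
        t = enrichment.build_table(ps, relevant, indication_map, kb.universe)
        if t is None:
            n_removed += 1
            continue
        by_method[ps.method].append(t)
        tables.append(t)
    for m in config.methods:
        if by_method[m]:
            r = enrichment.cmh_pool(by_method[m], method=m)
            r.mean_new_targets = float(np.mean(sizes[m])) if sizes[m] else np.nan
            results[m] = r
        else:
            results[m] = None
    logger.info("enrichment: %d strata kept, %d removed", len(tables), n_removed)

    summary = enrichment.summarize_methods(results, proxy_sets)
    score_dist = (
        proxy_score_distributions(proxy_sets, scores_by_trait)
        if scores_by_trait
        else pd.DataFrame()
    )

    manifest = {
        "seed": config.seed,
        "methods": list(config.methods),
        "beta": config.beta,
        "k_min": config.k_min,
        "delta_n_perm": config.delta_n_perm,
        "pathway_n_perm": config.pathway_n_perm,
        "n_traits_retained": len(retained),
        "n_strata": len(tables),
        "n_strata_removed": n_removed,
        "runtime_s": round(time.time() - t0, 2),
        "simulation": None
        if config.simulation is None
        else {
            k: list(v) if isinstance(v, tuple) else v
            for k, v in vars(config.simulation).items()
        },
    }

    result = RunResult(
        world=world,
        hcgh_sets=hcgh_sets,
        retained_traits=retained,
        outcomes=outcomes,
        proxy_sets=proxy_sets,
        tables=tables,
        enrichment=results,
        summary=summary,
        scores_by_trait=scores_by_trait,
        score_distributions=score_dist,
        manifest=manifest,
        modules=modules,
        heats=heats,
    )
    if config.out_dir is not None:
        write_results(result, config.out_dir)
    return result


def write_results(result: RunResult, out_dir) -> None:
    d = Path(out_dir)
    d.mkdir(parents=True, exist_ok=True)
    hcgh.hcghs_to_frame(result.hcgh_sets).to_csv(d / "hcgh.tsv", sep="\t", index=False)
    knowledge.proxy_sets_to_frame(result.proxy_sets).to_csv(
        d / "proxies.tsv", sep="\t", index=False
    )
    clinical.outcomes_to_frame(result.outcomes).to_csv(
        d / "outcomes.tsv", sep="\t", index=False
    )
    pd.DataFrame(
        [
            (t.method, t.trait_id, t.a, t.b, t.c, t.d, int(t.corrected))
            for t in result.tables
        ],
        columns=["method", "trait_id", "a", "b", "c", "d", "corrected"],
    ).to_csv(d / "tables.tsv", sep="\t", index=False)
    result.summary.to_csv(d / "enrichment.tsv", sep="\t", index=False)
    if result.modules:
        pd.DataFrame(
            [
                (m.trait_id, m.network, i, g, m.delta)
                for i, m in enumerate(result.modules)
                for g in sorted(m.genes)
            ],
            columns=["trait_id", "network", "module_id", "gene_id", "delta"],
        ).to_csv(d / "modules.tsv", sep="\t", index=False)
    if result.heats:
        pd.DataFrame(
            [
                (t, g, h)
                for t in sorted(result.heats)
                for g, h in sorted(result.heats[t].heat.items())
            ],
            columns=["trait_id", "gene_id", "heat"],
        ).to_csv(d / "heat.tsv", sep="\t", index=False)
    if not result.score_distributions.empty:
        result.score_distributions.to_csv(
            d / "score_distributions.tsv", sep="\t", index=False
        )
    with open(d / "manifest.yaml", "w") as fh:
        yaml.safe_dump(result.manifest, fh, sort_keys=True)


def plot_enrichment(summary: pd.DataFrame, path) -> None:
    """Forest plot of per-method pooled odds ratios with 95% CIs."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = summary.dropna(subset=["OR"]).reset_index(drop=True)
    fig, ax = plt.subplots(figsize=(6, 0.5 * max(len(df), 2) + 1))
    y = np.arange(len(df))
    ax.errorbar(
        df["OR"], y,
        xerr=[df["OR"] - df["ci_low"], df["ci_high"] - df["OR"]],
        fmt="o", color="tab:blue", ecolor="gray", capsize=3,
    )
    ax.axvline(1.0, color="k", lw=0.8, ls="--")
    ax.set_yticks(y)
    ax.set_yticklabels(df["method"])
    ax.set_xscale("log")
    ax.set_xlabel("pooled odds ratio (95% CI)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
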