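"""Synthetic world generator: determinism, planted structure, round trips."""

import numpy as np
import pytest
from scipy import stats

from targetprop.clinical import classify_target_indication, outcome_sets
from targetprop.synthetic_data import (
    SimulationConfig,
    WorldIOError,
    generate_world,
    read_world,
    variant_panel_for_trait,
    write_world,
)


def test_fixed_seed_bit_reproducible(tmp_path):
    cfg = SimulationConfig(n_genes=150, n_traits=3, seed=1)
    w1, w2 = generate_world(cfg), generate_world(cfg)
    assert w1.equals(w2)
    write_world(w1, tmp_path / "a")
    write_world(w2, tmp_path / "b")
    for f in sorted((tmp_path / "a").rglob("*")):
        if f.is_file():
            other = tmp_path / "b" / f.relative_to(tmp_path / "a")
            assert f.read_bytes() == other.read_bytes(), f.name


def test_round_trip_identity(tmp_path):
    cfg = SimulationConfig(n_genes=120, n_traits=3, seed=3)
    w = generate_world(cfg)
    write_world(w, tmp_path)
    w2 = read_world(tmp_path)
    assert w.equals(w2)


def test_empty_directory_error_lists_missing(tmp_path):
    with pytest.raises(WorldIOError, match="universe.tsv"):
        read_world(tmp_path)


def test_gmt_duplicate_deduplicated_with_warning(tmp_path):
    from targetprop.synthetic_data import read_gmt

    p = tmp_path / "x.gmt"
    p.write_text("s1\tdesc\tg1\tg2\tg1\n")
    with pytest.warns(UserWarning, match="duplicate"):
        sets = read_gmt(p)
    assert sets == [("s1", frozenset({"g1", "g2"}))]


def test_sizing_error():
    with pytest.raises(ValueError, match="n_genes"):
        SimulationConfig(n_genes=50, pathway_size_range=(10, 100)).validate()
    with pytest.raises(ValueError):
        SimulationConfig(coding_fraction=1.5).validate()
    with pytest.raises(ValueError):
        SimulationConfig(planted_success_or=0.0).validate()


def test_world_structure(small_world):
    w = small_world
    kb = w.knowledge_base
    genes = kb.universe.gene_set
    # every referenced gene is in the universe
    for members in kb.complexes.complexes:
        assert members <= genes
    for _, m in kb.pathways.pathways:
        assert m <= genes
    for t, module in w.trait_truth.items():
        assert module <= genes
        # planted module is a connected subgraph
        sub = kb.interactome.graph.subgraph(module)
        import networkx as nx

        assert nx.is_connected(sub)
    # one indication per trait
    assert len(set(w.trait_indications.values())) == len(w.trait_indications)


def test_scale_free_heavier_tailed_than_er():
    ba = generate_world(SimulationConfig(n_genes=500, n_traits=1, seed=2, with_variants=False))
    er = generate_world(
        SimulationConfig(n_genes=500, n_traits=1, seed=2, topology="erdos_renyi", with_variants=False)
    )
    dmax_ba = max(d for _, d in ba.knowledge_base.interactome.graph.degree())
    dmax_er = max(d for _, d in er.knowledge_base.interactome.graph.degree())
    assert dmax_ba > 2 * dmax_er


def test_hub_bias_in_tested_targets():
    """With degree exponent > 0, degree correlates positively with the
    number of indications a gene was tested against."""
    w = generate_world(
        SimulationConfig(
            n_genes=400, n_traits=40, seed=5, with_variants=False,
            target_sampling_degree_exponent=1.0,
        )
    )
    counts = {}
    for a in w.assets:
        for g in a.target_genes:
            counts.setdefault(g, set()).add(a.indication_id)
    deg = dict(w.knowledge_base.interactome.graph.degree())
    genes = sorted(counts)
    rho = stats.spearmanr([deg[g] for g in genes], [len(counts[g]) for g in genes])
    assert rho.statistic > 0.2


def test_null_world_success_independent_of_module_distance():
    """planted_success_or = 1: success rates of module-adjacent and distant
    tested targets agree within 3 binomial SE."""
    import networkx as nx

    w = generate_world(
        SimulationConfig(n_genes=500, n_traits=40, seed=9, planted_success_or=1.0,
                         with_variants=False)
    )
    outcomes = classify_target_indication(w.assets)
    pos, neg = outcome_sets(outcomes)
    ind_to_trait = {v: k for k, v in w.trait_indications.items()}
    g = w.knowledge_base.interactome.graph
    near_stats, far_stats = [0, 0], [0, 0]  # [successes, total]
    for (gene, ind), label in [(p, 1) for p in pos] + [(n, 0) for n in neg]:
        trait = ind_to_trait[ind]
        module = w.trait_truth[trait]
        near = gene in module or any(
            gene in g[m] for m in module if m in g
        )
        bucket = near_stats if near else far_stats
        bucket[0] += label
        bucket[1] += 1
    p_near = near_stats[0] / max(near_stats[1], 1)
    p_far = far_stats[0] / max(far_stats[1], 1)
    se = np.sqrt(p_far * (1 - p_far) * (1 / max(near_stats[1], 1) + 1 / max(far_stats[1], 1)))
    assert abs(p_near - p_far) < 3 * se


def test_planted_coloc_records_pass_filters(small_world):
    """Module-adjacent loci carry records above all four HCGH thresholds."""
    from targetprop.hcgh import define_hcghs

    w = small_world
    recalls = []
    for t, records in w.trait_coloc.items():
        hs = define_hcghs(records, w.knowledge_base.universe)
        module = w.trait_truth[t]
        coding_module = module & w.knowledge_base.universe.coding
        if coding_module:
            recalls.append(len(hs.genes & module) / len(coding_module))
    assert np.mean(recalls) > 0.6


def test_null_variant_z_chisq_distributed():
    """causal_effect_mu = 0, ld_rho = 0: per-variant z^2 follows chi2_1
    (KS on ~1e5 draws)."""
    w = generate_world(
        SimulationConfig(
            n_genes=400, n_traits=1, seed=13, causal_effect_mu=0.0, ld_rho=0.0,
            variants_per_gene=250, module_size=(2, 3), loci_per_trait=(2, 3),
            targets_tested_per_trait=5,
        )
    )
    z2 = np.concatenate([b.z**2 for b in w.variant_stats.values()])
    assert z2.size >= 1e5
    assert stats.kstest(z2, "chi2", args=(1,)).pvalue > 0.01


def test_per_trait_panels_deterministic_and_trait_specific(small_world):
    w = small_world
    traits = sorted(w.trait_truth)
    p1 = variant_panel_for_trait(w, traits[1])
    p1b = variant_panel_for_trait(w, traits[1])
    g = next(iter(p1))
    assert np.array_equal(p1[g].z, p1b[g].z)
    # focal trait panel is the stored one
    focal = f"T{w.config.focal_trait_index:03d}"
    pf = variant_panel_for_trait(w, focal)
    assert pf is w.variant_stats
    # signal sits on the trait's own module
    from targetprop.genescore import sum_gene_score

    module_p = [sum_gene_score(p1[g]).p_value for g in w.trait_truth[traits[1]]]
    other_p = [sum_gene_score(p1[g]).p_value for g in sorted(w.trait_truth[traits[3]] - w.trait_truth[traits[1]])]
    assert np.median(module_p) < 0.01
    assert np.median(module_p) < np.median(other_p)
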