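"""Gene scores, weighted chi-square tail, fusion, pathway enrichment, BH."""

import numpy as np
import pytest
from scipy import stats

from targetprop.genescore import (
    GeneScore,
    GeneWindow,
    VariantBlock,
    bh_adjust,
    fuse_genes,
    pathway_empirical_p,
    score_genes,
    select_pathway_proxies,
    sum_gene_score,
    weighted_chisq_sf,
)


def block(gene, z, R=None, ids=None):
    z = np.atleast_1d(np.asarray(z, dtype=float))
    if R is None:
        R = np.eye(z.size)
    return VariantBlock(gene, z, np.asarray(R, float), tuple(ids) if ids else ())


def test_single_variant_chi2_tail():
    s = sum_gene_score(block("g", [1.959964]))
    assert s.p_value == pytest.approx(0.05, abs=1e-6)
    assert s.statistic == pytest.approx(1.959964**2)


def test_independent_variants_chi2_m():
    # m=2, T at the chi2_2 95th percentile
    z = np.sqrt(np.array([5.991464547 / 2] * 2))
    s = sum_gene_score(block("g", z))
    assert s.p_value == pytest.approx(0.05, abs=1e-6)


def test_perfect_ld_closed_form_and_mc():
    """All-ones R: eigenvalues (m, 0, .., 0), so p = P(chi2_1 > T/m);
    agreement with a Monte-Carlo oracle within 3 MC SE."""
    m, zval = 3, 1.7
    R = np.ones((m, m))
    s = sum_gene_score(block("g", [zval] * m, R))
    T = m * zval**2
    assert s.p_value == pytest.approx(stats.chi2.sf(T / m, 1), rel=1e-12)

    rng = np.random.default_rng(0)
    draws = rng.standard_normal(100_000)
    Q = m * draws**2
    mc = float((Q > T).mean())
    se = np.sqrt(mc * (1 - mc) / 100_000)
    assert abs(s.p_value - mc) <= 3 * se


def test_non_psd_rejected_naming_gene():
    R = np.array([[1.0, 2.0], [2.0, 1.0]])
    with pytest.raises(ValueError, match="gBAD"):
        sum_gene_score(block("gBAD", [1.0, 1.0], R))


def test_empty_block_skipped_with_warning():
    b1 = block("g1", [1.0])
    b0 = VariantBlock.__new__(VariantBlock)
    b0.gene_id, b0.z, b0.R, b0.variant_ids = "g0", np.empty(0), np.empty((0, 0)), ()
    with pytest.warns(UserWarning, match="skipped"):
        scores = score_genes([b1, b0])
    assert set(scores) == {"g1"}


def test_null_calibration_uniform_pvalues():
    """z ~ MVN(0, R) per gene gives uniform gene-score p (KS)."""
    rng = np.random.default_rng(11)
    m = 6
    idx = np.arange(m)
    R = 0.6 ** np.abs(idx[:, None] - idx[None, :])
    L = np.linalg.cholesky(R)
    ps = []
    for i in range(400):
        z = L @ rng.standard_normal(m)
        ps.append(sum_gene_score(block(f"g{i}", z, R)).p_value)
    assert stats.kstest(ps, "uniform").pvalue > 0.01


# ---------------------------------------------------------------------------
# fusion
# ---------------------------------------------------------------------------

W = {
    "gA": GeneWindow("gA", "chr1", 0, 100),
    "gB": GeneWindow("gB", "chr1", 50, 150),
    "gC": GeneWindow("gC", "chr1", 140, 250),
    "gD": GeneWindow("gD", "chr2", 0, 100),
}


def test_fusion_identity_when_no_overlap():
    blocks = {"gA": block("gA", [1.0]), "gD": block("gD", [2.0])}
    fused = fuse_genes(blocks, {"gA", "gD"}, W)
    assert sorted(b.gene_id for b in fused) == ["gA", "gD"]


def test_fusion_dedups_shared_variants():
    bA = block("gA", [1.0, 2.0], ids=["v1", "v2"])
    bB = block("gB", [2.0, 3.0], ids=["v2", "v3"])
    fused = fuse_genes({"gA": bA, "gB": bB}, {"gA", "gB"}, W)
    assert len(fused) == 1
    f = fused[0]
    assert f.gene_id == "gA+gB"
    assert set(f.variant_ids) == {"v1", "v2", "v3"}
    assert len(f) == 3


def test_fusion_transitive_chain():
    blocks = {g: block(g, [1.0]) for g in ("gA", "gB", "gC")}
    fused = fuse_genes(blocks, {"gA", "gB", "gC"}, W)
    assert [b.gene_id for b in fused] == ["gA+gB+gC"]


def test_fusion_never_loses_variants():
    blocks = {g: block(g, [1.0, 2.0]) for g in W}
    fused = fuse_genes(blocks, set(W), W)
    total = sum(len(b) for b in fused)
    covered = set().union(*(b.variant_ids for b in fused))
    assert total == len(covered)
    assert covered == set().union(*(blocks[g].variant_ids for g in W))


# ---------------------------------------------------------------------------
# pathway enrichment
# ---------------------------------------------------------------------------


def _null_scores(n, seed):
    rng = np.random.default_rng(seed)
    return {
        f"g{i}": GeneScore(f"g{i}", 0.0, float(rng.uniform(1e-12, 1.0)))
        for i in range(n)
    }


def test_whole_universe_pathway_p_one():
    scores = _null_scores(50, 0)
    res = pathway_empirical_p(scores, "p", set(scores), n_perm=100, seed=1)
    assert res.p_value == 1.0


def test_top_genes_pathway_significant():
    scores = _null_scores(500, 1)
    top5 = sorted(scores, key=lambda g: scores[g].p_value)[:5]
    res = pathway_empirical_p(scores, "p", set(top5), n_perm=10_000, seed=2)
    assert res.p_value <= 0.001


def test_empirical_p_bounds_and_determinism():
    scores = _null_scores(100, 2)
    members = set(list(scores)[:10])
    r1 = pathway_empirical_p(scores, "p", members, n_perm=200, seed=3)
    r2 = pathway_empirical_p(scores, "p", members, n_perm=200, seed=3)
    assert r1.p_value == r2.p_value
    assert 1 / 201 <= r1.p_value <= 1.0


def test_unscored_pathway_skipped_with_warning():
    scores = _null_scores(10, 3)
    with pytest.warns(UserWarning, match="no scored members"):
        assert pathway_empirical_p(scores, "p", {"zz"}, n_perm=100, seed=0) is None


def test_empirical_p_uniform_under_null():
    """With null member scores, the empirical pathway p is uniform."""
    ps = []
    for rep in range(200):
        scores = _null_scores(80, 100 + rep)
        members = set(list(scores)[:8])
        ps.append(pathway_empirical_p(scores, "p", members, n_perm=199, seed=rep).p_value)
    assert stats.kstest(ps, "uniform").pvalue > 0.01


# ---------------------------------------------------------------------------
# BH and proxy selection
# ---------------------------------------------------------------------------


def test_bh_adjust_examples():
    assert bh_adjust([0.03]) == pytest.approx([0.03])
    assert bh_adjust([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)
    assert bh_adjust([0.2, 0.2, 0.2]) == pytest.approx([0.2] * 3)
    assert list(bh_adjust([])) == []
    with pytest.raises(ValueError):
        bh_adjust([0.0, 0.5])


def test_bh_monotone_and_bounded():
    rng = np.random.default_rng(0)
    p = rng.uniform(1e-6, 1, 50)
    adj = bh_adjust(p)
    assert np.all(adj >= p - 1e-15) and np.all(adj <= 1.0)
    order = np.argsort(p)
    assert np.all(np.diff(adj[order]) >= -1e-15)


def test_select_pathway_proxies_rules():
    from targetprop.genescore import PathwayEnrichmentResult

    scores = {
        "gSig": GeneScore("gSig", 0, 0.04),
        "gNull": GeneScore("gNull", 0, 0.2),
        "gHla": GeneScore("gHla", 0, 0.001),
        "gSeed": GeneScore("gSeed", 0, 0.001),
    }
    members = {"pw": {"gSig", "gNull", "gHla", "gSeed"}}
    passing = PathwayEnrichmentResult("pw", 1.0, 0.001, adj_p=0.01)
    failing = PathwayEnrichmentResult("pw", 1.0, 0.5, adj_p=0.6)
    sel = lambda res: select_pathway_proxies(
        [res], scores, members, hla_genes={"gHla"}, seeds={"gSeed"}
    ).proxies
    assert sel(passing) == {"gSig"}
    assert sel(failing) == set()
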