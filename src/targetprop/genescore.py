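"""Gene scores from variant z-statistics and empirical pathway enrichment.

The 'sum' gene score for a gene with variant z-scores z_1..z_m inside the
gene body +/- 50 kb is T = sum z_i^2. Under the null, z ~ MVN(0, R) with R
the local LD correlation matrix, so T is distributed as a mixture
Q = sum_j lambda_j * chi2_1 with lambda_j the eigenvalues of R. The tail
P(Q > T) is computed by Imhof's numerical inversion of the characteristic
function, with a Satterthwaite moment-matched chi-square as fallback; when
all retained eigenvalues are equal (e.g. perfect LD, lambda = (m, 0, .., 0))
the exact closed form P(chi2_1 > T/lambda) is used.

Genes in the same pathway whose +/- 50 kb windows overlap share LD, which
would double-count signal in a pathway statistic; such genes are *fused*
(variants pooled, shared variants deduplicated) and rescored as one unit.

Pathway enrichment uses the Fisher-style statistic S = sum(-ln p) over the
pathway's (fused) units and an empirical p-value against size-matched random
gene sets drawn from the scored universe, followed by Benjamini–Hochberg
adjustment across pathways. Proxy genes are members of BH-significant
pathways that themselves carry a nominally significant (p < 0.05) gene
score, excluding HLA genes and the original seeds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
from scipy import integrate, stats
from statsmodels.stats.multitest import multipletests

from .knowledge import ProxySet

__all__ = [
    "WINDOW_BP",
    "VariantBlock",
    "GeneScore",
    "GeneWindow",
    "PathwayEnrichmentResult",
    "sum_gene_score",
    "score_genes",
    "fuse_genes",
    "window_fusion_groups",
    "merge_blocks",
    "pathway_empirical_p",
    "bh_adjust",
    "select_pathway_proxies",
    "weighted_chisq_sf",
]

#: Gene locus definition: gene body +/- 50 kb.
WINDOW_BP = 50_000

_EIG_TOL = 1e-10
_PSD_TOL = 1e-8


@dataclass
class VariantBlock:
    """Variant z-scores and LD for one gene (or fused gene unit)."""

    gene_id: str
    z: np.ndarray
    R: np.ndarray
    variant_ids: Tuple[str, ...] = ()

    def __post_init__(self):
        self.z = np.asarray(self.z, dtype=float).ravel()
        self.R = np.asarray(self.R, dtype=float)
        if self.R.shape != (self.z.size, self.z.size):
            raise ValueError(
                f"gene {self.gene_id}: z has {self.z.size} variants but "
                f"R is {self.R.shape}"
            )
        if not self.variant_ids:
            self.variant_ids = tuple(
                f"{self.gene_id}:{i}" for i in range(self.z.size)
            )
        elif len(self.variant_ids) != self.z.size:
            raise ValueError(f"gene {self.gene_id}: variant_ids length mismatch")

    def __len__(self) -> int:
        return self.z.size


@dataclass(frozen=True)
class GeneScore:
    gene_id: str
    statistic: float
    p_value: float
    n_variants: int = 0
    members: FrozenSet[str] = frozenset()  # constituent genes if fused


@dataclass(frozen=True)
class GeneWindow:
    """Synthetic genomic window (already including the +/- 50 kb flank)."""

    gene_id: str
    chrom: str
    start: int
    end: int

    def overlaps(self, other: "GeneWindow") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.end
            and other.start <= self.end
        )


@dataclass
class PathwayEnrichmentResult:
    pathway_id: str
    statistic: float
    p_value: float
    adj_p: float = float("nan")
    member_scores: Dict[str, float] = field(default_factory=dict)
    n_units: int = 0


def _imhof_sf(lam: np.ndarray, x: float, eps: float = 1e-9) -> float:
    """Imhof (1961) numerical inversion for P(sum lam_j chi2_1 > x).

    The oscillatory integrand sin(theta(u)) / (u rho(u)) is integrated by
    composite Simpson on a uniform grid resolving the oscillation period;
    the domain is truncated where one further half-oscillation (an
    alternating-series tail) contributes less than ``eps``.
    """
    lam = np.asarray(lam, dtype=float)
    freq = 0.5 * (lam.sum() + x)  # worst-case |theta'(u)|
    period = 2.0 * np.pi / freq
    step = period / 24.0

    # amplitude envelope 1/(u * prod(1+lam^2 u^2)^(1/4)); truncate where one
    # half-period's worth of envelope falls below eps
    tail_tol = eps * max(x, lam.sum()) / (2.0 * np.pi)
    u_hi = 1.0
    for _ in range(80):
        env = 1.0 / (u_hi * np.exp(0.25 * np.sum(np.log1p((lam * u_hi) ** 2))))
        if env < tail_tol:
            break
        u_hi *= 1.6
    n_pts = int(u_hi / step) + 1
    if n_pts > 2_000_000:
        raise FloatingPointError("Imhof grid too large; fall back")
    n_pts = max(n_pts, 64)
    u = np.linspace(0.0, u_hi, n_pts)
    lu = lam[:, None] * u[None, 1:]
    theta = 0.5 * np.arctan(lu).sum(axis=0) - 0.5 * x * u[1:]
    rho = np.exp(0.25 * np.log1p(lu**2).sum(axis=0))
    vals = np.empty(n_pts)
    vals[0] = 0.5 * (lam.sum() - x)  # limit of the integrand at u -> 0
    vals[1:] = np.sin(theta) / (u[1:] * rho)
    val = integrate.simpson(vals, x=u)
    p = 0.5 + val / np.pi
    if not np.isfinite(p):
        raise FloatingPointError("Imhof integration unreliable")
    return p


def _satterthwaite_sf(lam: np.ndarray, x: float) -> float:
    """Moment-matched approximation Q ~ c * chi2_nu."""
    s1, s2 = lam.sum(), (lam**2).sum()
    c = s2 / s1
    nu = s1**2 / s2
    return float(stats.chi2.sf(x / c, nu))


def weighted_chisq_sf(eigenvalues: Sequence[float], x: float) -> float:
    """Survival function of Q = sum_j lambda_j chi2_1 at x.

    Near-zero eigenvalues are dropped; equal surviving eigenvalues use the
    exact chi-square closed form; otherwise Imhof inversion with a
    Satterthwaite fallback. The result is clipped to (0, 1].
    """
    lam = np.asarray(eigenvalues, dtype=float)
    lam = lam[lam > _EIG_TOL * max(lam.max(initial=1.0), 1.0)]
    if lam.size == 0:
        raise ValueError("no positive eigenvalues")
    if x <= 0:
        return 1.0
    if np.allclose(lam, lam[0], rtol=1e-12, atol=0.0):
        # perfect-correlation / identity closed form: Q ~ lam * chi2_k
        return float(stats.chi2.sf(x / lam[0], lam.size))
    try:
        p = _imhof_sf(lam, x)
    except FloatingPointError:
        p = _satterthwaite_sf(lam, x)
    if p < 1e-12:
        # Imhof loses relative accuracy deep in the tail
        p = min(p if p > 0 else np.inf, _satterthwaite_sf(lam, x))
    return float(min(max(p, 5e-324), 1.0))


def sum_gene_score(block: VariantBlock) -> GeneScore:
    """Score a gene: T = sum z_i^2 against the LD-eigenvalue null."""
    if len(block) == 0:
        raise ValueError(f"gene {block.gene_id}: empty variant block")
    R = 0.5 * (block.R + block.R.T)
    lam = np.linalg.eigvalsh(R)
    scale = max(abs(lam[-1]), 1.0)
    if lam[0] < -_PSD_TOL * scale:
        raise ValueError(
            f"gene {block.gene_id}: LD matrix not positive semi-definite "
            f"(min eigenvalue {lam[0]:.3g})"
        )
    lam = np.clip(lam, 0.0, None)
    T = float(block.z @ block.z)
    p = weighted_chisq_sf(lam, T)
    return GeneScore(
        gene_id=block.gene_id,
        statistic=T,
        p_value=p,
        n_variants=len(block),
        members=frozenset({block.gene_id}),
    )


def score_genes(blocks: Sequence[VariantBlock]) -> Dict[str, GeneScore]:
    """Score many genes, skipping empty blocks with a warning."""
    scores: Dict[str, GeneScore] = {}
    skipped = []
    for b in blocks:
        if len(b) == 0:
            skipped.append(b.gene_id)
            continue
        scores[b.gene_id] = sum_gene_score(b)
    if skipped:
        warnings.warn(
            f"skipped {len(skipped)} gene(s) with empty variant blocks",
            stacklevel=2,
        )
    return scores


# ---------------------------------------------------------------------------
# Gene fusion
# ---------------------------------------------------------------------------


def window_fusion_groups(
    gene_set: Set[str],
    gene_windows: Mapping[str, GeneWindow],
    available: Set[str],
) -> List[List[str]]:
    """Partition ``gene_set`` into fusion groups by window overlap.

    Overlap is transitive (connected components of the window-overlap
    graph); genes without a window form singleton groups.
    """
    members = sorted(g for g in gene_set if g in available and g in gene_windows)
    lone = sorted(g for g in gene_set if g in available and g not in gene_windows)
    parent = {g: g for g in members}

    def find(g):
        while parent[g] != g:
            parent[g] = parent[parent[g]]
            g = parent[g]
        return g

    for i, a in enumerate(members):
        wa = gene_windows[a]
        for b in members[i + 1 :]:
            if wa.overlaps(gene_windows[b]):
                ra, rb = find(a), find(b)
                if ra != rb:
                    parent[rb] = ra

    grouped: Dict[str, List[str]] = {}
    for g in members:
        grouped.setdefault(find(g), []).append(g)
    groups = [sorted(v) for v in grouped.values()]
    groups += [[g] for g in lone]
    return sorted(groups)


def merge_blocks(blocks: Mapping[str, VariantBlock], group: Sequence[str]) -> VariantBlock:
    """Concatenate the group's variants into one block.

    Shared variants are deduplicated; LD between variants never observed in
    a common input block is taken as zero (block-diagonal completion).
    """
    group = sorted(group)
    if len(group) == 1:
        return blocks[group[0]]
    order: List[str] = []
    z_by_id: Dict[str, float] = {}
    for g in group:
        b = blocks[g]
        for vid, zval in zip(b.variant_ids, b.z):
            if vid not in z_by_id:
                z_by_id[vid] = float(zval)
                order.append(vid)
    idx = {vid: i for i, vid in enumerate(order)}
    m = len(order)
    R = np.eye(m)
    for g in group:
        b = blocks[g]
        pos = [idx[v] for v in b.variant_ids]
        R[np.ix_(pos, pos)] = b.R
    return VariantBlock(
        gene_id="+".join(group),
        z=np.array([z_by_id[v] for v in order]),
        R=R,
        variant_ids=tuple(order),
    )


def fuse_genes(
    blocks: Mapping[str, VariantBlock],
    gene_set: Set[str],
    gene_windows: Mapping[str, GeneWindow],
) -> List[VariantBlock]:
    """Fuse same-set genes with overlapping windows into joint blocks."""
    groups = window_fusion_groups(gene_set, gene_windows, set(blocks))
    return [merge_blocks(blocks, g) for g in groups]


# ---------------------------------------------------------------------------
# Pathway enrichment
# ---------------------------------------------------------------------------


def pathway_empirical_p(
    gene_scores: Mapping[str, GeneScore],
    pathway_id: str,
    members: Set[str],
    universe_scores: Optional[Mapping[str, GeneScore]] = None,
    n_perm: int = 1000,
    seed: int = 0,
) -> Optional[PathwayEnrichmentResult]:
    """Empirical enrichment p for one pathway.

    S = sum over scored members of -ln(gene p); the null draws size-matched
    gene sets without replacement from the scored universe. Add-one
    estimator: p = (1 + #{S* >= S}) / (n_perm + 1), never zero.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    universe_scores = universe_scores if universe_scores is not None else gene_scores
    scored = {g: gene_scores[g] for g in members if g in gene_scores}
    if not scored:
        warnings.warn(f"pathway {pathway_id}: no scored members; skipped", stacklevel=2)
        return None
    neglogp_all = np.array(
        [-np.log(universe_scores[g].p_value) for g in sorted(universe_scores)]
    )
    member_neglogp = {g: -np.log(s.p_value) for g, s in scored.items()}
    S = float(sum(member_neglogp.values()))
    k = len(scored)
    rng = np.random.default_rng(seed)
    if k >= neglogp_all.size:
        n_ge = n_perm  # every same-size draw is the whole universe
    else:
        # size-matched draws without replacement, vectorized via
        # argpartition; chunked to bound memory at large n_perm
        n_ge = 0
        done = 0
        while done < n_perm:
            chunk = min(2000, n_perm - done)
            u = rng.random((chunk, neglogp_all.size))
            idx = np.argpartition(u, k, axis=1)[:, :k]
            null_S = neglogp_all[idx].sum(axis=1)
            n_ge += int(np.sum(null_S >= S - 1e-12))
            done += chunk
    p = (1 + n_ge) / (n_perm + 1)
    return PathwayEnrichmentResult(
        pathway_id=pathway_id,
        statistic=S,
        p_value=p,
        member_scores=member_neglogp,
        n_units=k,
    )


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (monotone, <= 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def adjust_pathway_results(
    results: Sequence[PathwayEnrichmentResult],
) -> List[PathwayEnrichmentResult]:
    """Apply BH across one pathway collection (one testing family)."""
    res = list(results)
    if not res:
        return res
    adj = bh_adjust([r.p_value for r in res])
    for r, a in zip(res, adj):
        r.adj_p = float(a)
    return res


def select_pathway_proxies(
    results: Sequence[PathwayEnrichmentResult],
    gene_scores: Mapping[str, GeneScore],
    pathway_members: Mapping[str, Set[str]],
    hla_genes: Set[str],
    seeds: Set[str],
    trait_id: str = "",
    adj_p_max: float = 0.05,
    gene_p_max: float = 0.05,
) -> ProxySet:
    """Proxies: members of BH-significant pathways with nominally significant
    gene scores, excluding HLA genes and seeds."""
    seeds = frozenset(seeds)
    out: Set[str] = set()
    for r in results:
        if not np.isfinite(r.adj_p) or r.adj_p >= adj_p_max:
            continue
        for g in pathway_members.get(r.pathway_id, set()):
            sc = gene_scores.get(g)
            if sc is None or sc.p_value >= gene_p_max:
                continue
            if g in hla_genes:
                continue
            out.add(g)
    return ProxySet(trait_id, "pascal", seeds, frozenset(out - seeds))
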