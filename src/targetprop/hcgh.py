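"""High-confidence genetic hits (HCGHs) from GWAS–eQTL colocalization.

A gene counts as a high-confidence genetic hit for a trait when a GWAS
association colocalizes with an eQTL for that gene: the eGene is protein
coding, the GWAS p-value is genome-wide significant (<= 5e-8), the eQTL
p-value passes 1e-4, and the colocalization posterior p12 (H4, probability
of a shared causal variant) is >= 0.8. Each disease-associated locus yields
at most one hit: among passing eGenes at a locus, the one with the highest
p12 across tissues wins.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Sequence, Set

import pandas as pd

from .knowledge import GeneUniverse

__all__ = [
    "GWAS_P_MAX",
    "EQTL_P_MAX",
    "P12_MIN",
    "ColocRecord",
    "HcghSet",
    "define_hcghs",
    "retain_traits",
]

GWAS_P_MAX = 5e-8
EQTL_P_MAX = 1e-4
P12_MIN = 0.8


@dataclass(frozen=True)
class ColocRecord:
    """One trait/locus/eGene/tissue colocalization result."""

    trait_id: str
    locus_id: str
    gene_id: str
    tissue: str
    gwas_p: float
    eqtl_p: float
    p12: float

    def __post_init__(self):
        if not (0.0 <= self.p12 <= 1.0):
            raise ValueError(f"p12 out of [0,1]: {self.p12}")
        for name in ("gwas_p", "eqtl_p"):
            p = getattr(self, name)
            if not (0.0 < p <= 1.0):
                raise ValueError(f"{name} out of (0,1]: {p}")

    def passes_filters(self, universe: GeneUniverse) -> bool:
        """All four inclusion rules; thresholds are inclusive."""
        return (
            self.gene_id in universe.coding
            and self.gwas_p <= GWAS_P_MAX
            and self.eqtl_p <= EQTL_P_MAX
            and self.p12 >= P12_MIN
        )


@dataclass
class HcghSet:
    """Per-trait high-confidence genetic hits: gene -> winning record."""

    trait_id: str
    hits: Dict[str, ColocRecord]

    @property
    def genes(self) -> frozenset:
        return frozenset(self.hits)

    def __len__(self) -> int:
        return len(self.hits)


def define_hcghs(
    records: Sequence[ColocRecord], universe: GeneUniverse
) -> HcghSet:
    """Filter colocalization records to HCGHs for a single trait.

    Per locus, records passing all four filters reduce to the single eGene
    with maximal p12 across tissues (the per-tissue eQTL filter is applied
    first, then the max is taken over surviving tissue records). p12 ties
    break lexicographically by gene_id for determinism. A gene winning at
    several loci counts once; its maximal-p12 record is kept.
    """
    if not records:
        raise ValueError("no colocalization records supplied")
    trait_ids = {r.trait_id for r in records}
    if len(trait_ids) != 1:
        raise ValueError(f"records span multiple traits: {sorted(trait_ids)}")
    (trait_id,) = trait_ids

    known, n_unknown = [], 0
    for r in records:
        if r.gene_id not in universe:
            n_unknown += 1
            continue
        known.append(r)
    if n_unknown:
        warnings.warn(
            f"{n_unknown} colocalization record(s) reference unknown genes; rejected",
            stacklevel=2,
        )

    by_locus: Dict[str, List[ColocRecord]] = {}
    for r in known:
        if r.passes_filters(universe):
            by_locus.setdefault(r.locus_id, []).append(r)

    hits: Dict[str, ColocRecord] = {}
    for locus in sorted(by_locus):
        # max p12 across tissues and candidate eGenes; ties -> smallest gene_id
        winner = min(by_locus[locus], key=lambda r: (-r.p12, r.gene_id))
        prev = hits.get(winner.gene_id)
        if prev is None or winner.p12 > prev.p12:
            hits[winner.gene_id] = winner
    return HcghSet(trait_id=trait_id, hits=hits)


def retain_traits(
    hcgh_sets: Mapping[str, HcghSet],
    outcome_genes_by_trait: Mapping[str, Set[str]],
    blacklist: Iterable[str] = (),
) -> List[str]:
    """Traits kept for analysis: >= 1 HCGH and >= 1 drug target with a
    success/failure outcome for a matched indication.

    ``outcome_genes_by_trait`` maps trait -> genes carrying a Succeeded or
    ClinicalFailure outcome for an indication matched to that trait.
    ``blacklist`` models the removal of e.g. surgical traits caught by fuzzy
    trait–indication matching.
    """
    blacklist = set(blacklist)
    kept = []
    for trait_id, hs in hcgh_sets.items():
        if trait_id in blacklist:
            continue
        if len(hs) >= 1 and outcome_genes_by_trait.get(trait_id):
            kept.append(trait_id)
    return sorted(kept)


def hcghs_to_frame(hcgh_sets: Mapping[str, HcghSet]) -> pd.DataFrame:
    rows = [
        (t, r.gene_id, r.locus_id, r.p12)
        for t in sorted(hcgh_sets)
        for r in sorted(hcgh_sets[t].hits.values(), key=lambda r: r.gene_id)
    ]
    return pd.DataFrame(rows, columns=["trait_id", "gene_id", "locus_id", "p12"])
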