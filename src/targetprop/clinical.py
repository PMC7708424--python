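"""Clinical trial outcome classification for drug target–indication pairs.

Historical pipeline records arrive as asset–target–indication triples (an
asset is a drug or candidate; it may bind one target — 'Selective' — or
several — 'Non-Selective'). Asset statuses collapse to Succeeded (Launched),
Failed (Discontinued / No Development Reported / Withdrawn / Suspended) or
In Progress, and failed assets split into clinical failures (reached Phase
I–III) versus preclinical failures.

Target–indication pairs are then classified by a precedence cascade that
trusts selective assets first:

  1. any Selective asset Launched            -> Succeeded
  2. else any Selective clinical failure     -> ClinicalFailure
  3. else any Non-Selective asset Launched   -> Succeeded
  4. else any Non-Selective clinical failure -> ClinicalFailure
  5. else any Selective preclinical failure  -> PreclinicalFailure
  6. else any Non-Selective precl. failure   -> PreclinicalFailure
  7. else                                    -> InProgress

Succeeded pairs form the positive set and ClinicalFailure pairs the negative
set for enrichment; preclinical failures and in-progress pairs are excluded
from both (a preclinical kill says little about the target, and an ongoing
program has no outcome yet).
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Dict, FrozenSet, Iterable, List, Optional, Sequence, Set, Tuple

import pandas as pd

__all__ = [
    "Outcome",
    "AssetRecord",
    "TargetIndicationOutcome",
    "classify_asset_status",
    "classify_target_indication",
    "outcome_sets",
    "DEFAULT_INDICATION_BLACKLIST",
]

#: Unspecified / diagnostic indications dropped on load.
DEFAULT_INDICATION_BLACKLIST = frozenset(
    {
        "Ideopathic disease, unspecified",
        "Not applicable",
        "Undisclosed",
        "Unspecified",
    }
)

FAILED_STATUSES = frozenset(
    {"Discontinued", "No Development Reported", "Withdrawn", "Suspended"}
)

CLINICAL_PHASES = frozenset({"PhaseI", "PhaseII", "PhaseIII"})

PHASE_ORDER = {
    None: -1,
    "Preclinical": 0,
    "PhaseI": 1,
    "PhaseII": 2,
    "PhaseIII": 3,
    "Launched": 4,
}


class Outcome(str, Enum):
    SUCCEEDED = "Succeeded"
    CLINICAL_FAILURE = "ClinicalFailure"
    PRECLINICAL_FAILURE = "PreclinicalFailure"
    IN_PROGRESS = "InProgress"


@dataclass(frozen=True)
class AssetRecord:
    """One asset–(targets)–indication row from a trial-records table."""

    asset_id: str
    target_genes: FrozenSet[str]
    indication_id: str
    status_text: str
    phase_reached: Optional[str] = None

    def __post_init__(self):
        if not self.target_genes:
            raise ValueError(f"asset {self.asset_id} has no target genes")
        if self.phase_reached is not None and self.phase_reached not in PHASE_ORDER:
            raise ValueError(
                f"asset {self.asset_id}: unknown phase {self.phase_reached!r}"
            )

    @property
    def selective(self) -> bool:
        """Selective = interacts with exactly one target."""
        return len(self.target_genes) == 1


@dataclass(frozen=True)
class TargetIndicationOutcome:
    gene_id: str
    indication_id: str
    outcome: Outcome
    furthest_phase: Optional[str]


def classify_asset_status(status_text: str) -> str:
    """Collapse a pipeline status to 'Succeeded', 'Failed' or 'InProgress'."""
    if not status_text:
        raise ValueError("empty status text")
    if status_text == "Launched":
        return "Succeeded"
    if status_text in FAILED_STATUSES:
        return "Failed"
    return "InProgress"


def _asset_flags(asset: AssetRecord) -> Tuple[bool, bool, bool]:
    """(succeeded, clinical_failure, preclinical_failure) for one asset."""
    status = classify_asset_status(asset.status_text)
    if status == "Succeeded":
        return True, False, False
    if status == "Failed":
        clinical = asset.phase_reached in CLINICAL_PHASES
        return False, clinical, not clinical
    return False, False, False


def classify_target_indication(
    assets: Sequence[AssetRecord],
    selective_failure_overrides_nonselective_success: bool = True,
) -> List[TargetIndicationOutcome]:
    """Group assets into (gene, indication) pairs and classify each pair.

    The default precedence runs both Selective steps before the
    Non-Selective ones (a selective clinical failure outranks a
    non-selective launch); set the flag False for the alternative reading
    in which any launch wins before failures are considered.
    """
    pairs: Dict[Tuple[str, str], List[AssetRecord]] = {}
    for asset in assets:
        for gene in asset.target_genes:
            pairs.setdefault((gene, asset.indication_id), []).append(asset)

    out: List[TargetIndicationOutcome] = []
    for (gene, indication) in sorted(pairs):
        group = pairs[(gene, indication)]
        sel = [a for a in group if a.selective]
        nonsel = [a for a in group if not a.selective]
        s_succ = any(_asset_flags(a)[0] for a in sel)
        s_clin = any(_asset_flags(a)[1] for a in sel)
        s_pre = any(_asset_flags(a)[2] for a in sel)
        n_succ = any(_asset_flags(a)[0] for a in nonsel)
        n_clin = any(_asset_flags(a)[1] for a in nonsel)
        n_pre = any(_asset_flags(a)[2] for a in nonsel)

        if selective_failure_overrides_nonselective_success:
            cascade = [
                (s_succ, Outcome.SUCCEEDED),
                (s_clin, Outcome.CLINICAL_FAILURE),
                (n_succ, Outcome.SUCCEEDED),
                (n_clin, Outcome.CLINICAL_FAILURE),
                (s_pre, Outcome.PRECLINICAL_FAILURE),
                (n_pre, Outcome.PRECLINICAL_FAILURE),
            ]
        else:
            cascade = [
                (s_succ or n_succ, Outcome.SUCCEEDED),
                (s_clin or n_clin, Outcome.CLINICAL_FAILURE),
                (s_pre or n_pre, Outcome.PRECLINICAL_FAILURE),
            ]
        outcome = Outcome.IN_PROGRESS
        for hit, o in cascade:
            if hit:
                outcome = o
                break

        furthest = max(
            (a.phase_reached for a in group),
            key=lambda p: PHASE_ORDER[p],
            default=None,
        )
        out.append(TargetIndicationOutcome(gene, indication, outcome, furthest))
    return out


def outcome_sets(
    outcomes: Iterable[TargetIndicationOutcome],
) -> Tuple[Set[Tuple[str, str]], Set[Tuple[str, str]]]:
    """(positive, negative) gene–indication sets: Succeeded vs ClinicalFailure."""
    pos, neg = set(), set()
    for o in outcomes:
        if o.outcome is Outcome.SUCCEEDED:
            pos.add((o.gene_id, o.indication_id))
        elif o.outcome is Outcome.CLINICAL_FAILURE:
            neg.add((o.gene_id, o.indication_id))
    return pos, neg


def assets_from_frame(
    df: pd.DataFrame,
    indication_blacklist: FrozenSet[str] = DEFAULT_INDICATION_BLACKLIST,
) -> List[AssetRecord]:
    """Build asset records from an assets table (one row per
    asset–target–indication triple); blacklisted indications are dropped.
    """
    grouped: Dict[Tuple[str, str], Dict] = {}
    for row in df.itertuples(index=False):
        if row.indication_id in indication_blacklist:
            continue
        key = (str(row.asset_id), str(row.indication_id))
        phase = getattr(row, "phase_reached", None)
        if pd.isna(phase) or phase == "":
            phase = None
        entry = grouped.setdefault(
            key,
            {"targets": set(), "status": str(row.status_text), "phase": phase},
        )
        entry["targets"].add(str(row.gene_id))
    return [
        AssetRecord(
            asset_id=aid,
            target_genes=frozenset(e["targets"]),
            indication_id=ind,
            status_text=e["status"],
            phase_reached=e["phase"],
        )
        for (aid, ind), e in sorted(grouped.items())
    ]


def outcomes_to_frame(outcomes: Sequence[TargetIndicationOutcome]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (o.gene_id, o.indication_id, o.outcome.value, o.furthest_phase or "")
            for o in outcomes
        ],
        columns=["gene_id", "indication_id", "outcome", "furthest_phase"],
    )
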