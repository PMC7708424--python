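"""Stratified enrichment of successful drug targets in proxy gene sets.

For each (trait, method) a 2x2 table splits the protein-coding genes that
carry a clinical outcome for an indication matched to the trait:

                Success   Failure
    Hit            a         b        (gene in the proxy set)
    Not hit        c         d

Tables with a = b = 0 carry no information about the hit set and are
removed. Tables where a or b is zero get the Haldane correction (+0.5 to
every cell) so the odds ratio stays finite. Strata (one per trait/GWAS) are
pooled with the Cochran–Mantel–Haenszel framework:

    OR_MH = sum_i(a_i d_i / n_i) / sum_i(b_i c_i / n_i)

with a Robins–Breslow–Greenland 95% confidence interval for log OR_MH and
the CMH chi-square test of OR = 1.

The pooling step is exposed as a small model/results pair:
``StratifiedEnrichment(tables).fit()`` returns an :class:`EnrichmentResult`
with estimates, interval, test and a ``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple
import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .clinical import Outcome, TargetIndicationOutcome
from .knowledge import GeneUniverse, ProxySet

__all__ = [
    "ContingencyTable",
    "EnrichmentResult",
    "StratifiedEnrichment",
    "build_table",
    "haldane_correct",
    "cmh_pool",
    "summarize_methods",
]


@dataclass(frozen=True)
class ContingencyTable:
    """One stratum: proxy-hit status vs clinical outcome for one trait."""

    a: float  # hit & success
    b: float  # hit & failure
    c: float  # not hit & success
    d: float  # not hit & failure
    trait_id: str = ""
    method: str = ""
    corrected: bool = False

    def __post_init__(self):
        cells = (self.a, self.b, self.c, self.d)
        if any(x < 0 for x in cells):
            raise ValueError(f"negative cell count: {cells}")
        if sum(cells) <= 0:
            raise ValueError("empty contingency table")

    @property
    def n(self) -> float:
        return self.a + self.b + self.c + self.d

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=float)


def build_table(
    proxies: ProxySet,
    outcomes: Sequence[TargetIndicationOutcome],
    trait_indications: Mapping[str, Set[str]],
    universe: GeneUniverse,
    any_success: bool = True,
) -> Optional[ContingencyTable]:
    """Count the 2x2 table for one (trait, method), or None if removed.

    The counted population is the protein-coding genes with a Succeeded or
    ClinicalFailure outcome for an indication matched to the trait, with the
    original seed genes removed entirely (the enrichment is computed on new
    proxy genes only; a genetically supported seed left in the background
    would deflate every method's odds ratio). A gene with outcomes for
    several matched indications counts once — as a success if any matched
    indication Succeeded (``any_success=True``, default), else as a failure.
    Tables with both a and b zero are removed.
    """
    trait = proxies.trait_id
    indications = trait_indications.get(trait)
    if not indications:
        warnings.warn(f"trait {trait} has no matched indication; no table", stacklevel=2)
        return None
    coding = universe.coding - proxies.seeds
    succ_genes: Set[str] = set()
    fail_genes: Set[str] = set()
    for o in outcomes:
        if o.indication_id not in indications or o.gene_id not in coding:
            continue
        if o.outcome is Outcome.SUCCEEDED:
            succ_genes.add(o.gene_id)
        elif o.outcome is Outcome.CLINICAL_FAILURE:
            fail_genes.add(o.gene_id)
    if any_success:
        fail_genes -= succ_genes
    else:
        succ_genes -= fail_genes
    if not (succ_genes or fail_genes):
        return None
    hits = proxies.proxies
    a = len(succ_genes & hits)
    b = len(fail_genes & hits)
    c = len(succ_genes) - a
    d = len(fail_genes) - b
    if a == 0 and b == 0:
        return None
    return ContingencyTable(a, b, c, d, trait_id=trait, method=proxies.method)


def haldane_correct(table: ContingencyTable) -> ContingencyTable:
    """Add 0.5 to every cell when a or b is zero (Haldane correction).

    Tables with both a and b zero should already have been removed; applying
    the rule to such a table is an error.
    """
    if table.a == 0 and table.b == 0:
        raise ValueError("table with a = b = 0 should have been removed")
    if table.a == 0 or table.b == 0:
        return replace(
            table,
            a=table.a + 0.5,
            b=table.b + 0.5,
            c=table.c + 0.5,
            d=table.d + 0.5,
            corrected=True,
        )
    return table


@dataclass
class EnrichmentResult:
    """Pooled enrichment estimate for one method across trait strata."""

    method: str
    oddsratio: float
    ci_low: float
    ci_high: float
    p_value: float
    statistic: float
    n_strata: int
    mean_new_targets: float = float("nan")
    log_or_se: float = float("nan")
    error: Optional[str] = None

    def covers(self, value: float) -> bool:
        return self.ci_low <= value <= self.ci_high

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "method": [self.method],
                "OR": [self.oddsratio],
                "ci_low": [self.ci_low],
                "ci_high": [self.ci_high],
                "cmh_chi2": [self.statistic],
                "p": [self.p_value],
                "n_strata": [self.n_strata],
                "mean_new_targets": [self.mean_new_targets],
            }
        )

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"{self.method}: OR={self.oddsratio:.3g} "
            f"[{self.ci_low:.3g}, {self.ci_high:.3g}], p={self.p_value:.3g}, "
            f"k={self.n_strata}"
        )


class StratifiedEnrichment:
    """Mantel–Haenszel pooling model over Haldane-corrected 2x2 strata.

    Parameters
    ----------
    tables
        Strata that survived the a=b=0 removal rule. Cells may be
        non-integer (Haldane-corrected); the corrected cells feed both the
        pooled odds ratio and the CMH statistic.
    continuity_correction
        Apply the 0.5 continuity correction in the CMH statistic
        (off by default).
    """

    def __init__(
        self,
        tables: Sequence[ContingencyTable],
        continuity_correction: bool = False,
    ):
        if not tables:
            raise ValueError("at least one stratum required")
        self.tables = [haldane_correct(t) for t in tables]
        self.continuity_correction = continuity_correction

    @classmethod
    def from_counts(
        cls, counts: Iterable[Tuple[float, float, float, float]], **kw
    ) -> "StratifiedEnrichment":
        return cls([ContingencyTable(*t) for t in counts], **kw)

    def fit(self, alpha: float = 0.05, method: str = "") -> EnrichmentResult:
        a = np.array([t.a for t in self.tables])
        b = np.array([t.b for t in self.tables])
        c = np.array([t.c for t in self.tables])
        d = np.array([t.d for t in self.tables])
        n = a + b + c + d
        method = method or (self.tables[0].method if self.tables[0].method else "")

        R = a * d / n
        S = b * c / n
        sum_R, sum_S = R.sum(), S.sum()
        if sum_R == 0 or sum_S == 0:
            return EnrichmentResult(
                method=method,
                oddsratio=np.nan,
                ci_low=np.nan,
                ci_high=np.nan,
                p_value=np.nan,
                statistic=np.nan,
                n_strata=len(self.tables),
                error="Mantel-Haenszel odds ratio undefined (zero denominator)",
            )
        or_mh = sum_R / sum_S

        # Robins–Breslow–Greenland variance of log(OR_MH)
        P = (a + d) / n
        Q = (b + c) / n
        var = (
            np.sum(P * R) / (2 * sum_R**2)
            + np.sum(P * S + Q * R) / (2 * sum_R * sum_S)
            + np.sum(Q * S) / (2 * sum_S**2)
        )
        se = np.sqrt(var)
        zcrit = stats.norm.ppf(1 - alpha / 2)
        ci_low = or_mh * np.exp(-zcrit * se)
        ci_high = or_mh * np.exp(zcrit * se)

        # CMH chi-square test of common OR = 1
        e = (a + b) * (a + c) / n
        v = (a + b) * (c + d) * (a + c) * (b + d) / (n**2 * (n - 1))
        num = abs(np.sum(a - e))
        if self.continuity_correction:
            num = max(num - 0.5, 0.0)
        denom = np.sum(v)
        statistic = num**2 / denom if denom > 0 else np.nan
        p = float(stats.chi2.sf(statistic, 1)) if np.isfinite(statistic) else np.nan

        return EnrichmentResult(
            method=method,
            oddsratio=float(or_mh),
            ci_low=float(ci_low),
            ci_high=float(ci_high),
            p_value=p,
            statistic=float(statistic),
            n_strata=len(self.tables),
            log_or_se=float(se),
        )


def cmh_pool(
    tables: Sequence[ContingencyTable],
    continuity_correction: bool = False,
    method: str = "",
) -> EnrichmentResult:
    """Functional wrapper: pool strata into one :class:`EnrichmentResult`."""
    return StratifiedEnrichment(
        tables, continuity_correction=continuity_correction
    ).fit(method=method)


def summarize_methods(
    results: Mapping[str, Optional[EnrichmentResult]],
    proxy_sets: Sequence[ProxySet] = (),
) -> pd.DataFrame:
    """One row per method: pooled OR, CI, p, strata and proxy-set sizes.

    Methods whose strata were all removed appear flagged as ``no data``.
    """
    sizes: Dict[str, List[int]] = {}
    for ps in proxy_sets:
        sizes.setdefault(ps.method, []).append(len(ps.proxies))
    rows = []
    for m in sorted(set(results) | set(sizes)):
        r = results.get(m)
        sz = sizes.get(m, [])
        base = {
            "method": m,
            "mean_proxies": float(np.mean(sz)) if sz else np.nan,
            "median_proxies": float(np.median(sz)) if sz else np.nan,
        }
        if r is None or r.error is not None:
            rows.append(
                {
                    **base,
                    "OR": np.nan,
                    "ci_low": np.nan,
                    "ci_high": np.nan,
                    "cmh_chi2": np.nan,
                    "p": np.nan,
                    "n_strata": 0 if r is None else r.n_strata,
                    "note": "no data" if r is None else r.error,
                }
            )
        else:
            rows.append(
                {
                    **base,
                    "OR": r.oddsratio,
                    "ci_low": r.ci_low,
                    "ci_high": r.ci_high,
                    "cmh_chi2": r.statistic,
                    "p": r.p_value,
                    "n_strata": r.n_strata,
                    "note": "",
                }
            )
    return pd.DataFrame(rows)
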