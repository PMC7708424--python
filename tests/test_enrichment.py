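"""2x2 construction, Haldane correction and Mantel-Haenszel pooling."""

import numpy as np
import pytest
import statsmodels.api as sm
from hypothesis import given, strategies as st

from targetprop.clinical import Outcome, TargetIndicationOutcome
from targetprop.enrichment import (
    ContingencyTable,
    StratifiedEnrichment,
    build_table,
    cmh_pool,
    haldane_correct,
    summarize_methods,
)
from targetprop.knowledge import GeneUniverse, ProxySet


def out(gene, outcome, ind="I"):
    return TargetIndicationOutcome(gene, ind, outcome, None)


UNI = GeneUniverse(
    genes=tuple(f"g{i}" for i in range(12)),
    is_coding=tuple([True] * 11 + [False]),
    is_hla=(False,) * 12,
)
TI = {"T": {"I"}}


def test_build_table_counting():
    """10 outcome targets (4 success, 6 failure); proxies cover 2 successes
    and 1 failure -> (a, b, c, d) = (2, 1, 2, 5)."""
    outcomes = [out(f"g{i}", Outcome.SUCCEEDED) for i in range(4)] + [
        out(f"g{i}", Outcome.CLINICAL_FAILURE) for i in range(4, 10)
    ]
    ps = ProxySet("T", "m", frozenset(), frozenset({"g0", "g1", "g4"}))
    t = build_table(ps, outcomes, TI, UNI)
    assert (t.a, t.b, t.c, t.d) == (2, 1, 2, 5)


def test_table_removed_when_a_and_b_zero():
    outcomes = [out("g0", Outcome.SUCCEEDED), out("g1", Outcome.CLINICAL_FAILURE)]
    ps = ProxySet("T", "m", frozenset(), frozenset({"g5"}))
    assert build_table(ps, outcomes, TI, UNI) is None


def test_table_retained_when_c_d_zero():
    outcomes = [out("g0", Outcome.SUCCEEDED), out("g1", Outcome.CLINICAL_FAILURE)]
    ps = ProxySet("T", "m", frozenset(), frozenset({"g0", "g1"}))
    t = build_table(ps, outcomes, TI, UNI)
    assert (t.a, t.b, t.c, t.d) == (1, 1, 0, 0)


def test_build_table_excludes_noncoding_and_other_outcomes():
    outcomes = [
        out("g11", Outcome.SUCCEEDED),  # non-coding: not counted
        out("g0", Outcome.PRECLINICAL_FAILURE),  # excluded from both sets
        out("g1", Outcome.IN_PROGRESS),
        out("g2", Outcome.SUCCEEDED),
        out("g3", Outcome.CLINICAL_FAILURE),
    ]
    ps = ProxySet("T", "m", frozenset(), frozenset({"g2", "g11", "g0"}))
    t = build_table(ps, outcomes, TI, UNI)
    assert (t.a, t.b, t.c, t.d) == (1, 0, 0, 1)


def test_gene_counted_once_any_success():
    ti = {"T": {"I", "J"}}
    outcomes = [
        out("g0", Outcome.CLINICAL_FAILURE, "I"),
        out("g0", Outcome.SUCCEEDED, "J"),
        out("g1", Outcome.CLINICAL_FAILURE, "I"),
    ]
    ps = ProxySet("T", "m", frozenset(), frozenset({"g0"}))
    t = build_table(ps, outcomes, ti, UNI)
    assert (t.a, t.b, t.c, t.d) == (1, 0, 0, 1)


def test_no_matched_indication_warns():
    ps = ProxySet("T2", "m", frozenset(), frozenset({"g0"}))
    with pytest.warns(UserWarning, match="no matched indication"):
        assert build_table(ps, [out("g0", Outcome.SUCCEEDED)], TI, UNI) is None


@pytest.mark.parametrize(
    "cells,expected,corrected",
    [
        ((0, 5, 10, 100), (0.5, 5.5, 10.5, 100.5), True),
        ((3, 4, 5, 6), (3, 4, 5, 6), False),
        ((7, 0, 2, 9), (7.5, 0.5, 2.5, 9.5), True),
    ],
)
def test_haldane_correction(cells, expected, corrected):
    t = haldane_correct(ContingencyTable(*cells))
    assert (t.a, t.b, t.c, t.d) == expected
    assert t.corrected is corrected


def test_haldane_rejects_removed_table():
    with pytest.raises(ValueError, match="removed"):
        haldane_correct(ContingencyTable(0, 0, 1, 1))


def test_single_stratum_or_exactly_four():
    r = cmh_pool([ContingencyTable(2, 1, 1, 2)])
    assert r.oddsratio == pytest.approx(4.0, abs=1e-12)


def test_identical_strata_same_or():
    t = ContingencyTable(3, 2, 4, 6)
    single = cmh_pool([t])
    many = cmh_pool([t] * 7)
    assert many.oddsratio == pytest.approx(single.oddsratio, abs=1e-12)


def test_undefined_or_reported_as_error():
    # every stratum has ad = bc = 0: the MH ratio is undefined
    r = cmh_pool([ContingencyTable(1, 1, 0, 0)])
    assert r.error is not None and np.isnan(r.oddsratio)


def _random_strata(rng, k):
    tables = []
    for _ in range(k):
        a, b = int(rng.integers(0, 6)), int(rng.integers(0, 6))
        c, d = int(rng.integers(1, 30)), int(rng.integers(1, 30))
        if a == 0 and b == 0:
            a = 1
        tables.append(ContingencyTable(a, b, c, d))
    return tables


def test_matches_statsmodels_oracle():
    """Pooled OR, RBG 95% CI and CMH statistic agree with the independently
    implemented statsmodels StratifiedTable to 1e-10, including
    Haldane-corrected non-integer cells."""
    rng = np.random.default_rng(42)
    for _ in range(20):
        tables = _random_strata(rng, int(rng.integers(2, 8)))
        model = StratifiedEnrichment(tables)
        r = model.fit()
        arrays = [t.as_array() for t in model.tables]  # corrected cells
        st_tab = sm.stats.StratifiedTable(arrays)
        assert r.oddsratio == pytest.approx(st_tab.oddsratio_pooled, abs=1e-10)
        lo, hi = st_tab.oddsratio_pooled_confint()
        assert r.ci_low == pytest.approx(lo, abs=1e-10)
        assert r.ci_high == pytest.approx(hi, abs=1e-10)
        tn = st_tab.test_null_odds(correction=False)
        assert r.statistic == pytest.approx(tn.statistic, abs=1e-10)
        assert r.p_value == pytest.approx(tn.pvalue, abs=1e-10)


@given(st.integers(0, 10_000))
def test_or_invariant_to_stratum_order_and_duplication(seed):
    rng = np.random.default_rng(seed)
    tables = _random_strata(rng, 4)
    base = cmh_pool(tables).oddsratio
    shuffled = [tables[i] for i in rng.permutation(4)]
    assert cmh_pool(shuffled).oddsratio == pytest.approx(base, abs=1e-12)
    assert cmh_pool(tables + tables).oddsratio == pytest.approx(base, abs=1e-12)


def test_haldane_gives_finite_positive_or():
    r = cmh_pool([ContingencyTable(0, 5, 10, 100)])
    assert np.isfinite(r.oddsratio) and r.oddsratio > 0


def test_summarize_methods_flags_no_data():
    res = {"good": cmh_pool([ContingencyTable(2, 1, 1, 2)]), "empty": None}
    df = summarize_methods(res)
    row = df.set_index("method").loc["empty"]
    assert row["note"] == "no data" and np.isnan(row["OR"])
    # identical proxy sets under two labels give identical statistics
    res2 = {"m1": cmh_pool([ContingencyTable(2, 1, 1, 2)]),
            "m2": cmh_pool([ContingencyTable(2, 1, 1, 2)])}
    df2 = summarize_methods(res2).set_index("method")
    assert df2.loc["m1", "OR"] == df2.loc["m2", "OR"]
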