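"""Contingency tables, Fisher/FDR, selection calls, magnitude arithmetic."""

import math

import numpy as np
import pytest

from tfselect.stats import (ContingencyTable, MotifSelectionResult, bh_fdr,
                            build_table, call_selection, dnase_fold_change,
                            evaluate_family, fisher_two_sided)


def fisher_oracle(a, b, c, d):
    """Exact two-sided Fisher P by integer hypergeometric enumeration."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    denom = math.comb(n, c1)
    obs = math.comb(r1, a) * math.comb(r2, c)
    total = 0
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        num = math.comb(r1, x) * math.comb(r2, c1 - x)
        if num <= obs:
            total += num
    return total / denom


def _tally(events, eligible, direction="loss"):
    return {f"n_{direction}_events": events, f"n_{direction}_eligible": eligible}


def _result(q, magnitude, control="shuffle", direction="loss"):
    # table with f_exp = 0.1 and f_obs = magnitude * 0.1, so M is exact
    a = int(round(magnitude * 100))
    return MotifSelectionResult("M", "toy", control, direction,
                                ContingencyTable(a, 1000 - a, 100, 900, direction),
                                deficit=0, p=q, q=q)


# -- build_table -------------------------------------------------------------------


def test_build_table_no_deficit_is_raw():
    t = build_table(_tally(3, 40), _tally(10, 200), 0, "loss")
    assert (t.a, t.b, t.c, t.d) == (3, 37, 10, 190)


def test_build_table_imputes_at_observed_rate():
    t = build_table(_tally(10, 100), _tally(5, 100), 100, "loss")
    # f_obs = 0.10 -> 10 imputed events, 90 imputed non-events
    assert (t.c, t.d) == (5 + 10, 95 + 90)


def test_imputation_never_increases_difference(rng):
    """Imputed windows pull f_exp toward f_obs; rounding the imputed event
    count to an integer can perturb the pull by at most one control count."""
    for _ in range(300):
        a, n_t = int(rng.integers(0, 50)), int(rng.integers(50, 400))
        c, n_c = int(rng.integers(0, 50)), int(rng.integers(50, 400))
        deficit = int(rng.integers(1, 200))
        raw = build_table(_tally(a, n_t), _tally(c, n_c), 0, "loss")
        imp = build_table(_tally(a, n_t), _tally(c, n_c), deficit, "loss")
        rounding_slack = 1.0 / (imp.c + imp.d)
        assert abs(imp.f_obs - imp.f_exp) \
            <= abs(raw.f_obs - raw.f_exp) + rounding_slack


def test_build_table_rejects_negative():
    with pytest.raises(ValueError):
        build_table(_tally(3, 40), _tally(10, 200), -1, "loss")
    with pytest.raises(ValueError):
        ContingencyTable(-1, 1, 1, 1, "loss")


# -- Fisher ------------------------------------------------------------------------


def test_fisher_balanced_table_is_one():
    assert fisher_two_sided(ContingencyTable(5, 5, 5, 5, "loss")) == 1.0


@pytest.mark.parametrize("table", [(0, 0, 3, 7), (4, 0, 6, 0), (0, 5, 0, 9)])
def test_fisher_degenerate_margin_is_one(table):
    a, b, c, d = table
    assert fisher_two_sided(ContingencyTable(a, b, c, d, "loss")) == 1.0


def test_fisher_matches_enumeration_oracle():
    assert fisher_two_sided(ContingencyTable(1, 9, 11, 3, "loss")) \
        == pytest.approx(fisher_oracle(1, 9, 11, 3), rel=1e-9)


def test_fisher_random_tables_against_oracle(rng):
    for _ in range(100):
        a, b, c, d = (int(x) for x in rng.integers(0, 12, size=4))
        got = fisher_two_sided(ContingencyTable(a, b, c, d, "loss"))
        assert got == pytest.approx(fisher_oracle(a, b, c, d), rel=1e-9)


# -- BH FDR ------------------------------------------------------------------------


def bh_oracle(ps):
    """Direct step-up computation: q_(i) = cummin_{j>=i} p_(j) * m / j."""
    ps = np.asarray(ps, float)
    m = len(ps)
    order = np.argsort(ps)
    adj = ps[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(adj[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


def test_bh_trivial_cases():
    assert bh_fdr([0.04]) == pytest.approx([0.04])
    assert bh_fdr([0.2, 0.2, 0.2]) == pytest.approx([0.2, 0.2, 0.2])
    assert list(bh_fdr([])) == []


def test_bh_matches_stepup_oracle(rng):
    ps = rng.uniform(size=20)
    np.testing.assert_allclose(bh_fdr(ps), bh_oracle(ps), rtol=1e-12)
    assert np.all(bh_fdr(ps) >= ps - 1e-15)


from hypothesis import given, settings
from hypothesis import strategies as st


@settings(derandomize=True, max_examples=50, deadline=None)
@given(st.lists(st.floats(min_value=1e-12, max_value=1.0), min_size=1, max_size=40))
def test_bh_properties_hold_for_arbitrary_pvalues(ps):
    qs = bh_fdr(ps)
    assert np.all(qs >= np.asarray(ps) - 1e-12)  # q >= p elementwise
    assert np.all(qs <= 1.0 + 1e-12)
    order = np.argsort(ps)
    assert np.all(np.diff(qs[order]) >= -1e-12)  # monotone after sorting by p
    np.testing.assert_allclose(qs, bh_oracle(ps), rtol=1e-9)


# -- selection calls ----------------------------------------------------------------


def test_call_selection_negative():
    assert call_selection(_result(0.01, 0.90), _result(0.02, 0.93, "genomic")) \
        == "negative"


def test_call_selection_one_control_not_significant():
    assert call_selection(_result(0.01, 0.90), _result(0.2, 0.90, "genomic")) \
        == "none"


def test_call_selection_inconsistent_direction():
    assert call_selection(_result(0.01, 0.90), _result(0.01, 1.10, "genomic")) \
        == "none"


def test_call_selection_positive_and_missing():
    assert call_selection(_result(0.01, 1.2), _result(0.03, 1.4, "genomic")) \
        == "positive"
    with pytest.warns(UserWarning, match="missing one control"):
        assert call_selection(_result(0.01, 1.2), None) == "none"


def test_evaluate_family_power_gate():
    strong = MotifSelectionResult("M1", "toy", "shuffle", "loss",
                                  ContingencyTable(30, 170, 10, 990, "loss"),
                                  0, p=1e-8)
    tiny = MotifSelectionResult("M2", "toy", "shuffle", "loss",
                                ContingencyTable(5, 5, 0, 50, "loss"),
                                0, p=1e-4)
    evaluate_family([strong, tiny], alpha=0.05, min_eligible=100)
    assert strong.significant is True
    assert tiny.significant is False  # q < alpha but below the power gate
    assert tiny.q is not None


# -- magnitude / fold change ---------------------------------------------------------


def test_magnitude_sign_convention():
    t = ContingencyTable(10, 90, 20, 80, "loss")
    r = MotifSelectionResult("M", "toy", "shuffle", "loss", t, 0, p=0.5)
    assert r.magnitude == pytest.approx(0.5)
    assert (r.magnitude > 1) == (r.f_obs > r.f_exp)


def test_dnase_fold_change_values(rng):
    assert dnase_fold_change(1.0, 1.0) == 0.0
    assert dnase_fold_change(0.8, 1.0) == pytest.approx(-0.32192809, abs=1e-6)
    for _ in range(20):
        m1, m2 = rng.uniform(0.1, 3, size=2)
        assert dnase_fold_change(m1, m2) == pytest.approx(np.log2(m1) - np.log2(m2))
    with pytest.warns(UserWarning, match="undefined"):
        assert math.isnan(dnase_fold_change(0.0, 1.0))
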