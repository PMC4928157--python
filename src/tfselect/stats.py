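"""Selection statistics: contingency tables, Fisher/FDR, magnitude, calls.

For one (motif, cancer type, control, direction) combination the 2x2 table
opposes affinity-change events vs non-events in cancer vs control windows
(both restricted to the direction's eligible set and context-equalized).
Control windows missing after equalization (deficits) are imputed at the
observed cancer event rate, which pulls the expected frequency toward the
observed one and can only weaken — never manufacture — significance.

The *selection magnitude* M is the ratio of the observed event frequency to
the control (expected) frequency: M < 1 indicates negative selection
(protection of sites), M > 1 positive selection. A motif is called under
selection in a direction only when both the shuffle and the genomic
comparisons are FDR-significant with the same sign of M - 1.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

ALPHA_DEFAULT = 0.05
MIN_ELIGIBLE_DEFAULT = 100

DIRECTIONS = ("loss", "gain")


@dataclass(frozen=True)
class ContingencyTable:
    """a,b: test events/non-events; c,d: control events/non-events."""

    a: int
    b: int
    c: int
    d: int
    direction: str

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError(f"negative count in {self}")

    @property
    def f_obs(self) -> float:
        return self.a / (self.a + self.b) if self.a + self.b else float("nan")

    @property
    def f_exp(self) -> float:
        return self.c / (self.c + self.d) if self.c + self.d else float("nan")


@dataclass
class MotifSelectionResult:
    motif: str
    cancer_type: str
    control: str          # 'shuffle' | 'genomic'
    direction: str        # 'loss' | 'gain' | 'overlap'
    table: ContingencyTable
    deficit: int
    p: float
    q: Optional[float] = None
    significant: Optional[bool] = None

    @property
    def f_obs(self) -> float:
        return self.table.f_obs

    @property
    def f_exp(self) -> float:
        return self.table.f_exp

    @property
    def magnitude(self) -> float:
        """Observed/expected event frequency; <1 negative, >1 positive selection."""
        fe = self.f_exp
        return self.f_obs / fe if fe and not math.isnan(fe) else float("nan")


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def build_table(test_tally: dict, control_tally: dict, deficit: int,
                direction: str) -> ContingencyTable:
    """Assemble the 2x2 table, imputing missing control windows uniformly.

    ``deficit`` control windows that could not be context-matched are added
    on the control side at the observed cancer event rate (rounded half away
    from zero), so imputation shrinks |f_obs - f_exp|.
    """
    if direction not in ("loss", "gain", "overlap"):
        raise ValueError(f"unknown direction {direction!r}")
    if deficit < 0:
        raise ValueError("deficit must be >= 0")
    key = direction if direction != "overlap" else "overlap"
    a = int(test_tally[f"n_{key}_events"])
    n_test = int(test_tally[f"n_{key}_eligible"])
    c = int(control_tally[f"n_{key}_events"])
    n_ctrl = int(control_tally[f"n_{key}_eligible"])
    b = n_test - a
    d = n_ctrl - c
    if deficit:
        f_obs = a / n_test if n_test else 0.0
        imputed_events = _round_half_away(deficit * f_obs)
        c += imputed_events
        d += deficit - imputed_events
    return ContingencyTable(a, b, c, d, direction)


def fisher_two_sided(table: ContingencyTable) -> float:
    """Exact two-sided Fisher P (sum of hypergeometric probs <= observed)."""
    _, p = sps.fisher_exact([[table.a, table.b], [table.c, table.d]],
                            alternative="two-sided")
    return float(min(p, 1.0))


def bh_fdr(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values over one family of tests."""
    pvalues = np.asarray(list(pvalues), dtype=float)
    if pvalues.size == 0:
        return pvalues
    return multipletests(pvalues, method="fdr_bh")[1]


def call_selection(shuffle_result: Optional[MotifSelectionResult],
                   genomic_result: Optional[MotifSelectionResult],
                   alpha: float = ALPHA_DEFAULT) -> str:
    """Final per-(motif, direction) call requiring both-controls consistency.

    'negative' iff q < alpha and M < 1 against *both* controls; 'positive'
    iff q < alpha and M > 1 against both; anything else (including a missing
    control or inconsistent directions) is 'none'.
    """
    if shuffle_result is None or genomic_result is None:
        warnings.warn("call_selection: missing one control, returning 'none'",
                      stacklevel=2)
        return "none"
    pair = (shuffle_result, genomic_result)
    if any(r.q is None or math.isnan(r.magnitude) for r in pair):
        return "none"

    def sig(r):
        # honor the low-power gate when evaluate_family has applied it
        return r.significant if r.significant is not None else r.q < alpha

    if all(sig(r) and r.magnitude < 1 for r in pair):
        return "negative"
    if all(sig(r) and r.magnitude > 1 for r in pair):
        return "positive"
    return "none"


def dnase_fold_change(m_dnase: float, m_all: float) -> float:
    """log2 ratio of the DNase-stratum magnitude to the full-region magnitude.

    Negative values mean stronger negative selection inside DNase-accessible
    regions. Non-positive or undefined magnitudes yield NaN with a warning.
    """
    if not (m_dnase > 0 and m_all > 0) or math.isnan(m_dnase) or math.isnan(m_all):
        warnings.warn("dnase_fold_change: undefined for non-positive magnitude",
                      stacklevel=2)
        return float("nan")
    return math.log2(m_dnase / m_all)


def evaluate_family(results: Sequence[MotifSelectionResult],
                    alpha: float = ALPHA_DEFAULT,
                    min_eligible: int = MIN_ELIGIBLE_DEFAULT) -> None:
    """Attach BH q-values and significance flags to one FDR family in place.

    A family is all tested motifs for one (cancer type, control, direction).
    Results whose test or control denominator falls below ``min_eligible``
    keep their q-value but are never flagged significant (low-power guard).
    """
    if not results:
        return
    qs = bh_fdr([r.p for r in results])
    for r, q in zip(results, qs):
        r.q = float(q)
        powered = (r.table.a + r.table.b >= min_eligible
                   and r.table.c + r.table.d >= min_eligible)
        r.significant = bool(q < alpha and powered)


def results_to_table(results: Sequence[MotifSelectionResult], calls: dict = None):
    """Flatten results into the pipeline's primary TSV schema."""
    import pandas as pd

    rows = []
    for r in results:
        call = (calls or {}).get((r.motif, r.direction), "")
        rows.append((r.motif, r.direction, r.control, r.table.a, r.table.b,
                     r.table.c, r.table.d, r.deficit, r.f_obs, r.f_exp,
                     r.magnitude, r.p, r.q, r.significant, call))
    return pd.DataFrame(rows, columns=[
        "motif", "direction", "control", "a", "b", "c", "d", "deficit",
        "f_obs", "f_exp", "magnitude", "p", "q", "significant", "call"])
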