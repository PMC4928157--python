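"""Simplified selection test: motif/mutation overlap without affinity calls.

A window counts as *overlapping* when the mutated base lies inside the
germline best hit's [start, start+L) interval; eligibility is the same as
in the main workflow (germline best hit passing the site P-value within the
scanning distance). The 2x2 table opposes overlapping vs non-overlapping
eligible windows in test vs control data, with Fisher/FDR and magnitude
computed exactly as for the affinity-change directions. The test ignores
the substitution itself, so it cannot separate loss from gain or discount
neutral in-motif substitutions — but it is free of the fold-ratio cutoff.
"""

from __future__ import annotations

from typing import Sequence

from .affinity import MAX_DIST_DEFAULT, P_SITE_DEFAULT, encode_window_pair
from .pwm import PositionWeightMatrix
from .stats import ContingencyTable, MotifSelectionResult, build_table, fisher_two_sided
from .windows import CENTER


def overlap_tally(windows: Sequence, pwm: PositionWeightMatrix,
                  p_site: float = P_SITE_DEFAULT,
                  max_dist: int = MAX_DIST_DEFAULT) -> dict:
    """Counts of eligible and overlapping windows for one window set."""
    counts = {"n_overlap_eligible": 0, "n_overlap_events": 0}
    if not windows:
        return counts
    germ, _ = encode_window_pair(windows)
    hits = pwm.scan_batch(germ, CENTER, max_dist)
    eligible = hits.pvalue <= p_site
    counts["n_overlap_eligible"] = int(eligible.sum())
    counts["n_overlap_events"] = int((eligible & (hits.dist == 0)).sum())
    return counts


def overlap_test(test_windows: Sequence, control_windows: Sequence,
                 pwm: PositionWeightMatrix, *, p_site: float = P_SITE_DEFAULT,
                 max_dist: int = MAX_DIST_DEFAULT, deficit: int = 0,
                 cancer_type: str = "", control: str = "") -> MotifSelectionResult:
    """Fisher comparison of overlap rates in test vs (equalized) control windows."""
    test_tally = overlap_tally(test_windows, pwm, p_site, max_dist)
    ctrl_tally = overlap_tally(control_windows, pwm, p_site, max_dist)
    table = build_table(test_tally, ctrl_tally, deficit, "overlap")
    return MotifSelectionResult(motif=pwm.name, cancer_type=cancer_type,
                                control=control, direction="overlap",
                                table=table, deficit=deficit,
                                p=fisher_two_sided(table))
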