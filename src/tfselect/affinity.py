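"""Affinity-change classification of mutation-centered windows.

For one motif and one window, the best-hit motif P-values of the germline
(p_g) and mutant (p_m) alleles are compared, each taken over hits lying
within ``max_dist`` bp of the mutated base (the hits need not share a
position). With site-calling stringency p_site and fold threshold ``fold``:

* LOSS: p_g <= p_site and p_m >= fold * p_g (site disrupted >= fold-fold)
* GAIN: p_m <= p_site and p_g >= fold * p_m (site emerges / strengthens)
* otherwise NONE.

Comparisons at the fold boundary are inclusive ("at least fold times
weaker"). With fold > 1 the two calls are mutually exclusive. Eligibility
flags (p_g <= p_site, p_m <= p_site) are kept on every call: they are the
denominators of the loss and gain frequencies, and a window eligible for
both directions enters both denominators.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np

from .pwm import PositionWeightMatrix, encode
from .windows import CENTER, MutationWindow

P_SITE_DEFAULT = 0.0005
FOLD_DEFAULT = 4.0
MAX_DIST_DEFAULT = 10

LOSS, GAIN, NONE = "LOSS", "GAIN", "NONE"


@dataclass(frozen=True)
class AffinityCall:
    motif: str
    window: object  # the classified window (MutationWindow / ControlWindow)
    p_g: Optional[float]
    p_m: Optional[float]
    ratio: Optional[float]  # p_m / p_g
    call: str
    eligible_for_loss: bool
    eligible_for_gain: bool

    @property
    def context(self):
        """Mutation context of the underlying window (for equalization)."""
        return self.window.context


def _decide(p_g: float, p_m: float, p_site: float, fold: float):
    eligible_loss = p_g <= p_site
    eligible_gain = p_m <= p_site
    call = NONE
    if eligible_loss and p_m >= fold * p_g:
        call = LOSS
    if eligible_gain and p_g >= fold * p_m:
        # fold <= 1 would allow both; the last assignment wins only for the
        # degenerate configuration, with fold > 1 the branches are exclusive
        call = GAIN
    return call, eligible_loss, eligible_gain


def classify(window: MutationWindow, pwm: PositionWeightMatrix,
             p_site: float = P_SITE_DEFAULT, fold: float = FOLD_DEFAULT,
             max_dist: int = MAX_DIST_DEFAULT) -> AffinityCall:
    """Classify one window against one motif (reference implementation)."""
    hit_g = pwm.best_hit(window.germline, CENTER, max_dist, allele="germline")
    hit_m = pwm.best_hit(window.mutant, CENTER, max_dist, allele="mutant")
    if hit_g is None or hit_m is None:
        return AffinityCall(pwm.name, window, None, None, None, NONE, False, False)
    p_g, p_m = hit_g.motif_pvalue, hit_m.motif_pvalue
    call, el, eg = _decide(p_g, p_m, p_site, fold)
    return AffinityCall(pwm.name, window, p_g, p_m, p_m / p_g, call, el, eg)


def classify_batch(windows: Sequence, pwm: PositionWeightMatrix,
                   p_site: float = P_SITE_DEFAULT, fold: float = FOLD_DEFAULT,
                   max_dist: int = MAX_DIST_DEFAULT) -> list[AffinityCall]:
    """Vectorized classification of many windows (same decisions as classify)."""
    if not windows:
        return []
    germ, mut = encode_window_pair(windows)
    hits_g = pwm.scan_batch(germ, CENTER, max_dist)
    hits_m = pwm.scan_batch(mut, CENTER, max_dist)
    calls = []
    for i, w in enumerate(windows):
        p_g = float(hits_g.pvalue[i])
        p_m = float(hits_m.pvalue[i])
        call, el, eg = _decide(p_g, p_m, p_site, fold)
        calls.append(AffinityCall(pwm.name, w, p_g, p_m, p_m / p_g, call, el, eg))
    return calls


def encode_window_pair(windows: Sequence) -> tuple[np.ndarray, np.ndarray]:
    """Stack germline and mutant sequences of windows into code matrices."""
    germ = np.vstack([encode(w.germline) for w in windows])
    mut = np.vstack([encode(w.mutant) for w in windows])
    return germ, mut


def tally(calls: Iterable[AffinityCall]) -> dict:
    """Per-motif event/denominator counts for one (motif, dataset) pair."""
    counts = {"n_loss_eligible": 0, "n_loss_events": 0,
              "n_gain_eligible": 0, "n_gain_events": 0}
    motif = None
    for c in calls:
        if motif is None:
            motif = c.motif
        elif c.motif != motif:
            raise ValueError(f"mixed motifs in tally: {motif} vs {c.motif}")
        counts["n_loss_eligible"] += c.eligible_for_loss
        counts["n_loss_events"] += c.call == LOSS
        counts["n_gain_eligible"] += c.eligible_for_gain
        counts["n_gain_events"] += c.call == GAIN
    return counts


def calls_to_table(calls: Sequence[AffinityCall]):
    """Per-call debug table (motif, window id, p_g, p_m, ratio, call)."""
    import pandas as pd

    rows = []
    for c in calls:
        mut = getattr(c.window, "mutation", None)
        wid = f"{mut.chrom}:{mut.pos}:{mut.alt}" if mut is not None else repr(c.window)
        rows.append((c.motif, wid, c.p_g, c.p_m, c.ratio, c.call,
                     c.eligible_for_loss, c.eligible_for_gain))
    return pd.DataFrame(rows, columns=["motif", "window", "p_g", "p_m", "ratio",
                                       "call", "eligible_for_loss", "eligible_for_gain"])
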