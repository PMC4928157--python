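"""Positional density of mutations relative to aligned motif occurrences.

Windows with a legitimate germline best hit are aligned in motif
orientation and the offset of the mutated base relative to the motif start
is histogrammed and normalized by the number of eligible windows. Offsets
in [0, L-1] fall inside the motif; negative / >= L offsets are flanking
(bounded by the scanning distance). Built identically for cancer and
control window sets, the profiles are directly comparable; positions of
high information content that avoid mutations relative to the controls
indicate purifying pressure on the motif.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .affinity import MAX_DIST_DEFAULT, P_SITE_DEFAULT
from .pwm import MotifHit, PositionWeightMatrix
from .windows import CENTER


@dataclass
class PositionalProfile:
    motif: str
    label: str                 # dataset label: cancer | shuffle | genomic
    offsets: np.ndarray        # motif-oriented offsets covered by the scan
    density: np.ndarray        # fraction of eligible windows mutated at each offset
    n_windows: int             # eligible windows (normalization denominator)

    def to_frame(self):
        import pandas as pd
        return pd.DataFrame({"motif": self.motif, "dataset": self.label,
                             "offset": self.offsets, "density": self.density})


def mutation_offset(hit: MotifHit, anchor: int = CENTER) -> int:
    """Offset of the mutated base in the motif's 5'->3' orientation.

    For a + strand hit the offset is anchor - start; for a - strand hit the
    motif reads right-to-left on the window, so the offset is
    start + L - 1 - anchor. Offsets outside [0, L-1] are flanking.
    """
    if hit.strand == "+":
        return anchor - hit.start
    return hit.start + hit.length - 1 - anchor


def build_profile(windows, pwm: PositionWeightMatrix, label: str = "cancer",
                  p_site: float = P_SITE_DEFAULT,
                  max_dist: int = MAX_DIST_DEFAULT) -> PositionalProfile:
    """Normalized mutation-offset histogram over loss-eligible windows.

    Each window with a germline best hit passing ``p_site`` within
    ``max_dist`` contributes exactly one offset (its single best hit, after
    tie-breaking), so the densities sum to 1 over the covered offset range.
    """
    lo, hi = -max_dist, pwm.length - 1 + max_dist
    offsets = np.arange(lo, hi + 1)
    counts = np.zeros(offsets.size, dtype=np.int64)
    windows = list(windows)
    n_eligible = 0
    if windows:
        from .pwm import encode
        codes = np.vstack([encode(w.germline) for w in windows])
        hits = pwm.scan_batch(codes, CENTER, max_dist)
        eligible = hits.pvalue <= p_site
        n_eligible = int(eligible.sum())
        off = np.where(hits.strand == 0, CENTER - hits.start,
                       hits.start + pwm.length - 1 - CENTER)
        np.add.at(counts, off[eligible] - lo, 1)
    density = counts / n_eligible if n_eligible else counts.astype(float)
    return PositionalProfile(pwm.name, label, offsets, density, n_eligible)


def information_content(pwm: PositionWeightMatrix, pseudocount: float = 1.0
                        ) -> np.ndarray:
    """Per-column Shannon information content in bits (for logo scaling).

    IC_j = 2 + sum_b f_b log2 f_b with f_b the pseudocounted column
    frequencies; ranges from 0 (uniform column) to 2 (single base). Requires
    the matrix's original counts.
    """
    if pwm.source_counts is None:
        raise ValueError(f"{pwm.name}: information content needs source counts; "
                         "load the matrix in 'counts' format")
    c = pwm.source_counts + pseudocount / 4.0
    f = c / c.sum(axis=1, keepdims=True)
    return 2.0 + (f * np.log2(f)).sum(axis=1)
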