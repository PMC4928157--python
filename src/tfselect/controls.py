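"""Simulated control window sets and mutation-context equalization.

Two null models estimate the expected affinity-change frequency:

* **shuffle control** — per real mutation window, the 98 flanking positions
  are jointly permuted while the central trinucleotide and the substitution
  stay fixed; local composition is preserved, sequence structure destroyed.
* **genomic control** — windows sampled from promoter/intron regions whose
  central trinucleotide matches a requested mutation context and whose
  [-50, +50] span does not overlap any real mutation-centered window; the
  context's alternate allele is substituted to form the mutant sequence.

Because site predictions depend on composition, control windows *with
predictions* are then re-sampled per motif so their mutation-context
distribution matches the cancer data (``equalize_contexts``); per-class
shortfalls are recorded as deficits for the downstream uniformization rule.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from .pwm import encode, ALPHABET
from .windows import (CENTER, HALF_WINDOW, WINDOW, ContextClass,
                      MutationWindow, RegionSet)

logger = logging.getLogger(__name__)

_FLANK_IDX = np.array([i for i in range(WINDOW) if i not in (CENTER - 1, CENTER, CENTER + 1)])


@dataclass(frozen=True)
class ControlWindow:
    """A control window with the same shape as a MutationWindow."""

    germline: str
    mutant: str
    context: ContextClass
    origin: str                      # 'shuffle' | 'genomic'
    source: object = None            # source MutationWindow or (chrom, pos0) locus

    def __post_init__(self):
        if len(self.germline) != WINDOW or len(self.mutant) != WINDOW:
            raise ValueError("control window must be exactly 101 nt")


@dataclass
class EqualizationReport:
    """Bookkeeping of per-context targets, achieved counts and deficits."""

    motif: Optional[str] = None
    per_class: dict = field(default_factory=dict)  # ContextClass -> dict

    @property
    def total_target(self) -> int:
        return sum(v["target"] for v in self.per_class.values())

    @property
    def total_sampled(self) -> int:
        return sum(v["sampled"] for v in self.per_class.values())

    @property
    def total_deficit(self) -> int:
        return sum(v["deficit"] for v in self.per_class.values())

    @property
    def match_fraction(self) -> float:
        """Fraction of requested context-matched windows actually sampled."""
        tgt = self.total_target
        return 1.0 if tgt == 0 else self.total_sampled / tgt


# -- shuffle control ----------------------------------------------------------


def make_shuffle_controls(window: MutationWindow, n_per: int,
                          rng: np.random.Generator) -> list[ControlWindow]:
    """Shuffled-flank copies of one mutation window.

    Each copy applies one uniform joint permutation to the 98 positions
    outside the central trinucleotide; the trinucleotide and the substituted
    allele are untouched, so the mutation context is conserved exactly and
    the flank nucleotide multiset is invariant.
    """
    if n_per < 1:
        raise ValueError("n_per must be >= 1")
    germ = np.frombuffer(window.germline.encode("ascii"), dtype="S1").copy()
    flank = germ[_FLANK_IDX]
    out = []
    for _ in range(n_per):
        perm = rng.permutation(len(_FLANK_IDX))
        shuffled = germ.copy()
        shuffled[_FLANK_IDX] = flank[perm]
        g = shuffled.tobytes().decode("ascii")
        m = g[:CENTER] + window.mutation.alt + g[CENTER + 1:]
        out.append(ControlWindow(g, m, window.context, "shuffle", window))
    return out


# -- genomic control ----------------------------------------------------------


class GenomicSampler:
    """Trinucleotide-indexed sampler of control loci from regulatory regions.

    Precomputes, for every central trinucleotide, the region positions whose
    [-50, +50] window fits the contig and avoids the exclusion windows, so
    repeated per-context sampling is O(draws).
    """

    def __init__(self, genome, regions: Sequence[RegionSet],
                 exclusion: Iterable = (), half: int = HALF_WINDOW):
        from .windows import _as_fasta

        self.half = half
        genome = _as_fasta(genome)
        self._seqs: dict[str, str] = {}
        self._index: dict[int, list[tuple[str, np.ndarray]]] = {}

        excl_by_chrom: dict[str, list[tuple[int, int]]] = {}
        for item in exclusion:
            if isinstance(item, MutationWindow):
                chrom, pos0 = item.mutation.chrom, item.mutation.pos - 1
                start, end = pos0 - half, pos0 + half + 1
            else:
                chrom, start, end = item
            excl_by_chrom.setdefault(chrom, []).append((int(start), int(end)))

        chroms = sorted({chrom for rs in regions for chrom in rs.trees})
        for chrom in chroms:
            seq = str(genome[chrom][:]).upper()
            self._seqs[chrom] = seq
            n = len(seq)
            codes = encode(seq)
            in_region = np.zeros(n, dtype=bool)
            for rs in regions:
                tree = rs.trees.get(chrom)
                if tree is None:
                    continue
                for iv in tree:
                    in_region[max(0, iv.begin):min(n, iv.end)] = True
            ok = in_region.copy()
            ok[:half] = False
            ok[n - half:] = False
            # exclude positions whose window would intersect an exclusion window
            for start, end in excl_by_chrom.get(chrom, ()):
                ok[max(0, start - half):min(n, end + half)] = False
            # central trinucleotide must be unambiguous
            tri_ok = (codes[:-2] <= 3) & (codes[1:-1] <= 3) & (codes[2:] <= 3)
            centers = np.nonzero(ok[1:-1] & tri_ok)[0] + 1
            tri_id = (codes[centers - 1].astype(np.int32) * 16
                      + codes[centers].astype(np.int32) * 4
                      + codes[centers + 1].astype(np.int32))
            for tid in np.unique(tri_id):
                self._index.setdefault(int(tid), []).append(
                    (chrom, centers[tri_id == tid].astype(np.int32)))

    @staticmethod
    def _tri_id(context: ContextClass) -> int:
        return (ALPHABET.index(context.five_prime) * 16
                + ALPHABET.index(context.ref) * 4
                + ALPHABET.index(context.three_prime))

    def n_candidates(self, context: ContextClass) -> int:
        return sum(len(pos) for _, pos in self._index.get(self._tri_id(context), ()))

    def sample(self, context: ContextClass, n: int,
               rng: np.random.Generator) -> list[ControlWindow]:
        """Sample up to n non-overlapping loci matching the context trinucleotide."""
        buckets = self._index.get(self._tri_id(context), [])
        sizes = [len(positions) for _, positions in buckets]
        total = sum(sizes)
        if total == 0:
            logger.warning("genomic control: no candidate loci for context %s", context)
            return []
        take = min(n, total)
        if take < n:
            logger.warning("genomic control: only %d of %d requested loci for context %s",
                           take, n, context)
        picked = rng.choice(total, size=take, replace=False)
        bounds = np.cumsum([0] + sizes)
        out = []
        for idx in picked:
            b = int(np.searchsorted(bounds, idx, side="right")) - 1
            chrom, pos0 = buckets[b][0], int(buckets[b][1][idx - bounds[b]])
            seq = self._seqs[chrom]
            g = seq[pos0 - self.half:pos0 + self.half + 1]
            m = g[:self.half] + context.alt + g[self.half + 1:]
            out.append(ControlWindow(g, m, context, "genomic", (chrom, pos0)))
        return out


def sample_genomic_controls(context: ContextClass, n: int,
                            regions: Sequence[RegionSet], genome,
                            exclusion: Iterable = (), rng=None,
                            sampler: Optional[GenomicSampler] = None
                            ) -> list[ControlWindow]:
    """One-shot genomic control sampling (builds the index when not supplied)."""
    if rng is None:
        rng = np.random.default_rng()
    if sampler is None:
        sampler = GenomicSampler(genome, regions, exclusion)
    return sampler.sample(context, n, rng)


# -- context equalization ------------------------------------------------------


def _largest_remainder(freqs: dict, total: int) -> dict:
    """Integer targets summing to ``total`` proportional to ``freqs``."""
    keys = sorted(freqs)
    raw = {k: freqs[k] * total for k in keys}
    base = {k: math.floor(raw[k]) for k in keys}
    rest = total - sum(base.values())
    order = sorted(keys, key=lambda k: (-(raw[k] - base[k]), str(k)))
    for k in order[:rest]:
        base[k] += 1
    return base


def equalize_contexts(test_windows: Sequence, control_windows: Sequence,
                      rng: np.random.Generator, n_target: Optional[int] = None,
                      multiplier: float = 5.0, motif: Optional[str] = None
                      ) -> tuple[list, EqualizationReport]:
    """Sample control windows to match the test mutation-context distribution.

    Both inputs must already be restricted to windows with legitimate motif
    predictions for the relevant allele. The requested control size defaults
    to ``multiplier`` x len(test_windows); per-class targets follow the test
    class frequencies (largest-remainder rounding), each met by sampling
    without replacement up to availability, with the shortfall recorded as a
    deficit.
    """
    report = EqualizationReport(motif=motif)
    if not test_windows:
        return [], report
    n_test = len(test_windows)
    total = int(n_target) if n_target is not None else int(round(multiplier * n_test))
    freqs: dict[ContextClass, float] = {}
    for w in test_windows:
        freqs[w.context] = freqs.get(w.context, 0.0) + 1.0 / n_test
    targets = _largest_remainder(freqs, total)
    by_class: dict[ContextClass, list] = {}
    for w in control_windows:
        by_class.setdefault(w.context, []).append(w)
    sampled: list = []
    for ctx in sorted(targets, key=str):
        target = targets[ctx]
        avail = by_class.get(ctx, [])
        take = min(target, len(avail))
        if take:
            picked = rng.choice(len(avail), size=take, replace=False)
            sampled.extend(avail[int(i)] for i in picked)
        report.per_class[ctx] = {"target": target, "sampled": take,
                                 "deficit": max(0, target - take)}
    return sampled, report
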