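"""Position weight matrices with exact word-enumeration P-values.

A PWM assigns each length-L word the sum of per-position, per-nucleotide
score terms. Under a uniform background the *motif P-value* of a score
threshold t is the fraction of all 4^L words scoring >= t; it is computed
exactly by dynamic programming over a discretized score lattice, never by
sampling. Scores are snapped to the lattice (multiples of ``step``) at
construction time, so word scores, the score distribution and the
score->P-value map are mutually exact: ``pvalue_from_score(score_word(w))``
is the true fraction of words scoring at least ``score_word(w)``.

Scanning is anchored: ``best_hit`` considers hits on both strands whose
interval lies within ``max_dist`` bp of an anchor base (distance 0 when the
anchor is covered), the convention used to tie binding-site predictions to
a mutated base.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np

ALPHABET = "ACGT"
_CODE = {c: i for i, c in enumerate(ALPHABET)}
_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")

# sentinel per-position score bin for non-ACGT characters: any word touching
# one can never win a scan and maps to P-value 1.0
_BAD_BIN = -(10**12)

_MAX_LENGTH = 31  # 4**31 < 2**63: exact word counts stay inside int64


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def encode(seq: str) -> np.ndarray:
    """Map a nucleotide string to int8 codes A,C,G,T -> 0..3; other chars -> 4."""
    raw = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    out = np.full(raw.shape, 4, dtype=np.int8)
    for base, code in _CODE.items():
        out[raw == ord(base)] = code
    return out


class MatrixParseError(ValueError):
    pass


@dataclass(frozen=True)
class MotifHit:
    """A single best-hit prediction inside a scanned window."""

    motif: str
    start: int            # 0-based offset of the hit interval within the window
    strand: str           # '+' or '-'
    score: float
    motif_pvalue: float
    distance_to_anchor: int
    length: int
    allele: Optional[str] = None  # 'germline' | 'mutant' when set by callers

    @property
    def end(self) -> int:
        return self.start + self.length

    def covers_anchor(self) -> bool:
        return self.distance_to_anchor == 0


class ScoreDistribution:
    """Exact distribution of lattice word scores for one matrix.

    ``bins``/``counts`` enumerate every attainable discretized score and the
    number of length-L words attaining it; counts total exactly 4**L.
    """

    def __init__(self, motif: str, length: int, step: float,
                 bins: np.ndarray, counts: np.ndarray):
        order = np.argsort(bins)
        self.motif = motif
        self.length = length
        self.step = float(step)
        self.bins = np.asarray(bins, dtype=np.int64)[order]
        self.counts = np.asarray(counts, dtype=np.int64)[order]
        self.total = 4 ** length
        # survival counts: number of words with bin >= bins[i]
        rev = np.cumsum(self.counts[::-1])[::-1]
        self._sf = np.concatenate([rev, [0]])  # padded for searchsorted overflow

    def count_ge(self, score_bin: int) -> int:
        """Number of words whose lattice score is >= ``score_bin`` (inclusive)."""
        pos = np.searchsorted(self.bins, score_bin, side="left")
        return int(self._sf[pos])

    def pvalue_of_bin(self, score_bin) -> float:
        pos = np.searchsorted(self.bins, score_bin, side="left")
        return float(self._sf[pos]) / self.total

    def pvalue(self, score: float) -> float:
        # ceil with a tolerance: a probe score strictly between lattice points
        # counts only the words at or above the next attainable lattice score
        k = math.ceil(score / self.step - 1e-9)
        return self.count_ge(k) / self.total


class PositionWeightMatrix:
    """An additive L x 4 scoring model over the DNA alphabet (A,C,G,T order).

    Weights are discretized to multiples of ``step`` at construction; the
    original values are retained in ``raw_weights`` and, when the matrix was
    built from counts, in ``source_counts``.
    """

    def __init__(self, name: str, weights, *, step: float = 0.001,
                 source_counts=None, quality: Optional[str] = None):
        w = np.asarray(weights, dtype=float)
        if w.ndim != 2 or w.shape[1] != 4 or w.shape[0] < 1:
            raise MatrixParseError(f"{name}: weights must be an Lx4 block, got {w.shape}")
        if not np.all(np.isfinite(w)):
            raise MatrixParseError(f"{name}: non-finite weight")
        if w.shape[0] > _MAX_LENGTH:
            raise MatrixParseError(f"{name}: motif length {w.shape[0]} exceeds {_MAX_LENGTH}")
        if step <= 0:
            raise ValueError("step must be positive")
        self.name = name
        self.step = float(step)
        self.raw_weights = w
        self.bins = np.rint(w / step).astype(np.int64)
        self.weights = self.bins * self.step
        self.source_counts = None if source_counts is None else np.asarray(source_counts, dtype=float)
        self.quality = quality
        # padded lookup (L x 5): column 4 is the non-ACGT sentinel
        self._padded = np.concatenate(
            [self.bins, np.full((self.length, 1), _BAD_BIN, dtype=np.int64)], axis=1)
        self._dist: Optional[ScoreDistribution] = None
        self._rc_padded = self._padded[::-1, [3, 2, 1, 0, 4]]

    # -- construction ----------------------------------------------------

    @classmethod
    def from_counts(cls, name: str, counts, *, step: float = 0.001,
                    background: float = 0.25, quality: Optional[str] = None
                    ) -> "PositionWeightMatrix":
        """Log-odds transform of a position count matrix.

        Per position with column total N the weight of base b is
        ln((c_b + background * k) / ((N + k) * background)) with pseudocount
        k = ln(N) (k = 1 when N <= 1), against a uniform background of 0.25.
        """
        c = np.asarray(counts, dtype=float)
        if c.ndim != 2 or c.shape[1] != 4:
            raise MatrixParseError(f"{name}: counts must be an Lx4 block, got {c.shape}")
        if np.any(c < 0):
            raise MatrixParseError(f"{name}: negative count")
        totals = c.sum(axis=1)
        if np.any(totals <= 0):
            raise MatrixParseError(f"{name}: zero column total")
        pseudo = np.where(totals > 1, np.log(np.maximum(totals, 1.0 + 1e-12)), 1.0)
        w = np.log((c + background * pseudo[:, None])
                   / ((totals + pseudo)[:, None] * background))
        return cls(name, w, step=step, source_counts=c, quality=quality)

    # -- basics ----------------------------------------------------------

    @property
    def length(self) -> int:
        return self.raw_weights.shape[0]

    @property
    def max_score(self) -> float:
        return float(self.bins.max(axis=1).sum() * self.step)

    @property
    def min_score(self) -> float:
        return float(self.bins.min(axis=1).sum() * self.step)

    @property
    def consensus(self) -> str:
        return "".join(ALPHABET[i] for i in self.bins.argmax(axis=1))

    def score_word(self, word: str) -> float:
        """Score of one length-L word (sum of per-position weights)."""
        if len(word) != self.length:
            raise ValueError(f"{self.name}: word length {len(word)} != motif length {self.length}")
        codes = encode(word)
        if np.any(codes > 3):
            raise ValueError(f"{self.name}: word contains a non-ACGT character: {word!r}")
        return float(self.bins[np.arange(self.length), codes].sum() * self.step)

    # -- exact P-value machinery ------------------------------------------

    def score_distribution(self) -> ScoreDistribution:
        """Exact DP convolution of per-position score bins over all 4^L words."""
        if self._dist is None:
            cur = np.array([1], dtype=np.int64)  # empty prefix
            cur_lo = 0
            for j in range(self.length):
                row = self.bins[j]
                new_lo = cur_lo + int(row.min())
                new_hi = cur_lo + len(cur) - 1 + int(row.max())
                new = np.zeros(new_hi - new_lo + 1, dtype=np.int64)
                for b in range(4):
                    off = cur_lo + int(row[b]) - new_lo
                    new[off:off + len(cur)] += cur
                cur, cur_lo = new, new_lo
            nz = np.nonzero(cur)[0]
            self._dist = ScoreDistribution(self.name, self.length, self.step,
                                           nz + cur_lo, cur[nz])
        return self._dist

    def pvalue_from_score(self, score: float) -> float:
        """Fraction of all 4^L words scoring >= ``score`` (ties inclusive)."""
        return self.score_distribution().pvalue(score)

    def threshold_for_pvalue(self, target_p: float) -> float:
        """Minimal lattice score t with pvalue_from_score(t) <= target_p.

        Conservative: the attained P-value never exceeds ``target_p``. When
        ``target_p`` < 4^-L no threshold attains it; the maximal score is
        returned with a warning.
        """
        if not 0 < target_p <= 1:
            raise ValueError("target_p must be in (0, 1]")
        dist = self.score_distribution()
        pvals = dist._sf[:-1] / dist.total  # P-value at each attainable bin, descending in value
        idx = np.nonzero(pvals <= target_p)[0]
        if len(idx) == 0:
            warnings.warn(
                f"{self.name}: target P-value {target_p} below the 4^-L resolution "
                f"({1.0 / dist.total:.3g}); returning the maximal score", stacklevel=2)
            return self.max_score
        return float(dist.bins[idx[0]] * self.step)

    # -- scanning ----------------------------------------------------------

    def _candidate_starts(self, seq_len: int, anchor: int, max_dist: int):
        """Eligible hit starts ordered by the tie-break preference.

        Eligibility: the nearest base of [start, start+L) is within
        ``max_dist`` of the anchor (0 when overlapping). Order: distance
        ascending, then start ascending; strand is handled by the caller.
        """
        L = self.length
        lo = max(0, anchor - max_dist - L + 1)
        hi = min(seq_len - L, anchor + max_dist)
        if hi < lo:
            return []
        starts = np.arange(lo, hi + 1)
        dists = np.maximum(0, np.maximum(starts - anchor, anchor - (starts + L - 1)))
        order = np.lexsort((starts, dists))
        return list(zip(starts[order].tolist(), dists[order].tolist()))

    def best_hit(self, sequence: str, anchor: int, max_dist: int,
                 allele: Optional[str] = None) -> Optional[MotifHit]:
        """Best-scoring eligible hit on either strand, or None.

        Ties break by higher score, then smaller anchor distance, then
        leftmost start, then '+' strand. The hit is returned regardless of
        any P-value threshold.
        """
        if not 0 <= anchor < len(sequence):
            raise ValueError(f"anchor {anchor} outside sequence of length {len(sequence)}")
        if max_dist < 0:
            raise ValueError("max_dist must be >= 0")
        cands = self._candidate_starts(len(sequence), anchor, max_dist)
        if not cands:
            return None
        codes = encode(sequence)
        L = self.length
        jj = np.arange(L)
        best = None  # (score_bin, dist, start, strand_order)
        for start, dist in cands:
            win = codes[start:start + L]
            for strand_order, table in ((0, self._padded), (1, self._rc_padded)):
                sb = int(table[jj, win].sum())
                key = (-sb, dist, start, strand_order)
                if best is None or key < best:
                    best = key
        sb, dist, start, strand_order = -best[0], best[1], best[2], best[3]
        dist_obj = self.score_distribution()
        return MotifHit(
            motif=self.name, start=int(start), strand="+-"[strand_order],
            score=float(sb * self.step), motif_pvalue=dist_obj.pvalue_of_bin(sb),
            distance_to_anchor=int(dist), length=L, allele=allele)

    def scan_batch(self, codes: np.ndarray, anchor: int = 50, max_dist: int = 10
                   ) -> "BatchHits":
        """Vectorized best-hit scan over an (n, window) matrix of base codes.

        Equivalent to calling :meth:`best_hit` on every row (same tie-break);
        used on large window sets where the per-row path would dominate the
        runtime.
        """
        codes = np.asarray(codes, dtype=np.int8)
        n, width = codes.shape
        cands = self._candidate_starts(width, anchor, max_dist)
        if not cands:
            raise ValueError("window too short for any eligible hit")
        L = self.length
        jj = np.arange(L)[:, None]
        best_score = np.full(n, np.iinfo(np.int64).min, dtype=np.int64)
        best_start = np.zeros(n, dtype=np.int32)
        best_dist = np.zeros(n, dtype=np.int32)
        best_strand = np.zeros(n, dtype=np.int8)
        for start, dist in cands:
            win = codes[:, start:start + L].T  # (L, n)
            for strand_order, table in ((0, self._padded), (1, self._rc_padded)):
                sc = table[jj, win].sum(axis=0)
                upd = sc > best_score  # strict: preference order keeps earlier ties
                if upd.any():
                    best_score[upd] = sc[upd]
                    best_start[upd] = start
                    best_dist[upd] = dist
                    best_strand[upd] = strand_order
        dist_obj = self.score_distribution()
        pos = np.searchsorted(dist_obj.bins, best_score, side="left")
        pvalues = dist_obj._sf[pos] / dist_obj.total
        return BatchHits(motif=self.name, length=L, score=best_score * self.step,
                         pvalue=pvalues, start=best_start, dist=best_dist,
                         strand=best_strand)

    def count_hits(self, sequence: str, score_threshold: float) -> tuple[int, int]:
        """Count hits >= threshold over every start position on both strands.

        Returns (total hits, number of start positions per strand); the
        empirical per-position per-strand prediction rate is
        ``hits / (2 * positions)``. Used to verify threshold calibration on
        random sequence.
        """
        from numpy.lib.stride_tricks import sliding_window_view

        codes = encode(sequence)
        if len(codes) < self.length:
            return 0, 0
        win = sliding_window_view(codes, self.length)
        thr_bin = int(np.rint(score_threshold / self.step))
        jj = np.arange(self.length)[None, :]
        hits = 0
        for table in (self._padded, self._rc_padded):
            scores = table[jj, win].sum(axis=1)
            hits += int((scores >= thr_bin).sum())
        return hits, win.shape[0]

    def __repr__(self) -> str:
        return f"PositionWeightMatrix({self.name!r}, L={self.length})"


@dataclass
class BatchHits:
    """Structure-of-arrays result of :meth:`PositionWeightMatrix.scan_batch`."""

    motif: str
    length: int
    score: np.ndarray
    pvalue: np.ndarray
    start: np.ndarray
    dist: np.ndarray
    strand: np.ndarray  # 0 = '+', 1 = '-'


# -- file I/O ---------------------------------------------------------------


def load_matrix(path, format: str = "counts", *, step: float = 0.001
                ) -> PositionWeightMatrix:
    """Read a HOCOMOCO-style plain-text matrix.

    Layout: an optional ``>NAME`` header followed by L rows of 4 whitespace-
    separated numbers in A,C,G,T column order. ``format`` selects whether the
    numbers are nucleotide counts (transformed to log-odds weights) or
    ready-made additive weights.
    """
    if format not in ("counts", "weights"):
        raise ValueError(f"format must be 'counts' or 'weights', got {format!r}")
    path = Path(path)
    name = path.stem
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                if rows:
                    raise MatrixParseError(f"{path}:{lineno}: header after data rows")
                header = line[1:].strip().split()
                if header:
                    name = header[0]
                continue
            fields = line.split()
            if len(fields) != 4:
                raise MatrixParseError(
                    f"{path}:{lineno}: expected 4 columns, got {len(fields)}")
            try:
                rows.append([float(x) for x in fields])
            except ValueError as exc:
                raise MatrixParseError(f"{path}:{lineno}: {exc}") from None
    if not rows:
        raise MatrixParseError(f"{path}: empty matrix")
    block = np.asarray(rows, dtype=float)
    if format == "counts":
        if np.any(block < 0):
            bad = int(np.nonzero(np.any(block < 0, axis=1))[0][0]) + 1
            raise MatrixParseError(f"{path}: negative count in matrix row {bad}")
        return PositionWeightMatrix.from_counts(name, block, step=step)
    return PositionWeightMatrix(name, block, step=step)


def save_matrix(pwm: PositionWeightMatrix, path, format: str = "weights") -> None:
    """Write a matrix back in the text layout accepted by :func:`load_matrix`."""
    if format == "counts":
        if pwm.source_counts is None:
            raise ValueError(f"{pwm.name}: no source counts to write")
        block = pwm.source_counts
    elif format == "weights":
        block = pwm.weights
    else:
        raise ValueError(f"format must be 'counts' or 'weights', got {format!r}")
    with open(path, "w") as fh:
        fh.write(f">{pwm.name}\n")
        for row in block:
            fh.write("\t".join(f"{x:.10g}" for x in row) + "\n")


def load_matrix_dir(directory, format: str = "counts", *, step: float = 0.001,
                    pattern: str = "*.p*m") -> list[PositionWeightMatrix]:
    """Load every matrix file in a directory (sorted by name)."""
    paths = sorted(Path(directory).glob(pattern))
    if not paths:
        paths = sorted(p for p in Path(directory).iterdir() if p.is_file())
    return [load_matrix(p, format=format, step=step) for p in paths]
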