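"""Self-contained synthetic study with planted, recoverable selection.

The generator builds a toy genome (i.i.d. background at a configured GC
fraction, organized into promoter / coding / intron / spacer cassettes with
a DNase-accessible subset), plants motif instances sampled from each
matrix's count distribution, and draws somatic substitutions whose loci and
alternate alleles follow a context-dependent mutation signature over the
regulatory regions.

Selection is implemented as calibrated rejection thinning. For a depletion
factor m < 1 on motif X, candidate mutations that would cause an affinity
event for X are retained with probability r = m(1-lam)/(1-m*lam), where lam
is the event rate among eligible candidate windows (estimated from the
candidate stream itself); for an enrichment factor m > 1 the eligible
*non*-events are thinned by r = (1-m*lam)/(m(1-lam)) instead. The
calibration compensates for thinned windows also leaving the eligible
denominator, so against an ideal (unselected, context-matched) control the
ground-truth selection magnitude f_obs / f_exp equals m exactly — naive
event thinning at rate m would instead plant m/(1-(1-m)*lam). Every
emitted mutation carries ground-truth labels (its affinity call for each
configured motif).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import affinity
from .pwm import ALPHABET, PositionWeightMatrix, encode
from .windows import (CENTER, HALF_WINDOW, ContextClass, MutationRecord,
                      MutationWindow, RegionSet)

N_CONTEXT_CLASSES = 192
_ALT_RANKS = {ref: [b for b in range(4) if b != ref] for ref in range(4)}


def class_index(five: int, ref: int, alt: int, three: int) -> int:
    """Dense 0..191 index of a (5', ref, alt, 3') context class (codes 0..3)."""
    rank = _ALT_RANKS[ref].index(alt)
    return ((five * 4 + ref) * 3 + rank) * 4 + three


def context_from_index(idx: int) -> ContextClass:
    three = idx % 4
    rest = idx // 4
    rank = rest % 3
    rest //= 3
    ref = rest % 4
    five = rest // 4
    alt = _ALT_RANKS[ref][rank]
    return ContextClass(ALPHABET[five], ALPHABET[ref], ALPHABET[alt], ALPHABET[three])


class SignatureModel:
    """Relative mutation probability per 4-symbol context class (192 entries)."""

    def __init__(self, probs):
        p = np.asarray(probs, dtype=float)
        if p.shape != (N_CONTEXT_CLASSES,):
            raise ValueError(f"signature must have {N_CONTEXT_CLASSES} entries")
        if np.any(p < 0) or p.sum() <= 0:
            raise ValueError("signature probabilities must be nonnegative, not all zero")
        self.probs = p / p.sum()

    def prob(self, ctx: ContextClass) -> float:
        return float(self.probs[class_index(*(ALPHABET.index(c) for c in ctx))])

    @classmethod
    def uniform(cls) -> "SignatureModel":
        return cls(np.ones(N_CONTEXT_CLASSES))

    @classmethod
    def cancer_like(cls) -> "SignatureModel":
        """Strand-symmetric signature with elevated C>T (CpG-boosted) and C>A.

        Emulates the dominant substitution classes of common solid-tumor
        signatures without reproducing any specific catalog.
        """
        w = np.ones(N_CONTEXT_CLASSES)
        A, C, G, T = range(4)
        for five in range(4):
            for three in range(4):
                # C>T and its reverse-strand twin G>A
                w[class_index(five, C, T, three)] *= 6.0 * (3.0 if three == G else 1.0)
                w[class_index(five, G, A, three)] *= 6.0 * (3.0 if five == C else 1.0)
                # C>A / G>T (tobacco-like)
                w[class_index(five, C, A, three)] *= 2.0
                w[class_index(five, G, T, three)] *= 2.0
        return cls(w)


@dataclass(frozen=True)
class PlantedMotif:
    """A motif planted in the synthetic genome with its selection factors."""

    pwm: PositionWeightMatrix
    density_per_kb: float = 0.0     # planted instances per kb of promoter+intron
    m_loss: float = 1.0             # retention factor for affinity-loss events
    m_gain: float = 1.0             # retention (>1: enrichment) for gain events

    def __post_init__(self):
        if self.m_loss <= 0 or self.m_gain <= 0:
            raise ValueError("retention factors must be positive")


@dataclass
class SyntheticStudyConfig:
    genome_length: int = 20_000_000
    gc: float = 0.41
    promoter_length: int = 2_000
    coding_length: int = 1_000
    intron_length: int = 6_000
    spacer_length: int = 1_000
    dnase_fraction: float = 0.35
    motifs: Sequence[PlantedMotif] = field(default_factory=list)
    n_mutations: int = 20_000
    n_samples: int = 20
    cancer_type: str = "synthetic"
    signature: Optional[SignatureModel] = None
    seed: int = 1

    @property
    def cassette_length(self) -> int:
        return (self.promoter_length + self.coding_length
                + self.intron_length + self.spacer_length)


@dataclass
class SyntheticGenome:
    chrom: str
    sequence: str
    regions: dict            # label -> RegionSet (promoter, intron, coding, dnase)
    truth: pd.DataFrame      # planted motif loci: motif, start, strand, word
    config: SyntheticStudyConfig

    @property
    def fasta_like(self) -> dict:
        """Mapping usable wherever an indexed FASTA is accepted."""
        return {self.chrom: self.sequence}

    def write(self, outdir) -> dict:
        """Write FASTA + BED region files + truth table; returns the paths."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {"fasta": outdir / "genome.fa"}
        with open(paths["fasta"], "w") as fh:
            fh.write(f">{self.chrom}\n")
            for i in range(0, len(self.sequence), 80):
                fh.write(self.sequence[i:i + 80] + "\n")
        for label, rs in self.regions.items():
            paths[label] = outdir / f"{label}.bed"
            rs.to_bed(paths[label])
        paths["truth"] = outdir / "planted_motifs.tsv"
        self.truth.to_csv(paths["truth"], sep="\t", index=False)
        return paths


# -- built-in demo motifs ------------------------------------------------------


def _counts_from_consensus(columns: Sequence[tuple[str, int]], total: int = 100) -> np.ndarray:
    """Count matrix from (consensus base, consensus count) per position;
    the remaining mass is spread evenly over the other three bases."""
    rows = []
    for base, hits in columns:
        row = [(total - hits) / 3.0] * 4
        row[ALPHABET.index(base)] = hits
        rows.append(row)
    return np.asarray(rows)


def demo_motifs() -> list[PositionWeightMatrix]:
    """Three synthetic motifs used by the demo study.

    TF_ALPHA: a 10-bp motif with mixed-information columns (neutral in the
    demo). TF_BETA: a 12-bp motif with four near-invariant core positions
    among degenerate ones — a small core keeps the loss rate among eligible
    windows low. TF_GAMMA: a strong 9-bp motif (gain-enriched in the demo).
    """
    alpha = PositionWeightMatrix.from_counts("TF_ALPHA", _counts_from_consensus(
        [("T", 85), ("G", 94), ("A", 91), ("C", 70), ("T", 88),
         ("G", 55), ("A", 94), ("C", 82), ("T", 64), ("G", 90)]), quality="A")
    beta = PositionWeightMatrix.from_counts("TF_BETA", _counts_from_consensus(
        [("A", 55), ("C", 60), ("G", 97), ("T", 97), ("A", 50), ("C", 55),
         ("G", 97), ("A", 97), ("C", 52), ("T", 58), ("G", 55), ("A", 60)]),
        quality="A")
    gamma = PositionWeightMatrix.from_counts("TF_GAMMA", _counts_from_consensus(
        [("C", 92), ("A", 88), ("C", 93), ("G", 75), ("T", 92),
         ("G", 86), ("C", 68), ("A", 90), ("T", 85)]), quality="B")
    return [alpha, beta, gamma]


def random_count_motifs(n: int, rng: np.random.Generator, min_length: int = 8,
                        max_length: int = 14, concentration: float = 0.7,
                        prefix: str = "RND") -> list[PositionWeightMatrix]:
    """Random count matrices with Dirichlet columns (mixed information content)."""
    out = []
    for i in range(n):
        L = int(rng.integers(min_length, max_length + 1))
        counts = np.rint(rng.dirichlet([concentration] * 4, size=L) * 1000) + 1
        out.append(PositionWeightMatrix.from_counts(f"{prefix}{i:03d}", counts))
    return out


def null_config(seed: int = 1, n_motifs: int = 100) -> SyntheticStudyConfig:
    """A no-selection study over many motifs for null calibration.

    All retention factors are 1; motifs are planted sparsely so eligible
    window sets mix planted sites and chance hits, stressing the
    both-controls significance rule without any true signal.
    """
    rng = np.random.default_rng(seed + 977)  # motif shapes, not study randomness
    motifs = [PlantedMotif(pwm, density_per_kb=0.15)
              for pwm in random_count_motifs(n_motifs, rng, prefix="NULL")]
    return SyntheticStudyConfig(genome_length=8_000_000, motifs=motifs,
                                n_mutations=4_000, seed=seed)


def recovery_config(seed: int = 1, m_loss: float = 0.7,
                    n_mutations: int = 70_000) -> SyntheticStudyConfig:
    """A parameter-recovery study: one motif under loss depletion, one neutral.

    Motifs are not planted, so eligible windows arise purely from chance
    hits and the shuffle, genomic and candidate populations share one event
    rate; the recoverable magnitude then equals the retention factor against
    both controls. The mutation count is sized for >= 2,000 loss-eligible
    windows per motif at the default site stringency.
    """
    alpha, beta, _ = demo_motifs()
    return SyntheticStudyConfig(
        genome_length=40_000_000, dnase_fraction=0.0,
        motifs=[PlantedMotif(alpha), PlantedMotif(beta, m_loss=m_loss)],
        n_mutations=n_mutations, seed=seed)


def default_config(seed: int = 1) -> SyntheticStudyConfig:
    """The demo study: 20 Mb genome, three motifs (one neutral, one under
    negative loss selection m_loss = 0.7, one gain-enriched m_gain = 1.3),
    20,000 mutations (~1 per kb of regulatory DNA, comparable to real
    whole-genome catalogs, which keeps the genomic control pool rich after
    excluding loci overlapping mutation windows)."""
    alpha, beta, gamma = demo_motifs()
    return SyntheticStudyConfig(
        motifs=[PlantedMotif(alpha, density_per_kb=3.0),
                PlantedMotif(beta, density_per_kb=3.0, m_loss=0.7),
                PlantedMotif(gamma, density_per_kb=3.0, m_gain=1.3)],
        seed=seed)


# -- genome generation ---------------------------------------------------------


def generate_genome(config: SyntheticStudyConfig,
                    rng: Optional[np.random.Generator] = None) -> SyntheticGenome:
    """i.i.d. background genome with cassette regions and planted motif loci.

    Motif instances are sampled from each matrix's count distribution (not
    just the consensus), placed uniformly at random on either strand within
    promoter + intron regions, never overlapping one another.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    G = config.genome_length
    gc = config.gc
    base_p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    codes = rng.choice(4, size=G, p=base_p).astype(np.int8)

    promoters, coding, introns, dnase = [], [], [], []
    pos = 0
    while pos + config.cassette_length <= G:
        p0 = pos
        promoters.append(("chr1", p0, p0 + config.promoter_length))
        p0 += config.promoter_length
        coding.append(("chr1", p0, p0 + config.coding_length))
        p0 += config.coding_length
        introns.append(("chr1", p0, p0 + config.intron_length))
        pos += config.cassette_length
    regions = {
        "promoter": RegionSet("promoter", promoters),
        "coding": RegionSet("coding", coding),
        "intron": RegionSet("intron", introns),
    }
    # DNase-accessible subset: 200-bp tiles of promoter+intron kept at random
    tile = 200
    for rs in (regions["promoter"], regions["intron"]):
        for chrom, start, end in rs.iter_intervals():
            for t0 in range(start, end, tile):
                if rng.random() < config.dnase_fraction:
                    dnase.append((chrom, t0, min(t0 + tile, end)))
    regions["dnase"] = RegionSet("dnase", dnase)

    plantable = np.zeros(G, dtype=bool)
    for rs in (regions["promoter"], regions["intron"]):
        for _, start, end in rs.iter_intervals():
            plantable[start:end] = True
    plant_bp = int(plantable.sum())

    occupied = np.zeros(G, dtype=bool)
    truth_rows = []
    for planted in config.motifs:
        pwm = planted.pwm
        L = pwm.length
        n_inst = int(round(planted.density_per_kb * plant_bp / 1000.0))
        if n_inst == 0:
            continue
        freqs = _column_frequencies(pwm)
        # pre-draw words and strands in bulk; placement retries draw fresh starts
        words = np.empty((n_inst, L), dtype=np.int8)
        for j in range(L):
            words[:, j] = rng.choice(4, size=n_inst, p=freqs[j])
        strands = rng.random(n_inst) < 0.5
        placed, attempts = 0, 0
        max_attempts = 60 * n_inst
        while placed < n_inst:
            attempts += 1
            if attempts > max_attempts:
                raise ValueError(
                    f"{pwm.name}: planting density {planted.density_per_kb}/kb too "
                    f"high to avoid overlaps ({placed}/{n_inst} placed)")
            start = int(rng.integers(0, G - L))
            if not plantable[start:start + L].all() or occupied[start:start + L].any():
                continue
            word_codes = words[placed]
            strand = "+" if strands[placed] else "-"
            if strand == "-":
                word_codes = (3 - word_codes)[::-1]
            codes[start:start + L] = word_codes
            occupied[start:start + L] = True
            word = "".join(ALPHABET[c] for c in word_codes)
            truth_rows.append((pwm.name, start, strand, word))
            placed += 1

    sequence = "".join(ALPHABET[c] for c in codes)
    truth = pd.DataFrame(truth_rows, columns=["motif", "start", "strand", "word"])
    return SyntheticGenome("chr1", sequence, regions, truth, config)


def _column_frequencies(pwm: PositionWeightMatrix, pseudocount: float = 1.0
                        ) -> np.ndarray:
    if pwm.source_counts is not None:
        c = pwm.source_counts + pseudocount / 4.0
    else:  # fall back to softmax of the weights
        c = np.exp(pwm.weights)
    return c / c.sum(axis=1, keepdims=True)


# -- mutation generation --------------------------------------------------------


class _CandidateModel:
    """Signature-weighted distribution over (locus, alt) candidates.

    The per-candidate weight depends only on the 4-symbol context class, so
    sampling factorizes: draw a class with probability proportional to
    signature[class] * availability[class], then a locus uniformly among the
    positions carrying the class's central trinucleotide. Memory stays
    linear in the number of eligible positions.
    """

    def __init__(self, genome: SyntheticGenome, signature: SignatureModel):
        G = len(genome.sequence)
        codes = encode(genome.sequence)
        eligible = np.zeros(G, dtype=bool)
        for label in ("promoter", "intron"):
            for _, start, end in genome.regions[label].iter_intervals():
                eligible[start:end] = True
        for _, start, end in genome.regions["coding"].iter_intervals():
            eligible[start:end] = False
        eligible[:HALF_WINDOW] = False
        eligible[G - HALF_WINDOW:] = False
        positions = np.nonzero(eligible)[0].astype(np.int32)
        tri_ok = (codes[positions - 1] <= 3) & (codes[positions] <= 3) \
            & (codes[positions + 1] <= 3)
        positions = positions[tri_ok]
        tri = (codes[positions - 1].astype(np.int32) * 16
               + codes[positions].astype(np.int32) * 4
               + codes[positions + 1].astype(np.int32))
        order = np.argsort(tri, kind="stable")
        self._positions = positions[order]
        tri_sorted = tri[order]
        self._tri_offsets = np.searchsorted(tri_sorted, np.arange(65))
        avail = np.diff(self._tri_offsets)  # candidates per trinucleotide

        class_tri = np.empty(N_CONTEXT_CLASSES, dtype=np.int32)
        class_alt = np.empty(N_CONTEXT_CLASSES, dtype=np.int8)
        for idx in range(N_CONTEXT_CLASSES):
            ctx = context_from_index(idx)
            five, ref, alt, three = (ALPHABET.index(c) for c in ctx)
            class_tri[idx] = five * 16 + ref * 4 + three
            class_alt[idx] = alt
        self._class_tri = class_tri
        self._class_alt = class_alt
        class_w = signature.probs * avail[class_tri]
        total = class_w.sum()
        if total <= 0:
            raise ValueError("signature puts no mass on any context available "
                             "in the regulatory regions")
        self._class_p = class_w / total

    def expected_context_distribution(self) -> dict[ContextClass, float]:
        """Signature renormalized by genome context availability."""
        return {context_from_index(i): float(self._class_p[i])
                for i in np.nonzero(self._class_p)[0]}

    def draw(self, size: int, rng: np.random.Generator):
        cls = rng.choice(N_CONTEXT_CLASSES, size=size, p=self._class_p)
        tri = self._class_tri[cls]
        lo, hi = self._tri_offsets[tri], self._tri_offsets[tri + 1]
        pos = self._positions[(lo + (rng.random(size) * (hi - lo)).astype(np.int64))]
        return pos.astype(np.int64), self._class_alt[cls]


def expected_context_distribution(genome: SyntheticGenome,
                                  signature: SignatureModel) -> dict:
    """Oracle-side helper: the context distribution candidates are drawn from."""
    return _CandidateModel(genome, signature).expected_context_distribution()


def _retention(call, event_call: str, eligible_flag: str, m: float,
               lam: float) -> float:
    """Per-window survival probability planting a ground-truth magnitude m.

    Thinning removes windows from both the event numerator and the eligible
    denominator; the rates below solve f_obs/f_exp = m exactly given the
    candidate event rate lam among eligible windows.
    """
    if m < 1.0:
        if call.call == event_call:
            return m * (1.0 - lam) / (1.0 - m * lam)
        return 1.0
    if m > 1.0 and getattr(call, eligible_flag) and call.call != event_call:
        if m * lam >= 1.0:  # enrichment beyond saturation: drop all non-events
            return 0.0
        return (1.0 - m * lam) / (m * (1.0 - lam))
    return 1.0


def generate_mutations(genome: SyntheticGenome, signature: SignatureModel,
                       n: int, motifs: Sequence[PlantedMotif],
                       rng: np.random.Generator, *, n_samples: int = 20,
                       cancer_type: str = "synthetic",
                       p_site: float = affinity.P_SITE_DEFAULT,
                       fold: float = affinity.FOLD_DEFAULT,
                       max_dist: int = affinity.MAX_DIST_DEFAULT,
                       ) -> tuple[list[MutationRecord], pd.DataFrame]:
    """Draw n signature-weighted mutations with per-motif selection thinning.

    Returns the retained mutation records (in emission order, with sample
    ids assigned round-robin) and a ground-truth label table with one row
    per (mutation, motif) giving the true affinity call of the retained
    mutation.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    model = _CandidateModel(genome, signature)
    seq = genome.sequence
    chrom = genome.chrom

    records: list[MutationRecord] = []
    label_rows: list[tuple] = []
    thinned = any(pm.m_loss != 1.0 or pm.m_gain != 1.0 for pm in motifs)
    # running candidate tallies per (motif, direction) for the lambda estimate
    cand_counts = {(pm.pwm.name, d): [0, 0] for pm in motifs for d in ("loss", "gain")}

    while len(records) < n:
        need = n - len(records)
        batch = max(256, int(need * (1.3 if thinned else 1.02)))
        pos0, alt_code = model.draw(batch, rng)
        windows, muts = [], []
        for p, a in zip(pos0.tolist(), alt_code.tolist()):
            germ = seq[p - HALF_WINDOW:p + HALF_WINDOW + 1]
            alt = ALPHABET[a]
            mut = MutationRecord(chrom, p + 1, germ[CENTER], alt, "pending",
                                 cancer_type)
            windows.append(MutationWindow(mut, germ,
                                          germ[:CENTER] + alt + germ[CENTER + 1:],
                                          ContextClass(germ[CENTER - 1], germ[CENTER],
                                                       alt, germ[CENTER + 1])))
            muts.append(mut)
        keep_p = np.ones(batch)
        calls_per_motif = {}
        for pm in motifs:
            calls = affinity.classify_batch(windows, pm.pwm, p_site, fold, max_dist)
            calls_per_motif[pm.pwm.name] = calls
            for direction, m in (("loss", pm.m_loss), ("gain", pm.m_gain)):
                tallies = cand_counts[(pm.pwm.name, direction)]
                event_call = affinity.LOSS if direction == "loss" else affinity.GAIN
                flag = f"eligible_for_{direction}"
                for c in calls:
                    if getattr(c, flag):
                        tallies[0] += 1
                        tallies[1] += c.call == event_call
                if m == 1.0:
                    continue
                lam = tallies[1] / tallies[0] if tallies[0] else 0.0
                for i, c in enumerate(calls):
                    keep_p[i] *= _retention(c, event_call, flag, m, lam)
        accepted = rng.random(batch) < keep_p
        for i in np.nonzero(accepted)[0]:
            if len(records) >= n:
                break
            mut_id = len(records)
            mut = replace(muts[int(i)], sample=f"S{mut_id % n_samples:03d}")
            records.append(mut)
            for name, calls in calls_per_motif.items():
                label_rows.append((mut_id, mut.chrom, mut.pos, mut.alt, name,
                                   calls[int(i)].call))
    labels = pd.DataFrame(label_rows, columns=["mutation_id", "chrom", "pos",
                                               "alt", "motif", "call"])
    return records, labels


@dataclass
class SyntheticStudy:
    genome: SyntheticGenome
    mutations: list[MutationRecord]
    labels: pd.DataFrame
    signature: SignatureModel
    config: SyntheticStudyConfig

    def write(self, outdir) -> dict:
        from .windows import write_mutations_tsv
        paths = self.genome.write(outdir)
        paths["mutations"] = Path(outdir) / "mutations.tsv"
        write_mutations_tsv(self.mutations, paths["mutations"])
        paths["labels"] = Path(outdir) / "truth_labels.tsv"
        self.labels.to_csv(paths["labels"], sep="\t", index=False)
        return paths


def simulate_study(config: Optional[SyntheticStudyConfig] = None,
                   seed: Optional[int] = None) -> SyntheticStudy:
    """Generate the full study (genome + mutations + ground-truth labels)."""
    if config is None:
        config = default_config(seed if seed is not None else 1)
    elif seed is not None:
        config = replace(config, seed=seed)
    rng = np.random.default_rng(config.seed)
    genome = generate_genome(config, rng)
    signature = config.signature or SignatureModel.cancer_like()
    mutations, labels = generate_mutations(
        genome, signature, config.n_mutations, config.motifs, rng,
        n_samples=config.n_samples, cancer_type=config.cancer_type)
    return SyntheticStudy(genome, mutations, labels, signature, config)
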