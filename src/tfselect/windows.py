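"""Somatic mutation ingestion and mutation-centered window extraction.

Mutations are single-nucleotide substitutions. Each one kept after
regulatory-region filtering is expanded into a [-50, +50] bp window pair:
the germline sequence read from the reference and the mutant sequence with
the alternate base substituted at the center. The 4-symbol mutation context
(5' neighbor, germline base, mutant base, 3' neighbor) travels with the
window; it is the unit of signature matching downstream.

Coordinates are 0-based half-open internally; mutation tables are 1-based
(VCF convention) and BED region files 0-based, as those formats define.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, NamedTuple, Optional

import pandas as pd
from intervaltree import IntervalTree

logger = logging.getLogger(__name__)

VALID_BASES = frozenset("ACGT")

HALF_WINDOW = 50
WINDOW = 2 * HALF_WINDOW + 1
CENTER = HALF_WINDOW

MUTATION_COLUMNS = ["chrom", "pos", "ref", "alt", "sample", "cancer_type"]


class ContextClass(NamedTuple):
    """Mutation context: 5' neighbor, germline base, mutant base, 3' neighbor.

    192 classes exist (4 x 4 x 3 x 4 after folding ref != alt). Contexts are
    read from the genome strand as-is; there is no pyrimidine-strand
    collapsing anywhere in the pipeline, because motif scanning is
    strand-aware.
    """

    five_prime: str
    ref: str
    alt: str
    three_prime: str

    def __str__(self) -> str:
        return f"{self.five_prime}[{self.ref}>{self.alt}]{self.three_prime}"


@dataclass(frozen=True)
class MutationRecord:
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    sample: str
    cancer_type: str

    def __post_init__(self):
        if self.ref not in VALID_BASES or self.alt not in VALID_BASES:
            raise ValueError(f"non-ACGT allele in {self}")
        if self.ref == self.alt:
            raise ValueError(f"ref == alt in {self}")


@dataclass(frozen=True)
class MutationWindow:
    """A 101-nt mutation-centered window pair (germline / mutant alleles)."""

    mutation: MutationRecord
    germline: str
    mutant: str
    context: ContextClass

    def __post_init__(self):
        if len(self.germline) != WINDOW or len(self.mutant) != WINDOW:
            raise ValueError("window sequences must be exactly 101 nt")
        if self.germline[CENTER] != self.mutation.ref:
            raise ValueError("germline center does not match ref allele")
        if self.mutant[CENTER] != self.mutation.alt:
            raise ValueError("mutant center does not match alt allele")


class RegionSet:
    """Merged, non-overlapping genomic intervals (one label per set)."""

    def __init__(self, label: str, intervals: Iterable[tuple[str, int, int]] = ()):
        self.label = label
        self.trees: dict[str, IntervalTree] = {}
        for chrom, start, end in intervals:
            self.trees.setdefault(chrom, IntervalTree()).addi(start, end)
        for tree in self.trees.values():
            tree.merge_overlaps(strict=False)

    @classmethod
    def from_bed(cls, path, label: Optional[str] = None) -> "RegionSet":
        path = Path(path)
        intervals = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.strip()
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                fields = line.split("\t")
                if len(fields) < 3:
                    raise ValueError(f"{path}:{lineno}: BED line with <3 columns")
                intervals.append((fields[0], int(fields[1]), int(fields[2])))
        return cls(label or path.stem, intervals)

    def contains(self, chrom: str, pos0: int) -> bool:
        """Membership of a 0-based position."""
        tree = self.trees.get(chrom)
        return bool(tree is not None and tree.overlaps_point(pos0))

    def iter_intervals(self):
        for chrom in sorted(self.trees):
            for iv in sorted(self.trees[chrom]):
                yield chrom, iv.begin, iv.end

    def total_length(self) -> int:
        return sum(end - start for _, start, end in self.iter_intervals())

    def to_bed(self, path) -> None:
        with open(path, "w") as fh:
            for chrom, start, end in self.iter_intervals():
                fh.write(f"{chrom}\t{start}\t{end}\t{self.label}\n")


# -- ingestion ---------------------------------------------------------------


def load_mutations(path, format: str = "tsv") -> list[MutationRecord]:
    """Read substitution calls from a TSV table or a minimal VCF.

    TSV columns: chrom, pos (1-based), ref, alt, sample, cancer_type (header
    required). VCF: one ALT per record after splitting multi-allelic sites;
    sample and cancer type are taken from the SAMPLE / CANCER INFO fields
    when present. Non-SNV records are dropped with a logged count.
    """
    if format == "tsv":
        return _load_tsv(path)
    if format == "vcf":
        return _load_vcf(path)
    raise ValueError(f"format must be 'tsv' or 'vcf', got {format!r}")


def _load_tsv(path) -> list[MutationRecord]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "sample": str})
    if df.empty and df.columns.size == 0:
        return []
    missing = [c for c in MUTATION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    records, skipped = [], 0
    for row in df.itertuples(index=False):
        ref, alt = str(row.ref).upper(), str(row.alt).upper()
        if len(ref) != 1 or len(alt) != 1 or ref not in VALID_BASES \
                or alt not in VALID_BASES or ref == alt:
            skipped += 1
            continue
        records.append(MutationRecord(str(row.chrom), int(row.pos), ref, alt,
                                      str(row.sample), str(row.cancer_type)))
    if skipped:
        logger.info("load_mutations: dropped %d non-SNV records", skipped)
    return records


def _load_vcf(path) -> list[MutationRecord]:
    import pysam

    records, skipped = [], 0
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            info = dict(rec.info)
            sample = str(info.get("SAMPLE", "sample0"))
            cancer = str(info.get("CANCER", "unknown"))
            ref = (rec.ref or "").upper()
            for alt in rec.alts or ():
                alt = alt.upper()
                if len(ref) != 1 or len(alt) != 1 or ref not in VALID_BASES \
                        or alt not in VALID_BASES or ref == alt:
                    skipped += 1
                    continue
                records.append(MutationRecord(rec.chrom, rec.pos, ref, alt,
                                              sample, cancer))
    if skipped:
        logger.info("load_mutations: dropped %d non-SNV VCF alleles", skipped)
    return records


def write_mutations_tsv(records: Iterable[MutationRecord], path) -> None:
    df = pd.DataFrame([r.__dict__ for r in records], columns=MUTATION_COLUMNS)
    df.to_csv(path, sep="\t", index=False)


# -- filtering and window extraction ------------------------------------------


def select_regulatory(mutations: Iterable[MutationRecord],
                      promoters: RegionSet, introns: RegionSet,
                      coding: Optional[RegionSet] = None,
                      dnase: Optional[RegionSet] = None) -> list[MutationRecord]:
    """Keep mutations in (promoter u intron) \\ coding, optionally n DNase."""
    kept = []
    for mut in mutations:
        pos0 = mut.pos - 1
        if not (promoters.contains(mut.chrom, pos0) or introns.contains(mut.chrom, pos0)):
            continue
        if coding is not None and coding.contains(mut.chrom, pos0):
            continue
        if dnase is not None and not dnase.contains(mut.chrom, pos0):
            continue
        kept.append(mut)
    return kept


def extract_windows(mutations: Iterable[MutationRecord], genome,
                    half: int = HALF_WINDOW) -> list[MutationWindow]:
    """Extract mutation-centered [-half, +half] windows from an indexed FASTA.

    ``genome`` is a pyfaidx.Fasta (or a path to a FASTA file). Mutations too
    close to a contig end or whose ref allele disagrees with the genome are
    skipped with a logged count.
    """
    genome = _as_fasta(genome)
    windows, near_edge, mismatched = [], 0, 0
    for mut in mutations:
        pos0 = mut.pos - 1
        contig = genome[mut.chrom]
        if pos0 - half < 0 or pos0 + half >= len(contig):
            near_edge += 1
            continue
        germ = str(contig[pos0 - half:pos0 + half + 1]).upper()
        if germ[half] != mut.ref:
            mismatched += 1
            continue
        mutant = germ[:half] + mut.alt + germ[half + 1:]
        ctx = ContextClass(germ[half - 1], mut.ref, mut.alt, germ[half + 1])
        windows.append(MutationWindow(mut, germ, mutant, ctx))
    if near_edge:
        logger.info("extract_windows: skipped %d mutations within %d bp of a contig end",
                    near_edge, half)
    if mismatched:
        logger.warning("extract_windows: excluded %d mutations whose ref allele "
                       "mismatched the genome", mismatched)
    return windows


def _as_fasta(genome):
    if isinstance(genome, (str, Path)):
        import pyfaidx
        return pyfaidx.Fasta(str(genome))
    return genome


def dedup_windows(windows: Iterable[MutationWindow]) -> list[MutationWindow]:
    """Drop repeat-induced duplicate windows within each sample.

    Within one sample, windows at different coordinates with identical
    (germline, mutant) sequence pairs collapse to the first by coordinate
    order. Identical windows in *different* samples are all retained:
    recurrent mutations across samples are independent observations.
    """
    ws = list(windows)
    by_coord = sorted(range(len(ws)),
                      key=lambda i: (ws[i].mutation.chrom, ws[i].mutation.pos,
                                     ws[i].mutation.alt))
    seen: set[tuple[str, str, str]] = set()
    winners: set[int] = set()
    for i in by_coord:
        key = (ws[i].mutation.sample, ws[i].germline, ws[i].mutant)
        if key in seen:
            continue
        seen.add(key)
        winners.add(i)
    return [w for i, w in enumerate(ws) if i in winners]
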