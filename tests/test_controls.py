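"""Shuffle/genomic control construction and context equalization."""

import numpy as np
import pytest
from scipy import stats as sps

from tfselect.controls import (GenomicSampler, equalize_contexts,
                               make_shuffle_controls, sample_genomic_controls)
from tfselect.windows import CENTER, ContextClass, RegionSet

from conftest import make_window, random_window


# -- shuffle control --------------------------------------------------------------


def test_shuffle_preserves_context_and_multiset(rng):
    w = random_window(rng)
    for ctrl in make_shuffle_controls(w, 20, rng):
        assert ctrl.germline[CENTER - 1:CENTER + 2] == w.germline[CENTER - 1:CENTER + 2]
        assert ctrl.mutant[CENTER] == w.mutation.alt
        assert ctrl.context == w.context
        flanks = lambda s: sorted(s[:CENTER - 1] + s[CENTER + 2:])
        assert flanks(ctrl.germline) == flanks(w.germline)
        assert ctrl.origin == "shuffle"


def test_shuffle_of_constant_flanks_is_identity(rng):
    germ = "A" * 49 + "GCT" + "A" * 49
    w = make_window(germ, "A")
    for ctrl in make_shuffle_controls(w, 5, rng):
        assert ctrl.germline == w.germline
        assert ctrl.mutant == w.mutant


def test_shuffle_position_uniformity(rng):
    """A single G in the flanks lands uniformly over the 98 flank slots."""
    germ = "G" + "A" * 48 + "ACT" + "A" * 49
    w = make_window(germ, "G")
    flank_idx = [i for i in range(101) if i not in (49, 50, 51)]
    counts = np.zeros(98)
    for ctrl in make_shuffle_controls(w, 10_000, rng):
        where = [k for k, i in enumerate(flank_idx) if ctrl.germline[i] == "G"]
        counts[where[0]] += 1
    chi2 = ((counts - counts.mean()) ** 2 / counts.mean()).sum()
    assert sps.chi2.sf(chi2, 97) > 0.01


# -- genomic control --------------------------------------------------------------


@pytest.fixture
def tiny_region_genome():
    # regions covering [60, 240) of a 300-bp contig with exactly three TCA
    seq = list("ACGT" * 75)
    for p in (100, 150, 200):
        seq[p - 1:p + 2] = "TCA"
    return {"chr1": "".join(seq)}, [RegionSet("promoter", [("chr1", 60, 240)])]


def test_genomic_exhaustion_returns_fewer(tiny_region_genome, rng):
    genome, regions = tiny_region_genome
    ctx = ContextClass("T", "C", "G", "A")
    controls = sample_genomic_controls(ctx, 5, regions, genome, rng=rng)
    assert len(controls) == 3  # only three TCA loci exist


def test_genomic_control_invariants(tiny_region_genome, rng):
    genome, regions = tiny_region_genome
    ctx = ContextClass("T", "C", "G", "A")
    for ctrl in sample_genomic_controls(ctx, 3, regions, genome, rng=rng):
        assert ctrl.germline[CENTER - 1:CENTER + 2] == "TCA"
        assert ctrl.mutant[CENTER] == "G"
        assert ctrl.origin == "genomic"
        chrom, pos0 = ctrl.source
        assert genome[chrom][pos0 - 1:pos0 + 2] == "TCA"


def test_genomic_exclusion_blocks_everything(tiny_region_genome, rng):
    genome, regions = tiny_region_genome
    ctx = ContextClass("T", "C", "G", "A")
    exclusion = [("chr1", 0, 300)]
    controls = sample_genomic_controls(ctx, 3, regions, genome,
                                       exclusion=exclusion, rng=rng)
    assert controls == []


def test_genomic_never_overlaps_exclusion_windows(rng):
    seq = "".join(rng.choice(list("ACGT"), size=5000))
    genome = {"chr1": seq}
    regions = [RegionSet("promoter", [("chr1", 0, 5000)])]
    exclusion = [("chr1", 1000, 1101), ("chr1", 3000, 3101)]
    sampler = GenomicSampler(genome, regions, exclusion=exclusion)
    ref = seq[2500]
    ctx = ContextClass(seq[2499], ref, [b for b in "ACGT" if b != ref][0], seq[2501])
    for ctrl in sampler.sample(ctx, 200, rng):
        _, pos0 = ctrl.source
        for start, end in ((1000, 1101), (3000, 3101)):
            assert pos0 + 50 < start or pos0 - 50 >= end


# -- equalization ------------------------------------------------------------------


def _windows_with_contexts(rng, context_counts):
    out = []
    for (f, r, a, t), n in context_counts.items():
        for _ in range(n):
            germ = "".join(rng.choice(list("ACGT"), size=101))
            germ = germ[:49] + f + r + t + germ[52:]
            out.append(make_window(germ, a))
    return out


def test_equalize_ample_proportional_pool(rng):
    test = _windows_with_contexts(rng, {("A", "C", "T", "G"): 30,
                                        ("T", "C", "A", "A"): 10})
    pool = _windows_with_contexts(rng, {("A", "C", "T", "G"): 600,
                                        ("T", "C", "A", "A"): 200})
    sampled, report = equalize_contexts(test, pool, rng, multiplier=5.0)
    assert report.match_fraction == 1.0
    assert report.total_deficit == 0
    assert len(sampled) == 200
    freq = sum(w.context == ("A", "C", "T", "G") for w in sampled) / 200
    assert freq == pytest.approx(0.75)  # exactly the test frequency


def test_equalize_missing_class_records_deficit(rng):
    test = _windows_with_contexts(rng, {("A", "C", "T", "G"): 10,
                                        ("G", "T", "A", "C"): 10})
    pool = _windows_with_contexts(rng, {("A", "C", "T", "G"): 300})
    sampled, report = equalize_contexts(test, pool, rng, multiplier=4.0)
    missing = report.per_class[("G", "T", "A", "C")]
    assert missing["deficit"] == missing["target"] == 40
    assert report.match_fraction == pytest.approx(0.5)
    assert len(sampled) == 40


def test_equalize_skewed_pool_matches_test_frequencies(rng):
    counts = {("A", "C", "T", "G"): 50, ("T", "C", "A", "A"): 30,
              ("C", "G", "A", "T"): 20}
    test = _windows_with_contexts(rng, counts)
    pool = _windows_with_contexts(rng, {("A", "C", "T", "G"): 900,
                                        ("T", "C", "A", "A"): 2500,
                                        ("C", "G", "A", "T"): 700})
    sampled, report = equalize_contexts(test, pool, rng, n_target=500)
    assert report.total_deficit == 0
    got = {ctx: sum(w.context == ctx for w in sampled) / 500 for ctx in counts}
    for ctx, n in counts.items():
        # class frequencies equal the test ones up to integer rounding
        assert abs(got[ctx] - n / 100) <= 1 / 500 + 1e-12


def test_equalize_empty_test_set(rng):
    sampled, report = equalize_contexts([], _windows_with_contexts(
        rng, {("A", "C", "T", "G"): 5}), rng)
    assert sampled == [] and report.match_fraction == 1.0
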