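"""PWM scoring, exact P-value enumeration, calibration and anchored scanning."""

import itertools

import numpy as np
import pytest

from tfselect.pwm import (MatrixParseError, PositionWeightMatrix, encode,
                          load_matrix, reverse_complement, save_matrix)


def enumerate_scores(pwm):
    """Brute-force scores of all 4^L words (independent of the DP path)."""
    words = ["".join(t) for t in itertools.product("ACGT", repeat=pwm.length)]
    return words, np.array([pwm.score_word(w) for w in words])


# -- loading and scoring --------------------------------------------------------


def test_load_counts_single_consensus(tmp_path):
    path = tmp_path / "cons.pcm"
    path.write_text(">CONS\n" + "100 0 0 0\n" * 4)
    pwm = load_matrix(path, format="counts")
    assert pwm.name == "CONS"
    assert pwm.length == 4
    _, scores = enumerate_scores(pwm)
    assert pwm.score_word("AAAA") == pytest.approx(scores.max())
    assert (scores == scores.max()).sum() == 1  # consensus uniquely maximal


def test_weights_roundtrip(tmp_path, random_pwm):
    path = tmp_path / "m.pwm"
    save_matrix(random_pwm, path, format="weights")
    again = load_matrix(path, format="weights")
    np.testing.assert_allclose(again.weights, random_pwm.weights, atol=1e-9)


def test_fully_degenerate_counts(tmp_path):
    pwm = PositionWeightMatrix.from_counts("DEG", [[1, 1, 1, 1]] * 3)
    # all 4^L words share one score and the P-value at that score is 1
    dist = pwm.score_distribution()
    assert len(dist.bins) == 1
    assert pwm.pvalue_from_score(pwm.score_word("ACG")) == 1.0


@pytest.mark.parametrize("content,message", [
    ("1 2 3\n", "expected 4 columns"),
    (">m\n", "empty matrix"),
    ("1 2 3 4\n5 6 seven 8\n", "could not convert"),
])
def test_parse_errors(tmp_path, content, message):
    path = tmp_path / "bad.pcm"
    path.write_text(content)
    with pytest.raises(MatrixParseError, match=message):
        load_matrix(path, format="weights" if "seven" in content else "counts")


def test_negative_counts_rejected(tmp_path):
    path = tmp_path / "neg.pcm"
    path.write_text("1 2 3 4\n-1 2 3 4\n")
    with pytest.raises(MatrixParseError, match="negative count"):
        load_matrix(path, format="counts")


def test_score_word_is_positionwise_sum(rng, random_pwm):
    for _ in range(20):
        word = "".join(rng.choice(list("ACGT"), size=6))
        manual = sum(random_pwm.weights[j, "ACGT".index(b)]
                     for j, b in enumerate(word))
        assert random_pwm.score_word(word) == pytest.approx(manual)


from hypothesis import given, settings
from hypothesis import strategies as st


@settings(derandomize=True, max_examples=40, deadline=None)
@given(st.text(alphabet="ACGT", min_size=6, max_size=6))
def test_score_word_additivity_property(word):
    pwm = PositionWeightMatrix("FIXED6",
                               np.arange(24, dtype=float).reshape(6, 4) / 7.0)
    manual = sum(pwm.weights[j, "ACGT".index(b)] for j, b in enumerate(word))
    assert pwm.score_word(word) == pytest.approx(manual, abs=1e-9)


def test_score_word_input_errors(random_pwm):
    with pytest.raises(ValueError, match="length"):
        random_pwm.score_word("ACGT")
    with pytest.raises(ValueError, match="non-ACGT"):
        random_pwm.score_word("ACGTNA")


# -- exact distribution ---------------------------------------------------------


def test_distribution_L1():
    pwm = PositionWeightMatrix("L1", [[2.0, 0.0, 0.0, 0.0]])
    dist = pwm.score_distribution()
    assert dict(zip((dist.bins * dist.step).tolist(), dist.counts.tolist())) \
        == {2.0: 1, 0.0: 3}


@pytest.mark.parametrize("L", [2, 4, 6, 8])
def test_distribution_matches_enumeration(rng, L):
    pwm = PositionWeightMatrix(f"R{L}", rng.normal(scale=2.0, size=(L, 4)))
    _, scores = enumerate_scores(pwm)
    dist = pwm.score_distribution()
    assert int(dist.counts.sum()) == 4 ** L  # exact mass conservation
    # every bin count agrees with the brute-force histogram on the lattice
    bins = np.rint(scores / pwm.step).astype(np.int64)
    vals, counts = np.unique(bins, return_counts=True)
    np.testing.assert_array_equal(dist.bins, vals)
    np.testing.assert_array_equal(dist.counts, counts)


def test_pvalue_monotone_and_matches_enumeration(rng):
    pwm = PositionWeightMatrix("R6", rng.normal(scale=1.2, size=(6, 4)))
    _, scores = enumerate_scores(pwm)
    probes = np.concatenate([rng.choice(scores, 40), rng.normal(scale=4, size=10)])
    last = 1.1
    for probe in np.sort(probes):
        p = pwm.pvalue_from_score(probe)
        frac_ge = (scores >= probe - pwm.step / 2).mean()
        frac_gt = (scores >= probe + pwm.step / 2).mean()
        assert frac_gt - 1e-12 <= p <= frac_ge + 1e-12  # within one lattice bin
        assert p <= last + 1e-12  # non-increasing in score
        last = p
    assert pwm.pvalue_from_score(scores.min() - 1) == 1.0
    assert pwm.pvalue_from_score(scores.max() + 1) == 0.0


def test_threshold_calibration_against_enumeration(rng):
    pwm = PositionWeightMatrix("R8", rng.normal(scale=1.5, size=(8, 4)))
    _, scores = enumerate_scores(pwm)
    total = scores.size
    for target in (1.0, 0.25, 0.01, 0.0005):
        thr = pwm.threshold_for_pvalue(target)
        attained = pwm.pvalue_from_score(thr)
        assert attained <= target  # conservative calibration
        assert attained == pytest.approx((scores >= thr - pwm.step / 2).mean())
        # minimality: the next attainable score below must exceed the target
        dist = pwm.score_distribution()
        lower = dist.bins[dist.bins < np.rint(thr / pwm.step)]
        if lower.size:
            assert pwm.pvalue_from_score(lower[-1] * pwm.step) > target
    assert pwm.threshold_for_pvalue(1.0) == pytest.approx(scores.min(), abs=pwm.step)


def test_threshold_below_resolution_warns(consensus_pwm):
    # 4^-4 = 1/256 ~ 0.0039 > 0.0005: the target is unreachable
    with pytest.warns(UserWarning, match="below the 4\\^-L resolution"):
        thr = consensus_pwm.threshold_for_pvalue(0.0005)
    assert thr == pytest.approx(consensus_pwm.max_score)


# -- anchored best-hit scanning --------------------------------------------------


def test_best_hit_distance_boundary(consensus_pwm):
    # consensus planted with its leftmost base exactly 10 bp right of the anchor
    seq = "C" * 50 + "G" + "C" * 9 + "AAAA" + "C" * 37
    hit = consensus_pwm.best_hit(seq, anchor=50, max_dist=10)
    assert hit.start == 60 and hit.distance_to_anchor == 10
    assert hit.score == pytest.approx(consensus_pwm.max_score)
    # at 11 bp the planted word is ineligible and a weaker hit wins
    seq11 = "C" * 50 + "G" + "C" * 10 + "AAAA" + "C" * 36
    hit11 = consensus_pwm.best_hit(seq11, anchor=50, max_dist=10)
    assert hit11.score < consensus_pwm.max_score


def test_best_hit_reverse_complement_strand(consensus_pwm):
    # reverse complement of AAAA planted across the anchor
    seq = "C" * 48 + "TTTT" + "C" * 49
    hit = consensus_pwm.best_hit(seq, anchor=50, max_dist=10)
    assert hit.strand == "-"
    assert hit.score == pytest.approx(consensus_pwm.max_score)
    assert hit.distance_to_anchor == 0


def test_best_hit_strand_symmetry(rng, random_pwm):
    """Scanning the reverse complement mirrors coordinates and flips strand."""
    for _ in range(25):
        seq = "".join(rng.choice(list("ACGT"), size=101))
        fwd = random_pwm.best_hit(seq, 50, 10)
        rev = random_pwm.best_hit(reverse_complement(seq), 50, 10)
        assert fwd.score == pytest.approx(rev.score)
        assert fwd.distance_to_anchor == rev.distance_to_anchor
        assert rev.start == len(seq) - fwd.start - random_pwm.length


def test_best_hit_roundtrip_pvalue(rng, random_pwm):
    seq = "".join(rng.choice(list("ACGT"), size=101))
    hit = random_pwm.best_hit(seq, 50, 10)
    assert hit.motif_pvalue == random_pwm.pvalue_from_score(hit.score)


def test_best_hit_anchor_out_of_bounds(random_pwm):
    with pytest.raises(ValueError, match="anchor"):
        random_pwm.best_hit("ACGT" * 10, 100, 10)


def test_scan_batch_matches_best_hit(rng, random_pwm):
    seqs = ["".join(rng.choice(list("ACGT"), size=101)) for _ in range(300)]
    codes = np.vstack([encode(s) for s in seqs])
    batch = random_pwm.scan_batch(codes, 50, 10)
    for i, s in enumerate(seqs):
        hit = random_pwm.best_hit(s, 50, 10)
        assert hit.score == pytest.approx(batch.score[i])
        assert hit.start == batch.start[i]
        assert hit.strand == "+-"[batch.strand[i]]
        assert hit.motif_pvalue == pytest.approx(batch.pvalue[i])


def test_count_hits_matches_naive(rng):
    pwm = PositionWeightMatrix("R4", rng.normal(size=(4, 4)))
    seq = "".join(rng.choice(list("ACGT"), size=500))
    thr = pwm.threshold_for_pvalue(0.05)
    hits, positions = pwm.count_hits(seq, thr)
    naive = 0
    for s in range(len(seq) - pwm.length + 1):
        word = seq[s:s + pwm.length]
        naive += pwm.score_word(word) >= thr - pwm.step / 2
        naive += pwm.score_word(reverse_complement(word)) >= thr - pwm.step / 2
    assert positions == len(seq) - pwm.length + 1
    assert hits == naive
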