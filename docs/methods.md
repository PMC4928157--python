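# Methods

## Motif model and exact P-values

A position weight matrix (PWM) of length L assigns word w the score
Σ_j W[j, w_j]. Count matrices are converted to weights by a log-odds
transform against a uniform background of 0.25 with a per-column
pseudocount k = ln(N) (N the column total; k = 1 when N ≤ 1):
w = ln((c + 0.25·k) / ((N + k)·0.25)). This is the convention of the
HOCOMOCO-style motif collections the pipeline is designed to consume; a
fully flat count column maps to identical weights, so a matrix of all-ones
counts scores every word equally.

Weights are snapped to a lattice of multiples of the score step (default
0.001) at construction. The exact score distribution is then a dynamic
programming convolution of the per-position lattice contributions: an
integer count for every attainable score, totalling exactly 4^L (int64
arithmetic; L ≤ 31 enforced). Because scoring and the distribution share
one lattice, `pvalue_from_score(score_word(w))` is the exact fraction of
words scoring ≥ w's score — there is no within-bin ambiguity; probe scores
strictly between lattice points are resolved upward (only words at or above
the next attainable score are counted). The 0.001 step perturbs each raw
weight by ≤ 0.0005, far below the 4-fold (≈ 1.386 in log-score units)
granularity used downstream; P-value ratios near the 4-fold boundary may
still differ in the last digit from implementations with other
discretizations.

`threshold_for_pvalue(target)` returns the minimal lattice score whose
P-value is ≤ target (conservative: the attained false-positive rate never
exceeds the target; targets below 4^-L return the maximal score with a
warning). Empirically, scanning i.i.d. uniform sequence at the default
target 0.0005 yields the attained rate per position per strand — about one
prediction per kb of double-stranded sequence.

## Windows, scanning and affinity calls

Mutations are single-nucleotide substitutions, filtered to
(promoter ∪ intron) \ coding (all regions supplied as BED; the promoter
definition, e.g. strand awareness around the TSS, is the caller's choice).
Each mutation becomes a 101-nt window pair centered on the mutated base;
within one sample, windows with identical sequence pairs (genomic repeats)
are collapsed to the first by coordinate order, while identical windows in
different samples are independent observations. Overlapping windows of
nearby mutations are kept.

Scanning is anchored: hits on both strands whose interval lies within
max_dist = 10 bp of the window center (distance 0 when covering it)
compete; the best hit wins by score, then smaller anchor distance, then
leftmost start, then '+' strand — a deterministic tie-break so every window
contributes exactly one hit. Germline and mutant best hits need not share a
position; a window with two strong sites of which only one is damaged
therefore yields no event. Calls with p_site = 0.0005 and fold = 4
(inclusive comparisons at the boundary):

* LOSS: p_g ≤ p_site and p_m ≥ 4 p_g;
* GAIN: p_m ≤ p_site and p_g ≥ 4 p_m;

eligibility flags (p_g ≤ p_site; p_m ≤ p_site) define the loss/gain
denominators, and a window eligible both ways enters both.

A vectorized batch scanner reproduces the per-window reference path
bit-for-bit (tested) and is used wherever window sets are large.

## Controls and context equalization

The mutation context — 5' neighbor, germline base, mutant base, 3'
neighbor, 192 classes, read from the genome strand with no pyrimidine
collapsing (motif scanning is strand-aware) — is the unit of matching.

*Shuffle control*: per window, one uniform joint permutation of the 98
flank positions (central trinucleotide and substitution fixed), several per
mutation. Dinucleotide content is not preserved. *Genomic control*: loci
sampled without replacement from promoter ∪ intron with the matching
central trinucleotide, the context's alternate allele substituted, windows
never overlapping any real mutation window (enforced over all cancer types
at once).

Per motif and direction, control windows with the relevant prediction are
re-sampled to match the cancer context distribution (largest-remainder
integer targets). The requested control size is multiplier × test size
(default 5), capped at the available prediction pool so deficits reflect
context-mix mismatch rather than sheer pool size; per-class shortfalls are
recorded and imputed into the contingency table at the observed cancer
event rate (rounded half away from zero). Exact-rate imputation can only
shrink |f_obs − f_exp|; integer rounding can perturb that pull by at most
one control count — the invariant tests state it with that slack.

## Statistics

Fisher's exact test (two-sided, via scipy) per 2×2 table;
Benjamini–Hochberg q-values (statsmodels) within one family = all motifs
for a (cancer type, control, direction) — directions are corrected
separately, a choice left open by the method description. Selection
magnitude M = f_obs / f_exp. The final call requires q < 0.05 against both
controls with a consistent sign of M − 1; results whose test or control
denominator is below `min_eligible` (default 100 windows) keep their
q-value but are never flagged significant — magnitudes are still reported.
`dnase_fold_change` contrasts log2(M_dnase / M_all) for DNase-restricted
strata (negative = stronger negative selection in accessible chromatin),
with the DNase run using the same pipeline restricted to accessible
regions. The simplified overlap test replaces the affinity-change event
with "mutated base inside the best germline hit" (judged against the
single best hit, consistent with the main workflow) and reuses the same
table/Fisher/FDR machinery.

## Synthetic studies and ground truth

The generator emulates the study conditions at desk scale: an i.i.d.
genome at GC 0.41 organized in 2 kb promoter / 1 kb coding / 6 kb intron /
1 kb spacer cassettes, a 35 % DNase-tile subset, motif instances sampled
from each matrix's count distribution (not the consensus) planted uniformly
and non-overlapping in regulatory regions, and mutations drawn with
probability proportional to a strand-symmetric, C>T- and CpG-elevated
context signature times genome availability of the context.

Selection is calibrated rejection thinning. Naive thinning of loss events
at rate m also removes those windows from the eligible denominator and
would plant m / (1 − (1 − m)·λ), where λ is the event rate among eligible
candidate windows. The generator instead retains events with probability
r = m(1 − λ)/(1 − mλ) (λ estimated from its own candidate stream), so the
ground-truth magnitude against an ideal context-matched control equals m
exactly; enrichment factors m > 1 thin eligible non-events by the
symmetric rate. Every emitted mutation carries its true per-motif call,
and re-classifying the emitted windows reproduces the labels exactly.

Study sizes are configuration, chosen so each answer is estimated with
adequate power while running in minutes on one core:

* **demo** (`default_config`): 20 Mb genome, three motifs planted at
  3 /kb (neutral; m_loss = 0.7; m_gain = 1.3), 20,000 mutations — about
  one per kb of regulatory DNA, comparable to dense real catalogs. A much
  smaller genome would let the mutation-window exclusion zone swallow the
  genomic-control locus pool.
* **null study** (`null_config`): 8 Mb, 100 random Dirichlet-column motifs
  planted sparsely (0.15 /kb), 4,000 mutations, all factors 1 — 200
  (motif, direction) families for false-positive calibration of the
  both-controls rule.
* **recovery study** (`recovery_config`): 40 Mb, two *unplanted* motifs,
  70,000 mutations, m_loss = 0.7 on one. With no planted instances,
  eligible windows arise from chance hits only, so cancer, shuffle and
  genomic windows share one event rate and the planted magnitude is
  recoverable against both controls.

What passing these tests does and does not show: the generator's genome is
i.i.d. — it has no CpG islands, repeats, chromatin-covariate mutation-rate
variation, or correlated site clustering. One consequence is visible and
instructive: in the *planted* demo genome, shuffling flanks removes the
planted sites, so shuffle-control eligible windows are chance hits with a
different (here lower-fragility for loss, higher for gain) event rate than
the cancer windows — the shuffle comparison is then biased even without
selection, exactly the genomic-regularity concern that motivates requiring
consistency of both controls. The both-controls call remains calibrated
(the genomic control is unbiased under the null), which the null study
verifies, but single-control shuffle results on motif-dense sequence
should be read with care. None of this says anything about biases of real
genomes beyond the mechanisms modelled.

## Numerical and design choices

* All sampling flows from one seeded NumPy generator per run (per-cancer
  streams spawned via `SeedSequence`); reruns are bit-identical and the
  manifest records the seed, configuration hash and library versions.
* Fisher and BH are delegated to scipy/statsmodels; tests verify them
  against integer hypergeometric enumeration and the direct step-up
  formula.
* Degenerate inputs: empty window sets yield empty outputs; an empty test
  set defines equalization match fraction 1; zero-margin tables give
  Fisher p = 1; magnitudes with empty denominators are NaN and excluded
  from calls; non-positive magnitudes make the DNase fold change NaN with
  a warning.
* Information content (logo scaling only) is plain Shannon IC on
  pseudocounted column frequencies, 2 + Σ f log2 f bits.
* The command-line interface is deliberately thin (`simulate`, `all`,
  `demo`); stage-level operations are library functions demonstrated in
  `examples/`.

## Known limitations

* The shuffle control preserves the nucleotide multiset, not dinucleotide
  content; CpG-driven prediction biases survive only in the genomic
  control.
* Equalization matches the 4-symbol context only — no pentanucleotide,
  replication-timing or expression covariates.
* Magnitudes carry no confidence intervals; the reported point ratio plus
  the Fisher/FDR machinery is the inferential surface.
* Selection factors interact multiplicatively across motifs in the
  generator; heavily overlapping planted motifs would couple their
  effective magnitudes.
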