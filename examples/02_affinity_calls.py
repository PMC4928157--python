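"""Affinity-change classification of a single mutation-centered window.

A somatic substitution disrupting a core position of a predicted binding
site raises the motif P-value of the best hit at least 4-fold — an affinity
LOSS event. Hits are searched within 10 bp of the mutated base on both
strands, separately for the germline and the mutant allele.
"""

from tfselect import PositionWeightMatrix, classify
from tfselect.windows import CENTER, ContextClass, MutationRecord, MutationWindow

rows = []
for base in "TGACGTCA":  # strong 8-bp site
    row = [1.0] * 4
    row["ACGT".index(base)] = 97.0
    rows.append(row)
pwm = PositionWeightMatrix.from_counts("TOY_TF", rows)

# the site's 'A' (its third base) sits at the window center and mutates A>T
germline = "C" * 48 + "TGACGTCA" + "C" * 45
mutant = germline[:CENTER] + "T" + germline[CENTER + 1:]
mutation = MutationRecord("chr1", 1001, "A", "T", "sample1", "demo")
context = ContextClass(germline[CENTER - 1], "A", "T", germline[CENTER + 1])
window = MutationWindow(mutation, germline, mutant, context)

call = classify(window, pwm, p_site=0.0005, fold=4, max_dist=10)
print(f"mutation {mutation.chrom}:{mutation.pos} {mutation.ref}>{mutation.alt} "
      f"in context {context}")
print(f"germline best-hit P-value: {call.p_g:.3g}")
print(f"mutant   best-hit P-value: {call.p_m:.3g}")
print(f"P-value ratio p_m/p_g: {call.ratio:.1f}  ->  call: {call.call}")
print("(LOSS requires a germline hit at P <= 0.0005 and a >= 4-fold weaker "
      "mutant prediction)")
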