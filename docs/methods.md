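# Methods

## Read joining and merging

A read pair (R1 from the fragment's 5′ end on the plus strand, R2 from the
3′ end on the minus strand) is turned into a single read in one of three
ways.

**Direct joining** concatenates `R1 + N×pad + revcomp(R2)`. The true gap
between the reads is unknown without the amplicon length, so a fixed spacer
of 8 Ns is used by default (configurable; callers that know the amplicon can
pass the exact gap). Pad positions carry quality `!` (phred 0) so a pad can
never win a downstream quality comparison. **Inside-out joining** concatenates
`revcomp(R2) + R1`; no spacer is needed and the low-quality read tails end up
at the two ends of the product.

**Merging** scans candidate overlaps between R1's 3′ end and revcomp(R2)'s 5′
end from longest to shortest and accepts the first whose within-overlap
mismatch rate is ≤ `max_mismatch_rate` (default 0.25, with `min_overlap`
= 10). Longest-first is a deterministic choice that maximises use of the
data; merging tools differ in their internal search order and none publishes
it. Within the accepted overlap each disagreeing position takes the base with
the higher quality score — quality-based rather than majority-based
correction, because a pair offers only two votes — with ties going to R1,
the generally more accurate read; the higher quality is recorded.

**Trimming.** Primer trimming matches the primer's IUPAC codes against the
read's 5′ start with a mismatch budget (default 3); an N in the read matches
no code (an unknown base cannot be credited as a primer match). Fixed-length
tail trimming supports the recommended preprocessing for OTU clustering;
`optimize_trim_length` scans lengths L, L−step, … ≥ min_len and keeps the
length with maximal mean genus-level classifier confidence, ties going to
the longer candidate so information is never discarded without a confidence
gain.

## Amplicon extraction through a main reference

Primer sites cannot be located on reference sequences that stop short of
them. The workflow therefore selects a **main reference**: among sequences
with exactly one match of each primer within the mismatch budget (reverse
site 3′ of the forward site), the one with the longest summed flanks outside
the two sites. "Longest segments outside" could also be read as the minimum
of the two flanks; the sum is used. Primer sites are then the
fewest-mismatch matches (leftmost for the forward primer, rightmost for the
reverse) on that single sequence.

Every reference is aligned to the main reference (semi-global, free end
gaps, match +1 / mismatch −2 / gap open −4 / extend −1 — end-gap-free
semantics fit sequences of different extents; exact scoring in published
pipelines is not documented, so one scheme is fixed here and logged) and
each base receives the main-reference coordinate of its aligned column.
Inserted bases repeat the previous aligned coordinate; deleted main-reference
bases leave skipped coordinates; the list is monotone non-decreasing by
construction. All coordinates are 1-based inclusive.

Extraction then works purely on the coordinate list. Forward edge: the first
reference base whose coordinate exceeds the forward site start `s` is found
and `coordinate − s` literal reference bases are back-traced; shortfall
beyond the 5′ end becomes left pad Ns. Reverse edge, symmetrically from the
3′ end against the reverse site end `e`, extending `e − coordinate` bases
rightward. The amplicon spans the outer primer edges inclusive, so
primer-binding regions are part of the amplicon — forced by the back-trace
arithmetic, which pads *to the primer start*. Back-tracing counts literal
reference bases even across an insertion; the coordinate list cannot say
which physical bases an illustration would have skipped, and literal
counting is the only self-consistent reading. An amplicon whose real
(non-pad, non-N) bases cover less than half its span is rejected —
*strictly* less, so a sequence covering exactly half is kept.

The packaged worked example (`simulate.worked_amplicon_example`) rebuilds
this scenario end to end: primer sites at main positions 10–17 and 31–36, a
partial reference whose first mapped coordinate is 12 (two Ns padded), an
insertion repeating coordinate 14, a deletion skipping coordinate 36, and a
last in-band coordinate 35 at reference position 57, extending the amplicon
to reference position 58. The example's coordinate map is constructed
explicitly rather than re-derived by alignment: the scenario packs 33
inserted bases into a 24-coordinate window, which an affine-gap aligner
rightly refuses to bridge when end gaps are free. The coordinate-map builder
itself is validated on alignable cases (single insertions, single deletions,
random indel mutants) in the unit tests.

**Rearrangement** reshapes an amplicon of length L into read layout:
`direct` = first `len1` bases + N×(L−len1−len2) + last `len2` bases (the
amplicon unchanged when L ≤ len1+len2); `inside_out` = last `len2` bases +
first `len1` bases. Left-pad Ns of a partial amplicon therefore end up in
the interior of an inside-out reference.

## Cross-validation by identity

All amplicon pairs are aligned semi-globally and identity is matching
columns over the mutual overlap, in percent; each unordered pair is aligned
once so the table is exactly symmetric. Columns pairing N with N are
uninformative (pad against pad) and excluded from both numerator and
denominator; N against a real base or a gap is a mismatched column. This
makes error-free joined reads align at 100% to their matching rearranged
references while pads still never contribute evidence.

The greedy split at target identity d with half-width δ (defaults 0.5, and
1.0 at d = 90; at d = 100 the whole collection is both training and test
set) classifies each reference's hits into z(r) (> d+δ, must be excluded
from training if r is tested), t(r) (in band, eligible top hits) and the
rest (< d−δ, always safe in training). References are processed in
ascending (|z(r)|, |tz(r)|, id) order, tz(r) being the pooled z-sets of r's
in-band hits — fewest exclusions first, and ties broken by id for
determinism. A reference joins the test set S when at least one in-band hit
can serve in training and, additionally, when excluding its z-set would not
strip any earlier test sequence of its last in-band training hit; the
procedure as a straight-line recipe can otherwise violate its own top-hit
constraint, and exclusion is enforced absolutely (a z-member already in A is
moved to Z). At most three references newly enter the training set A per
accepted test sequence, keeping A growing slowly; overflow in-band hits
remain unassigned and fall into A at the end together with hitless
references. The final A is reported as T (members with an in-band identity
to some test sequence) ∪ W (members entirely below d−δ); T is taken as
"has an in-band identity to S" rather than strictly "is a top hit", since an
in-band non-top hit belongs to neither a strict T nor W.

The first-come baseline (`naive_partition`) applies the identical assignment
rule in plain id order; the greedy ordering's benefit is asserted in
aggregate over random instances, as greedy heuristics are not dominant on
every single instance.

## Classifiers

The built-in classifiers are simplified stand-ins for the four families
commonly benchmarked on 16S data; the package's claims concern joining and
rearrangement effects, which these reproduce qualitatively, not any external
tool's exact scores.

* **Global top-hit**: identity against every reference, computed over the
  query's full aligned span — query bases that cannot be placed on the
  reference dilute the identity rather than hiding in free overhangs — with
  a minimum-identity acceptance threshold (default 80%), the way a database
  search with an identity cutoff behaves. This is what makes inside-out
  reads genuinely unclassifiable against unrearranged amplicons: their best
  arrangement strands one half, identity falls to ~50% and no hit is
  reported. Ties go to the smallest reference id.
* **Local top-hit**: Smith–Waterman (match +2 / mismatch −3 / gap open −5 /
  extend −2). On an inside-out read against plain amplicons the winning
  alignment covers only one read half — at least as good as first reads, but
  the second read's information is unused.
* **Word-counting**: per-genus k-mer presence naive Bayes (k = 8), document
  frequency with add-one smoothing, P(w|g) = (df+1)/(n+2); uniform genus
  prior. Confidence at each rank is the fraction of 100 bootstrap draws
  (each resampling 1/8 of the query's distinct k-mers, with replacement,
  seeded) whose winner agrees with the full-data prediction down to that
  rank, so confidence is monotone non-increasing with depth and a higher
  cutoff can only truncate, never deepen, a prediction. The two conventional
  reporting cutoffs, 50% and 80%, are both just values of `cutoff`. K-mers
  touching any non-ACGT character (including pad Ns) are skipped, keeping
  pads information-free. One word-counting implementation covers both
  bootstrap-confidence classifier styles; their scoring differences do not
  affect the joining/rearrangement conclusions.

## Hierarchical metrics and the paired OTU screen

Per rank: OC — predicted name absent from training (it could never be
verified); UC — the true name exists in training but nothing was predicted;
MC — a wrong training name; TP — correct. Accuracy = TP/(K+OC), K the count
of test sequences whose true name at the rank exists in training. A sequence
with an unknown truth and no prediction is a correct rejection, counted
nowhere. Mean accuracy across identity levels (100, 99, 97, 95, 90) is
unweighted. The library reports fractions; the CLI formats percentages.

The paired screen takes OTU × patient proportion tables for two phases.
"Shift by ≥ 3%" is an absolute proportion difference of 0.03 (the quantity
is a proportion, not a ratio), and an OTU is flagged only when one direction
beats the other both three-fold *and* by three cases — a literal conjunction.
Defaults: min_delta 0.03, fold 3, diff 3.

## Synthetic data

The generator emulates a curated, taxonomically structured reference
collection and an empirical read simulator, at desk scale:

* **Database**: one random ancestor; genus ancestors diverge at
  `genus_divergence` (default 0.10 — comfortably distinct genera); members
  diverge at `within_divergence` (default 0.02, giving within-genus
  identities around 96–98%, where identity-controlled benchmarking is
  interesting). Upper ranks are deterministic groupings of genera so full
  six-rank lineages exist. Uniform substitutions only; no rate
  heterogeneity.
* **Reads**: R1 is the amplicon's 5′ prefix, R2 the reverse complement of
  its 3′ suffix; per-position substitution probabilities rise toward the
  tail, read 2 worse than read 1. The MiSeq-like preset (2 × 300 bp,
  quadratic ramp 0.1→1.3% / 0.2→3%) and HiSeq-like preset (2 × 250 bp,
  linear 0.05→0.25% / 0.1→0.5%) are parameterised stand-ins — real
  instrument profiles are not numerically published — and differ as real
  instruments do: shorter but cleaner. Quality characters encode the local
  error rate through the phred relation so merging sees self-consistent
  data. Indels, chimeras and abundance bias are not simulated; substitution
  is the dominant Illumina mode and the downstream methods are
  substitution-limited.
* Three read pairs per test sequence is the default simulation depth.

Because the generator omits indel errors, real length variation, conserved
16S secondary structure and database mislabeling, green tests demonstrate
the algorithms' correctness and the direction of the joining/rearrangement
effects — not the absolute accuracies achievable on real survey data.

## Problem sizes and numerical choices

The shipped benchmark uses 20 genera × 3 members of 725 bp (the geometry
where 2 × 300 bp pairs cannot overlap), two simulated pairs per held-out
member; partition properties are checked over 100 random 10-sequence
databases spanning within-genus divergences 0.4–8%. These sizes give stable
qualitative results while keeping the whole suite under a minute of
alignment work. Alignment scoring, tie-breaks (lexicographic ids
everywhere), the strict-inequality rejection rule, pad quality `!`, and the
80% top-hit identity floor are all fixed constants logged by the CLI, so any
run is reproducible from its inputs, flags and seeds alone.

## Known limitations

* Identity between very short, heavily padded sequences is ill-conditioned:
  with free end gaps an aligner may stagger pure-N blocks rather than align
  them. Real amplicons with real cores are unaffected.
* The main-reference coordinate system inherits the main reference's
  idiosyncrasies; a different main reference yields different (equally
  valid) coordinates.
* The classifiers are not drop-in replacements for the external tools they
  emulate and their absolute accuracies should not be compared with
  published tables.
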