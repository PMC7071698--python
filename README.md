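# pairtax

Using **unmergeable paired-end reads** of a marker gene (e.g. 16S rRNA) for
taxonomy annotation.

Illumina paired-end (PE) reads can be merged into one long read only when the
amplified fragment is shorter than twice the read length. For many popular
primer pairs it is not: a ~725 bp V3–V6 amplicon leaves no overlap at all for
2 × 300 bp reads, and sequencing errors sink most merges even when a short
overlap exists. Discarding the second read wastes half the data. `pairtax`
implements and benchmarks the alternative — *joining* the pair into a single
read and, crucially, *rearranging the reference database into the same
layout* so that alignment-based classifiers still work:

* **direct joining** — `R1 + N···N + revcomp(R2)`, an N spacer standing in
  for the unsequenced middle;
* **inside-out joining** — `revcomp(R2) + R1`, which needs no spacer and
  moves the error-prone read tails to the two ends;
* **reference rearrangement** — each reference amplicon is cut into its
  first `len1` and last `len2` bases and reassembled in the same
  direct/inside-out layout as the reads.

Because reference databases contain many sequences that do not reach the
primer sites, amplicons are extracted through a **main-reference coordinate
system**: one reference with unique, complete binding sites for both primers
is chosen, every other sequence is aligned to it, and primer sites are mapped
through per-base coordinates, padding Ns where a sequence falls short.
Sequences whose real bases cover less than half the amplicon span are
rejected.

For benchmarking, the package provides **cross-validation by identity**: a
greedy partition of a database into test (S) and training (A) sets such that
every test sequence's top-hit identity to the training set lies in a band
d ± δ (d ∈ {100, 99, 97, 95, 90}%, δ = 0.5, or 1.0 at 90%), built-in
classifiers (global/local top-hit, k-mer naive-Bayes with bootstrap
confidence), and hierarchical metrics: at each rank a prediction is a true
positive (TP), over-classification (OC: predicted name absent from
training), under-classification (UC: known name not predicted) or
misclassification (MC), with

```
accuracy = TP / (K + OC)
```

where K counts test sequences whose true name at that rank exists in
training. A paired differential-OTU screen (proportion shift ≥ 3%, one
direction at least three-fold and three cases ahead of the other) completes
the downstream analysis tools.

## Worked example

Simulate a small benchmark, hold one sequence out, and classify its reads
(the library API; every step is also a `pairtax` CLI subcommand):

```python
from pairtax import (direct_join, inside_out_join, generate_reference_db,
                     simulate_pe_reads, classify_tophit_global,
                     classify_wordcount, rearrange_reference, Amplicon)
from pairtax.simulate import miseq_300

db = generate_reference_db(n_genera=20, seqs_per_genus=3, seq_len=725, seed=11)
train = [r for r in db if not r.id.endswith("S3")]
held_out = next(r for r in db if r.id == "G1S3")

amp = Amplicon(held_out.id, held_out.seq, 1, 725, 0, 0, held_out.lineage)
r1, r2 = simulate_pe_reads(amp, miseq_300(), n_pairs=1, seed=100)[0]

dj = direct_join(r1, r2)       # R1 + NNNNNNNN + revcomp(R2)
io = inside_out_join(r1, r2)   # revcomp(R2) + R1

p = classify_wordcount(dj.to_record(), train, cutoff=0.5, seed=7)
print("word-count on direct-joined read:", p.predicted,
      "genus confidence", p.confidence["g"])

p_io = classify_tophit_global(io.to_record(), train)
print("global top-hit on inside-out read vs amplicons:",
      p_io.predicted, f"identity {p_io.top_hit_identity:.1f}%")

iorefs = [rearrange_reference(Amplicon(r.id, r.seq, 1, 725, 0, 0, r.lineage),
                              300, 300, "inside_out").to_record()
          for r in train]
p_fix = classify_tophit_global(io.to_record(), iorefs)
print("same read vs inside-out rearranged references:",
      p_fix.predicted, f"identity {p_fix.top_hit_identity:.1f}%")
```

Output:

```
word-count on direct-joined read: d:Bacteria,p:p1,c:c1,o:o1,f:f1,g:g1 genus confidence 1.0
global top-hit on inside-out read vs amplicons: None identity 48.2%
same read vs inside-out rearranged references: d:Bacteria,p:p1,c:c1,o:o1,f:f1,g:g1 identity 95.7%
```

The three lines show the package's central point. The word-counting
classifier, indifferent to base order, places the direct-joined read in the
correct genus with full bootstrap confidence. The global top-hit search
cannot place the inside-out read on unrearranged amplicons — its two halves
sit in the wrong order, identity collapses to 48% and the read goes
unclassified — but against inside-out rearranged references the same read
aligns at 95.7% and recovers the correct genus.

## Command line

```bash
pairtax join --r1 R1.fastq --r2 R2.fastq --mode direct --pad 8 -o joined.fastq
pairtax merge --r1 R1.fastq --r2 R2.fastq --min-overlap 10 --max-mismatch-rate 0.25 -o merged.fastq
pairtax extract --ref refs.fasta --fwd CCTACGGGAGGCAGCAG --rev CCGTCAATTCMTTTRAGT -o amplicons.fasta
pairtax rearrange --amplicons amplicons.fasta --len1 300 --len2 300 --mode inside-out -o iorefs.fasta
pairtax partition --amplicons amplicons.fasta --d 97 --train train.fasta --test test.fasta
pairtax classify --query joined.fastq --ref train.fasta --method wordcount -o preds.tsv
pairtax evaluate --pred preds.tsv --truth truth.tsv --train train.fasta -o report.tsv
pairtax screen --otu-table otus.tsv --pairs pairs.tsv
pairtax simulate-db -o refs.fasta ; pairtax simulate-reads --amplicons amplicons.fasta --r1 r1.fastq --r2 r2.fastq
```

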