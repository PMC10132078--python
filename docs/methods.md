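# Methods

## The problem

Insertion sequences (ISs) are the smallest autonomous mobile genetic elements
in bacteria: a transposase gene (or two) bounded by a pair of inverted
terminal repeats (ITRs), short sequences of roughly 10–50 bp at either end
that are reverse complements of each other. Reference databases under-represent
them, and assembly-based detection struggles because assemblers collapse or
break repeated elements. `iscovery` instead looks for ITR-sized repeats
directly in the short reads of a mixed microbial community, then uses the
community's assemblies only to anchor and pair the repeats. Five stages run in
order; each consumes the previous stage's records and only filters or pairs
them.

## Stage 1 — inter-read repeats by sparse maximal exact matching

All reads of a read set are packed into a single array of 2-bit base codes
(A=00, C=01, G=10, T=11). Reads with any non-ACGT base, or shorter than the
minimum ITR length, are excluded (counted and logged). A pseudo-random
10-code (20-bit) spacer separates consecutive reads; a boundaries table maps
any offset back to (read, position). Windows that overlap a spacer are skipped
explicitly during both indexing and scanning, so the spacer content never
influences results (its randomness is defence in depth, not a correctness
assumption).

The reference side of the search is a sparse k-mer table: a k-mer starting at
within-read position `p` is indexed only when `p` is a multiple of the stride

    stride = (L - k) + 1

with `k` the k-mer length (default 15) and `L` the minimum ITR length
(default 25). This stride is the largest sampling interval that still
guarantees every window of length ≥ L in every read contains at least one
indexed k-mer start, so no repeat of at least ITR length can be missed while
the table holds only ~1/stride of all k-mers. The query side slides over
every k-mer of every read; each index hit is extended to a maximal exact
match (MEM) by interval halving: try the whole available extension as one
block comparison, halve on mismatch until a block matches, then elongate one
base at a time. The result is exactly the unique maximal match containing the
seed (verified in tests against naive per-base extension).

A MEM is accepted when

* its length lies in `[min_itr_length, max_itr_length]` (default 25–50 nt) —
  repeats of ITR size; longer MEMs are rejected outright, not trimmed; and
* on **both** reads it neither begins within 20 nt of the read start nor ends
  within 20 nt of the read end. Exact duplicate reads from library
  amplification align as prefix/suffix matches, which this end buffer removes.

On the first accepted MEM, the query read and its partner are both recorded as
repeat reads (one repeat interval per read — a 150-nt read is not expected to
hold more than one ITR) and the scan moves to the next read; reads already
recorded are not scanned again. Scan order (k-mer position ascending, index
hits in (read, position) order) is fixed, so the output is deterministic.
Internally the scan groups seed hits by (reference read, diagonal): all seeds
on one diagonal belong to the same maximal match, so only one seed per group
is extended, plus any seed falling outside the group's match span.

The store is single-orientation: reverse-complement repeat copies are found
anyway because shotgun reads sample both genomic strands. In particular the
two ITRs of a single element form an exact inter-read repeat between a
forward read over ITR1 and a reverse-strand read over ITR2. This is a
documented limitation for data that covers only one strand.

## Stage 2 — placement and proximity pairing

Repeat reads are placed on their sample's assembly. The internal mapper is an
exact end-to-end matcher (21-nt seed table plus full-length verification, both
strands, all occurrences), which is the right tool for the error-free reads
the synthetic generator produces; real-data users can supply placements from
any external aligner through a minimal SAM reader (flags 0/16 accepted;
unmapped, clipped or gapped records rejected — a deliberate strictness
policy, since a partially aligned repeat read has ambiguous repeat
coordinates). Repeat intervals are projected into contig coordinates (with
the strand reflection for minus-strand placements) and duplicate candidates
from different reads collapse to one. Two candidates on the same contig are
paired when the span from the start of the earlier to the end of the later
lies within `[min_is_len, max_is_len]` (default 500–3000 nt) — the span of
the putative IS including both ITRs. A candidate may join several pairs.

## Stage 3 — clustering and reverse-complement validation

Candidate ITRs from the whole run are clustered with a greedy longest-first
algorithm reproducing the documented CD-HIT-EST parameter semantics: identity
threshold `c` (default 0.9), local (`G=0`, default) or global alignment,
coverage thresholds on the shorter (`aS`, default 0.9) and longer (`aL`,
default 0) sequence, and minimum alignment length `A` (default 0, the tool
default; only the other four parameters are given explicit defaults by the
method's standard command line). Alignments are scored +2/−2 with gap
open −4 / extend −1; identity is identical bases over alignment columns.
Both orientations are tried, as in CD-HIT-EST's default nucleotide mode —
necessary, since the two ITRs of one element are reverse complements and must
co-cluster. We reproduce the parameter semantics, not CD-HIT's short-word
heuristics, so exact cluster boundaries may differ from the original tool on
borderline pairs; correctness is defined by the admission predicate, which an
independent dynamic-programming aligner re-verifies in the tests. Ties in the
greedy order (equal lengths) break lexicographically, then by input order.
Cluster count is checked to be non-decreasing in `c` on fixed inputs; this is
an empirical property of greedy clustering, not a theorem.

A proximity pair becomes an insertion sequence if (1) both candidates are in
the same cluster, (2) both lengths are within the ITR window, (3) the span is
within the IS window, and (4) the candidates are reverse complements: a local
alignment of the first against the reverse complement of the second must have
at least `min_itr_length` identical bases ("identities", blastn-style counts,
not percent). A full dynamic-programming alignment stands in for a word-seeded
search here; it finds every alignment a seeded search would.

## Stage 4 — transposase evidence

Candidate ISs are screened for transposase proteins. Protein detection is a
pluggable port. The production route exports all six-frame stop-to-stop ORFs
(standard bacterial code, no start codon required, default ≥ 30 aa) and
ingests InterProScan-format 15-column TSV hits computed externally against
those ORFs; the offline route is a bundled mock annotator that matches
amino-acid motif regexes against the same ORFs. Either way, hits are mapped
back to nucleotide coordinates on the IS (`nt = orf_start + 3·(aa−1)` on the
forward strand, mirrored on the reverse) and a record is kept only if some hit
description contains "Transposase", "Integrase-like" or "Ribonuclease H"
(case-insensitive substring over both the signature and the InterPro
description fields). With annotation disabled the filter is skipped entirely.

## Stage 5 — outputs and the catalogue

Each IS is named `IS_length_<len>` plus one `-<accession>_<start>_<end>`
segment per protein hit. `name_is` preserves the caller-supplied hit order —
the reference catalogue contains multi-accession names that are not sorted by
position, so sorting inside the grammar would make such names unrepresentable;
the pipeline itself supplies hits sorted by ascending nucleotide start.
Outputs are a FASTA of IS sequences (headers = names, 80-column wrap) and a
TSV with name, sample, contig, the 1-based inclusive coordinates of both
ITRs, and the semicolon-joined protein descriptions. Internally all
coordinates are 0-based half-open; conversion happens only at the output
boundary. Pooled run outputs dereplicate at 95 % global identity (greedy, as
above, coverage constraints off), keeping the longest member of each cluster
as representative and every member's provenance in a membership table.

## The synthetic truth generator

The generator is the package's offline test surface: contigs with planted
ISs, error-free reads, and a truth table, all reproducible byte-for-byte from
a seed.

* Contig backgrounds are i.i.d. uniform ACGT. At desk scale the chance of an
  accidental ≥ 25-nt repeat between two loci is negligible (~10⁻⁹ per 500 kb
  genome for a 25-mer collision), and the end-to-end tests would surface one
  as a false positive.
* Each planted element is `ITR1 + body + ITR2` with `ITR2 = revcomp(ITR1)`,
  ITR length uniform in 25–50 nt, IS length uniform in the configured range
  (500–3000 by default), bodies independent. `itr_mismatches` substitutions
  are placed contiguously at ITR2's outer end, so the exact-match core of an
  n-nt pair is exactly n−m bases; the scanner can then still find the core
  (if n−m ≥ L) and the validation alignment sees exactly n−m identities.
  Scattered mismatches would leave no exact inter-read repeat of ITR length
  at all — with them, no read-level exact-match method can recover the pair.
* The bases immediately flanking each element (and the first/last body bases)
  are constrained so that no maximal match can extend past an ITR boundary
  through the complementary strand; without this guard, chance flank matches
  (probability 1/4 per side) shift recovered coordinates off the truth table.
* When `transposase_stub` is set, a stop-bounded marker ORF (a fixed 12-aa
  recognition motif plus 30 random amino acids, stop-free codons) is embedded
  90 nt into each body. The default mock rule maps the motif to a transposase
  family accession/description. The motif's coding sequence recurs in every
  element, which makes it a deliberate built-in negative control: it produces
  direct-repeat candidates across loci that must be rejected by the
  reverse-complement validation.
* Reads tile both strands at `tiling_step` (default 10 nt, read length
  150 nt), so every planted ITR is covered by reads that keep it clear of the
  20-nt end buffer. `duplicate_read_fraction` appends exact copies so that
  the stated fraction of the final read set are duplicates (technical
  repeats). Loci on one contig sit more than the maximum IS length apart, and
  at least two read lengths from contig ends.
* What the generator does **not** emulate: sequencing errors, indels, quality
  profiles, abundance/coverage variation, community composition, or genuinely
  repeated elements across loci. Passing the planted-recovery tests therefore
  demonstrates the correctness of the repeat/projection/validation machinery
  on clean signal, not robustness to noisy real-world libraries — for those,
  placements should come from a mismatch-tolerant external aligner via the
  SAM adapter, and the MEM stage's exact-match requirement means heavily
  mutated ITR copies are found only through their exact cores.

## Numerical and policy choices

* 2-bit k-mer values are exact 30-bit integers (k=15), so index lookups are
  collision-free; no hashing heuristics are involved.
* The end-buffer rule reads "within 20 nt of either end" as: match start
  < 20 from the read start, or match end < 20 from the read end, on either
  read of the pair.
* Ordering everywhere (scan order, candidate order, cluster tie-breaks, hit
  order in names) is fixed and documented so that identical inputs and seed
  give byte-identical outputs; gzip members are written with a zeroed mtime
  for the same reason.
* Amino-acid→nucleotide mapping is codon-exact: a hit over aa `a..b` of an
  ORF starting at nt `s` spans `s+3(a−1) .. s+3b−1`. Reference names in the
  wild occasionally imply spans that are not whole codon multiples; such
  conventions cannot be reproduced exactly and are not attempted.
* Cluster membership is evaluated on the global candidate pool across all
  samples of a run, maximising cross-sample sensitivity; per-sample
  clustering is the alternative reading and would only split clusters.
* Whether a pair's two ITR candidates must come from different reads is not
  constrained; proximity pairing already enforces distinct loci.

## Problem sizes used in the checks

The standard recovery condition is 10 contigs × 50 kb with 15 planted ISs
(IS 600–2900 nt) tiled at step 10 on both strands (~100 k reads, ~15 Mnt);
the scanner/oracle equivalence suite uses 50 pools of 40 × 150-nt reads with
planted shared blocks of 20–60 nt; the duplicate negative control uses 2 ×
20 kb contigs at 30 % duplication. These sizes were chosen to exercise every
code path (multi-contig assemblies, multi-locus repeats, buffer rejections,
marker direct repeats) with comfortable margins on a single CPU.

## Known limitations

* Exact matching only in the scanner: diverged ITR copies are recovered
  through their longest exact core, or not at all.
* The internal read mapper is exact; real reads need an external aligner.
* Composite transposons, target-site duplications and IS-within-IS nesting
  are out of scope; elements whose ITR spacing exceeds `max_is_len` are
  missed by construction.
* CD-HIT's exact clustering boundaries are not reproduced, only its parameter
  semantics; catalogues built here and by CD-HIT-EST may differ on borderline
  pairs near the identity threshold.
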