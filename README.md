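# iscovery

Discovery of insertion sequences (ISs) from short reads of mixed microbial
communities, by detecting their inverted terminal repeats (ITRs) as
inter-read repeats.

ISs are the smallest bacterial mobile genetic elements: a transposase gene
bounded by two ITRs — short (10–50 bp) sequences at either end that are
reverse complements of each other. They drive horizontal gene transfer and
the spread of antimicrobial resistance, yet reference databases
under-represent them and assemblers collapse or truncate repeated elements.
`iscovery` sidesteps assembly-based detection: it finds ITR-sized repeats
directly in the reads, then uses assemblies only to anchor, pair and validate
them. It is written for microbiome researchers who want to mine their own
metagenomes for novel ISs and build a dereplicated IS catalogue.

## Method in brief

1. **Repeat scan.** All reads are packed into a 2-bit code array (A=00, C=01,
   G=10, T=11) with random spacers marking read boundaries. A sparse k-mer
   table indexes only k-mers at positions that are multiples of
   `(L − k) + 1` (k = 15, L = minimum ITR length 25); this stride is the
   largest for which every window of length ≥ L still contains an indexed
   k-mer, so nothing of ITR size can be missed. Query k-mers are extended to
   maximal exact matches (MEMs) by interval halving. A MEM is kept if its
   length is within the ITR window (25–50 nt) and it stays ≥ 20 nt clear of
   both ends of both reads — prefix/suffix matches are the signature of
   technical (PCR-duplicate) repeats. One repeat interval is recorded per
   read.
2. **Placement.** Repeat reads are placed exactly on their sample's assembly
   (or placements are ingested from any aligner as minimal SAM), repeat
   intervals are projected into contig coordinates, and candidate ITRs on the
   same contig are paired when their joint span is IS-sized (500–3000 nt).
3. **Validation.** Candidates are clustered greedily with CD-HIT-EST
   parameter semantics (c = 0.9, local alignment, aS = 0.9, both strands).
   A pair becomes an IS iff both ITRs are in the same cluster, both lengths
   and the span are in range, and a local alignment of the first ITR against
   the reverse complement of the second has ≥ 25 identical bases.
4. **Annotation.** Six-frame ORFs are screened for transposase evidence —
   InterProScan-format TSV hits in production, a bundled motif-based mock
   annotator for offline runs — and ISs without a "Transposase",
   "Integrase-like" or "Ribonuclease H" description are dropped.
5. **Outputs.** A FASTA + TSV pair with names like
   `IS_length_1391-IPR001207_495_804` (length, protein accessions,
   nucleotide positions). Pooled runs dereplicate at 95 % global identity
   into a non-redundant catalogue.

## Worked example

Generate a synthetic community with four planted ISs, run discovery with the
mock annotator, and build a catalogue:

```sh
cat > spec.toml <<EOF
n_contigs = 2
contig_length = 20000
n_is = 4
is_len_range = [600, 2900]
tiling_step = 10
seed = 1
EOF
iscovery simulate --spec spec.toml --out sim
iscovery discover --manifest sim/manifest.tsv --annotation mock --seed 1 --out run
iscovery catalogue --inputs run --c 0.95 --out cat
```

which prints

```
truth set with 4 planted ISs written to sim
4 insertion sequences written to run/insertion_sequences.fasta
4 catalogue representatives written to cat
```

with per-stage counts in the log: 7944 reads packed, 186 repeat reads, 14
candidate ITRs in 5 clusters, 10 proximity pairs, 4 validated ISs, 4 after
the transposase filter. `run/insertion_sequences_info.tsv` contains:

```
name	sample_id	contig	itr1_start_position	itr1_end_position	itr2_start_position	itr2_end_position	description
IS_length_2158-IPR001207_120_155	sample1	contig1	6909	6934	9041	9066	Transposase, mutator type
IS_length_2421-IPR001207_122_157	sample1	contig1	15701	15728	18094	18121	Transposase, mutator type
IS_length_1590-IPR001207_130_165	sample1	contig2	1999	2034	3553	3588	Transposase, mutator type
IS_length_1034-IPR001207_132_167	sample1	contig2	18113	18150	19109	19146	Transposase, mutator type
```

Each row is one called IS: its name encodes the element length and the
nucleotide span of the transposase-family hit inside it; the four coordinate
columns are the 1-based inclusive positions of the two ITRs on the contig.
The calls coincide exactly with `sim/truth.tsv`, the generator's planted
coordinates. Rows 1 and 2 for instance are a 2158-nt and a 2421-nt element
on contig1, each with a marker transposase ORF ~120 nt into the element.

On real data, replace `simulate` outputs with your own manifest
(`lane_id  fastq1_path  fastq2_path  sample_id  assembly_path`,
tab-separated) and pass `--annotation interproscan_tsv:hits.tsv`, where
`hits.tsv` is InterProScan output for the ORFs the pipeline exports under
`run/intermediates/orfs.faa` (run discovery once with `--annotation none` to
get them).

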