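# Methods

## Scope and model

The package integrates per-library de novo transcriptome assemblies into a
single non-redundant representative set. It deliberately consumes
*precomputed* similarity-search results (the 12-column tabular hit format)
rather than running an aligner: the integration logic — which pairs count,
which thresholds apply, how ties break — is the subject here, and it is
fully determined by the hit tables plus the sequences. Read mapping,
variant calling and benchmark tools likewise stay outside; the package
takes their outputs (pre-counted read totals, called VCFs).

Coordinates are 1-based inclusive everywhere, the native convention of the
tabular hit format; nothing converts to half-open coordinates internally.
Minus-strand subject hits are normalized (start ≤ end) and flagged, not
rejected, because transcript-vs-transcript searches legitimately match
either strand; coverage treats both orientations identically.

## Stage semantics and the parameters that matter

**Seed filters.** Per contig–protein pair, HSPs with alignment length
< 20 aa are removed *first*; the survivors' merged subject coverage must
then be ≥ 50 % (inclusive). Filtering rows first is the only order in
which both thresholds act independently of each other. Merged coverage
(union of intervals) is the default because a ratio from raw summed HSP
lengths can exceed 100 %; a `raw_sum` mode exists for comparison.

**Reciprocal best hit.** The ranking chain is a total order: bit score
(desc), e-value (asc), merged coverage (desc), partner id (asc,
lexicographic). Tie-breaking by id is arbitrary but reproducible; every
tie actually broken is logged. The same two seed filters are applied in
the reverse search direction by default (coverage measured on the
reference protein, which is the reverse query); `filter_reverse=False`
ranks the reverse direction unfiltered.

**Concentrate.** The redundancy tolerance — at most 2 bp of combined
mismatches and gaps — is read as a *global* unit-cost edit distance over
the full sequences: the strictest reading, appropriate for collapsing
near-identical full-length contigs. An end-gap-free (infix) mode is
available behind a flag for partially overlapping contigs, without any
claim of equivalence. The bounded distance is computed with a banded
k-bounded aligner (edlib); a length difference beyond the tolerance
short-circuits without alignment. Clustering is single-linkage over the
pairwise relation (connected components): the tolerance relation is not
transitive, so a chain a–b–c clusters together even when d(a,c) exceeds
the bound. This is the simplest closure of a pairwise relation; it is
acknowledged, tested explicitly, and the synthetic generator plants an
exact anchor copy in every family so that planted clusters never depend
on chain effects. The representative is the longest member (most complete
transcript), ties to the smallest (library, contig) key. Retention
requires members from ≥ 2 distinct libraries; seeds stranded in dropped
clusters are rescued back, since a gene expressed in one tissue only is
real but unrepeatable across libraries.

**Taxonomy filter.** A contig is classified by its best hit (bit score,
e-value, subject id). `module3` keeps Eukaryota, unclassified and no-hit
contigs — the permissive reading appropriate mid-pipeline; the
`strict_eukaryote` policy keeps only positive eukaryote matches. Both are
exposed because the two defensible readings of the final filter differ on
no-hit contigs; neither is asserted as uniquely correct, and the default
is `module3`.

**Merge.** Collapsing a semi-manual contig into an automatic one requires
100 % identity HSPs covering 100 % of the shorter sequence — deliberately
conservative, since "homology" alone is under-specified; both knobs
(`merge_min_identity_pct`, `merge_min_containment`) are configurable.

**Isoforms.** An edge requires an HSP strictly longer than 150 bp at
strictly more than 90 % identity, from a self search run with word size
100 bp; groups are components of size ≥ 2. The identity threshold is read
as HSP percent identity — the only quantity available in a pairwise hit
table; a covered-fraction variant can be emulated upstream but is not
claimed equivalent.

**Coverage evaluation.** Per-pair HSPs are merged on each sequence's own
axis; a sequence's coverage is the **best single partner's** merged
coverage, not the union across partners (segments from different partners
need not tile one transcript consistently; a union mode exists behind a
flag). Counting is strict (> 0.75 by default) and denominators are full
set sizes. Percentages round half-up to 2 decimals, matching how such
tables are conventionally printed.

**Variants.** QUAL > 20 and DP > 3, both strict; sites with no depth
anywhere fail the depth filter by construction. Depth is INFO/DP with a
fallback to the sum of per-sample DP. Presence of an alternate allele is
genotype-based (any called alt allele, heterozygous included); allele
indices above 1 count as present by default (`collapse_multiallelic`),
mirroring the set-intersection semantics of VCF bitmask tools. A
group-specific site must carry the alt in every include accession and in
no other accession of the universe (explicit exclude sets override the
complement default).

## The synthetic generator

`unigene.fixtures` plants a complete toy study and records its truth:
gene families (random stop-free CDS, 300–1500 bp, multiple of 3) copied
into ≥ 2 libraries with 0–2 random edits per copy, always including one
exact anchor copy; single-library seed genes; contaminant families
labelled Bacteria/Archaea/Viruses; isoform pairs sharing a codon-aligned
exact block > 150 bp; and a toy pedigree (6 accessions, 2 parental lines)
with line-specific alternate alleles plus boundary-failing distractor
sites (QUAL = 20, DP = 3). Families are kept pairwise > 10 edits apart so
clusters cannot merge. Hit tables are emitted from the planted
coordinates with analytic score surrogates (bit = 2·matches,
e-value = 10^(−matches/10)); only their ordering matters downstream. A
default study uses 8 genes × 4 libraries; the acceptance script spans
5–50 genes × 3–10 libraries.

What the generator does **not** emulate — and what passing tests
therefore do not show about real data: sequencing error and coverage
gradients, fragmented or chimeric contigs, genuinely ambiguous cluster
boundaries (families closer than the tolerance plus noise), aligner
idiosyncrasies in HSP placement and scoring, multi-hit homology across
gene families, and linkage/relatedness structure beyond simple
presence/absence of alleles. Recovery on fixtures demonstrates the logic
is implemented exactly as specified, not that the thresholds are optimal
for any particular organism.

## Numerical and degenerate-input choices

- Edit distance: |len(a)−len(b)| > k returns the EXCEEDS sentinel without
  alignment; empty strings follow d("", x) = |x|.
- ORF finding: stop-to-stop maximal runs, no ATG requirement (de novo
  contigs are frequently 5'-truncated); any codon containing a non-ACGT
  symbol translates to 'X' and never acts as a stop — conservative for
  IUPAC ambiguity codes. Tie-break: longest, then frame order
  +1, +2, +3, −1, −2, −3, then smaller start on the input strand. An
  all-stops input returns an empty ORF on frame +1.
- Interval merging coalesces adjacent intervals (end + 1 == next start);
  inverted intervals are a hard error naming the interval.
- Percentage reporting uses decimal half-up rounding, not float banker's
  rounding.
- Duplicate FASTA ids and malformed hit rows are hard errors naming the
  id/line; empty files are warnings, not errors.
- All tie-breaks are total orders ending in a lexicographic comparison,
  so identical inputs give byte-identical outputs.

## Known limitations

Concentrate compares candidate pairs within a length-sorted window; with
the global distance this is O(n·w) alignments and fast, but the
end-gap-free mode disables the window prune and is quadratic in candidate
count. The merge step trusts the cross-hit table for pair discovery: a
truly identical pair absent from the table will not collapse. VCF parsing
requires parseable 4.x input; no liftover or normalization of variant
representations is attempted.
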