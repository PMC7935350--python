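# unigene

Multi-library **de novo transcriptome integration**: build one non-redundant
representative transcript set from RNA-Seq libraries that were assembled
independently (different tissues, accessions, assemblers or k-mers), then
evaluate it and mine it for group-specific variants.

Keeping only contigs that were assembled independently in at least two
libraries is a powerful guard against assembler-specific misassembly, but it
requires careful bookkeeping: orthology seeding, cross-library redundancy
collapsing, rescue of genuine single-library genes, and contamination
removal. This package implements that workflow as a tested library plus a
CLI operating on standard formats (FASTA, 12-column tabular hit files, VCF,
TSV).

## The workflow

1. **Seed selection (reciprocal best hit).** Each library's contigs are
   searched (translated) against a reference protein set. Per
   contig–protein pair, HSPs shorter than 20 aa are discarded and the
   merged HSPs must cover ≥ 50 % of the protein. For every reference
   protein the best contig wins (bit score, then e-value, merged coverage,
   contig id), and the link is kept only when it is reciprocal — the
   contig's own best protein is that same protein.
2. **Paralog extension and concentrate.** Seeds are searched against *all*
   libraries; every hit contig becomes a candidate. Candidates within a
   bounded edit distance — at most **2 bp** of mismatches plus gaps,
   computed globally — are linked, clusters are the connected components,
   the longest member represents each cluster, and a cluster survives only
   if its members span **≥ 2 libraries**.
3. **Singleton rescue.** Seed contigs with no close homolog in any other
   library (stranded in dropped clusters) are added back.
4. **Taxonomy filter.** Each contig is classified by the superkingdom of
   its best database hit; non-eukaryote matches are discarded
   (`module3` keeps unclassified and no-hit contigs; `strict_eukaryote`
   keeps only eukaryote matches).
5. **Merge + isoforms.** The semi-manual set can be merged with an
   independently produced automatic set (collapsing perfect-identity,
   fully contained duplicates), and isoform groups are detected from an
   all-vs-all self search: an HSP **> 150 bp** at **> 90 %** identity
   (word size 100 bp) links two contigs as isoforms of one gene.

Evaluation utilities compute mutual coverage between two transcript sets
(per-pair HSPs merged; a sequence counts as covered when its best single
partner covers **> 75 %** of its length) and read-mapping rates
(1 − unmapped/total). The variant module filters calls at **QUAL > 20 and
DP > 3** (strict) and selects *group-specific* variants: sites whose
alternate allele is present in every accession of an include set and absent
from all others — presence/absence bitmask semantics, with a pedigree's
parental lines as the patterns.

## Worked example

Simulate a toy study (8 gene families over 4 libraries, 2 single-library
seed genes, 2 bacterial/viral contaminants, 1 planted isoform pair) and
integrate it:

```bash
unigene simulate sim/ --n-genes 8 --n-libraries 4 --singletons 2 \
    --contaminants 2 --isoform-pairs 1 --seed 7
unigene integrate-all --input-dir sim/ --out-dir out/
```

This prints the stage report:

```json
{
  "assignments": 26,
  "candidates": 26,
  "clusters_dropped": 2,
  "clusters_retained": 10,
  "input_contigs": 26,
  "integrated_contigs": 10,
  "isoform_groups": 1,
  "isoform_members": 2,
  "rescued_singletons": 2,
  "seeds": 26,
  "taxonomy_discarded": 2,
  "taxonomy_kept": 10,
  ...
}
```

Reading it: 26 planted contigs all became reciprocal-best-hit seeds; they
concentrate into 10 retained multi-library clusters (8 genes + 2
contaminant families) and 2 dropped singleton clusters whose seeds are
rescued; the taxonomy filter then discards the 2 contaminant
representatives, leaving 10 integrated transcripts (8 genes + 2
singletons) and recovering the 1 planted isoform pair — exactly the
generator's ground truth (`sim/manifest.json`). `out/` contains the
integrated FASTA, a provenance/cluster TSV and `report.json`.

Every stage is also a standalone subcommand (`seeds`, `concentrate`,
`taxfilter`, `merge`, `isoforms`, `coverage`, `mapping-rate`,
`variants-groups`) and a plain Python function (`unigene.select_seeds`,
`unigene.concentrate`, `unigene.mutual_coverage`, ...).

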