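"""Deterministic synthetic-data generator with known ground truth.

The generator stands in for a multi-library de novo assembly study at toy
scale: gene families copied into several libraries with bounded divergence
(at most the concentrate tolerance, default 2 bp), seed genes present in a
single library (which only the singleton rescue can save), contaminant
gene families whose database best hit is non-eukaryote, planted isoform
pairs sharing a long high-identity block, and a small pedigree of
accessions segregating line-specific alternate alleles.

Hit tables are emitted *by construction* from the known copy coordinates
rather than by running an aligner: identities and coordinates are exact,
and the score columns use analytic surrogates (bit score = 2x matches,
e-value = 10^(-matches/10)). Nothing downstream depends on their absolute
scale, only on their ordering. Every sequence copy carries one exact
(0-edit) anchor so that single-linkage clusters are unambiguous: each
edited copy is within the tolerance of its anchor.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field
from pathlib import Path

from .io_formats import ContigRecord, HspRecord, VariantSite, write_fasta, write_hit_table
from .sequence_ops import EXCEEDS, bounded_edit_distance, translate_codon

_NONSTOP_CODONS = tuple(
    a + b + c
    for a in "ACGT" for b in "ACGT" for c in "ACGT"
    if translate_codon(a + b + c) != "*"
)

#: minimum edit distance required between distinct gene families, so that
#: clusters under the 2 bp tolerance can never merge
GENE_SEPARATION_BP = 10

DEFAULT_ACCESSIONS = ("S1", "S2", "S3", "S4", "S5", "S6")
#: toy pedigree: two parental lines, each transmitting a private allele to
#: a pair of descendant accessions
DEFAULT_PEDIGREE = {
    "lineA": ("S5", "S6"),
    "lineB": ("S1", "S2"),
}


@dataclass
class CopyFixture:
    library_id: str
    contig_id: str
    sequence: str
    n_edits: int
    is_anchor: bool

    @property
    def key(self) -> tuple[str, str]:
        return (self.library_id, self.contig_id)


@dataclass
class GeneFixture:
    gene_id: str
    cds: str
    protein: str
    kind: str  # "gene", "singleton", or "contaminant"
    superkingdom: str
    copies: list[CopyFixture] = field(default_factory=list)

    @property
    def reference_id(self) -> str:
        return f"P_{self.gene_id}"

    @property
    def nr_subject_id(self) -> str:
        return f"NR_{self.gene_id}"

    def representative(self) -> CopyFixture:
        """Longest copy; ties break on the smaller (library, contig) key —
        the same rule the concentrate step applies."""
        best_len = max(c.sequence.__len__() for c in self.copies)
        return min(
            (c for c in self.copies if len(c.sequence) == best_len),
            key=lambda c: c.key,
        )


@dataclass
class PlantedSite:
    contig_id: str
    pos: int
    ref: str
    alt: str
    carriers: tuple[str, ...]  # accessions whose VCF carries the alt call
    qual: float
    depth: int
    passes_filter: bool
    line: str | None  # parental line this site is specific to, if any


@dataclass
class FixtureManifest:
    """Everything the generator planted, plus the derived truth tables."""

    seed: int
    library_ids: list[str]
    genes: list[GeneFixture]
    isoform_pairs: list[tuple[str, str, int]]  # (gene_a, gene_b, block_bp)
    accessions: list[str]
    pedigree: dict[str, tuple[str, ...]]
    planted_sites: list[PlantedSite]

    # ---- derived truth ----

    def genes_of_kind(self, kind: str) -> list[GeneFixture]:
        return [g for g in self.genes if g.kind == kind]

    def truth_retained_representatives(self) -> set[tuple[str, str]]:
        """Representatives of clusters spanning >= 2 libraries (multi-library
        genes and contaminants; contaminants are removed later, by taxonomy)."""
        return {
            g.representative().key
            for g in self.genes
            if len({c.library_id for c in g.copies}) >= 2
        }

    def truth_rescues(self) -> set[tuple[str, str]]:
        return {g.representative().key for g in self.genes_of_kind("singleton")}

    def truth_discards(self) -> set[tuple[str, str]]:
        return {g.representative().key for g in self.genes_of_kind("contaminant")}

    def truth_final_contigs(self) -> set[tuple[str, str]]:
        kept_kinds = ("gene", "singleton")
        return {
            g.representative().key for g in self.genes if g.kind in kept_kinds
        }

    def truth_isoform_groups(self) -> list[set[str]]:
        by_id = {g.gene_id: g for g in self.genes}
        return [
            {
                by_id[a].representative().contig_id,
                by_id[b].representative().contig_id,
            }
            for a, b, _ in self.isoform_pairs
        ]

    def truth_line_counts(self) -> dict[str, int]:
        counts = {line: 0 for line in self.pedigree}
        for s in self.planted_sites:
            if s.line is not None and s.passes_filter:
                counts[s.line] += 1
        return counts

    def all_contigs(self) -> list[ContigRecord]:
        return [
            ContigRecord(c.contig_id, c.library_id, c.sequence)
            for g in self.genes
            for c in g.copies
        ]

    def contig_key_index(self) -> dict[str, tuple[str, str]]:
        return {c.contig_id: c.key for g in self.genes for c in g.copies}

    def taxonomy_map(self) -> dict[str, str]:
        return {g.nr_subject_id: g.superkingdom for g in self.genes}

    def to_json(self) -> dict:
        return {
            "seed": self.seed,
            "library_ids": self.library_ids,
            "n_genes": len(self.genes_of_kind("gene")),
            "n_singletons": len(self.genes_of_kind("singleton")),
            "n_contaminants": len(self.genes_of_kind("contaminant")),
            "retained_representatives": sorted(
                map(list, self.truth_retained_representatives())
            ),
            "rescues": sorted(map(list, self.truth_rescues())),
            "discards": sorted(map(list, self.truth_discards())),
            "final_contigs": sorted(map(list, self.truth_final_contigs())),
            "isoform_groups": sorted(
                sorted(g) for g in self.truth_isoform_groups()
            ),
            "line_counts": self.truth_line_counts(),
        }


# ---------------------------------------------------------------------------
# sequence planting


def _random_cds(rng: random.Random, min_bp: int = 300, max_bp: int = 1500) -> str:
    n_codons = rng.randrange(min_bp // 3, max_bp // 3 + 1)
    return "".join(rng.choice(_NONSTOP_CODONS) for _ in range(n_codons))


def _apply_edits(rng: random.Random, seq: str, n_edits: int) -> str:
    s = list(seq)
    for _ in range(n_edits):
        op = rng.choice(("sub", "ins", "del"))
        if op == "sub" and s:
            i = rng.randrange(len(s))
            s[i] = rng.choice([b for b in "ACGT" if b != s[i]])
        elif op == "ins":
            i = rng.randrange(len(s) + 1)
            s.insert(i, rng.choice("ACGT"))
        elif s:
            del s[rng.randrange(len(s))]
    return "".join(s)


def _well_separated(cds: str, existing: list[str]) -> bool:
    for other in existing:
        if abs(len(cds) - len(other)) > GENE_SEPARATION_BP:
            continue
        d = bounded_edit_distance(cds, other, k=GENE_SEPARATION_BP)
        if d is not EXCEEDS:
            return False
    return True


def _translate_cds(cds: str) -> str:
    return "".join(
        translate_codon(cds[i : i + 3]) for i in range(0, len(cds) - 2, 3)
    )


def generate_libraries(
    n_genes: int = 8,
    n_libraries: int = 4,
    copy_divergence_bp: int = 2,
    n_seed_singletons: int = 2,
    n_contaminants: int = 2,
    seed: int = 0,
    n_isoform_pairs: int = 1,
    accessions: tuple[str, ...] = DEFAULT_ACCESSIONS,
    pedigree: dict[str, tuple[str, ...]] | None = None,
    n_specific_per_line: int = 3,
    n_filter_fail_per_line: int = 2,
) -> FixtureManifest:
    """Plant a complete toy study with known truth.

    Each multi-library gene gets one exact anchor copy plus edited copies
    (each within *copy_divergence_bp* of the anchor) in at least two
    libraries; singletons get exactly one copy; contaminants look like
    multi-library genes but carry a non-eukaryote database label. Gene
    families are kept pairwise more than 10 edits apart so concentrate
    clusters can never merge; a parameter set that makes this separation
    impossible raises.
    """
    if min(n_genes, n_seed_singletons, n_contaminants, n_isoform_pairs) < 0:
        raise ValueError("counts must be non-negative")
    if copy_divergence_bp > 2:
        raise ValueError("copy_divergence_bp must be <= 2 (the concentrate tolerance)")
    if n_libraries < 2 and n_genes + n_contaminants > 0:
        raise ValueError("multi-library genes need at least 2 libraries")
    if n_isoform_pairs * 2 > n_genes:
        raise ValueError("not enough genes to pair into isoforms")
    pedigree = dict(pedigree) if pedigree is not None else dict(DEFAULT_PEDIGREE)
    for line, members in pedigree.items():
        unknown = set(members) - set(accessions)
        if unknown:
            raise ValueError(f"pedigree line {line} names unknown accessions {unknown}")
    rng = random.Random(seed)
    library_ids = [f"L{i:02d}" for i in range(1, n_libraries + 1)]
    counters = {lib: 0 for lib in library_ids}

    def new_contig_id(lib: str) -> str:
        counters[lib] += 1
        return f"{lib}_c{counters[lib]:04d}"

    existing_cds: list[str] = []

    def plant_cds() -> str:
        for _ in range(200):
            cds = _random_cds(rng)
            if _well_separated(cds, existing_cds):
                existing_cds.append(cds)
                return cds
        raise RuntimeError(
            "could not plant a gene family separated by more than "
            f"{GENE_SEPARATION_BP} edits from the existing ones"
        )

    genes: list[GeneFixture] = []

    def plant_gene(gene_id: str, kind: str, superkingdom: str, n_libs: int,
                   cds: str | None = None) -> GeneFixture:
        if cds is None:
            cds = plant_cds()
        else:
            existing_cds.append(cds)
        gene = GeneFixture(gene_id, cds, _translate_cds(cds), kind, superkingdom)
        libs = rng.sample(library_ids, n_libs)
        for j, lib in enumerate(libs):
            if j == 0:
                seq, n_edits = cds, 0
            else:
                n_edits = rng.randrange(copy_divergence_bp + 1)
                seq = _apply_edits(rng, cds, n_edits)
            gene.copies.append(
                CopyFixture(lib, new_contig_id(lib), seq, n_edits, j == 0)
            )
        genes.append(gene)
        return gene

    isoform_pairs: list[tuple[str, str, int]] = []
    block_donors: list[GeneFixture] = []
    for i in range(n_genes):
        n_libs = rng.randrange(2, n_libraries + 1)
        gene = plant_gene(f"G{i + 1:03d}", "gene", "Eukaryota", n_libs)
        block_donors.append(gene)

    # isoform pairs: rewrite the second gene of each pair to embed a
    # codon-aligned block of the first, long enough to exceed the 150 bp rule
    for p in range(n_isoform_pairs):
        a, b = block_donors[2 * p], block_donors[2 * p + 1]
        block_bp = 3 * rng.randrange(60, min(150, len(a.cds) // 3) )
        start = 3 * rng.randrange(0, (len(a.cds) - block_bp) // 3 + 1)
        block = a.cds[start : start + block_bp]
        prefix = _random_cds(rng, 150, 450)
        suffix = _random_cds(rng, 150, 450)
        new_cds = prefix + block + suffix
        # regenerate b's copies from the rewritten CDS
        b.cds, b.protein = new_cds, _translate_cds(new_cds)
        for j, c in enumerate(b.copies):
            if j == 0:
                c.sequence, c.n_edits = new_cds, 0
            else:
                c.n_edits = rng.randrange(copy_divergence_bp + 1)
                c.sequence = _apply_edits(rng, new_cds, c.n_edits)
        isoform_pairs.append((a.gene_id, b.gene_id, block_bp))

    for i in range(n_seed_singletons):
        plant_gene(f"S{i + 1:03d}", "singleton", "Eukaryota", 1)
    for i in range(n_contaminants):
        superkingdom = rng.choice(("Bacteria", "Archaea", "Viruses"))
        plant_gene(f"X{i + 1:03d}", "contaminant", superkingdom, min(2, n_libraries))

    planted_sites = _plant_variant_sites(
        rng, genes, list(accessions), pedigree,
        n_specific_per_line, n_filter_fail_per_line,
    )
    return FixtureManifest(
        seed=seed,
        library_ids=library_ids,
        genes=genes,
        isoform_pairs=isoform_pairs,
        accessions=list(accessions),
        pedigree={k: tuple(v) for k, v in pedigree.items()},
        planted_sites=planted_sites,
    )


def _plant_variant_sites(
    rng: random.Random,
    genes: list[GeneFixture],
    accessions: list[str],
    pedigree: dict[str, tuple[str, ...]],
    n_specific_per_line: int,
    n_filter_fail_per_line: int,
) -> list[PlantedSite]:
    hosts = [g for g in genes if g.kind in ("gene", "singleton")]
    if not hosts or not pedigree:
        return []
    sites: list[PlantedSite] = []
    used: set[tuple[str, int]] = set()

    def place(carriers: tuple[str, ...], qual: float, depth: int,
              passes: bool, line: str | None) -> None:
        host = rng.choice(hosts).representative()
        for _ in range(50):
            pos = rng.randrange(1, len(host.sequence) + 1)
            if (host.contig_id, pos) not in used:
                break
        used.add((host.contig_id, pos))
        ref = host.sequence[pos - 1]
        alt = rng.choice([b for b in "ACGT" if b != ref])
        sites.append(
            PlantedSite(host.contig_id, pos, ref, alt, carriers,
                        qual, depth, passes, line)
        )

    for line, members in pedigree.items():
        for _ in range(n_specific_per_line):
            place(tuple(members), rng.uniform(30, 60), rng.randrange(5, 21),
                  True, line)
        for i in range(n_filter_fail_per_line):
            # alternate the failing field, exercising both strict boundaries
            if i % 2 == 0:
                qual, depth = 20.0, rng.randrange(5, 21)
            else:
                qual, depth = rng.uniform(30, 60), 3
            place(tuple(members), qual, depth, False, line)
    # non-specific background: alt present in every accession
    for _ in range(3):
        place(tuple(accessions), rng.uniform(30, 60), rng.randrange(5, 21),
              True, None)
    return sites


# ---------------------------------------------------------------------------
# hit tables by construction


def _surrogate_scores(matches: int) -> tuple[float, float]:
    """(e-value, bit score) surrogates; only their ordering matters."""
    return (10.0 ** (-matches / 10.0), 2.0 * matches)


def generate_hit_tables(manifest: FixtureManifest) -> dict:
    """Emit every hit table the pipeline consumes, from planted coordinates.

    Returns a dict with per-library ``forward``/``reverse`` protein-space
    tables, the pooled nucleotide ``extend`` table (anchor seeds vs all
    copies), the ``taxonomy_hits`` table (copies vs database subjects) and
    the ``self_hits`` table for isoform detection (planted pairs plus
    sub-threshold decoys).
    """
    forward: dict[str, list[HspRecord]] = {lib: [] for lib in manifest.library_ids}
    reverse: dict[str, list[HspRecord]] = {lib: [] for lib in manifest.library_ids}
    extend: list[HspRecord] = []
    taxonomy_hits: list[HspRecord] = []
    for gene in manifest.genes:
        aa_len = len(gene.protein)
        anchor = next(c for c in gene.copies if c.is_anchor)
        for copy in gene.copies:
            matches_aa = max(1, aa_len - copy.n_edits)
            pident = 100.0 * matches_aa / aa_len
            evalue, bit = _surrogate_scores(matches_aa)
            forward[copy.library_id].append(
                HspRecord(copy.contig_id, gene.reference_id, round(pident, 2),
                          aa_len, copy.n_edits, 0,
                          1, len(copy.sequence), 1, aa_len, evalue, bit)
            )
            reverse[copy.library_id].append(
                HspRecord(gene.reference_id, copy.contig_id, round(pident, 2),
                          aa_len, copy.n_edits, 0,
                          1, aa_len, 1, len(copy.sequence), evalue, bit)
            )
            nt_len = min(len(anchor.sequence), len(copy.sequence))
            matches_nt = max(1, nt_len - copy.n_edits)
            pident_nt = 100.0 * matches_nt / nt_len
            ev_nt, bit_nt = _surrogate_scores(matches_nt)
            extend.append(
                HspRecord(anchor.contig_id, copy.contig_id, round(pident_nt, 2),
                          nt_len, copy.n_edits, 0,
                          1, nt_len, 1, nt_len, ev_nt, bit_nt)
            )
            taxonomy_hits.append(
                HspRecord(copy.contig_id, gene.nr_subject_id, round(pident, 2),
                          aa_len, copy.n_edits, 0,
                          1, len(copy.sequence), 1, aa_len, evalue, bit)
            )
    self_hits: list[HspRecord] = []
    by_id = {g.gene_id: g for g in manifest.genes}
    for a_id, b_id, block_bp in manifest.isoform_pairs:
        rep_a = by_id[a_id].representative()
        rep_b = by_id[b_id].representative()
        ev, bit = _surrogate_scores(block_bp)
        self_hits.append(
            HspRecord(rep_a.contig_id, rep_b.contig_id, 99.0, block_bp,
                      int(block_bp * 0.01), 0, 1, block_bp, 1, block_bp, ev, bit)
        )
    # sub-threshold decoys between the first two non-paired representatives:
    # short HSP at high identity, long HSP at low identity
    paired = {g for pair in manifest.isoform_pairs for g in pair[:2]}
    free = [g for g in manifest.genes if g.kind == "gene" and g.gene_id not in paired]
    if len(free) >= 2:
        r1, r2 = free[0].representative(), free[1].representative()
        ev, bit = _surrogate_scores(120)
        self_hits.append(
            HspRecord(r1.contig_id, r2.contig_id, 99.0, 120, 1, 0,
                      1, 120, 1, 120, ev, bit)
        )
        ev, bit = _surrogate_scores(180)
        self_hits.append(
            HspRecord(r1.contig_id, r2.contig_id, 85.0, 200, 30, 0,
                      1, 200, 1, 200, ev, bit)
        )
    return {
        "forward": forward,
        "reverse": reverse,
        "extend": extend,
        "taxonomy_hits": taxonomy_hits,
        "self_hits": self_hits,
    }


# ---------------------------------------------------------------------------
# VCF emission


def variant_sites_by_accession(
    manifest: FixtureManifest,
) -> dict[str, list[VariantSite]]:
    """In-memory per-accession variant sites (one single-sample set each).

    An accession's set contains only the sites where it carries the alt
    call, mirroring per-accession VCFs from a set-intersection workflow.
    """
    out: dict[str, list[VariantSite]] = {a: [] for a in manifest.accessions}
    for s in manifest.planted_sites:
        for acc in s.carriers:
            out[acc].append(
                VariantSite(
                    contig_id=s.contig_id, pos=s.pos, ref=s.ref,
                    alts=(s.alt,), qual=s.qual, depth=s.depth,
                    genotypes={acc: (0, 1)},
                )
            )
    for sites in out.values():
        sites.sort(key=lambda s: (s.contig_id, s.pos))
    return out


def write_pedigree_vcfs(manifest: FixtureManifest, out_dir: str | Path) -> dict[str, Path]:
    """Write one plain-text single-sample VCF per accession."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    lengths = {
        c.contig_id: len(c.sequence)
        for g in manifest.genes for c in g.copies
    }
    sites_by_acc = variant_sites_by_accession(manifest)
    paths: dict[str, Path] = {}
    for acc, sites in sites_by_acc.items():
        path = out_dir / f"{acc}.vcf"
        contigs = sorted({s.contig_id for s in sites})
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            fh.write('##INFO=<ID=DP,Number=1,Type=Integer,Description="Total depth">\n')
            fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
            for c in contigs:
                fh.write(f"##contig=<ID={c},length={lengths[c]}>\n")
            fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{acc}\n")
            for s in sites:
                fh.write(
                    f"{s.contig_id}\t{s.pos}\t.\t{s.ref}\t{','.join(s.alts)}\t"
                    f"{s.qual:g}\t.\tDP={s.depth}\tGT\t0/1\n"
                )
        paths[acc] = path
    return paths


# ---------------------------------------------------------------------------
# writing the whole fixture to disk


def write_fixture(manifest: FixtureManifest, out_dir: str | Path) -> dict[str, Path]:
    """Write every input file of the pipeline: per-library FASTA, reference
    protein FASTA, all hit tables, the taxonomy map, per-accession VCFs and
    the truth manifest JSON. Returns a name -> path map."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    by_lib: dict[str, list[ContigRecord]] = {lib: [] for lib in manifest.library_ids}
    for rec in manifest.all_contigs():
        by_lib[rec.library_id].append(rec)
    for lib, records in by_lib.items():
        p = out_dir / f"{lib}.fasta"
        write_fasta(sorted(records, key=lambda r: r.contig_id), p)
        paths[f"library:{lib}"] = p
    ref_path = out_dir / "reference_proteins.fasta"
    write_fasta(
        [ContigRecord(g.reference_id, "ref", g.protein) for g in manifest.genes],
        ref_path,
    )
    paths["reference"] = ref_path
    tables = generate_hit_tables(manifest)
    for lib in manifest.library_ids:
        p = out_dir / f"forward_{lib}.tsv"
        write_hit_table(tables["forward"][lib], p)
        paths[f"forward:{lib}"] = p
        p = out_dir / f"reverse_{lib}.tsv"
        write_hit_table(tables["reverse"][lib], p)
        paths[f"reverse:{lib}"] = p
    for name in ("extend", "taxonomy_hits", "self_hits"):
        p = out_dir / f"{name}.tsv"
        write_hit_table(tables[name], p)
        paths[name] = p
    tax_path = out_dir / "taxonomy.tsv"
    with open(tax_path, "w") as fh:
        for subject, kingdom in sorted(manifest.taxonomy_map().items()):
            fh.write(f"{subject}\t{kingdom}\n")
    paths["taxonomy"] = tax_path
    for acc, p in write_pedigree_vcfs(manifest, out_dir / "vcf").items():
        paths[f"vcf:{acc}"] = p
    manifest_path = out_dir / "manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(manifest.to_json(), fh, indent=2, sort_keys=True)
    paths["manifest"] = manifest_path
    return paths
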