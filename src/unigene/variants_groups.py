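"""Variant filtering and pedigree-aware group-specific site selection.

A group-specific variant is a site whose alternate allele is present in
every accession of a defined include set and absent from every other
accession — the presence/absence bitmask semantics of VCF set-intersection
tools. Presence is genotype-based: any called alternate allele counts,
heterozygous included; the pipeline works from called VCFs, not from raw
allele depths.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Hashable, Iterable, Mapping, Sequence

from .io_formats import VariantSite

SiteKey = Hashable


@dataclass(frozen=True)
class GroupPattern:
    """Accessions that must carry the alternate allele (include) and those
    that must not (exclude). When exclude is empty it defaults to the
    complement of include within the accession universe."""

    include: frozenset[str]
    exclude: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not self.include:
            raise ValueError("include set must be non-empty")
        if self.include & self.exclude:
            raise ValueError("include and exclude must be disjoint")


def filter_variants(
    sites: Iterable[VariantSite], qual_min: float = 20.0, dp_min: int = 3
) -> list[VariantSite]:
    """Keep sites with QUAL strictly above *qual_min* and depth strictly
    above *dp_min*; a site with missing depth fails."""
    return [
        s
        for s in sites
        if s.qual > qual_min and s.depth is not None and s.depth > dp_min
    ]


def has_alt_allele(
    site: VariantSite, accession: str, collapse_multiallelic: bool = True
) -> bool:
    """Whether *accession*'s genotype at *site* carries an alternate allele.

    With ``collapse_multiallelic`` (default) any allele index >= 1 counts as
    present; otherwise only allele index 1 does.
    """
    gt = site.genotypes.get(accession)
    if gt is None:
        return False
    threshold_ok = (
        (lambda a: a is not None and a >= 1)
        if collapse_multiallelic
        else (lambda a: a == 1)
    )
    return any(threshold_ok(a) for a in gt)


def presence_map(
    sites_by_accession: Mapping[str, Sequence[VariantSite]],
    collapse_multiallelic: bool = True,
) -> dict[str, set[SiteKey]]:
    """accession -> set of (contig, pos) keys where it carries an alt allele.

    Accepts one single-accession site list per accession (one VCF each) or
    repeated multi-sample lists; only the named accession's genotype is
    consulted in each list.
    """
    out: dict[str, set[SiteKey]] = {}
    for accession, sites in sites_by_accession.items():
        out[accession] = {
            s.key
            for s in sites
            if has_alt_allele(s, accession, collapse_multiallelic)
        }
    return out


def group_specific_sites(
    per_accession_presence: Mapping[str, set[SiteKey]],
    pattern: GroupPattern,
    universe: Iterable[str],
) -> set[SiteKey]:
    """Sites whose alt allele is present in every include accession and
    absent from every excluded one (default: the whole complement of the
    include set)."""
    universe = set(universe)
    unknown = (pattern.include | pattern.exclude) - universe
    if unknown:
        raise ValueError(f"pattern names unknown accessions: {sorted(unknown)}")
    exclude = pattern.exclude or (universe - pattern.include)
    selected = set.intersection(
        *(per_accession_presence.get(a, set()) for a in pattern.include)
    )
    for a in exclude:
        selected -= per_accession_presence.get(a, set())
    return selected


def per_line_specific_counts(
    sites_by_accession: Mapping[str, Sequence[VariantSite]],
    pedigree_patterns: Mapping[str, GroupPattern],
    qual_min: float = 20.0,
    dp_min: int = 3,
    collapse_multiallelic: bool = True,
) -> dict[str, int]:
    """Number of group-specific variants per parental line.

    Applies the QUAL/DP filter to each accession's sites, builds the
    presence bitmask, and counts the sites matching each line's pattern.
    """
    filtered = {
        acc: filter_variants(sites, qual_min, dp_min)
        for acc, sites in sites_by_accession.items()
    }
    presence = presence_map(filtered, collapse_multiallelic)
    universe = set(sites_by_accession)
    return {
        line: len(group_specific_sites(presence, pattern, universe))
        for line, pattern in pedigree_patterns.items()
    }


def write_selected_sites(
    sites: Iterable[VariantSite], selected_keys: set[SiteKey], path
) -> None:
    """VCF-like TSV of the selected sites (contig, pos, ref, alt, qual, dp)."""
    with open(path, "w") as fh:
        fh.write("contig_id\tpos\tref\talt\tqual\tdepth\n")
        for s in sorted(
            (s for s in sites if s.key in selected_keys),
            key=lambda s: (s.contig_id, s.pos),
        ):
            fh.write(
                f"{s.contig_id}\t{s.pos}\t{s.ref}\t{','.join(s.alts)}\t"
                f"{s.qual:g}\t{s.depth if s.depth is not None else '.'}\n"
            )


def write_count_table(counts: Mapping[str, int], path) -> None:
    with open(path, "w") as fh:
        fh.write("line\tspecific_variant_count\n")
        for line in sorted(counts):
            fh.write(f"{line}\t{counts[line]}\n")
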