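"""Readers and writers for the external formats the pipeline touches.

All coordinates are 1-based inclusive (the tabular BLAST convention); interval
algebra downstream keeps that convention and converts nowhere else.
Minus-strand subject hits are normalized (s_start <= s_end) and flagged rather
than rejected: transcript-vs-transcript searches legitimately hit both strands.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO

logger = logging.getLogger(__name__)

SUPERKINGDOMS = frozenset(
    {"Eukaryota", "Bacteria", "Archaea", "Viruses", "unclassified"}
)

#: column order of the 12-column tabular hit format
HIT_TABLE_COLUMNS = (
    "qseqid sseqid pident length mismatch gapopen "
    "qstart qend sstart send evalue bitscore"
).split()


@dataclass(frozen=True)
class ContigRecord:
    """One assembled transcript contig with its library of origin."""

    contig_id: str
    library_id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"empty sequence for contig {self.contig_id!r}")

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def key(self) -> tuple[str, str]:
        return (self.library_id, self.contig_id)


@dataclass(frozen=True)
class HspRecord:
    """One local-alignment segment (high-scoring segment pair).

    Coordinates are 1-based inclusive and normalized so start <= end on both
    axes; ``minus_strand`` records whether the raw row had s_start > s_end.
    """

    query_id: str
    subject_id: str
    percent_identity: float
    alignment_length: int
    mismatches: int
    gap_opens: int
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    evalue: float
    bit_score: float
    minus_strand: bool = False

    def __post_init__(self) -> None:
        if self.alignment_length < 1:
            raise ValueError("alignment_length must be >= 1")
        if self.q_start > self.q_end or self.s_start > self.s_end:
            raise ValueError("HspRecord coordinates must be normalized")

    @property
    def pair(self) -> tuple[str, str]:
        return (self.query_id, self.subject_id)


@dataclass(frozen=True)
class TaxonomyAnnotation:
    subject_id: str
    superkingdom: str

    def __post_init__(self) -> None:
        if self.superkingdom not in SUPERKINGDOMS:
            raise ValueError(
                f"superkingdom {self.superkingdom!r} not in {sorted(SUPERKINGDOMS)}"
            )


@dataclass
class VariantSite:
    """One called variant site with per-accession genotypes.

    ``depth`` is INFO/DP when present, else the sum of per-sample DP, else
    None (missing); a missing depth fails any depth filter.
    Genotype allele indices reference ref (0) and alts (1..); a missing call
    is represented by None entries.
    """

    contig_id: str
    pos: int
    ref: str
    alts: tuple[str, ...]
    qual: float
    depth: int | None
    genotypes: dict[str, tuple[int | None, int | None]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError("pos must be >= 1")
        if self.qual < 0:
            raise ValueError("qual must be >= 0")

    @property
    def key(self) -> tuple[str, int]:
        return (self.contig_id, self.pos)


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path, library_id: str = "") -> list[ContigRecord]:
    """Read a FASTA file into contig records labelled with *library_id*.

    Sequences are uppercased. Duplicate ids and empty sequences are hard
    errors; an empty file yields an empty list with a warning.
    """
    path = Path(path)
    records: list[ContigRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate sequence id {rec.id!r} in {path}")
        seen.add(rec.id)
        seq = str(rec.seq).upper()
        if not seq:
            raise ValueError(f"empty sequence {rec.id!r} in {path}")
        records.append(ContigRecord(rec.id, library_id, seq))
    if not records:
        logger.warning("no sequences found in %s", path)
    return records


def write_fasta(records: Iterable[ContigRecord], path: str | Path, width: int = 70) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.contig_id}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# 12-column tabular hit format


def _parse_hit_row(fieldsrow: Sequence[str], lineno: int) -> HspRecord:
    if len(fieldsrow) != 12:
        raise ValueError(
            f"line {lineno}: expected 12 tab-separated columns, got {len(fieldsrow)}"
        )
    try:
        (qseqid, sseqid, pident, length, mismatch, gapopen,
         qstart, qend, sstart, send, evalue, bitscore) = fieldsrow
        pident_f = float(pident)
        length_i = int(length)
        mismatch_i = int(mismatch)
        gapopen_i = int(gapopen)
        qs, qe = int(qstart), int(qend)
        ss, se = int(sstart), int(send)
        evalue_f = float(evalue)
        bitscore_f = float(bitscore)
    except ValueError as exc:
        raise ValueError(f"line {lineno}: malformed hit row ({exc})") from None
    if qs > qe:
        qs, qe = qe, qs
    minus = ss > se
    if minus:
        ss, se = se, ss
    return HspRecord(
        query_id=qseqid, subject_id=sseqid, percent_identity=pident_f,
        alignment_length=length_i, mismatches=mismatch_i, gap_opens=gapopen_i,
        q_start=qs, q_end=qe, s_start=ss, s_end=se,
        evalue=evalue_f, bit_score=bitscore_f, minus_strand=minus,
    )


def read_hit_table(path: str | Path) -> list[HspRecord]:
    """Read a 12-column tabular hit file, normalizing coordinates.

    Rows with s_start > s_end are flagged ``minus_strand`` and their subject
    range normalized. Malformed rows raise with the offending line number.
    """
    path = Path(path)
    out: list[HspRecord] = []
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "rt") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            out.append(_parse_hit_row(line.split("\t"), lineno))
    return out


def write_hit_table(hsps: Iterable[HspRecord], path: str | Path) -> None:
    """Write hit records back to the 12-column format (minus strand restored)."""
    with open(path, "w") as fh:
        for h in hsps:
            ss, se = (h.s_end, h.s_start) if h.minus_strand else (h.s_start, h.s_end)
            fh.write(
                "\t".join(
                    str(x)
                    for x in (
                        h.query_id, h.subject_id, f"{h.percent_identity:.2f}",
                        h.alignment_length, h.mismatches, h.gap_opens,
                        h.q_start, h.q_end, ss, se,
                        f"{h.evalue:.2e}", f"{h.bit_score:.1f}",
                    )
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# taxonomy map


def read_taxonomy_map(path: str | Path) -> dict[str, str]:
    """Read a 2-column TSV (subject_id, superkingdom) into a dict.

    Repeated subject ids keep the last row (logged); unknown superkingdom
    labels are a hard error.
    """
    mapping: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"line {lineno}: expected 2 columns")
            subject_id, superkingdom = parts
            if superkingdom not in SUPERKINGDOMS:
                raise ValueError(
                    f"line {lineno}: unknown superkingdom {superkingdom!r}"
                )
            if subject_id in mapping:
                logger.info(
                    "taxonomy map: subject %s re-annotated %s -> %s (last wins)",
                    subject_id, mapping[subject_id], superkingdom,
                )
            mapping[subject_id] = superkingdom
    return mapping


# ---------------------------------------------------------------------------
# VCF


def read_vcf(path: str | Path) -> list[VariantSite]:
    """Read a VCF 4.x file (plain or bgzipped) into variant sites.

    QUAL and site depth (INFO/DP, falling back to the sum of per-sample DP)
    are extracted; sample names are preserved as genotype keys. A file in
    which no site carries any DP logs one warning; such sites have
    depth=None and fail any depth filter.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    sites: list[VariantSite] = []
    warned_dp = False
    for v in vcf:
        depth: int | None = None
        info_dp = v.INFO.get("DP")
        if info_dp is not None:
            depth = int(info_dp)
        else:
            try:
                fmt_dp = v.format("DP")
            except KeyError:
                fmt_dp = None
            if fmt_dp is not None:
                total = int(fmt_dp[fmt_dp >= 0].sum())
                depth = total
        if depth is None and not warned_dp:
            logger.warning("%s: sites without any DP field; depth treated as missing", path)
            warned_dp = True
        genotypes: dict[str, tuple[int | None, int | None]] = {}
        for name, gt in zip(samples, v.genotypes):
            a0 = None if gt[0] < 0 else int(gt[0])
            a1 = None if len(gt) < 2 or gt[1] < 0 else int(gt[1])
            genotypes[name] = (a0, a1)
        sites.append(
            VariantSite(
                contig_id=v.CHROM,
                pos=v.POS,
                ref=v.REF,
                alts=tuple(v.ALT),
                qual=float(v.QUAL) if v.QUAL is not None else 0.0,
                depth=depth,
                genotypes=genotypes,
            )
        )
    return sites


def contig_lengths(records: Iterable[ContigRecord]) -> dict[str, int]:
    """Map contig_id -> length for a collection of records."""
    return {r.contig_id: r.length for r in records}
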