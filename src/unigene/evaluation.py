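"""Mutual-coverage tables between transcript sets and read-mapping rates.

Mutual coverage asks, for two transcript sets A and B searched against each
other, how many sequences of each set are covered over a threshold fraction
of their length by some single sequence of the other set. Per-pair coverage
merges that pair's HSPs; per-sequence coverage is the best single partner,
not the union over partners — segments of different partners need not tile
one transcript. Counting is strict (> threshold).
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Sequence

from .hsp_algebra import group_by_pair, merge_intervals, pair_coverage
from .io_formats import HspRecord


@dataclass(frozen=True)
class CoverageTableRow:
    """One source set's mutual coverage against a reference set."""

    source_name: str
    covered_by_count: int
    covered_by_pct: float
    cover_to_count: int
    cover_to_pct: float
    denominator_source: int
    denominator_target: int
    threshold: float


def percentage(count: int, denominator: int) -> float:
    """100*count/denominator, rounded half-up to 2 decimals."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    if not (0 <= count <= denominator):
        raise ValueError("count must satisfy 0 <= count <= denominator")
    pct = Decimal(100) * Decimal(count) / Decimal(denominator)
    return float(pct.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def _best_coverage_per_sequence(
    hits_as_query: Sequence[HspRecord],
    hits_as_subject: Sequence[HspRecord],
    lengths: Mapping[str, int],
    union_over_partners: bool = False,
) -> dict[str, float]:
    """Per-sequence coverage fraction on its own axis.

    A sequence may appear as the query of one search and the subject of the
    reciprocal one; both tables contribute. Default: max over partners of
    the merged per-pair coverage. ``union_over_partners=True`` merges
    intervals across all partners instead.
    """
    per_pair: dict[str, dict[str, list[tuple[int, int]]]] = {}
    for h in hits_as_query:
        per_pair.setdefault(h.query_id, {}).setdefault(h.subject_id, []).append(
            (h.q_start, h.q_end)
        )
    for h in hits_as_subject:
        per_pair.setdefault(h.subject_id, {}).setdefault(h.query_id, []).append(
            (h.s_start, h.s_end)
        )
    out: dict[str, float] = {}
    for seq_id, partners in per_pair.items():
        if seq_id not in lengths:
            raise KeyError(f"length unknown for sequence {seq_id!r}")
        length = lengths[seq_id]
        if union_over_partners:
            ivs = [iv for ivlist in partners.values() for iv in ivlist]
            cov = sum(e - s + 1 for s, e in merge_intervals(ivs)) / length
        else:
            cov = max(
                sum(e - s + 1 for s, e in merge_intervals(ivs)) / length
                for ivs in partners.values()
            )
        out[seq_id] = cov
    return out


def mutual_coverage(
    set_a_ids: Iterable[str],
    set_b_ids: Iterable[str],
    hits_a_vs_b: Sequence[HspRecord],
    hits_b_vs_a: Sequence[HspRecord],
    lengths: Mapping[str, int],
    threshold: float = 0.75,
    source_name: str = "source",
    union_over_partners: bool = False,
) -> CoverageTableRow:
    """Mutual coverage between a reference set A and a source set B.

    ``covered_by``: sequences of B whose best-partner merged coverage by A
    exceeds *threshold* (strict). ``cover_to``: likewise for sequences of A
    covered by B. Denominators are the full set sizes, so the percentages
    are fractions of each complete set.
    """
    set_a = set(set_a_ids)
    set_b = set(set_b_ids)
    cov_b = _best_coverage_per_sequence(
        [h for h in hits_b_vs_a if h.query_id in set_b],
        [h for h in hits_a_vs_b if h.subject_id in set_b],
        lengths, union_over_partners,
    )
    cov_a = _best_coverage_per_sequence(
        [h for h in hits_a_vs_b if h.query_id in set_a],
        [h for h in hits_b_vs_a if h.subject_id in set_a],
        lengths, union_over_partners,
    )
    covered_by = sum(1 for v in cov_b.values() if v > threshold)
    cover_to = sum(1 for v in cov_a.values() if v > threshold)
    return CoverageTableRow(
        source_name=source_name,
        covered_by_count=covered_by,
        covered_by_pct=percentage(covered_by, len(set_b)),
        cover_to_count=cover_to,
        cover_to_pct=percentage(cover_to, len(set_a)),
        denominator_source=len(set_b),
        denominator_target=len(set_a),
        threshold=threshold,
    )


def mapping_rate(total_reads: int, unmapped_reads: int) -> float:
    """Fraction of reads mapped: 1 - unmapped/total."""
    if total_reads <= 0:
        raise ValueError("total_reads must be positive")
    if not (0 <= unmapped_reads <= total_reads):
        raise ValueError("unmapped_reads must be in [0, total_reads]")
    return 1.0 - unmapped_reads / total_reads


def write_coverage_table(rows: Sequence[CoverageTableRow], path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "source\tcovered_by_count\tcovered_by_pct\t"
            "cover_to_count\tcover_to_pct\tn_source\tn_target\tthreshold\n"
        )
        for r in rows:
            fh.write(
                f"{r.source_name}\t{r.covered_by_count}\t{r.covered_by_pct:.2f}\t"
                f"{r.cover_to_count}\t{r.cover_to_pct:.2f}\t"
                f"{r.denominator_source}\t{r.denominator_target}\t{r.threshold}\n"
            )


def write_mapping_rates(
    counts: Mapping[str, tuple[int, int]], path
) -> None:
    """TSV of (library, total, unmapped, rate) from pre-counted read totals."""
    with open(path, "w") as fh:
        fh.write("library\ttotal_reads\tunmapped_reads\tmapping_rate\n")
        for library in sorted(counts):
            total, unmapped = counts[library]
            fh.write(
                f"{library}\t{total}\t{unmapped}\t{mapping_rate(total, unmapped):.4f}\n"
            )
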