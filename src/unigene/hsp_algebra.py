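"""Interval algebra over local-alignment segments (HSPs).

A similarity search reports several HSPs per query-subject pair; coverage of
either sequence is computed by merging those segments into maximal disjoint
intervals on the chosen axis and dividing the covered length by the axis
length. Intervals are 1-based inclusive throughout; adjacent intervals
(end + 1 == next start) coalesce, since together they cover a contiguous run
of positions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

from .io_formats import HspRecord

Axis = Literal["query", "subject"]

Interval = tuple[int, int]


@dataclass(frozen=True)
class MergedCoverage:
    """Merged-interval coverage of one query-subject pair on one axis."""

    pair: tuple[str, str]
    merged_intervals: tuple[Interval, ...]
    axis_length: int

    @property
    def covered_length(self) -> int:
        return sum(e - s + 1 for s, e in self.merged_intervals)

    @property
    def ratio(self) -> float:
        return self.covered_length / self.axis_length


def merge_intervals(intervals: Iterable[Interval]) -> list[Interval]:
    """Union of 1-based inclusive intervals as maximal disjoint intervals.

    Adjacent intervals coalesce. An interval with start > end is an error.
    """
    ivs = sorted(intervals)
    for s, e in ivs:
        if s > e:
            raise ValueError(f"invalid interval ({s}, {e}): start > end")
    merged: list[Interval] = []
    for s, e in ivs:
        if merged and s <= merged[-1][1] + 1:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def covered_length(intervals: Iterable[Interval]) -> int:
    return sum(e - s + 1 for s, e in merge_intervals(intervals))


def pair_coverage(
    hsps: Sequence[HspRecord], axis: Axis, axis_length: int
) -> MergedCoverage:
    """Merged coverage of one query-subject pair on the query or subject axis.

    All records must share one (query_id, subject_id) pair.
    """
    if axis_length < 1:
        raise ValueError("axis_length must be >= 1")
    pairs = {h.pair for h in hsps}
    if len(pairs) > 1:
        raise ValueError(f"mixed query-subject pairs: {sorted(pairs)}")
    pair = hsps[0].pair if hsps else ("", "")
    if axis == "query":
        ivs = [(h.q_start, h.q_end) for h in hsps]
    elif axis == "subject":
        ivs = [(h.s_start, h.s_end) for h in hsps]
    else:
        raise ValueError(f"axis must be 'query' or 'subject', got {axis!r}")
    return MergedCoverage(pair, tuple(merge_intervals(ivs)), axis_length)


def passes_seed_filters(
    hsps: Sequence[HspRecord],
    subject_length: int,
    min_ratio: float = 0.5,
    min_hsp_aa: int = 20,
    raw_sum: bool = False,
) -> bool:
    """Seed-selection pre-filter for one contig-vs-protein pair.

    HSPs shorter than *min_hsp_aa* (alignment length, amino acids) are
    discarded first; the survivors' merged subject coverage must then reach
    *min_ratio* (inclusive). The order matters: filtering rows first is the
    only order under which both thresholds act independently.

    ``raw_sum=True`` replaces merged coverage by the raw sum of HSP lengths
    (which can exceed 100%); the default merges, so coverage is a true ratio.
    """
    kept = [h for h in hsps if h.alignment_length >= min_hsp_aa]
    if not kept:
        return False
    if raw_sum:
        ratio = sum(h.alignment_length for h in kept) / subject_length
    else:
        ratio = pair_coverage(kept, "subject", subject_length).ratio
    return ratio >= min_ratio


def group_by_pair(hsps: Iterable[HspRecord]) -> dict[tuple[str, str], list[HspRecord]]:
    """Bucket hit rows by (query_id, subject_id)."""
    groups: dict[tuple[str, str], list[HspRecord]] = {}
    for h in hsps:
        groups.setdefault(h.pair, []).append(h)
    return groups
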