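"""Pure sequence computations: six-frame longest-ORF translation and
k-bounded edit distance.

An ORF here is a maximal stop-free run of codons (stop-to-stop); no start
codon is required, because de novo contigs are frequently 5'-truncated and an
ATG requirement would discard valid fragments. Any codon containing a
non-ACGT symbol translates to 'X' — conservative and deterministic for IUPAC
ambiguity codes.
"""

from __future__ import annotations

from dataclasses import dataclass

import edlib
from Bio.Data.CodonTable import standard_dna_table

#: sentinel returned when the edit distance exceeds the bound
EXCEEDS = "EXCEEDS"

_CODON_TABLE = dict(standard_dna_table.forward_table)
_STOP_CODONS = frozenset(standard_dna_table.stop_codons)

_COMPLEMENT = str.maketrans(
    "ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN"
)

#: frame evaluation order; ties in ORF length resolve in this order
FRAME_ORDER = (1, 2, 3, -1, -2, -3)


def reverse_complement(dna: str) -> str:
    return dna.translate(_COMPLEMENT)[::-1]


def translate_codon(codon: str) -> str:
    """Translate one codon with the standard code; '*' for stops, 'X' when
    the codon contains any symbol outside ACGT."""
    if any(c not in "ACGT" for c in codon):
        return "X"
    if codon in _STOP_CODONS:
        return "*"
    return _CODON_TABLE[codon]


@dataclass(frozen=True)
class OrfResult:
    """Longest open reading frame of a contig.

    ``frame`` is one of +1,+2,+3 (forward) or -1,-2,-3 (reverse complement);
    ``nt_start``/``nt_end`` are 1-based inclusive coordinates on the input
    contig (forward-strand coordinates for minus frames too).
    """

    protein: str
    frame: int
    nt_start: int
    nt_end: int

    def __post_init__(self) -> None:
        if 3 * len(self.protein) != self.nt_end - self.nt_start + 1:
            raise ValueError("ORF span must equal 3x protein length")


def _frame_orfs(strand_seq: str, offset: int) -> list[tuple[str, int, int]]:
    """Maximal stop-free codon runs of one frame.

    Returns (protein, start, end) with 1-based inclusive coordinates on
    *strand_seq*. ``offset`` is 0, 1 or 2.
    """
    n = len(strand_seq)
    orfs: list[tuple[str, int, int]] = []
    aa: list[str] = []
    run_start = None
    for i in range(offset, n - 2, 3):
        codon = strand_seq[i : i + 3]
        sym = translate_codon(codon)
        if sym == "*":
            if aa:
                orfs.append(("".join(aa), run_start + 1, i))
            aa, run_start = [], None
        else:
            if not aa:
                run_start = i
            aa.append(sym)
    if aa:
        orfs.append(("".join(aa), run_start + 1, run_start + 3 * len(aa)))
    return orfs


def longest_orf(dna: str) -> OrfResult:
    """Scan all six frames and return the longest ORF.

    Ties break by frame order +1,+2,+3,-1,-2,-3, then by smaller nt_start on
    the input contig. Raises on input shorter than one codon.
    """
    dna = dna.upper()
    n = len(dna)
    if n < 3:
        raise ValueError("sequence too short: need at least 3 nucleotides")
    rc = reverse_complement(dna)
    best: OrfResult | None = None
    for frame in FRAME_ORDER:
        strand_seq = dna if frame > 0 else rc
        offset = abs(frame) - 1
        for protein, start, end in _frame_orfs(strand_seq, offset):
            if frame > 0:
                nt_start, nt_end = start, end
            else:
                # map reverse-complement coordinates back to the input strand
                nt_start, nt_end = n - end + 1, n - start + 1
            cand = OrfResult(protein, frame, nt_start, nt_end)
            if (
                best is None
                or len(cand.protein) > len(best.protein)
                or (
                    len(cand.protein) == len(best.protein)
                    and FRAME_ORDER.index(frame) == FRAME_ORDER.index(best.frame)
                    and cand.nt_start < best.nt_start
                )
            ):
                best = cand
    assert best is not None  # every frame yields at least a possibly-empty run
    if not best.protein:
        # all codons are stops in every frame; return the empty ORF of frame +1
        return OrfResult("", 1, 1, 0)
    return best


def bounded_edit_distance(a: str, b: str, k: int = 2, end_gap_free: bool = False):
    """Unit-cost Levenshtein distance if <= *k*, else the EXCEEDS sentinel.

    Global by default: the tolerance counts every mismatch and gap over the
    full lengths of both sequences. With ``end_gap_free=True`` the shorter
    sequence is aligned infix-style (gaps at the ends of the longer sequence
    are free) — an alternative reading of the tolerance for partially
    overlapping contigs.

    A length difference greater than *k* short-circuits to EXCEEDS; otherwise
    the distance is computed in a band of width 2k+1 (delegated to edlib's
    k-bounded aligner).
    """
    if k < 0:
        raise ValueError("k must be >= 0")
    if not end_gap_free and abs(len(a) - len(b)) > k:
        return EXCEEDS
    if not a or not b:
        # d("", x) = len(x); infix mode: the empty string matches anywhere
        d = 0 if (end_gap_free and (not a) != (not b)) else len(a) + len(b)
        return d if d <= k else EXCEEDS
    if end_gap_free:
        query, target = (a, b) if len(a) <= len(b) else (b, a)
        res = edlib.align(query, target, mode="HW", task="distance", k=k)
    else:
        res = edlib.align(a, b, mode="NW", task="distance", k=k)
    d = res["editDistance"]
    return EXCEEDS if d == -1 else d
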