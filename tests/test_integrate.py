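"""Seed selection, concentrate clustering, rescue, taxonomy filter, merge
and isoform grouping."""

import itertools
import random

import pytest

from unigene.integrate import (
    IntegratedSet,
    IntegrationThresholds,
    cluster_candidates,
    concentrate,
    detect_isoforms,
    extend_paralogs,
    merge_sets,
    rescue_singletons,
    select_seeds,
    taxonomy_filter,
)
from unigene.io_formats import ContigRecord

from conftest import make_hsp

TH = IntegrationThresholds()


def full_hit(contig, gene, bit, aa_len=100, ev=None, reverse=False):
    """A full-protein-coverage hit row passing both seed filters."""
    ev = ev if ev is not None else 10.0 ** (-bit / 4)
    if reverse:
        return make_hsp(query_id=gene, subject_id=contig, bit_score=bit,
                        evalue=ev, alignment_length=aa_len,
                        q_start=1, q_end=aa_len, s_start=1, s_end=3 * aa_len)
    return make_hsp(query_id=contig, subject_id=gene, bit_score=bit,
                    evalue=ev, alignment_length=aa_len,
                    q_start=1, q_end=3 * aa_len, s_start=1, s_end=aa_len)


# ---------------------------------------------------------------------------
# seed selection


def test_select_seeds_picks_highest_bit_score():
    fwd = {"L1": [full_hit("c1", "g1", 180), full_hit("c2", "g1", 120)]}
    rev = {"L1": [full_hit("c1", "g1", 180, reverse=True),
                  full_hit("c2", "g1", 120, reverse=True)]}
    (a,) = select_seeds(fwd, rev, {"g1": 100}, TH)["L1"]
    assert (a.contig_id, a.reciprocal) == ("c1", True)


def test_select_seeds_non_reciprocal_excluded():
    # c1 is g1's best contig, but c1's best gene is g2
    fwd = {"L1": [full_hit("c1", "g1", 180), full_hit("c1", "g2", 200)]}
    rev = {"L1": [full_hit("c1", "g1", 180, reverse=True),
                  full_hit("c1", "g2", 200, reverse=True)]}
    by_gene = {a.reference_gene_id: a for a in
               select_seeds(fwd, rev, {"g1": 100, "g2": 100}, TH)["L1"]}
    assert not by_gene["g1"].reciprocal
    assert by_gene["g2"].reciprocal


def test_select_seeds_empty_table_warns(caplog):
    with caplog.at_level("WARNING"):
        out = select_seeds({"L1": []}, {"L1": []}, {}, TH)
    assert out == {"L1": []}
    assert "empty" in caplog.text


def _rbh_oracle(pairs):
    """Exhaustive reciprocal-best-hit enumeration over (contig, gene, bit)
    triples with distinct bit scores (one full-coverage HSP per pair)."""
    genes = {g for _, g, _ in pairs}
    contigs = {c for c, _, _ in pairs}
    best_contig = {
        g: max((p for p in pairs if p[1] == g), key=lambda p: p[2])[0]
        for g in genes
    }
    best_gene = {
        c: max((p for p in pairs if p[0] == c), key=lambda p: p[2])[1]
        for c in contigs
    }
    return {
        (best_contig[g], g) for g in genes if best_gene[best_contig[g]] == g
    }


def test_select_seeds_matches_exhaustive_rbh_enumeration():
    rng = random.Random(17)
    for _ in range(200):
        genes = [f"g{i}" for i in range(1, rng.randrange(2, 7))]
        contigs = [f"c{i}" for i in range(1, rng.randrange(2, 9))]
        possible = list(itertools.product(contigs, genes))
        chosen = rng.sample(possible, rng.randrange(1, len(possible) + 1))
        bits = rng.sample(range(100, 5000), len(chosen))
        pairs = [(c, g, float(b)) for (c, g), b in zip(chosen, bits)]
        fwd = {"L1": [full_hit(c, g, b) for c, g, b in pairs]}
        rev = {"L1": [full_hit(c, g, b, reverse=True) for c, g, b in pairs]}
        lengths = {g: 100 for g in genes}
        got = {
            (a.contig_id, a.reference_gene_id)
            for a in select_seeds(fwd, rev, lengths, TH)["L1"]
            if a.reciprocal
        }
        assert got == _rbh_oracle(pairs)


# ---------------------------------------------------------------------------
# paralog extension


def test_extend_paralogs_union_and_idempotence():
    seeds = [("L1", "c1")]
    keys = {"c1": ("L1", "c1"), "c7": ("L2", "c7"), "c9": ("L3", "c9")}
    hits = [make_hsp(query_id="c1", subject_id="c7"),
            make_hsp(query_id="c1", subject_id="c9"),
            make_hsp(query_id="c1", subject_id="c9")]  # duplicate row
    assert extend_paralogs(seeds, hits, keys) == {
        ("L1", "c1"), ("L2", "c7"), ("L3", "c9")
    }
    assert extend_paralogs(seeds, [], keys) == {("L1", "c1")}


# ---------------------------------------------------------------------------
# concentrate


def contig(lib, cid, seq):
    return ContigRecord(cid, lib, seq)


def test_concentrate_identical_across_three_libraries():
    seq = "ACGT" * 50
    cands = [contig(f"L{i}", f"c{i}", seq) for i in range(1, 4)]
    retained, dropped = concentrate(cands, TH)
    assert dropped == []
    (c,) = retained
    assert c.library_support == 3


def test_concentrate_distance_three_splits_and_drops():
    a = "ACGT" * 50
    b = "TTT" + a[3:]  # 3 substitutions
    retained, dropped = concentrate(
        [contig("L1", "c1", a), contig("L2", "c2", b)], TH
    )
    assert retained == []
    assert len(dropped) == 2


def test_concentrate_single_linkage_chains_non_transitively():
    # a-b and b-c are within 2 edits, a-c is 4 apart: one component of 3
    a = "ACGTACGTACGTACGTACGT" * 10
    b = "TT" + a[2:]
    c = "TTTA" + a[4:]
    from unigene.sequence_ops import EXCEEDS, bounded_edit_distance
    assert bounded_edit_distance(a, b, 2) == 2
    assert bounded_edit_distance(b, c, 2) == 2
    assert bounded_edit_distance(a, c, 2) is EXCEEDS
    clusters = cluster_candidates(
        [contig("L1", "a", a), contig("L2", "b", b), contig("L3", "c", c)]
    )
    assert len(clusters) == 1
    assert len(clusters[0].members) == 3


def test_concentrate_representative_is_longest_then_lexicographic():
    base = "ACGT" * 100
    longer = base + "A"
    cands = [contig("L2", "z", base), contig("L1", "b", longer),
             contig("L3", "a", base)]
    (cl,) = cluster_candidates(cands)
    assert cl.representative == ("L1", "b")
    # all same length: smallest (library, contig) key wins
    (cl2,) = cluster_candidates(
        [contig("L2", "z", base), contig("L1", "b", base), contig("L3", "a", base)]
    )
    assert cl2.representative == ("L1", "b")


# ---------------------------------------------------------------------------
# rescue


def test_rescue_singletons_definition():
    base = "ACGT" * 100
    other = "GGCC" * 100
    cands = [
        contig("L1", "s1", base),            # seed, no homolog anywhere
        contig("L1", "k1", other), contig("L2", "k2", other),  # retained pair
        contig("L2", "n1", "TTAA" * 100),    # non-seed singleton
    ]
    retained, _ = concentrate(cands, TH)
    seeds = [("L1", "s1"), ("L1", "k1")]
    assert rescue_singletons(seeds, retained) == [("L1", "s1")]


# ---------------------------------------------------------------------------
# taxonomy filter


def tax_contigs():
    return [
        ContigRecord("euk", "", "ACGT"),
        ContigRecord("bact", "", "ACGT"),
        ContigRecord("nohit", "", "ACGT"),
        ContigRecord("unk", "", "ACGT"),
    ]


def tax_hits():
    return [
        make_hsp(query_id="euk", subject_id="nr_e", bit_score=100),
        make_hsp(query_id="bact", subject_id="nr_b", bit_score=100),
        make_hsp(query_id="unk", subject_id="nr_missing", bit_score=100),
    ]


TAXMAP = {"nr_e": "Eukaryota", "nr_b": "Bacteria"}


def test_taxonomy_filter_module3_keeps_unclassified_and_no_hit():
    kept, discarded = taxonomy_filter(tax_contigs(), tax_hits(), TAXMAP, "module3")
    assert {c.contig_id for c in kept} == {"euk", "nohit", "unk"}
    assert {c.contig_id for c in discarded} == {"bact"}


def test_taxonomy_filter_strict_keeps_only_eukaryote_matches():
    kept, discarded = taxonomy_filter(
        tax_contigs(), tax_hits(), TAXMAP, "strict_eukaryote"
    )
    assert {c.contig_id for c in kept} == {"euk"}
    assert {c.contig_id for c in discarded} == {"bact", "nohit", "unk"}


def test_taxonomy_filter_partitions_input():
    contigs = tax_contigs()
    for policy in ("module3", "strict_eukaryote"):
        kept, discarded = taxonomy_filter(contigs, tax_hits(), TAXMAP, policy)
        assert len(kept) + len(discarded) == len(contigs)
        assert {c.contig_id for c in kept} | {c.contig_id for c in discarded} == {
            c.contig_id for c in contigs
        }


def test_taxonomy_filter_tie_breaks_lexicographically():
    # equal bit score and e-value to Eukaryota and Bacteria subjects: the
    # lexicographically smaller subject id decides; enumerating both name
    # orders shows the winner follows the id, not the insertion order
    contigs = [ContigRecord("c1", "", "ACGT")]
    for euk_name, bact_name in (("nr_a", "nr_b"), ("nr_z", "nr_b")):
        hits = [
            make_hsp(query_id="c1", subject_id=euk_name, bit_score=100, evalue=1e-10),
            make_hsp(query_id="c1", subject_id=bact_name, bit_score=100, evalue=1e-10),
        ]
        taxmap = {euk_name: "Eukaryota", bact_name: "Bacteria"}
        kept, discarded = taxonomy_filter(contigs, hits, taxmap, "module3")
        winner = min(euk_name, bact_name)
        if taxmap[winner] == "Eukaryota":
            assert [c.contig_id for c in kept] == ["c1"]
        else:
            assert [c.contig_id for c in discarded] == ["c1"]


# ---------------------------------------------------------------------------
# merge of the two pipelines


def iset(name, prov, *records):
    s = IntegratedSet(name)
    for r in records:
        s.add(r, prov)
    return s


def test_merge_sets_collapses_identical_contig():
    seq = "ACGT" * 100
    semi = iset("sm", "semi_manual", ContigRecord("s1", "", seq))
    auto = iset("au", "automatic", ContigRecord("a1", "", seq))
    cross = [make_hsp(query_id="s1", subject_id="a1", percent_identity=100.0,
                      q_start=1, q_end=400, s_start=1, s_end=400)]
    merged = merge_sets(semi, auto, cross, TH)
    assert set(merged.contigs) == {"a1"}
    assert merged.provenance["a1"] == "both"


def test_merge_sets_keeps_95pct_pair_and_disjoint_union():
    semi = iset("sm", "semi_manual", ContigRecord("s1", "", "ACGT" * 100))
    auto = iset("au", "automatic", ContigRecord("a1", "", "ACGT" * 100))
    cross = [make_hsp(query_id="s1", subject_id="a1", percent_identity=95.0,
                      q_start=1, q_end=400, s_start=1, s_end=400)]
    merged = merge_sets(semi, auto, cross, TH)
    assert set(merged.contigs) == {"s1", "a1"}
    # disjoint sets, no cross hits: plain union
    merged2 = merge_sets(semi, auto, [], TH)
    assert len(merged2) == len(semi) + len(auto)


def test_merge_sets_requires_full_containment_of_shorter():
    semi = iset("sm", "semi_manual", ContigRecord("s1", "", "ACGT" * 50))  # 200 bp
    auto = iset("au", "automatic", ContigRecord("a1", "", "ACGT" * 100))
    # identity 100 but only 150/200 of the shorter sequence covered
    cross = [make_hsp(query_id="s1", subject_id="a1", percent_identity=100.0,
                      q_start=1, q_end=150, s_start=1, s_end=150)]
    merged = merge_sets(semi, auto, cross, TH)
    assert set(merged.contigs) == {"s1", "a1"}


# ---------------------------------------------------------------------------
# isoforms


def iso_set():
    return iset(
        "x", "semi_manual",
        ContigRecord("c1", "", "A" * 500),
        ContigRecord("c2", "", "A" * 400),
        ContigRecord("c3", "", "A" * 300),
    )


def test_detect_isoforms_requires_both_strict_thresholds():
    def hit(pident, length):
        return make_hsp(query_id="c1", subject_id="c2", percent_identity=pident,
                        alignment_length=length, q_start=1, q_end=length,
                        s_start=1, s_end=length)

    assert detect_isoforms(iso_set(), [hit(95.0, 200)], TH) == [
        {"members": ["c1", "c2"], "representative": "c1"}
    ]
    assert detect_isoforms(iso_set(), [hit(90.0, 200)], TH) == []  # identity boundary
    assert detect_isoforms(iso_set(), [hit(99.0, 140)], TH) == []  # length boundary
    assert detect_isoforms(iso_set(), [hit(99.0, 150)], TH) == []  # exact 150


def test_detect_isoforms_ignores_self_pairs_and_sizes_groups():
    self_hit = make_hsp(query_id="c1", subject_id="c1", percent_identity=100.0,
                        alignment_length=500, q_start=1, q_end=500,
                        s_start=1, s_end=500)
    assert detect_isoforms(iso_set(), [self_hit], TH) == []
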