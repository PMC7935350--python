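import pytest

from unigene.fixtures import generate_hit_tables, generate_libraries
from unigene.io_formats import HspRecord


@pytest.fixture(scope="session")
def manifest():
    """One mid-sized planted study shared across tests."""
    return generate_libraries(
        n_genes=8, n_libraries=4, n_seed_singletons=2, n_contaminants=2,
        n_isoform_pairs=1, seed=7,
    )


@pytest.fixture(scope="session")
def hit_tables(manifest):
    return generate_hit_tables(manifest)


@pytest.fixture(scope="session")
def libraries(manifest):
    libs = {lib: [] for lib in manifest.library_ids}
    for rec in manifest.all_contigs():
        libs[rec.library_id].append(rec)
    return libs


@pytest.fixture(scope="session")
def reference_lengths(manifest):
    return {g.reference_id: len(g.protein) for g in manifest.genes}


def make_hsp(
    query_id="q", subject_id="s", percent_identity=100.0, alignment_length=None,
    mismatches=0, gap_opens=0, q_start=1, q_end=100, s_start=1, s_end=100,
    evalue=1e-50, bit_score=100.0, minus_strand=False,
):
    """HspRecord factory with a sane default row."""
    if alignment_length is None:
        alignment_length = s_end - s_start + 1
    return HspRecord(
        query_id=query_id, subject_id=subject_id,
        percent_identity=percent_identity, alignment_length=alignment_length,
        mismatches=mismatches, gap_opens=gap_opens,
        q_start=q_start, q_end=q_end, s_start=s_start, s_end=s_end,
        evalue=evalue, bit_score=bit_score, minus_strand=minus_strand,
    )
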