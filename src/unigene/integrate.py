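"""The semi-manual integration pipeline.

Stage order:

1. **Seed selection** — for every reference protein, the best-scoring contig
   per library (after the subject-coverage and minimum-HSP-length filters),
   kept only when the choice is a reciprocal best hit.
2. **Paralog extension + concentrate** — seeds are searched against every
   library; all hit contigs become candidates; candidates within a bounded
   edit distance (2 bp of mismatches + gaps by default) cluster together and
   a cluster survives only when its members span at least two libraries.
   Seed contigs stranded in dropped clusters are rescued back.
3. **Taxonomy filter** — each contig is classified by the superkingdom of
   its best database hit; non-eukaryote matches are discarded.

The concentrated semi-manual set can then be merged with an independently
produced automatic set, and isoform groups are detected by a self-search.

Every tie-break is a total order, so identical inputs yield identical
outputs; ties actually exercised are logged to make reruns auditable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Literal, Mapping, Sequence

import networkx as nx

from .hsp_algebra import group_by_pair, pair_coverage, passes_seed_filters
from .io_formats import ContigRecord, HspRecord
from .sequence_ops import EXCEEDS, bounded_edit_distance

logger = logging.getLogger(__name__)

TaxonomyPolicy = Literal["module3", "strict_eukaryote"]


@dataclass(frozen=True)
class IntegrationThresholds:
    """Every numeric threshold of the integration workflow.

    Units: ``min_subject_coverage`` and ``coverage_threshold`` are fractions;
    ``min_hsp_aa`` amino acids; ``concentrate_tolerance_bp`` base pairs of
    combined mismatches and gaps; isoform identity in percent.
    Coverage comparisons: seed-filter coverage is inclusive (>=); the
    evaluation threshold and both isoform thresholds are strict (>).
    """

    min_subject_coverage: float = 0.5
    min_hsp_aa: int = 20
    concentrate_tolerance_bp: int = 2
    min_library_support: int = 2
    isoform_min_identity_pct: float = 90.0
    isoform_min_hsp_bp: int = 150
    isoform_word_size_bp: int = 100
    coverage_threshold: float = 0.75
    merge_min_identity_pct: float = 100.0
    merge_min_containment: float = 1.0

    def __post_init__(self) -> None:
        if not (0 < self.min_subject_coverage <= 1):
            raise ValueError("min_subject_coverage must be in (0, 1]")
        if not (0 < self.coverage_threshold <= 1):
            raise ValueError("coverage_threshold must be in (0, 1]")
        for name in ("min_hsp_aa", "concentrate_tolerance_bp",
                     "min_library_support", "isoform_min_hsp_bp",
                     "isoform_word_size_bp"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        for name in ("isoform_min_identity_pct", "merge_min_identity_pct"):
            v = getattr(self, name)
            if not (0 < v <= 100):
                raise ValueError(f"{name} must be in (0, 100]")

    def with_overrides(self, **kwargs) -> "IntegrationThresholds":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class SeedAssignment:
    """One-to-one link between a reference gene and its best contig."""

    reference_gene_id: str
    library_id: str
    contig_id: str
    bit_score: float
    reciprocal: bool


@dataclass(frozen=True)
class Cluster:
    """A concentrate group of near-identical contigs across libraries."""

    cluster_id: str
    members: tuple[tuple[str, str], ...]  # (library_id, contig_id)
    representative: tuple[str, str]

    def __post_init__(self) -> None:
        if self.representative not in self.members:
            raise ValueError("representative must be a member")

    @property
    def library_support(self) -> int:
        return len({lib for lib, _ in self.members})


@dataclass
class IntegratedSet:
    """A named collection of contigs with per-contig provenance
    (semi_manual, automatic, or both)."""

    name: str
    contigs: dict[str, ContigRecord] = field(default_factory=dict)
    provenance: dict[str, str] = field(default_factory=dict)

    def add(self, record: ContigRecord, provenance: str) -> None:
        if record.contig_id in self.contigs:
            raise ValueError(f"duplicate contig id {record.contig_id!r}")
        self.contigs[record.contig_id] = record
        self.provenance[record.contig_id] = provenance

    def __len__(self) -> int:
        return len(self.contigs)


# ---------------------------------------------------------------------------
# module 1: seed selection


def _pair_stats(
    hsps: Sequence[HspRecord], axis: str, axis_length: int, min_hsp_aa: int
) -> tuple[float, float, float]:
    """(best bit score, best e-value, merged coverage) over length-filtered HSPs."""
    kept = [h for h in hsps if h.alignment_length >= min_hsp_aa]
    if not kept:
        return (0.0, float("inf"), 0.0)
    bit = max(h.bit_score for h in kept)
    ev = min(h.evalue for h in kept)
    cov = pair_coverage(kept, axis, axis_length).ratio
    return (bit, ev, cov)


def _best_partner(
    scored: Mapping[str, tuple[float, float, float]]
) -> str | None:
    """Argmax partner under the total order (bit desc, e-value asc,
    coverage desc, id asc)."""
    if not scored:
        return None
    ranked = sorted(
        scored.items(), key=lambda kv: (-kv[1][0], kv[1][1], -kv[1][2], kv[0])
    )
    if len(ranked) > 1 and ranked[0][1] == ranked[1][1]:
        logger.info(
            "best-partner tie between %s and %s broken lexicographically",
            ranked[0][0], ranked[1][0],
        )
    return ranked[0][0]


def select_seeds(
    forward_hits: Mapping[str, Sequence[HspRecord]],
    reverse_hits: Mapping[str, Sequence[HspRecord]],
    reference_lengths: Mapping[str, int],
    thresholds: IntegrationThresholds = IntegrationThresholds(),
    filter_reverse: bool = True,
) -> dict[str, list[SeedAssignment]]:
    """Reciprocal-best-hit seed selection, per library.

    *forward_hits* maps library_id to translated contig-vs-reference hit rows
    (subject axis = reference protein, amino acids); *reverse_hits* maps
    library_id to the reciprocal reference-vs-contig rows (query axis =
    reference protein).

    Pairs must pass the seed filters (HSPs >= ``min_hsp_aa`` aa, merged
    reference-protein coverage >= ``min_subject_coverage``); by default the
    same two filters are applied in the reverse direction
    (``filter_reverse=False`` ranks reverse hits unfiltered). For each
    reference gene the highest-bit-score contig wins (ties: lower e-value,
    larger merged coverage, lexicographically smaller contig id); the
    assignment is a seed only when that contig's best reference gene is the
    same gene. Every best-per-gene assignment is returned with its
    ``reciprocal`` flag; seeds are the reciprocal ones.
    """
    out: dict[str, list[SeedAssignment]] = {}
    for library_id, hits in forward_hits.items():
        if not hits:
            logger.warning("library %s: empty forward hit table", library_id)
            out[library_id] = []
            continue
        # forward: per gene, scored candidate contigs
        per_gene: dict[str, dict[str, tuple[float, float, float]]] = {}
        for (contig_id, gene_id), pair_hsps in group_by_pair(hits).items():
            if gene_id not in reference_lengths:
                raise KeyError(f"reference length unknown for {gene_id!r}")
            if not passes_seed_filters(
                pair_hsps,
                reference_lengths[gene_id],
                min_ratio=thresholds.min_subject_coverage,
                min_hsp_aa=thresholds.min_hsp_aa,
            ):
                continue
            per_gene.setdefault(gene_id, {})[contig_id] = _pair_stats(
                pair_hsps, "subject", reference_lengths[gene_id],
                thresholds.min_hsp_aa,
            )
        # reverse: per contig, scored candidate genes
        per_contig: dict[str, dict[str, tuple[float, float, float]]] = {}
        for (gene_id, contig_id), pair_hsps in group_by_pair(
            reverse_hits.get(library_id, [])
        ).items():
            if gene_id not in reference_lengths:
                raise KeyError(f"reference length unknown for {gene_id!r}")
            if filter_reverse and not _passes_query_filters(
                # reverse search: the reference protein is the query axis
                pair_hsps, reference_lengths[gene_id], thresholds
            ):
                continue
            per_contig.setdefault(contig_id, {})[gene_id] = _pair_stats(
                pair_hsps, "query", reference_lengths[gene_id],
                thresholds.min_hsp_aa,
            )
        assignments: list[SeedAssignment] = []
        for gene_id in sorted(per_gene):
            contig_id = _best_partner(per_gene[gene_id])
            best_gene_back = _best_partner(per_contig.get(contig_id, {}))
            assignments.append(
                SeedAssignment(
                    reference_gene_id=gene_id,
                    library_id=library_id,
                    contig_id=contig_id,
                    bit_score=per_gene[gene_id][contig_id][0],
                    reciprocal=(best_gene_back == gene_id),
                )
            )
        out[library_id] = assignments
    return out


def _passes_query_filters(
    pair_hsps: Sequence[HspRecord], gene_length: int,
    thresholds: IntegrationThresholds,
) -> bool:
    """Reverse-direction filter: coverage measured on the reference protein,
    which is the *query* of the reverse search."""
    kept = [h for h in pair_hsps if h.alignment_length >= thresholds.min_hsp_aa]
    if not kept:
        return False
    cov = pair_coverage(kept, "query", gene_length).ratio
    return cov >= thresholds.min_subject_coverage


def seeds_only(
    assignments: Mapping[str, Sequence[SeedAssignment]]
) -> list[SeedAssignment]:
    """Flatten per-library assignments to the reciprocal (seed) ones."""
    return [
        a
        for library_id in sorted(assignments)
        for a in assignments[library_id]
        if a.reciprocal
    ]


# ---------------------------------------------------------------------------
# module 2: paralog extension, concentrate, singleton rescue


def extend_paralogs(
    seed_keys: Iterable[tuple[str, str]],
    all_library_hits: Sequence[HspRecord],
    subject_keys: Mapping[str, tuple[str, str]],
) -> set[tuple[str, str]]:
    """Candidate set for concentration: every subject contig hit by a seed,
    plus the seeds themselves.

    *subject_keys* maps a hit-table subject id to its (library_id, contig_id)
    key, since the nucleotide search runs against all libraries pooled.
    """
    candidates = set(seed_keys)
    for h in all_library_hits:
        if h.subject_id not in subject_keys:
            raise KeyError(f"hit subject {h.subject_id!r} not a known contig")
        candidates.add(subject_keys[h.subject_id])
    return candidates


def cluster_candidates(
    candidates: Sequence[ContigRecord],
    tolerance_bp: int = 2,
    end_gap_free: bool = False,
) -> list[Cluster]:
    """Single-linkage clusters of candidates under the bounded edit distance.

    Two candidates are linked when their edit distance (substitutions +
    indels) is within *tolerance_bp*; clusters are the connected components
    of that relation, so chains a-b-c cluster together even when a and c
    individually exceed the tolerance. The representative is the longest
    member (ties: lexicographically smallest (library_id, contig_id)).
    Cluster ids are assigned in representative order.
    """
    graph: nx.Graph = nx.Graph()
    by_key = {c.key: c for c in candidates}
    graph.add_nodes_from(by_key)
    ordered = sorted(candidates, key=lambda c: (c.length, c.key))
    # length difference > tolerance already exceeds the bound; comparing a
    # length-sorted sliding window avoids the full quadratic sweep
    for i, a in enumerate(ordered):
        for b in ordered[i + 1 :]:
            if b.length - a.length > tolerance_bp and not end_gap_free:
                break
            d = bounded_edit_distance(
                a.sequence, b.sequence, k=tolerance_bp, end_gap_free=end_gap_free
            )
            if d is not EXCEEDS:
                graph.add_edge(a.key, b.key)
    clusters: list[Cluster] = []
    for comp in nx.connected_components(graph):
        members = tuple(sorted(comp))
        best_len = max(by_key[k].length for k in members)
        rep = min(k for k in members if by_key[k].length == best_len)
        clusters.append(Cluster("", members, rep))
    clusters.sort(key=lambda c: c.representative)
    return [
        Cluster(f"CL{i:05d}", c.members, c.representative)
        for i, c in enumerate(clusters, start=1)
    ]


def concentrate(
    candidates: Sequence[ContigRecord],
    thresholds: IntegrationThresholds = IntegrationThresholds(),
    end_gap_free: bool = False,
) -> tuple[list[Cluster], list[Cluster]]:
    """Cluster candidates and split into (retained, dropped) by library support.

    A cluster is retained only when its members span at least
    ``min_library_support`` distinct libraries.
    """
    clusters = cluster_candidates(
        candidates, thresholds.concentrate_tolerance_bp, end_gap_free
    )
    retained = [c for c in clusters if c.library_support >= thresholds.min_library_support]
    dropped = [c for c in clusters if c.library_support < thresholds.min_library_support]
    return retained, dropped


def rescue_singletons(
    seed_keys: Iterable[tuple[str, str]],
    retained_clusters: Sequence[Cluster],
) -> list[tuple[str, str]]:
    """Seed contigs not represented in any retained cluster.

    These are seeds without a close homolog in any other library, which the
    at-least-two-libraries rule would otherwise discard; they are added back
    to the integrated set.
    """
    retained_members = {m for c in retained_clusters for m in c.members}
    return sorted(k for k in set(seed_keys) if k not in retained_members)


# ---------------------------------------------------------------------------
# module 3: taxonomy filter


def best_hit_superkingdom(
    hsps: Sequence[HspRecord], taxonomy_map: Mapping[str, str]
) -> str:
    """Superkingdom of the best hit (bit score desc, e-value asc, subject id
    asc); subjects absent from the map count as unclassified."""
    ranked = sorted(hsps, key=lambda h: (-h.bit_score, h.evalue, h.subject_id))
    if (
        len(ranked) > 1
        and ranked[0].bit_score == ranked[1].bit_score
        and ranked[0].evalue == ranked[1].evalue
    ):
        logger.info(
            "taxonomy best-hit tie for %s: %s over %s (lexicographic)",
            ranked[0].query_id, ranked[0].subject_id, ranked[1].subject_id,
        )
    return taxonomy_map.get(ranked[0].subject_id, "unclassified")


def taxonomy_filter(
    contigs: Sequence[ContigRecord],
    best_hits: Sequence[HspRecord],
    taxonomy_map: Mapping[str, str],
    policy: TaxonomyPolicy = "module3",
) -> tuple[list[ContigRecord], list[ContigRecord]]:
    """Partition contigs into (kept, discarded) by best-hit superkingdom.

    ``module3`` keeps eukaryote matches, unclassified matches and contigs
    with no hit at all; ``strict_eukaryote`` keeps only contigs whose best
    hit is Eukaryota. Subjects missing from the taxonomy map are treated as
    unclassified (warned once).
    """
    if policy not in ("module3", "strict_eukaryote"):
        raise ValueError(f"unknown taxonomy policy {policy!r}")
    by_query = group_by_pair(best_hits)
    hits_per_contig: dict[str, list[HspRecord]] = {}
    for (q, _s), rows in by_query.items():
        hits_per_contig.setdefault(q, []).extend(rows)
    missing = {
        h.subject_id for h in best_hits if h.subject_id not in taxonomy_map
    }
    if missing:
        logger.warning(
            "%d hit subjects missing from taxonomy map; treated as unclassified",
            len(missing),
        )
    kept: list[ContigRecord] = []
    discarded: list[ContigRecord] = []
    for contig in contigs:
        rows = hits_per_contig.get(contig.contig_id)
        if not rows:
            verdict = "no_hit"
        else:
            verdict = best_hit_superkingdom(rows, taxonomy_map)
        if policy == "module3":
            keep = verdict in ("Eukaryota", "unclassified", "no_hit")
        else:
            keep = verdict == "Eukaryota"
        (kept if keep else discarded).append(contig)
    return kept, discarded


# ---------------------------------------------------------------------------
# merge of the semi-manual and automatic sets


def merge_sets(
    semi_manual: IntegratedSet,
    automatic: IntegratedSet,
    cross_hits: Sequence[HspRecord],
    thresholds: IntegrationThresholds = IntegrationThresholds(),
    name: str = "merged",
) -> IntegratedSet:
    """Union of the two sets, collapsing redundant semi-manual contigs.

    *cross_hits* is a hit table with semi-manual contigs as queries and
    automatic contigs as subjects. A semi-manual contig collapses into an
    automatic one (provenance ``both``) only when HSPs at
    >= ``merge_min_identity_pct`` identity cover at least
    ``merge_min_containment`` of the shorter of the two sequences — with the
    defaults, perfect identity and full containment. Anything short of that
    keeps both records.
    """
    collapse_into: dict[str, str] = {}
    for (sm_id, auto_id), rows in group_by_pair(cross_hits).items():
        if sm_id not in semi_manual.contigs or auto_id not in automatic.contigs:
            continue
        good = [
            h for h in rows
            if h.percent_identity >= thresholds.merge_min_identity_pct
        ]
        if not good:
            continue
        sm_len = semi_manual.contigs[sm_id].length
        auto_len = automatic.contigs[auto_id].length
        axis = "query" if sm_len <= auto_len else "subject"
        cov = pair_coverage(good, axis, min(sm_len, auto_len)).ratio
        if cov >= thresholds.merge_min_containment:
            # keep the first collapse target in sorted order for determinism
            if sm_id not in collapse_into or auto_id < collapse_into[sm_id]:
                collapse_into[sm_id] = auto_id
    merged = IntegratedSet(name=name)
    for cid in sorted(automatic.contigs):
        prov = "both" if cid in collapse_into.values() else automatic.provenance[cid]
        merged.add(automatic.contigs[cid], prov)
    for cid in sorted(semi_manual.contigs):
        if cid in collapse_into:
            continue
        merged.add(semi_manual.contigs[cid], semi_manual.provenance[cid])
    return merged


# ---------------------------------------------------------------------------
# isoform detection


def detect_isoforms(
    integrated: IntegratedSet,
    self_hits: Sequence[HspRecord],
    thresholds: IntegrationThresholds = IntegrationThresholds(),
) -> list[dict]:
    """Isoform groups from an all-vs-all self search of the integrated set.

    Two distinct contigs are isoforms of one gene when some HSP between them
    exceeds ``isoform_min_identity_pct`` identity (strict) over more than
    ``isoform_min_hsp_bp`` aligned bases (strict). Groups are connected
    components of size >= 2; each reports its longest member as
    representative. The self search is expected to have been run with a
    minimum word/seed size of ``isoform_word_size_bp``.
    """
    graph: nx.Graph = nx.Graph()
    for h in self_hits:
        if h.query_id == h.subject_id:
            continue
        if h.query_id not in integrated.contigs or h.subject_id not in integrated.contigs:
            continue
        if (
            h.percent_identity > thresholds.isoform_min_identity_pct
            and h.alignment_length > thresholds.isoform_min_hsp_bp
        ):
            graph.add_edge(h.query_id, h.subject_id)
    groups = []
    for comp in nx.connected_components(graph):
        if len(comp) < 2:
            continue
        members = sorted(comp)
        best_len = max(integrated.contigs[m].length for m in members)
        rep = min(m for m in members if integrated.contigs[m].length == best_len)
        groups.append({"members": members, "representative": rep})
    groups.sort(key=lambda g: g["representative"])
    return groups


# ---------------------------------------------------------------------------
# TSV emission


def write_integrated_tsv(
    integrated: IntegratedSet,
    path,
    clusters: Sequence[Cluster] = (),
    isoform_groups: Sequence[dict] = (),
) -> None:
    """Provenance/cluster table: contig_id, provenance, cluster_id,
    library_support, isoform_group."""
    cluster_of: dict[str, Cluster] = {}
    for c in clusters:
        cluster_of[c.representative[1]] = c
    isogroup_of: dict[str, str] = {}
    for i, g in enumerate(isoform_groups, start=1):
        for m in g["members"]:
            isogroup_of[m] = f"ISO{i:05d}"
    with open(path, "w") as fh:
        fh.write("contig_id\tprovenance\tcluster_id\tlibrary_support\tisoform_group\n")
        for cid in sorted(integrated.contigs):
            c = cluster_of.get(cid)
            fh.write(
                "\t".join(
                    (
                        cid,
                        integrated.provenance[cid],
                        c.cluster_id if c else "-",
                        str(c.library_support) if c else "-",
                        isogroup_of.get(cid, "-"),
                    )
                )
                + "\n"
            )
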