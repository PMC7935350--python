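"""End-to-end driver chaining the integration stages.

seeds -> paralog extension -> concentrate -> singleton rescue ->
taxonomy filter [-> merge with an automatic set] -> isoform detection.

The run report counts every stage and every filter's kept/discarded split;
kept + discarded always equals that filter's input count.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .integrate import (
    Cluster,
    IntegratedSet,
    IntegrationThresholds,
    TaxonomyPolicy,
    concentrate,
    detect_isoforms,
    extend_paralogs,
    merge_sets,
    rescue_singletons,
    seeds_only,
    select_seeds,
    taxonomy_filter,
)
from .io_formats import ContigRecord, HspRecord


@dataclass
class IntegrationResult:
    integrated: IntegratedSet
    retained_clusters: list[Cluster]
    dropped_clusters: list[Cluster]
    rescued: list[tuple[str, str]]
    discarded: list[ContigRecord]
    isoform_groups: list[dict]
    report: dict = field(default_factory=dict)


def integrate_all(
    libraries: Mapping[str, Sequence[ContigRecord]],
    forward_hits: Mapping[str, Sequence[HspRecord]],
    reverse_hits: Mapping[str, Sequence[HspRecord]],
    reference_lengths: Mapping[str, int],
    extend_hits: Sequence[HspRecord],
    taxonomy_hits: Sequence[HspRecord],
    taxonomy_map: Mapping[str, str],
    self_hits: Sequence[HspRecord] = (),
    automatic: IntegratedSet | None = None,
    cross_hits: Sequence[HspRecord] = (),
    thresholds: IntegrationThresholds = IntegrationThresholds(),
    taxonomy_policy: TaxonomyPolicy = "module3",
    set_name: str = "integrated",
) -> IntegrationResult:
    """Run the whole semi-manual pipeline on in-memory inputs."""
    by_key: dict[tuple[str, str], ContigRecord] = {}
    subject_keys: dict[str, tuple[str, str]] = {}
    for lib, records in libraries.items():
        for rec in records:
            by_key[rec.key] = rec
            subject_keys[rec.contig_id] = rec.key

    assignments = select_seeds(forward_hits, reverse_hits, reference_lengths, thresholds)
    seeds = seeds_only(assignments)
    seed_keys = [(a.library_id, a.contig_id) for a in seeds]

    candidate_keys = extend_paralogs(seed_keys, extend_hits, subject_keys)
    candidates = [by_key[k] for k in sorted(candidate_keys)]

    retained, dropped = concentrate(candidates, thresholds)
    rescued = rescue_singletons(seed_keys, retained)

    semi_contigs = [by_key[c.representative] for c in retained]
    semi_contigs += [by_key[k] for k in rescued if k not in
                     {c.representative for c in retained}]
    semi_contigs.sort(key=lambda r: r.key)

    kept, discarded = taxonomy_filter(
        semi_contigs, taxonomy_hits, taxonomy_map, taxonomy_policy
    )

    semi_set = IntegratedSet(name=f"{set_name}_semi_manual")
    for rec in kept:
        semi_set.add(rec, "semi_manual")

    if automatic is not None:
        integrated = merge_sets(semi_set, automatic, cross_hits, thresholds,
                                name=set_name)
    else:
        integrated = IntegratedSet(name=set_name)
        for cid in sorted(semi_set.contigs):
            integrated.add(semi_set.contigs[cid], semi_set.provenance[cid])

    isoform_groups = detect_isoforms(integrated, self_hits, thresholds)

    n_input = sum(len(v) for v in libraries.values())
    report = {
        "input_contigs": n_input,
        "assignments": sum(len(v) for v in assignments.values()),
        "seeds": len(seeds),
        "candidates": len(candidates),
        "clusters_retained": len(retained),
        "clusters_dropped": len(dropped),
        "rescued_singletons": len(rescued),
        "pre_taxonomy": len(semi_contigs),
        "taxonomy_kept": len(kept),
        "taxonomy_discarded": len(discarded),
        "automatic_contigs": len(automatic) if automatic is not None else 0,
        "integrated_contigs": len(integrated),
        "isoform_groups": len(isoform_groups),
        "isoform_members": sum(len(g["members"]) for g in isoform_groups),
    }
    return IntegrationResult(
        integrated=integrated,
        retained_clusters=retained,
        dropped_clusters=dropped,
        rescued=rescued,
        discarded=discarded,
        isoform_groups=isoform_groups,
        report=report,
    )
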