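"""End-to-end convenience wrappers over the stage modules.

These functions wire tagging, clustering, TSD calling and support filtering
into single calls operating on in-memory alignments — the paths the CLI and
the simulation-based validation drive.
"""

from __future__ import annotations

from typing import Mapping, Sequence

from . import cluster_caller, insight, tagger
from .cluster_caller import InsertionCandidate
from .seqio import AlignmentRecord, CatalogRow


def call_candidates(
    genome_alignments: Sequence[AlignmentRecord],
    te_alignments: Sequence[AlignmentRecord],
    reference: Mapping[str, str],
    family_map: Mapping[str, str] | None = None,
    min_mapq: int = 0,
    max_tsd: int = cluster_caller.DEFAULT_MAX_TSD,
    sample_id: str = "",
) -> list[InsertionCandidate]:
    """Tag reads, cluster the evidence, and emit insertion candidates."""
    genome = [a for a in genome_alignments if a.mapq >= min_mapq and not a.is_duplicate]
    interval = cluster_caller.estimate_insert_interval(genome)
    tagged = tagger.tag_reads(genome, te_alignments, family_map=dict(family_map) if family_map else None)
    clusters = cluster_caller.find_clusters(tagged, interval)
    return cluster_caller.emit_candidates(clusters, reference, max_tsd=max_tsd, sample_id=sample_id)


def candidate_to_catalog_row(
    cand: InsertionCandidate,
    sample_id: str = "",
    genotype: str = "",
    tissue: str = "",
    class_table: Mapping[str, str] | None = None,
    allele_frequency: float | None = None,
) -> CatalogRow:
    tsd_seq = cand.tsd.sequence if cand.tsd else ""
    return CatalogRow(
        sample_id=sample_id or cand.sample_id,
        genotype=genotype,
        tissue=tissue,
        chrom=cand.chrom,
        position=cand.insertion_point,
        te_family=cand.te_family,
        te_class=(class_table or {}).get(cand.te_family, "unknown"),
        tsd_sequence=tsd_seq,
        tsd_length=len(tsd_seq),
        support_split=cand.cluster.split_support,
        support_mate=cand.cluster.mate_support,
        allele_frequency=allele_frequency,
    )


def candidate_allele_frequency(
    cand: InsertionCandidate,
    genome_alignments: Sequence[AlignmentRecord],
) -> float | None:
    """AF of a candidate from its supporting pairs vs reference-spanning pairs.

    Only one junction's evidence is counted (the 5' side when present): the
    mutant allele presents two junctions, so counting both sides against
    reference pairs spanning the single insertion point would roughly double
    the apparent frequency of long inserts.
    """
    side_reads = cand.cluster.five_prime_reads or cand.cluster.three_prime_reads
    supporting = {tr.alignment.read_id for tr in side_reads}
    point = cand.insertion_point - 1
    est = insight.estimate_site_frequency(genome_alignments, supporting, cand.chrom, point)
    return est.allele_frequency
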