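"""Annotate genome alignments with TE-homology evidence (tagging stage).

A genome alignment becomes a :class:`TaggedRead` when the read itself has a
TE-consensus alignment overlapping one of its soft-clipped ends
(``evidence_source="self"``, split-read evidence) or when its mate aligns to
a TE consensus (``evidence_source="mate"``, discordant-pair evidence).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

from .seqio import AlignmentRecord

__all__ = ["TeHit", "TaggedRead", "tag_reads", "serialize_tags", "parse_tag", "TAG_NAME"]

#: custom SAM tag carrying the TE evidence (documented in the README)
TAG_NAME = "te"

DEFAULT_MIN_CLIP = 10


@dataclass(frozen=True)
class TeHit:
    """One alignment of read sequence against a TE consensus."""

    te_reference: str
    te_family: str
    aln_start: int  # 0-based half-open on the consensus
    aln_end: int
    query_start: int  # 0-based half-open on the read (sequencing orientation)
    query_end: int
    orientation: str  # 'same' or 'opposite' relative to the genome alignment
    score: float = 0.0
    ambiguous: bool = False


@dataclass
class TaggedRead:
    """A genome alignment carrying TE evidence from itself or its mate."""

    alignment: AlignmentRecord
    evidence_source: str  # 'self' or 'mate'
    hit: TeHit

    @property
    def key(self) -> tuple:
        return (
            self.alignment.read_id,
            self.alignment.mate_index,
            self.evidence_source,
            self.hit.te_family,
        )


def _hit_from_te_alignment(
    te_aln: AlignmentRecord,
    genome_strand: str,
    family_of: Callable[[str], str],
) -> TeHit:
    qs, qe = te_aln.query_aligned_interval(original_orientation=True)
    score = te_aln.tags.get("AS", qe - qs)
    orientation = "same" if te_aln.strand == genome_strand else "opposite"
    return TeHit(
        te_reference=te_aln.ref_name,
        te_family=family_of(te_aln.ref_name),
        aln_start=te_aln.ref_start,
        aln_end=te_aln.ref_end,
        query_start=qs,
        query_end=qe,
        orientation=orientation,
        score=float(score),
    )


def _collapse_by_family(hits: list[TeHit]) -> list[TeHit]:
    """Keep the best-scoring hit per family; flag score ties across families."""
    best: dict[str, TeHit] = {}
    for h in hits:
        cur = best.get(h.te_family)
        if cur is None or h.score > cur.score or (
            h.score == cur.score and h.te_reference < cur.te_reference
        ):
            best[h.te_family] = h
    out = sorted(best.values(), key=lambda h: (-h.score, h.te_family))
    if len(out) > 1 and out[0].score == out[1].score:
        out[0] = TeHit(**{**out[0].__dict__, "ambiguous": True})
    return out


def _clip_intervals(aln: AlignmentRecord) -> list[tuple[int, int]]:
    """Soft-clipped read intervals in sequencing orientation."""
    qlen = aln.query_length
    ivs = []
    nl, nr = len(aln.clip_left), len(aln.clip_right)
    if nl:
        ivs.append((0, nl) if aln.strand == "+" else (qlen - nl, qlen))
    if nr:
        ivs.append((qlen - nr, qlen) if aln.strand == "+" else (0, nr))
    return ivs


def tag_reads(
    genome_alignments: Iterable[AlignmentRecord],
    te_alignments: Iterable[AlignmentRecord],
    family_map: dict[str, str] | None = None,
    min_clip: int = DEFAULT_MIN_CLIP,
) -> list[TaggedRead]:
    """Join genome alignments with TE-consensus alignments into TaggedReads.

    Self evidence requires the TE alignment's query interval to overlap a
    soft-clipped portion of the genome alignment by at least ``min_clip``
    bases. Mate evidence requires any TE alignment of the other mate.
    Multiple consensus hits collapse to the best per family. Secondary and
    supplementary genome alignments are skipped (the primary carries the
    evidence); TE records without a query sequence are counted and skipped.
    """
    family_of = (lambda name: family_map.get(name, name)) if family_map else (lambda name: name)
    te_index: dict[tuple[str, int | None], list[AlignmentRecord]] = {}
    skipped_no_seq = 0
    for te in te_alignments:
        if te.query_sequence is None:
            skipped_no_seq += 1
            continue
        te_index.setdefault((te.read_id, te.mate_index), []).append(te)

    out: list[TaggedRead] = []
    seen: set[tuple] = set()
    for aln in genome_alignments:
        if aln.is_secondary or aln.is_supplementary:
            continue
        # self evidence: TE alignment of this read overlapping a clip
        own = te_index.get((aln.read_id, aln.mate_index), [])
        clips = _clip_intervals(aln)
        self_hits = []
        for te in own:
            hit = _hit_from_te_alignment(te, aln.strand, family_of)
            overlap = max(
                (min(hit.query_end, c1) - max(hit.query_start, c0) for c0, c1 in clips),
                default=0,
            )
            if overlap >= min_clip:
                self_hits.append(hit)
        for hit in _collapse_by_family(self_hits):
            tr = TaggedRead(aln, "self", hit)
            if tr.key not in seen:
                seen.add(tr.key)
                out.append(tr)
        # mate evidence
        if aln.mate_index in (1, 2):
            other = 2 if aln.mate_index == 1 else 1
            mate_hits = [
                _hit_from_te_alignment(te, aln.strand, family_of)
                for te in te_index.get((aln.read_id, other), [])
            ]
            for hit in _collapse_by_family(mate_hits):
                tr = TaggedRead(aln, "mate", hit)
                if tr.key not in seen:
                    seen.add(tr.key)
                    out.append(tr)
    out.sort(key=lambda t: (t.alignment.ref_name, t.alignment.ref_start, t.alignment.read_id, t.evidence_source, t.hit.te_family))
    return out


# ---------------------------------------------------------------------------
# SAM round-trip of the evidence tag

def _encode_hit(tagged: TaggedRead) -> str:
    h = tagged.hit
    return ",".join(
        [
            h.te_reference,
            h.te_family,
            str(h.aln_start),
            str(h.aln_end),
            str(h.query_start),
            str(h.query_end),
            h.orientation,
            tagged.evidence_source,
            f"{h.score:g}",
        ]
    )


def parse_tag(value: str) -> tuple[TeHit, str]:
    """Inverse of the tag encoding; returns (hit, evidence_source)."""
    (ref, fam, a0, a1, q0, q1, orient, source, score) = value.split(",")
    return (
        TeHit(ref, fam, int(a0), int(a1), int(q0), int(q1), orient, float(score)),
        source,
    )


def serialize_tags(
    tagged: Sequence[TaggedRead],
    untagged: Sequence[AlignmentRecord] = (),
) -> list[AlignmentRecord]:
    """Attach the evidence tag to each tagged alignment (copy-on-write).

    Untagged records pass through unmodified. Use seqio.write_alignments to
    emit the result as SAM/BAM for IGV.
    """
    out: list[AlignmentRecord] = []
    for tr in tagged:
        rec = AlignmentRecord(**{**tr.alignment.__dict__})
        rec.tags = dict(rec.tags)
        rec.tags[TAG_NAME] = _encode_hit(tr)
        out.append(rec)
    out.extend(untagged)
    return out
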