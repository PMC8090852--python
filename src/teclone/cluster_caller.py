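"""Group tagged reads into per-locus evidence clusters and call insertions.

Evidence geometry: a non-reference insertion at a point leaves two junction
signatures on the reference. Forward-oriented evidence ends at the 5'
junction (right-clipped split reads, forward mate-support reads pointing into
the insert); reverse-oriented evidence starts at the 3' junction. When the
integration produced a target-site duplication, the 3' junction lies
*upstream* of the 5' junction and the bases between them are the duplication.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .seqio import AlignmentRecord, GffFeature
from .tagger import TaggedRead

__all__ = [
    "InsertDistanceInterval",
    "EvidenceCluster",
    "TsdCall",
    "InsertionCandidate",
    "estimate_insert_interval",
    "find_clusters",
    "call_tsd",
    "link_softclips",
    "emit_candidates",
    "clips_match",
    "reads_compatible",
    "candidate_to_gff",
]

DEFAULT_MAX_TSD = 60
DEFAULT_MIN_CLIP_MATCH = 10
DEFAULT_CLIP_IDENTITY = 0.9


@dataclass(frozen=True)
class InsertDistanceInterval:
    """Central 95% range of proper-pair template lengths."""

    low: float
    high: float

    def __post_init__(self):
        if not (0 < self.low <= self.high):
            raise ValueError("need 0 < low <= high")


@dataclass
class SideEvidence:
    """One tagged read's junction interpretation."""

    read: TaggedRead
    side: str  # '5p' (forward, junction at read end) or '3p' (reverse, at read start)
    kind: str  # 'split' or 'mate'
    junction: int | None  # junction coordinate for split evidence
    clip: str  # junction-anchored clip sequence ('' for mate evidence)


@dataclass
class EvidenceCluster:
    chrom: str
    five_prime_reads: list[TaggedRead] = field(default_factory=list)
    three_prime_reads: list[TaggedRead] = field(default_factory=list)
    clip_seq_5p: str = ""
    clip_seq_3p: str = ""
    split_support: int = 0
    mate_support: int = 0
    te_families: Counter = field(default_factory=Counter)
    junction_5p: int | None = None
    junction_3p: int | None = None
    start: int = 0
    end: int = 0
    linkage_5p: int = 0
    linkage_3p: int = 0

    @property
    def n_reads(self) -> int:
        return len(self.five_prime_reads) + len(self.three_prime_reads)

    def reads(self) -> list[TaggedRead]:
        return self.five_prime_reads + self.three_prime_reads


@dataclass(frozen=True)
class TsdCall:
    sequence: str
    span: tuple[int, int]  # 0-based half-open on the reference

    @property
    def length(self) -> int:
        return self.span[1] - self.span[0]

    def __post_init__(self):
        if len(self.sequence) != self.span[1] - self.span[0] or self.length < 1:
            raise ValueError("TSD sequence/span mismatch")


@dataclass
class InsertionCandidate:
    cluster: EvidenceCluster
    tsd: TsdCall | None
    te_family: str
    insertion_point: int  # 1-based first duplicated base (or junction base)
    strand: str = "."
    ambiguity: float = 0.0
    sample_id: str = ""

    @property
    def chrom(self) -> str:
        return self.cluster.chrom


# ---------------------------------------------------------------------------

def estimate_insert_interval(alignments: Iterable[AlignmentRecord]) -> InsertDistanceInterval:
    """Empirical (2.5th, 97.5th) percentiles of |template length| of proper,
    non-duplicate first-mate records."""
    tlens = [
        abs(a.template_length)
        for a in alignments
        if a.is_proper_pair and not a.is_duplicate and a.template_length > 0
    ]
    if len(tlens) < 2:
        raise ValueError(f"need at least 2 proper pairs, got {len(tlens)}")
    lo, hi = np.percentile(np.asarray(tlens, dtype=float), [2.5, 97.5])
    return InsertDistanceInterval(float(lo), float(hi))


# ---------------------------------------------------------------------------
# per-read junction interpretation

def _side_evidence(tr: TaggedRead, min_clip: int = DEFAULT_MIN_CLIP_MATCH) -> SideEvidence:
    aln = tr.alignment
    if tr.evidence_source == "self":
        # which clip does the TE hit overlap? (hit coords are in sequencing
        # orientation; convert clip intervals the same way)
        qlen = aln.query_length
        nl, nr = len(aln.clip_left), len(aln.clip_right)
        left_iv = (0, nl) if aln.strand == "+" else (qlen - nl, qlen)
        right_iv = (qlen - nr, qlen) if aln.strand == "+" else (0, nr)
        ov_l = min(tr.hit.query_end, left_iv[1]) - max(tr.hit.query_start, left_iv[0]) if nl else 0
        ov_r = min(tr.hit.query_end, right_iv[1]) - max(tr.hit.query_start, right_iv[0]) if nr else 0
        if ov_r >= ov_l:
            # clip on the reference-right end: junction at ref_end, 5' side
            return SideEvidence(tr, "5p", "split", aln.ref_end, aln.clip_right)
        return SideEvidence(tr, "3p", "split", aln.ref_start, aln.clip_left)
    side = "5p" if aln.strand == "+" else "3p"
    return SideEvidence(tr, side, "mate", None, "")


def clips_match(
    a: str,
    b: str,
    side: str,
    min_len: int = DEFAULT_MIN_CLIP_MATCH,
    min_identity: float = DEFAULT_CLIP_IDENTITY,
) -> bool:
    """Junction-anchored clip compatibility.

    Two clips on the same side match when the shorter is at least ``min_len``
    bases and agrees with the longer at >= ``min_identity`` over its length,
    anchored at the junction (prefix for 5' clips, suffix for 3' clips).
    Clips shorter than ``min_len`` carry too little sequence to discriminate
    co-located insertions and are treated as compatible with anything.
    """
    n = min(len(a), len(b))
    if n < min_len:
        return True
    if side == "5p":
        x, y = a[:n], b[:n]
    else:
        x, y = a[-n:], b[-n:]
    same = sum(1 for u, v in zip(x, y) if u == v)
    return same / n >= min_identity


def reads_compatible(
    e1: SideEvidence,
    e2: SideEvidence,
    max_dist: float,
    min_clip_match: int = DEFAULT_MIN_CLIP_MATCH,
    min_identity: float = DEFAULT_CLIP_IDENTITY,
) -> bool:
    """Single-linkage compatibility predicate between two tagged reads."""
    a1, a2 = e1.read.alignment, e2.read.alignment
    if a1.ref_name != a2.ref_name:
        return False
    gap = max(a2.ref_start - a1.ref_end, a1.ref_start - a2.ref_end, 0)
    if gap > max_dist:
        return False
    if e1.kind == "split" and e2.kind == "split" and e1.side == e2.side:
        if e1.junction != e2.junction:
            return False
        return clips_match(e1.clip, e2.clip, e1.side, min_clip_match, min_identity)
    return True


# ---------------------------------------------------------------------------

class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int):
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[max(ri, rj)] = min(ri, rj)


def _modal(values: list[int]) -> int:
    c = Counter(values)
    top = max(c.values())
    return min(v for v, n in c.items() if n == top)


def _consensus_clip(evs: list[SideEvidence], side: str, junction: int) -> str:
    clips = [e.clip for e in evs if e.kind == "split" and e.junction == junction and e.clip]
    if not clips:
        return ""
    # longest clip at the modal junction; lexicographic tie-break
    return sorted(clips, key=lambda c: (-len(c), c))[0]


def _build_cluster(evs: list[SideEvidence]) -> EvidenceCluster:
    chrom = evs[0].read.alignment.ref_name
    cl = EvidenceCluster(chrom=chrom)
    for e in evs:
        if e.side == "5p":
            cl.five_prime_reads.append(e.read)
        else:
            cl.three_prime_reads.append(e.read)
        if e.kind == "split":
            cl.split_support += 1
        else:
            cl.mate_support += 1
        cl.te_families[e.read.hit.te_family] += 1
    cl.start = min(e.read.alignment.ref_start for e in evs)
    cl.end = max(e.read.alignment.ref_end for e in evs)
    splits_5p = [e.junction for e in evs if e.kind == "split" and e.side == "5p"]
    splits_3p = [e.junction for e in evs if e.kind == "split" and e.side == "3p"]
    if splits_5p:
        cl.junction_5p = _modal(splits_5p)
        cl.clip_seq_5p = _consensus_clip([e for e in evs if e.side == "5p"], "5p", cl.junction_5p)
    if splits_3p:
        cl.junction_3p = _modal(splits_3p)
        cl.clip_seq_3p = _consensus_clip([e for e in evs if e.side == "3p"], "3p", cl.junction_3p)
    if not splits_5p and not splits_3p:
        # mate-only cluster: junction at the cluster-span midpoint, no TSD
        mid = (cl.start + cl.end) // 2
        cl.junction_5p = mid
    return cl


def find_clusters(
    tagged_reads: Sequence[TaggedRead],
    interval: InsertDistanceInterval,
    min_clip_match: int = DEFAULT_MIN_CLIP_MATCH,
    min_identity: float = DEFAULT_CLIP_IDENTITY,
) -> list[EvidenceCluster]:
    """Single-linkage clustering of tagged reads under the compatibility
    predicate, with a sorted sweep so only reads within ``interval.high`` of
    each other are compared. Output sorted by (chrom, leftmost coordinate).
    """
    evs = [_side_evidence(tr) for tr in tagged_reads]
    order = sorted(
        range(len(evs)),
        key=lambda i: (
            evs[i].read.alignment.ref_name,
            evs[i].read.alignment.ref_start,
            evs[i].read.alignment.read_id,
        ),
    )
    uf = _UnionFind(len(evs))
    active: list[int] = []  # sweep window, indices into evs
    for i in order:
        ai = evs[i].read.alignment
        active = [
            j
            for j in active
            if evs[j].read.alignment.ref_name == ai.ref_name
            and ai.ref_start - evs[j].read.alignment.ref_end <= interval.high
        ]
        for j in active:
            if reads_compatible(evs[j], evs[i], interval.high, min_clip_match, min_identity):
                uf.union(i, j)
        active.append(i)
    groups: dict[int, list[SideEvidence]] = {}
    for i, e in enumerate(evs):
        groups.setdefault(uf.find(i), []).append(e)
    clusters = [_build_cluster(g) for g in groups.values()]
    clusters.sort(key=lambda c: (c.chrom, c.start, c.end))
    return clusters


# ---------------------------------------------------------------------------

def call_tsd(
    cluster: EvidenceCluster,
    reference: dict[str, str],
    max_tsd: int = DEFAULT_MAX_TSD,
) -> TsdCall | None:
    """TSD when the 3' junction lies strictly upstream of the 5' junction by
    1..max_tsd bases; the duplicated sequence is the reference between them."""
    p1, p2 = cluster.junction_5p, cluster.junction_3p
    if p1 is None or p2 is None:
        return None
    if not (p2 < p1 and 1 <= p1 - p2 <= max_tsd):
        return None
    seq = reference[cluster.chrom][p2:p1]
    return TsdCall(sequence=seq, span=(p2, p1))


def link_softclips(
    clusters: Sequence[EvidenceCluster],
    clip_index: dict[tuple[str, str, int], list[str]],
    min_clip_match: int = DEFAULT_MIN_CLIP_MATCH,
    min_identity: float = DEFAULT_CLIP_IDENTITY,
) -> None:
    """Annotate each cluster with sample-wide junction clip support.

    ``clip_index`` maps (chrom, side, junction position) -> clip sequences
    observed anywhere in the sample; the linkage count per side is the number
    of indexed clips matching the cluster's consensus clip under the clip
    rule. Mutates clusters in place.
    """
    for cl in clusters:
        for side, junction, cons, attr in (
            ("5p", cl.junction_5p, cl.clip_seq_5p, "linkage_5p"),
            ("3p", cl.junction_3p, cl.clip_seq_3p, "linkage_3p"),
        ):
            count = 0
            if junction is not None and cons:
                for clip in clip_index.get((cl.chrom, side, junction), []):
                    if clips_match(cons, clip, side, min_clip_match, min_identity):
                        count += 1
            setattr(cl, attr, count)


def _majority_family(cl: EvidenceCluster) -> tuple[str, float]:
    total = sum(cl.te_families.values())
    top = max(cl.te_families.values())
    fam = min(f for f, n in cl.te_families.items() if n == top)
    return fam, 1.0 - top / total


def emit_candidates(
    clusters: Sequence[EvidenceCluster],
    reference: dict[str, str],
    max_tsd: int = DEFAULT_MAX_TSD,
    sample_id: str = "",
) -> list[InsertionCandidate]:
    """One candidate per cluster: majority family, TSD call, insertion point
    (1-based first duplicated base, or the junction base without a TSD)."""
    out: list[InsertionCandidate] = []
    for cl in clusters:
        tsd = call_tsd(cl, reference, max_tsd)
        fam, ambiguity = _majority_family(cl)
        if tsd is not None:
            point = tsd.span[0] + 1
        else:
            anchor = cl.junction_3p if cl.junction_3p is not None else cl.junction_5p
            point = (anchor if anchor is not None else cl.start) + 1
        # element strand: a junction clip aligns to the consensus in the
        # element's own orientation; a TE-mapped mate reads it reversed
        votes = Counter()
        for tr in cl.reads():
            if tr.evidence_source == "self":
                votes["+" if tr.hit.orientation == "same" else "-"] += 1
            else:
                votes["-" if tr.hit.orientation == "same" else "+"] += 1
        strand = votes.most_common(1)[0][0] if votes else "."
        out.append(
            InsertionCandidate(
                cluster=cl,
                tsd=tsd,
                te_family=fam,
                insertion_point=point,
                strand=strand,
                ambiguity=ambiguity,
                sample_id=sample_id,
            )
        )
    return out


def candidate_to_gff(cand: InsertionCandidate) -> GffFeature:
    cl = cand.cluster
    if cand.tsd is not None:
        start = cand.tsd.span[0] + 1  # 1-based first duplicated base
        end = cand.tsd.span[1]  # 1-based last duplicated base
    else:
        start = end = cand.insertion_point
    return GffFeature(
        chrom=cand.chrom,
        source="teclone",
        feature_type="te_insertion",
        start=start,
        end=end,
        score=".",
        strand=cand.strand,
        attributes={
            "te_family": cand.te_family,
            "tsd_seq": cand.tsd.sequence if cand.tsd else "",
            "split_support": str(cl.split_support),
            "mate_support": str(cl.mate_support),
            "clip_5p": cl.clip_seq_5p,
            "clip_3p": cl.clip_seq_3p,
        },
    )


def evidence_reads(clusters: Sequence[EvidenceCluster]) -> list[AlignmentRecord]:
    """The alignment subset assigned to clusters (for the evidence SAM)."""
    out = []
    seen = set()
    for cl in clusters:
        for tr in cl.reads():
            k = (tr.alignment.read_id, tr.alignment.mate_index)
            if k not in seen:
                seen.add(k)
                out.append(tr.alignment)
    return out
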