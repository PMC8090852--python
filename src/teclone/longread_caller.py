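"""Non-reference TE insertions fully contained in single long reads.

Pooled-tissue long-read libraries capture rare somatic insertions as single
molecules: a read that spans the whole insert plus genomic flanks carries the
full element sequence and the target-site duplication. This module extracts
candidate insert segments from CIGAR I operations and long soft-clips, tests
them for TE homology with a seeded banded local aligner, normalizes libraries
to a shared read-size distribution, and calls tissue-specific singletons.
"""

from __future__ import annotations

import math
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .cluster_caller import TsdCall
from .seqio import AlignmentRecord, SequenceRecord, revcomp
from .tagger import TeHit

__all__ = [
    "LongVariant",
    "SingletonCall",
    "normalize_read_sizes",
    "extract_long_variants",
    "local_align_te",
    "detect_insert_tsd",
    "call_singletons",
]

DEFAULT_MIN_INSERT = 100
DEFAULT_MIN_FLANK = 200
DEFAULT_MIN_INSERT_COVERAGE = 0.8
DEFAULT_MIN_MAPQ = 40
DEFAULT_MAX_TSD = 60

# local alignment scoring: chosen so that genuine homology >= ~25 bases of
# 90% identity scores well above the noise floor of random sequence
MATCH, MISMATCH, GAP = 1, -2, -2
DEFAULT_MIN_SCORE = 25
SEED_K = 11
BAND = 48


@dataclass
class LongVariant:
    read_id: str
    chrom: str
    genome_flank_left: tuple[int, int] | None  # aligned ref interval, half-open
    genome_flank_right: tuple[int, int] | None
    insert_sequence: str  # candidate insert with any TSD copy trimmed off
    event_kind: str  # 'insert_cigar' or 'soft_clip'
    te_hits: list[TeHit] = field(default_factory=list)
    tsd: TsdCall | None = None
    tissue: str = ""
    library_id: str = ""

    @property
    def position(self) -> int:
        """0-based insertion point on the reference."""
        if self.tsd is not None:
            return self.tsd.span[1]
        if self.genome_flank_left is not None:
            return self.genome_flank_left[1]
        return self.genome_flank_right[0]

    @property
    def te_family(self) -> str:
        return self.te_hits[0].te_family if self.te_hits else ""


@dataclass
class SingletonCall:
    variant: LongVariant
    support_reads: int = 1
    tissue_specific: bool = True


# ---------------------------------------------------------------------------
# read-size normalization

def normalize_read_sizes(
    libraries: Sequence[Sequence[int]],
    seed: int = 0,
    bins_per_octave: int = 2,
) -> list[list[int]]:
    """Subsample libraries to a shared read-length distribution.

    Reads are binned on a log2-spaced grid (``bins_per_octave`` bins per
    doubling of length); each library is subsampled without replacement to
    the per-bin minimum count across libraries, so the binned histograms come
    out identical. Returns per-library keep-index lists (sorted).
    """
    if len(libraries) < 2:
        raise ValueError("need at least two libraries to normalize")
    all_lengths = [l for lib in libraries for l in lib]
    if not all_lengths:
        return [[] for _ in libraries]
    lo = math.floor(math.log2(max(1, min(all_lengths))) * bins_per_octave)
    hi = math.ceil(math.log2(max(all_lengths)) * bins_per_octave) + 1

    def bin_of(length: int) -> int:
        return math.floor(math.log2(max(1, length)) * bins_per_octave)

    binned: list[dict[int, list[int]]] = []
    for lib in libraries:
        d: dict[int, list[int]] = defaultdict(list)
        for idx, length in enumerate(lib):
            d[bin_of(length)].append(idx)
        binned.append(d)
    keep: list[list[int]] = []
    for li, d in enumerate(binned):
        rng = np.random.default_rng([seed, li])
        kept: list[int] = []
        for b in range(lo, hi + 1):
            target = min(len(dd.get(b, [])) for dd in binned)
            members = d.get(b, [])
            if target >= len(members):
                kept.extend(members)
            elif target > 0:
                pick = rng.choice(len(members), size=target, replace=False)
                kept.extend(members[i] for i in sorted(pick))
        keep.append(sorted(kept))
    return keep


# ---------------------------------------------------------------------------
# local alignment of candidate insert segments against the consensus library

def _kmer_index(seq: str, k: int) -> dict[str, list[int]]:
    idx: dict[str, list[int]] = defaultdict(list)
    for i in range(len(seq) - k + 1):
        idx[seq[i : i + k]].append(i)
    return idx


def _banded_sw_end(query: str, target: str, diag: int, band: int) -> tuple[int, int, int]:
    """Best local-alignment score and end cell inside a diagonal band.

    Linear gap penalty; row-vectorized with the prefix-max trick for
    horizontal gap chains (exact for linear gaps). Cells are indexed by
    offset o = j - (i + diag) + band within the band. Returns
    (score, q_end_exclusive, t_end_exclusive).
    """
    n, m = len(query), len(target)
    w = 2 * band + 1
    g = -GAP  # positive per-step gap cost
    q = np.frombuffer(query.encode(), dtype=np.uint8)
    t = np.frombuffer(target.encode(), dtype=np.uint8)
    off = np.arange(w)
    goff = g * off
    prev = np.zeros(w, dtype=np.int64)
    best_score, best_i, best_j = 0, 0, 0
    NEG = np.int64(-(10**9))
    for i in range(n):
        j = i + diag - band + off  # target columns covered by this row's band
        valid = (j >= 0) & (j < m)
        sub = np.full(w, NEG)
        jv = j[valid]
        sub[valid] = np.where(t[jv] == q[i], MATCH, MISMATCH)
        # diagonal uses prev at the same offset; vertical shifts by one
        up = np.concatenate([prev[1:], [0]])
        T = np.maximum(prev + sub, up + GAP)
        T = np.maximum(T, 0)
        T[~valid] = 0
        # horizontal gap chains: H[o] = max_k<=o (T[k] - g*(o-k))
        H = np.maximum.accumulate(T + goff) - goff
        H = np.maximum(H, 0)
        H[~valid] = 0
        o_best = int(np.argmax(H))
        if H[o_best] > best_score:
            best_score = int(H[o_best])
            best_i, best_j = i + 1, int(j[o_best]) + 1
        prev = H
    return best_score, best_i, best_j


def _banded_sw(query: str, target: str, diag: int, band: int) -> tuple[int, int, int, int, int]:
    """Banded Smith-Waterman around diagonal ``diag`` (= tpos - qpos).

    Returns (score, q0, q1, t0, t1) of the best local alignment inside the
    band, 0-based half-open. The start cell comes from a second pass on the
    reversed prefixes (the classic end-point/start-point symmetry).
    """
    score, q1, t1 = _banded_sw_end(query, target, diag, band)
    if score <= 0:
        return 0, 0, 0, 0, 0
    rq, rt = query[:q1][::-1], target[:t1][::-1]
    rev_diag = (t1 - q1) - diag
    rscore, rq1, rt1 = _banded_sw_end(rq, rt, rev_diag, band)
    # rscore == score when the band covers the alignment in both directions
    q0, t0 = q1 - rq1, t1 - rt1
    return score, q0, q1, t0, t1


def local_align_te(
    segment: str,
    te_library: Sequence[SequenceRecord],
    family_map: Mapping[str, str] | None = None,
    min_score: int = DEFAULT_MIN_SCORE,
    k: int = SEED_K,
    band: int = BAND,
) -> list[TeHit]:
    """K-mer-seeded banded local alignment of a segment against each consensus.

    For each consensus and strand, shared k-mers vote for diagonals; a banded
    Smith-Waterman is run around each well-supported diagonal group and the
    best local alignment per consensus is kept if it reaches ``min_score``.
    Hits are collapsed to the best per family and returned by descending
    score (family name breaks ties).
    """
    fam_of = (lambda n: family_map.get(n, n)) if family_map else (lambda n: n)
    seg_kmers = _kmer_index(segment, k)
    hits: list[TeHit] = []
    for rec in te_library:
        best_hit: TeHit | None = None
        for strand, target in (("+", rec.sequence), ("-", revcomp(rec.sequence))):
            diag_votes: Counter = Counter()
            tgt_kmers = _kmer_index(target, k)
            for kmer, qpos_list in seg_kmers.items():
                tpos_list = tgt_kmers.get(kmer)
                if not tpos_list:
                    continue
                for qp in qpos_list:
                    for tp in tpos_list:
                        diag_votes[(tp - qp) // band] += 1
            if not diag_votes:
                continue
            # strongest diagonal bands only; deterministic order
            ranked = sorted(diag_votes.items(), key=lambda kv: (-kv[1], kv[0]))[:3]
            for dband, _votes in ranked:
                diag = dband * band + band // 2
                score, q0, q1, t0, t1 = _banded_sw(segment, target, diag, band)
                if score < min_score:
                    continue
                if strand == "-":
                    t0, t1 = len(target) - t1, len(target) - t0
                hit = TeHit(
                    te_reference=rec.id,
                    te_family=fam_of(rec.id),
                    aln_start=t0,
                    aln_end=t1,
                    query_start=q0,
                    query_end=q1,
                    orientation="same" if strand == "+" else "opposite",
                    score=float(score),
                )
                if best_hit is None or (hit.score, -hit.aln_start) > (best_hit.score, -best_hit.aln_start):
                    best_hit = hit
        if best_hit is not None:
            hits.append(best_hit)
    # collapse per family, best score wins; ties lexicographic by family
    best_by_family: dict[str, TeHit] = {}
    for h in hits:
        cur = best_by_family.get(h.te_family)
        if cur is None or h.score > cur.score:
            best_by_family[h.te_family] = h
    return sorted(best_by_family.values(), key=lambda h: (-h.score, h.te_family))


# ---------------------------------------------------------------------------
# TSD from insert-segment / reference overlap

def _identity(a: str, b: str) -> float:
    if not a or len(a) != len(b):
        return 0.0
    return sum(1 for x, y in zip(a, b) if x == y) / len(a)


def detect_insert_tsd(
    insert_segment: str,
    reference: Mapping[str, str],
    chrom: str,
    position: int,
    max_tsd: int = DEFAULT_MAX_TSD,
    min_identity: float = 0.9,
    tail_hint: int | None = None,
) -> tuple[TsdCall | None, str]:
    """Recover the TSD from an insert segment at reference ``position``.

    An aligner that resumes matching at the insertion point packs the second
    copy of the duplication into the insert segment, so the segment's 3' tail
    should equal the reference immediately 5' of the resume point (the
    left-aligned alternative puts the copy at the segment's 5' head, matched
    against the reference just 3' of the point; both are checked). Returns
    (tsd_call_or_none, insert_with_duplication_trimmed).

    ``tail_hint`` — the number of segment bases not covered by the TE
    alignment at the 3' end — delimits the duplication more sharply than raw
    sequence comparison (a chance match of the last insert base against the
    reference would otherwise extend the duplication); when the hinted length
    verifies against the reference it wins, otherwise the longest qualifying
    duplication is searched, suffix before prefix.
    """
    ref = reference[chrom]
    best: tuple[int, str, TsdCall] | None = None
    limit = min(max_tsd, len(insert_segment) - 1)
    if tail_hint is not None and 1 <= tail_hint <= limit and position - tail_hint >= 0:
        dup = ref[position - tail_hint : position]
        if _identity(insert_segment[-tail_hint:], dup) >= min_identity:
            return (
                TsdCall(dup, (position - tail_hint, position)),
                insert_segment[:-tail_hint],
            )
    for l in range(limit, 0, -1):
        if position - l >= 0:
            dup = ref[position - l : position]
            if _identity(insert_segment[-l:], dup) >= min_identity:
                best = (l, insert_segment[:-l], TsdCall(dup, (position - l, position)))
                break
    if best is None:
        for l in range(limit, 0, -1):
            if position + l <= len(ref):
                dup = ref[position : position + l]
                if _identity(insert_segment[:l], dup) >= min_identity:
                    best = (l, insert_segment[l:], TsdCall(dup, (position, position + l)))
                    break
    if best is None:
        return None, insert_segment
    return best[2], best[1]


# ---------------------------------------------------------------------------
# variant extraction

def extract_long_variants(
    alignments: Iterable[AlignmentRecord],
    reference: Mapping[str, str],
    te_library: Sequence[SequenceRecord],
    family_map: Mapping[str, str] | None = None,
    min_mapq: int = DEFAULT_MIN_MAPQ,
    min_insert: int = DEFAULT_MIN_INSERT,
    max_tsd: int = DEFAULT_MAX_TSD,
    min_score: int = DEFAULT_MIN_SCORE,
    tissue_of_library: Mapping[str, str] | None = None,
    library_of_read=None,
) -> list[LongVariant]:
    """Scan long-read alignments for insert segments with TE homology.

    Every CIGAR I segment and terminal soft-clip of at least ``min_insert``
    bases is tested against the consensus library; alignments below
    ``min_mapq`` contribute nothing. Variants record their flanking aligned
    intervals, best TE hits, and the TSD recovered from the segment/reference
    duplication.
    """
    out: list[LongVariant] = []
    skipped_no_seq = 0
    for aln in alignments:
        if aln.mapq < min_mapq or aln.is_secondary or aln.is_supplementary:
            continue
        if aln.query_sequence is None:
            skipped_no_seq += 1
            continue
        seq = aln.query_sequence
        library_id = library_of_read(aln.read_id) if library_of_read else ""
        tissue = tissue_of_library.get(library_id, "") if tissue_of_library else ""
        qpos = 0
        rpos = aln.ref_start
        for op, length in aln.cigar:
            if op == "I" and length >= min_insert:
                segment = seq[qpos : qpos + length]
                hits = local_align_te(segment, te_library, family_map, min_score=min_score)
                hint = len(segment) - hits[0].query_end if hits else None
                tsd, trimmed = detect_insert_tsd(
                    segment, reference, aln.ref_name, rpos, max_tsd, tail_hint=hint
                )
                out.append(
                    LongVariant(
                        read_id=aln.read_id,
                        chrom=aln.ref_name,
                        genome_flank_left=(aln.ref_start, rpos),
                        genome_flank_right=(rpos, aln.ref_end),
                        insert_sequence=trimmed,
                        event_kind="insert_cigar",
                        te_hits=hits,
                        tsd=tsd,
                        tissue=tissue,
                        library_id=library_id,
                    )
                )
            elif op == "S" and length >= min_insert:
                segment = seq[qpos : qpos + length]
                left_clip = qpos == 0
                anchor = aln.ref_start if left_clip else aln.ref_end
                hits = local_align_te(segment, te_library, family_map, min_score=min_score)
                tsd, trimmed = detect_insert_tsd(segment, reference, aln.ref_name, anchor, max_tsd)
                out.append(
                    LongVariant(
                        read_id=aln.read_id,
                        chrom=aln.ref_name,
                        genome_flank_left=None if left_clip else (aln.ref_start, aln.ref_end),
                        genome_flank_right=(aln.ref_start, aln.ref_end) if left_clip else None,
                        insert_sequence=trimmed,
                        event_kind="soft_clip",
                        te_hits=hits,
                        tsd=tsd,
                        tissue=tissue,
                        library_id=library_id,
                    )
                )
            if op in "MDN=X":
                rpos += length
            if op in "MIS=X":
                qpos += length
    return [v for v in out if v.te_hits]


# ---------------------------------------------------------------------------
# singleton calling

def _full_length(
    v: LongVariant,
    min_flank: int,
    min_insert: int,
    min_insert_coverage: float,
) -> bool:
    if v.event_kind != "insert_cigar":
        return False
    if v.genome_flank_left is None or v.genome_flank_right is None:
        return False
    if (v.genome_flank_left[1] - v.genome_flank_left[0]) < min_flank:
        return False
    if (v.genome_flank_right[1] - v.genome_flank_right[0]) < min_flank:
        return False
    if len(v.insert_sequence) < min_insert:
        return False
    covered = sum(h.query_end - h.query_start for h in v.te_hits[:1])
    return covered >= min_insert_coverage * len(v.insert_sequence)


def call_singletons(
    variants: Sequence[LongVariant],
    tissues: Sequence[str] = ("gut", "head"),
    window: int = 50,
    min_flank: int = DEFAULT_MIN_FLANK,
    min_insert: int = DEFAULT_MIN_INSERT,
    min_insert_coverage: float = DEFAULT_MIN_INSERT_COVERAGE,
    require_tsd: bool = True,
    require_tissue_specific: bool = True,
) -> list[SingletonCall]:
    """Tissue-specific singleton insertions from pooled long-read libraries.

    Variants are grouped by (chromosome, position window, family); a group's
    call in a tissue is a singleton when exactly one read of that tissue
    supports it, and tissue-specific when no read of any other tissue does.
    Full-length and (by default) valid-TSD requirements apply per variant.
    """
    qualified = [
        v
        for v in variants
        if _full_length(v, min_flank, min_insert, min_insert_coverage)
        and (not require_tsd or v.tsd is not None)
    ]
    # group by key with positional tolerance: sort then link within window
    qualified.sort(key=lambda v: (v.chrom, v.te_family, v.position, v.read_id))
    groups: list[list[LongVariant]] = []
    for v in qualified:
        if (
            groups
            and groups[-1][0].chrom == v.chrom
            and groups[-1][0].te_family == v.te_family
            and v.position - groups[-1][-1].position <= window
        ):
            groups[-1].append(v)
        else:
            groups.append([v])
    calls: list[SingletonCall] = []
    for grp in groups:
        by_tissue = Counter(v.tissue for v in grp)
        for tissue in tissues:
            if by_tissue.get(tissue, 0) != 1:
                continue
            others = sum(n for t, n in by_tissue.items() if t != tissue)
            specific = others == 0
            if require_tissue_specific and not specific:
                continue
            variant = next(v for v in grp if v.tissue == tissue)
            calls.append(SingletonCall(variant=variant, support_reads=1, tissue_specific=specific))
    calls.sort(key=lambda c: (c.variant.chrom, c.variant.position, c.variant.te_family))
    return calls
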