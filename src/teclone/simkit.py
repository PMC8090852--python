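"""Synthetic-data generator for the insertion-calling pipeline.

Builds toy reference genomes and TE consensus libraries, implants TE copies
with target-site duplications (TSDs) into clonal cell populations, and emits
paired-end short reads or long reads together with *gold* alignments (placed
from the known read origins, no external aligner) and a truth manifest.

An insertion of element ``E`` (5'-truncated by ``t`` bases) at reference
point ``p`` with a TSD of length ``d`` turns

    ref = L | ref[p-d:p] | R        (L = ref[:p-d], R = ref[p:])

into the mutant haplotype

    hap = L | ref[p-d:p] | E[t:] | ref[p-d:p] | R

i.e. the ``d`` bases immediately 5' of the insertion point are duplicated on
both sides of the insert. Reads are drawn from the mutant haplotype with
probability equal to the implant's allele fraction (cell_fraction scaled by
zygosity) whenever the fragment overlaps the insertion junction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .seqio import AlignmentRecord, SequenceRecord, revcomp

__all__ = [
    "ImplantSpec",
    "RealizedImplant",
    "TruthManifest",
    "GoldShortReads",
    "GoldLongReads",
    "build_reference",
    "build_te_library",
    "TOY_TE_CLASSES",
    "implant",
    "simulate_short_reads",
    "simulate_long_reads",
]

_BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass(frozen=True)
class ImplantSpec:
    """A requested TE implant into the simulated population."""

    te_family: str
    target_chrom: str
    target_pos: int  # 0-based insertion point on the reference
    strand: str = "+"
    tsd_length: int = 5
    truncation_5p: int = 0
    cell_fraction: float = 1.0
    zygosity: str = "hemizygous"  # hemizygous | heterozygous | homozygous

    def __post_init__(self):
        if not (0.0 < self.cell_fraction <= 1.0):
            raise ValueError("cell_fraction must be in (0, 1]")
        if self.tsd_length < 0 or self.truncation_5p < 0:
            raise ValueError("tsd_length and truncation_5p must be >= 0")
        if self.zygosity not in ("hemizygous", "heterozygous", "homozygous"):
            raise ValueError(f"unknown zygosity {self.zygosity!r}")


@dataclass
class RealizedImplant:
    """An implant as realized on a mutant haplotype."""

    spec: ImplantSpec
    index: int
    insert_sequence: str  # genome-strand sequence actually inserted
    tsd_sequence: str
    allele_fraction: float
    haplotype: str  # full mutant chromosome sequence
    te_consensus: str  # consensus record id the insert derives from

    @property
    def chrom(self) -> str:
        return self.spec.target_chrom

    @property
    def pos(self) -> int:
        return self.spec.target_pos

    @property
    def insert_length(self) -> int:
        return len(self.insert_sequence)

    @property
    def tsd_span(self) -> tuple[int, int]:
        """Reference span of the duplicated bases, 0-based half-open."""
        return (self.pos - self.spec.tsd_length, self.pos)


@dataclass
class TruthManifest:
    """The simulator's record of what was implanted and where reads came from."""

    implants: list[RealizedImplant]
    read_origins: dict[str, int | None] = field(default_factory=dict)
    # read_id -> implant index (mutant haplotype) or None (reference)
    read_library: dict[str, str] = field(default_factory=dict)

    def implants_by_chrom(self) -> dict[str, list[RealizedImplant]]:
        out: dict[str, list[RealizedImplant]] = {}
        for imp in self.implants:
            out.setdefault(imp.chrom, []).append(imp)
        for lst in out.values():
            lst.sort(key=lambda i: i.pos)
        return out


@dataclass
class GoldShortReads:
    """In-memory product of a paired-end simulation."""

    genome_alignments: list[AlignmentRecord]
    te_alignments: list[AlignmentRecord]
    manifest: TruthManifest
    references: dict[str, int]
    te_references: dict[str, int]


@dataclass
class GoldLongReads:
    alignments: list[AlignmentRecord]
    manifest: TruthManifest
    references: dict[str, int]
    total_bases: int


# ---------------------------------------------------------------------------
# genome / TE library construction

def _random_seq(rng: np.random.Generator, length: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    idx = rng.choice(4, size=length, p=p)
    return _BASES[idx].tobytes().decode()


def build_reference(
    seed: int,
    chrom_lengths: dict[str, int],
    gc_fraction: float = 0.42,
) -> list[SequenceRecord]:
    """Random toy genome; deterministic for a fixed seed."""
    rng = np.random.default_rng(seed)
    return [SequenceRecord(name, _random_seq(rng, ln, gc_fraction)) for name, ln in chrom_lengths.items()]


#: family -> (length, class) for the built-in toy consensus library
_TOY_FAMILIES = {
    "rover": (3000, "LTR"),
    "copia": (2000, "LTR"),
    "blood": (1200, "LTR"),
    "I-element": (2500, "LINE-like"),
    "pogo": (800, "TIR"),
    "FB": (500, "FB"),
}

TOY_TE_CLASSES = {fam: cls for fam, (_, cls) in _TOY_FAMILIES.items()}


def build_te_library(seed: int = 7, gc_fraction: float = 0.45) -> list[SequenceRecord]:
    """Six-family toy consensus library (LTR / LINE-like / TIR / FB classes)."""
    rng = np.random.default_rng(seed)
    return [SequenceRecord(fam, _random_seq(rng, ln, gc_fraction)) for fam, (ln, _) in _TOY_FAMILIES.items()]


# ---------------------------------------------------------------------------
# implanting

def _allele_fraction(spec: ImplantSpec) -> float:
    # heterozygous: one of two chromosome copies per carrying cell
    if spec.zygosity == "heterozygous":
        return spec.cell_fraction / 2.0
    return spec.cell_fraction


def implant(
    genome: Sequence[SequenceRecord],
    te_library: Sequence[SequenceRecord],
    specs: Sequence[ImplantSpec],
    seed: int = 0,
) -> tuple[dict[str, list[RealizedImplant]], TruthManifest]:
    """Realize implants as mutant haplotypes; returns (per-chrom implants, manifest).

    Each implant gets its own full-chromosome mutant haplotype. Implants on
    one chromosome must not overlap (their junction neighbourhoods must be
    disjoint) so that read-level allele sampling is unambiguous.
    """
    ref = {r.id: r.sequence for r in genome}
    lib = {r.id: r.sequence for r in te_library}
    realized: list[RealizedImplant] = []
    for i, spec in enumerate(specs):
        if spec.target_chrom not in ref:
            raise ValueError(f"unknown chromosome {spec.target_chrom!r}")
        chrom_seq = ref[spec.target_chrom]
        if not (spec.tsd_length <= spec.target_pos < len(chrom_seq)):
            raise ValueError(f"implant position {spec.target_pos} out of bounds")
        if spec.te_family not in lib:
            raise ValueError(f"TE family {spec.te_family!r} not in library")
        element = lib[spec.te_family]
        if spec.truncation_5p >= len(element):
            raise ValueError(f"truncation_5p {spec.truncation_5p} >= element length {len(element)}")
        body = element[spec.truncation_5p :]
        insert_seq = body if spec.strand == "+" else revcomp(body)
        p, d = spec.target_pos, spec.tsd_length
        tsd_seq = chrom_seq[p - d : p]
        hap = chrom_seq[:p] + insert_seq + chrom_seq[p - d :]
        realized.append(
            RealizedImplant(
                spec=spec,
                index=i,
                insert_sequence=insert_seq,
                tsd_sequence=tsd_seq,
                allele_fraction=_allele_fraction(spec),
                haplotype=hap,
                te_consensus=spec.te_family,
            )
        )
    # overlap check per chromosome: junction regions must be disjoint
    by_chrom: dict[str, list[RealizedImplant]] = {}
    for imp in realized:
        by_chrom.setdefault(imp.chrom, []).append(imp)
    for chrom, imps in by_chrom.items():
        imps.sort(key=lambda x: x.pos)
        for a, b in zip(imps, imps[1:]):
            if b.pos - a.pos < max(a.spec.tsd_length, b.spec.tsd_length) + 1:
                raise ValueError(
                    f"overlapping implants on {chrom}: positions {a.pos} and {b.pos}"
                )
    return by_chrom, TruthManifest(implants=realized)


# ---------------------------------------------------------------------------
# shared helpers

def _apply_errors(seq: str, rng: np.random.Generator, error_rate: float) -> str:
    if error_rate <= 0.0 or not seq:
        return seq
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    hit = np.nonzero(rng.random(len(arr)) < error_rate)[0]
    if hit.size:
        # substitute with a uniformly different base
        subs = _BASES[rng.integers(0, 4, size=hit.size)]
        same = subs == arr[hit]
        while same.any():
            subs[same] = _BASES[rng.integers(0, 4, size=int(same.sum()))]
            same = subs == arr[hit]
        arr[hit] = subs
    return arr.tobytes().decode()


def _hap_projection(imp: RealizedImplant, h_start: int, h_end: int):
    """Split a mutant-haplotype interval into genome- and insert-derived parts.

    Returns (left_genome, insert_part, right_genome) where each part is
    ``None`` or a dict with query offsets (relative to h_start) and target
    coordinates. Right-genome reference coordinate: hap[p+ins+k] = ref[p-d+k].
    """
    p = imp.pos
    ins = imp.insert_length
    d = imp.spec.tsd_length
    left = insert_part = right = None
    lo, hi = h_start, min(h_end, p)
    if lo < hi:
        left = {"q0": lo - h_start, "q1": hi - h_start, "ref_start": lo, "ref_end": hi}
    lo, hi = max(h_start, p), min(h_end, p + ins)
    if lo < hi:
        insert_part = {"q0": lo - h_start, "q1": hi - h_start, "ins_start": lo - p, "ins_end": hi - p}
    lo, hi = max(h_start, p + ins), h_end
    if lo < hi:
        right = {
            "q0": lo - h_start,
            "q1": hi - h_start,
            "ref_start": lo - ins - d,
            "ref_end": hi - ins - d,
        }
    return left, insert_part, right


def _te_interval(imp: RealizedImplant, ins_start: int, ins_end: int) -> tuple[int, int, str]:
    """Map an interval on the inserted sequence to consensus coordinates."""
    t = imp.spec.truncation_5p
    if imp.spec.strand == "+":
        return t + ins_start, t + ins_end, "+"
    n = imp.insert_length
    return t + n - ins_end, t + n - ins_start, "-"


# ---------------------------------------------------------------------------
# short reads

def simulate_short_reads(
    genome: Sequence[SequenceRecord],
    te_library: Sequence[SequenceRecord],
    implants_by_chrom: dict[str, list[RealizedImplant]],
    manifest: TruthManifest,
    coverage: float = 47.0,
    read_len: int = 100,
    insert_mean: float = 350.0,
    insert_sd: float = 35.0,
    error_rate: float = 0.0,
    seed: int = 0,
) -> GoldShortReads:
    """Simulate paired-end reads with gold genome and gold TE alignments.

    The cell population is a mixture of the reference haplotype and, per
    implant, a mutant haplotype at the implant's allele fraction. Two
    fragment pools realize the mixture:

    * a reference pool at the requested coverage, thinned by the allele
      fraction inside a window around each implant (those molecules belong
      to the mutant allele there);
    * per implant, a mutant pool covering the modified haplotype region —
      both junctions and the insert interior — at allele_fraction x coverage.

    Flank bases thus see (1 - af) + af = 1x relative coverage, junctions and
    insert see af, and reference-allele molecules crossing the insertion
    point remain as the opposing reads an AF estimate needs. Reads crossing
    a junction get gold soft-clips; insert-derived read portions are aligned
    to the TE consensus in the gold TE alignments — what a genome +
    consensus-library aligner pair produces on error-free data.
    """
    if insert_mean <= read_len:
        raise ValueError("insert_mean must exceed read_len")
    rng = np.random.default_rng(seed)
    genome_out: list[AlignmentRecord] = []
    te_out: list[AlignmentRecord] = []
    references = {r.id: len(r.sequence) for r in genome}
    te_refs = {r.id: len(r.sequence) for r in te_library}
    pad = int(insert_mean + 4 * insert_sd)

    def emit_reference_pair(rid: str, chrom: str, seq: str, s: int, flen: int):
        manifest.read_origins[rid] = None
        for mate, (q0, q1, strand) in enumerate(
            [(0, read_len, "+"), (flen - read_len, flen, "-")], start=1
        ):
            rseq = _apply_errors(seq[s + q0 : s + q1], rng, error_rate)
            genome_out.append(
                AlignmentRecord(
                    read_id=rid,
                    mate_index=mate,
                    ref_name=chrom,
                    ref_start=s + q0,
                    ref_end=s + q1,
                    strand=strand,
                    mapq=60,
                    cigar=[("M", read_len)],
                    is_proper_pair=True,
                    query_sequence=rseq,
                    template_length=flen if mate == 1 else -flen,
                )
            )

    def emit_mutant_pair(rid: str, chrom: str, imp: RealizedImplant, s: int, flen: int):
        manifest.read_origins[rid] = imp.index
        hap = imp.haplotype
        recs: dict[int, AlignmentRecord | None] = {}
        for h0, h1, strand, mate in (
            (s, s + read_len, "+", 1),
            (s + flen - read_len, s + flen, "-", 2),
        ):
            rseq = _apply_errors(hap[h0:h1], rng, error_rate)
            g_rec, t_rec = _place_short_read(rid, mate, strand, chrom, imp, h0, h1, rseq, read_len)
            recs[mate] = g_rec
            if t_rec is not None:
                te_out.append(t_rec)
        r1, r2 = recs[1], recs[2]
        proper = (
            r1 is not None
            and r2 is not None
            and not (r1.clip_left or r1.clip_right or r2.clip_left or r2.clip_right)
        )
        for mate, rec in recs.items():
            if rec is None:
                continue
            rec.is_proper_pair = bool(proper)
            rec.mate_unmapped = recs[1 if mate == 2 else 2] is None
            if proper:
                tl = recs[2].ref_end - recs[1].ref_start
                rec.template_length = tl if mate == 1 else -tl
            genome_out.append(rec)

    for chrom_rec in genome:
        chrom, seq = chrom_rec.id, chrom_rec.sequence
        L = len(seq)
        imps = implants_by_chrom.get(chrom, [])
        win_starts = np.array([imp.pos - pad for imp in imps], dtype=int)
        win_ends = np.array([imp.pos + pad for imp in imps], dtype=int)
        afs = np.array([imp.allele_fraction for imp in imps], dtype=float)
        # reference pool
        n_frags = int(round(coverage * L / (2 * read_len)))
        flens = np.clip(
            np.round(rng.normal(insert_mean, insert_sd, size=n_frags)).astype(int),
            read_len + 10,
            None,
        )
        starts = rng.integers(0, np.maximum(1, L - flens), size=n_frags)
        thin_u = rng.random(n_frags)
        for i in range(n_frags):
            s = int(starts[i])
            flen = int(flens[i])
            if win_starts.size:
                j = int(np.searchsorted(win_ends, s, side="right"))
                if j < win_starts.size and s + flen > win_starts[j] and thin_u[i] < afs[j]:
                    continue  # molecule drawn from the mutant allele here
            emit_reference_pair(f"{chrom}_{i:07d}", chrom, seq, s, flen)
        # mutant pools
        for imp in imps:
            hap_len = len(imp.haplotype)
            a0 = max(0, imp.pos - pad)
            a1 = min(hap_len, imp.pos + imp.insert_length + imp.spec.tsd_length + pad)
            n_mut = int(round(imp.allele_fraction * coverage * (a1 - a0) / (2 * read_len)))
            m_flens = np.clip(
                np.round(rng.normal(insert_mean, insert_sd, size=n_mut)).astype(int),
                read_len + 10,
                None,
            )
            m_starts = rng.integers(a0, np.maximum(a0 + 1, a1 - m_flens), size=n_mut)
            for k in range(n_mut):
                emit_mutant_pair(
                    f"{chrom}_m{imp.index}_{k:06d}",
                    chrom,
                    imp,
                    int(m_starts[k]),
                    int(m_flens[k]),
                )
    return GoldShortReads(genome_out, te_out, manifest, references, te_refs)


def _place_short_read(
    rid: str,
    mate: int,
    strand: str,
    chrom: str,
    imp: RealizedImplant,
    h0: int,
    h1: int,
    rseq: str,
    read_len: int,
):
    """Gold genome and TE alignment for one read drawn from a mutant haplotype.

    Returns (genome_record | None, te_record | None). Sequences are stored in
    genome-forward orientation (the haplotype slice), matching SAM convention
    for the strands we assign.
    """
    left, ins_part, right = _hap_projection(imp, h0, h1)
    g_rec = None
    t_rec = None
    # genome alignment: anchor on the longer flank part
    parts = [p for p in (left, right) if p is not None]
    if parts:
        anchor = max(parts, key=lambda p: p["q1"] - p["q0"])
        alen = anchor["q1"] - anchor["q0"]
        cig: list[tuple[str, int]] = []
        if anchor["q0"] > 0:
            cig.append(("S", anchor["q0"]))
        cig.append(("M", alen))
        if anchor["q1"] < read_len:
            cig.append(("S", read_len - anchor["q1"]))
        g_rec = AlignmentRecord(
            read_id=rid,
            mate_index=mate,
            ref_name=chrom,
            ref_start=anchor["ref_start"],
            ref_end=anchor["ref_end"],
            strand=strand,
            mapq=60,
            cigar=cig,
            query_sequence=rseq,
            clip_left=rseq[: anchor["q0"]],
            clip_right=rseq[anchor["q1"] :],
        )
    if ins_part is not None:
        i0, i1 = ins_part["ins_start"], ins_part["ins_end"]
        te_start, te_end, te_strand = _te_interval(imp, i0, i1)
        q0, q1 = ins_part["q0"], ins_part["q1"]
        # express in TE-forward orientation when insert is on the minus strand
        if te_strand == "+":
            t_seq = rseq
            t_q0, t_q1 = q0, q1
            t_strand = strand
        else:
            t_seq = revcomp(rseq)
            t_q0, t_q1 = read_len - q1, read_len - q0
            t_strand = "-" if strand == "+" else "+"
        cig = []
        if t_q0 > 0:
            cig.append(("S", t_q0))
        cig.append(("M", t_q1 - t_q0))
        if t_q1 < read_len:
            cig.append(("S", read_len - t_q1))
        t_rec = AlignmentRecord(
            read_id=rid,
            mate_index=mate,
            ref_name=imp.te_consensus,
            ref_start=te_start,
            ref_end=te_end,
            strand=t_strand,
            mapq=60,
            cigar=cig,
            query_sequence=t_seq,
            clip_left=t_seq[:t_q0],
            clip_right=t_seq[t_q1:],
            tags={"AS": t_q1 - t_q0},
        )
    return g_rec, t_rec


# ---------------------------------------------------------------------------
# long reads

def simulate_long_reads(
    genome: Sequence[SequenceRecord],
    implants_by_chrom: dict[str, list[RealizedImplant]],
    manifest: TruthManifest,
    depth: float = 85.0,
    length_distribution: tuple[float, float] | Sequence[int] = (9.0, 0.6),
    error_rate: float = 0.0,
    seed: int = 0,
    library_id: str = "lib1",
    encode: str = "insert_cigar",  # or "soft_clip"
    implant_read_counts: dict[int, int] | None = None,
    min_flank: int = 300,
) -> GoldLongReads:
    """Simulate long reads with gold alignments.

    ``length_distribution`` is either (log-mean, log-sd) of a lognormal in
    bases, or an empirical list of lengths to resample from. Background reads
    are drawn from the reference; ``implant_read_counts`` additionally places,
    for each implant index, exactly that many reads fully containing the
    insert with at least ``min_flank`` aligned bases on each side — the rare
    single-molecule carriers that pooled-tissue libraries contain.
    """
    if encode not in ("insert_cigar", "soft_clip"):
        raise ValueError(f"unknown encoding {encode!r}")
    rng = np.random.default_rng(seed)
    ref = {r.id: r.sequence for r in genome}
    references = {r.id: len(r.sequence) for r in genome}
    chroms = list(references)
    lengths_total = sum(references.values())
    out: list[AlignmentRecord] = []
    total_bases = 0
    target = depth * lengths_total

    def draw_len() -> int:
        if isinstance(length_distribution, tuple):
            mu, sigma = length_distribution
            return max(500, int(rng.lognormal(mu, sigma)))
        return int(length_distribution[rng.integers(0, len(length_distribution))])

    i = 0
    weights = np.array([references[c] for c in chroms], dtype=float)
    weights /= weights.sum()
    while total_bases < target:
        chrom = chroms[rng.choice(len(chroms), p=weights)] if len(chroms) > 1 else chroms[0]
        seq = ref[chrom]
        L = len(seq)
        rl = min(draw_len(), L - 1)
        s = int(rng.integers(0, L - rl))
        rid = f"{library_id}_{chrom}_{i:06d}"
        i += 1
        rseq = _apply_errors(seq[s : s + rl], rng, error_rate)
        out.append(
            AlignmentRecord(
                read_id=rid,
                mate_index=None,
                ref_name=chrom,
                ref_start=s,
                ref_end=s + rl,
                strand="+",
                mapq=60,
                cigar=[("M", rl)],
                query_sequence=rseq,
            )
        )
        manifest.read_origins[rid] = None
        manifest.read_library[rid] = library_id
        total_bases += rl
    if implant_read_counts:
        for idx, count in sorted(implant_read_counts.items()):
            imp = manifest.implants[idx]
            for k in range(count):
                rid = f"{library_id}_imp{idx}_{k:03d}"
                rec = _long_read_over_implant(rng, imp, rid, encode, min_flank, error_rate)
                out.append(rec)
                manifest.read_origins[rid] = idx
                manifest.read_library[rid] = library_id
                total_bases += rec.query_length
    return GoldLongReads(out, manifest, references, total_bases)


def _long_read_over_implant(
    rng: np.random.Generator,
    imp: RealizedImplant,
    rid: str,
    encode: str,
    min_flank: int,
    error_rate: float,
) -> AlignmentRecord:
    """One long read fully containing the insert plus >= min_flank flanks.

    Gold CIGAR for ``insert_cigar``: M(left flank to the insertion point),
    I(insert + downstream TSD copy), M(rest) — the duplicated bases occur
    twice in the read, and a reference-consistent alignment absorbs the
    second copy into the I segment, resuming M at the insertion point.
    """
    p = imp.pos
    ins = imp.insert_length
    d = imp.spec.tsd_length
    hap = imp.haplotype
    extra_l = int(rng.integers(0, 200))
    extra_r = int(rng.integers(0, 200))
    a = max(0, p - min_flank - extra_l)
    b = min(len(hap), p + ins + d + min_flank + extra_r)
    rseq = _apply_errors(hap[a:b], rng, error_rate)
    rl = b - a
    left_m = p - a
    i_len = ins + d
    right_m = rl - left_m - i_len
    if encode == "insert_cigar":
        cigar = [("M", left_m), ("I", i_len), ("M", right_m)]
        ref_end = p + right_m
        return AlignmentRecord(
            read_id=rid,
            mate_index=None,
            ref_name=imp.chrom,
            ref_start=a,
            ref_end=ref_end,
            strand="+",
            mapq=60,
            cigar=cigar,
            query_sequence=rseq,
        )
    # soft-clip encoding: keep the left flank aligned, clip the rest
    cigar = [("M", left_m), ("S", rl - left_m)]
    return AlignmentRecord(
        read_id=rid,
        mate_index=None,
        ref_name=imp.chrom,
        ref_start=a,
        ref_end=p,
        strand="+",
        mapq=60,
        cigar=cigar,
        query_sequence=rseq,
        clip_right=rseq[left_m:],
    )
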