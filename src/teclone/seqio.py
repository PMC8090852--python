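"""Readers and writers for the formats the pipeline touches.

All internal coordinates are 0-based half-open. Conversion to the 1-based
closed convention of GFF3 and catalog tables happens only at the file
boundary, so reading back a file we wrote yields identical in-memory objects.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence
from urllib.parse import quote, unquote

import pysam

__all__ = [
    "SequenceRecord",
    "AlignmentRecord",
    "IntervalFeature",
    "CatalogRow",
    "read_fasta",
    "write_fasta",
    "parse_alignments",
    "write_alignments",
    "write_gff",
    "read_gff",
    "GffFeature",
    "read_catalog",
    "write_catalog",
    "read_bed",
    "revcomp",
]

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

# CIGAR operations that consume the reference / the query
_REF_OPS = set("MDN=X")
_QUERY_OPS = set("MIS=X")


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (N-safe)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class SequenceRecord:
    """A named nucleotide sequence (reference contig or TE consensus)."""

    id: str
    sequence: str


@dataclass
class AlignmentRecord:
    """One alignment of a read (or read mate) against a reference.

    ``clip_left``/``clip_right`` hold the soft-clipped bases exactly as they
    appear in the stored (reference-oriented) query sequence.
    """

    read_id: str
    mate_index: int | None  # 1, 2, or None for unpaired
    ref_name: str
    ref_start: int  # 0-based inclusive
    ref_end: int  # 0-based exclusive
    strand: str  # '+' or '-'
    mapq: int
    cigar: list[tuple[str, int]]
    is_proper_pair: bool = False
    is_duplicate: bool = False
    is_secondary: bool = False
    is_supplementary: bool = False
    mate_unmapped: bool = False
    query_sequence: str | None = None
    clip_left: str = ""
    clip_right: str = ""
    template_length: int = 0
    tags: dict = field(default_factory=dict)

    @property
    def query_length(self) -> int:
        return sum(n for op, n in self.cigar if op in _QUERY_OPS)

    def query_aligned_interval(self, original_orientation: bool = True) -> tuple[int, int]:
        """Aligned interval on the query, 0-based half-open.

        With ``original_orientation`` the interval is expressed in the read's
        sequencing orientation (SAM stores reverse-strand reads complemented).
        """
        left = len(self.clip_left)
        right = len(self.clip_right)
        qlen = self.query_length
        start, end = left, qlen - right
        if original_orientation and self.strand == "-":
            start, end = qlen - end, qlen - start
        return start, end


@dataclass(frozen=True)
class IntervalFeature:
    """A genomic interval from a BED/GFF annotation track."""

    chrom: str
    start: int  # 0-based inclusive
    end: int  # 0-based exclusive
    name: str = "."
    strand: str = "."
    feature_class: str = "track"

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError(f"empty interval {self.chrom}:{self.start}-{self.end}")


@dataclass
class CatalogRow:
    """One row of an insertion catalog (one called insertion in one sample)."""

    sample_id: str
    genotype: str
    tissue: str
    chrom: str
    position: int  # 1-based insertion point (first duplicated base)
    te_family: str
    te_class: str = "unknown"
    tsd_sequence: str = ""
    tsd_length: int = 0
    support_split: int = 0
    support_mate: int = 0
    allele_frequency: float | None = None

    def __post_init__(self):
        if self.tsd_sequence and self.tsd_length != len(self.tsd_sequence):
            raise ValueError(
                f"tsd_length {self.tsd_length} != len(tsd_sequence) for "
                f"{self.sample_id} {self.chrom}:{self.position}"
            )


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a FASTA file into uppercase SequenceRecords, in file order."""
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    name: str | None = None
    chunks: list[str] = []

    def flush():
        if name is None:
            return
        seq = "".join(chunks).upper()
        if not seq:
            raise ValueError(f"record {name!r} has an empty sequence")
        records.append(SequenceRecord(name, seq))

    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                name = line[1:].split()[0]
                if name in seen:
                    raise ValueError(f"duplicate FASTA id {name!r}")
                seen.add(name)
                chunks = []
            else:
                if name is None:
                    raise ValueError("sequence data before first FASTA header")
                chunks.append(line)
    flush()
    if not records:
        raise ValueError(f"no records in {path}")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            seq = rec.sequence
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# SAM/BAM

_CIGAR_CODES = "MIDNSHP=X"


def _record_from_segment(seg: pysam.AlignedSegment) -> AlignmentRecord:
    cigar = [( _CIGAR_CODES[op], n) for op, n in (seg.cigartuples or [])]
    seq = seg.query_sequence
    if seq is not None:
        qlen = sum(n for op, n in cigar if op in _QUERY_OPS)
        if cigar and qlen != len(seq):
            raise ValueError(
                f"CIGAR/sequence length mismatch for read {seg.query_name!r}: "
                f"cigar consumes {qlen}, sequence is {len(seq)}"
            )
    clip_left = clip_right = ""
    if seq is not None and cigar:
        if cigar[0][0] == "S":
            clip_left = seq[: cigar[0][1]]
        if cigar[-1][0] == "S":
            clip_right = seq[len(seq) - cigar[-1][1] :]
    mate_index: int | None = None
    if seg.is_paired:
        mate_index = 1 if seg.is_read1 else 2
    return AlignmentRecord(
        read_id=seg.query_name,
        mate_index=mate_index,
        ref_name=seg.reference_name,
        ref_start=seg.reference_start,
        ref_end=seg.reference_end,
        strand="-" if seg.is_reverse else "+",
        mapq=seg.mapping_quality,
        cigar=cigar,
        is_proper_pair=seg.is_proper_pair,
        is_duplicate=seg.is_duplicate,
        is_secondary=seg.is_secondary,
        is_supplementary=seg.is_supplementary,
        mate_unmapped=bool(seg.is_paired and seg.mate_is_unmapped),
        query_sequence=seq,
        clip_left=clip_left,
        clip_right=clip_right,
        template_length=seg.template_length,
        tags=dict(seg.get_tags()),
    )


def parse_alignments(
    path: str | Path,
    min_mapq: int = 0,
    include_duplicates: bool = False,
) -> Iterator[AlignmentRecord]:
    """Stream mapped alignments from a SAM/BAM file.

    Unmapped records are skipped; records below ``min_mapq`` are skipped;
    duplicate-marked records are skipped unless ``include_duplicates``.
    """
    mode = "rb" if str(path).endswith(".bam") else "r"
    with pysam.AlignmentFile(str(path), mode, check_sq=False) as fh:
        for seg in fh:
            if seg.is_unmapped:
                continue
            if seg.mapping_quality < min_mapq:
                continue
            if seg.is_duplicate and not include_duplicates:
                continue
            yield _record_from_segment(seg)


def _flag(rec: AlignmentRecord) -> int:
    flag = 0
    if rec.mate_index is not None:
        flag |= 0x1
        if rec.is_proper_pair:
            flag |= 0x2
        if rec.mate_unmapped:
            flag |= 0x8
        flag |= 0x40 if rec.mate_index == 1 else 0x80
    if rec.strand == "-":
        flag |= 0x10
    if rec.is_secondary:
        flag |= 0x100
    if rec.is_duplicate:
        flag |= 0x400
    if rec.is_supplementary:
        flag |= 0x800
    return flag


def write_alignments(
    records: Sequence[AlignmentRecord],
    path: str | Path,
    references: dict[str, int],
) -> None:
    """Write AlignmentRecords to SAM/BAM. ``references`` maps name -> length."""
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": n, "LN": ln} for n, ln in references.items()],
    }
    mode = "wb" if str(path).endswith(".bam") else "w"
    with pysam.AlignmentFile(str(path), mode, header=header) as out:
        tid = {n: i for i, n in enumerate(references)}
        for rec in records:
            seg = pysam.AlignedSegment(out.header)
            seg.query_name = rec.read_id
            seg.flag = _flag(rec)
            seg.reference_id = tid[rec.ref_name]
            seg.reference_start = rec.ref_start
            seg.mapping_quality = rec.mapq
            seg.cigarstring = "".join(f"{n}{op}" for op, n in rec.cigar)
            seg.query_sequence = rec.query_sequence
            seg.template_length = rec.template_length
            for tag, value in rec.tags.items():
                seg.set_tag(tag, value)
            out.write(seg)


# ---------------------------------------------------------------------------
# GFF3

@dataclass
class GffFeature:
    chrom: str
    source: str
    feature_type: str
    start: int  # 1-based inclusive (GFF convention, converted at boundary)
    end: int  # 1-based inclusive
    score: str
    strand: str
    attributes: dict[str, str]


def write_gff(features: Iterable[GffFeature], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in features:
            attrs = ";".join(f"{quote(k, safe='')}={quote(str(v), safe='')}" for k, v in f.attributes.items())
            fh.write(
                "\t".join(
                    [
                        f.chrom,
                        f.source,
                        f.feature_type,
                        str(f.start),
                        str(f.end),
                        f.score,
                        f.strand,
                        ".",
                        attrs or ".",
                    ]
                )
                + "\n"
            )


def read_gff(path: str | Path) -> list[GffFeature]:
    out: list[GffFeature] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise ValueError(f"malformed GFF3 line: {line!r}")
            attrs: dict[str, str] = {}
            if cols[8] != ".":
                for pair in cols[8].split(";"):
                    if not pair:
                        continue
                    k, _, v = pair.partition("=")
                    attrs[unquote(k)] = unquote(v)
            out.append(
                GffFeature(
                    chrom=cols[0],
                    source=cols[1],
                    feature_type=cols[2],
                    start=int(cols[3]),
                    end=int(cols[4]),
                    score=cols[5],
                    strand=cols[6],
                    attributes=attrs,
                )
            )
    return out


# ---------------------------------------------------------------------------
# BED

def read_bed(path: str | Path, feature_class: str = "track") -> list[IntervalFeature]:
    """Read a 3-6 column BED file (0-based half-open, as BED is)."""
    out: list[IntervalFeature] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            out.append(
                IntervalFeature(
                    chrom=cols[0],
                    start=int(cols[1]),
                    end=int(cols[2]),
                    name=cols[3] if len(cols) > 3 else ".",
                    strand=cols[5] if len(cols) > 5 else ".",
                    feature_class=feature_class,
                )
            )
    return out


# ---------------------------------------------------------------------------
# Insertion catalogs (TSV)

#: canonical column name -> CatalogRow field
DEFAULT_CATALOG_COLUMNS = {
    "sample_id": "sample_id",
    "genotype": "genotype",
    "tissue": "tissue",
    "chrom": "chrom",
    "position": "position",
    "te_family": "te_family",
    "te_class": "te_class",
    "tsd_sequence": "tsd_sequence",
    "tsd_length": "tsd_length",
    "support_split": "support_split",
    "support_mate": "support_mate",
    "allele_frequency": "allele_frequency",
}

_MANDATORY = ("sample_id", "chrom", "position", "te_family")


def read_catalog(
    path: str | Path,
    column_map: dict[str, str] | None = None,
    delimiter: str = "\t",
) -> list[CatalogRow]:
    """Read an insertion catalog table.

    ``column_map`` maps file column header -> CatalogRow field, absorbing
    supplementary-table header variation; identity mapping by default.
    """
    colmap = dict(DEFAULT_CATALOG_COLUMNS)
    if column_map:
        colmap.update(column_map)
    rows: list[CatalogRow] = []
    errors: list[str] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter=delimiter)
        header = reader.fieldnames or []
        mapped = {c: colmap[c] for c in header if c in colmap}
        present_fields = set(mapped.values())
        for need in _MANDATORY:
            if need not in present_fields:
                raise ValueError(f"catalog {path} is missing mandatory column {need!r}")
        for lineno, raw in enumerate(reader, start=2):
            kwargs: dict = {"genotype": "", "tissue": ""}
            try:
                for col, fld in mapped.items():
                    val = raw[col]
                    if fld == "position":
                        kwargs[fld] = int(val)
                    elif fld in ("tsd_length", "support_split", "support_mate"):
                        kwargs[fld] = int(val) if val not in ("", None) else 0
                    elif fld == "allele_frequency":
                        kwargs[fld] = float(val) if val not in ("", "NA", None) else None
                    else:
                        kwargs[fld] = val if val is not None else ""
                rows.append(CatalogRow(**kwargs))
            except (ValueError, TypeError) as exc:
                errors.append(f"line {lineno}: {exc}")
    if errors:
        raise ValueError(f"catalog {path} had malformed rows:\n" + "\n".join(errors))
    return rows


def write_catalog(rows: Iterable[CatalogRow], path: str | Path, delimiter: str = "\t") -> None:
    fields = list(DEFAULT_CATALOG_COLUMNS)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter=delimiter)
        writer.writerow(fields)
        for r in rows:
            writer.writerow(
                [
                    r.sample_id,
                    r.genotype,
                    r.tissue,
                    r.chrom,
                    r.position,
                    r.te_family,
                    r.te_class,
                    r.tsd_sequence,
                    r.tsd_length,
                    r.support_split,
                    r.support_mate,
                    "" if r.allele_frequency is None else f"{r.allele_frequency:.6g}",
                ]
            )
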