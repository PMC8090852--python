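"""Downstream statistics on insertion call sets.

Covers allele-frequency and cell-fraction estimation, timing of insertions
relative to the clonal (neoplasia-initiating) event, per-family TSD length
summaries, family/class counts, target-site flank extraction, genic
annotation, and interval-enrichment testing with Fisher's exact test and
Benjamini-Hochberg correction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from intervaltree import IntervalTree

from .seqio import CatalogRow, IntervalFeature, SequenceRecord

__all__ = [
    "FrequencyEstimate",
    "TimingClass",
    "EnrichmentRow",
    "MotifSummary",
    "allele_frequency",
    "cell_fraction",
    "classify_timing",
    "tsd_summary",
    "family_counts",
    "extract_flanks",
    "annotate_genic",
    "enrichment",
    "estimate_site_frequency",
]

DEFAULT_SEX_CHROMS = ("X", "chrX", "Y", "chrY")


@dataclass(frozen=True)
class FrequencyEstimate:
    support_pairs: int
    opposing_pairs: int
    allele_frequency: float | None
    cell_fraction: float | None = None


@dataclass(frozen=True)
class TimingClass:
    insertion_cf: float
    clonal_cf: float

    @property
    def label(self) -> str:
        return "pre_clonal" if self.insertion_cf >= self.clonal_cf else "post_clonal"


@dataclass
class EnrichmentRow:
    track: str
    a: int  # calls in track
    b: int  # calls out of track
    c: int  # background units in track
    d: int  # background units out
    odds_ratio: float
    signed_enrichment: float
    p_fisher: float
    p_adjusted: float = float("nan")
    significant: bool = False
    untestable: bool = False


@dataclass
class MotifSummary:
    flanks: list[str]
    base_frequencies: np.ndarray  # (positions, 4) order A,C,G,T
    at_fraction: float
    information_content: np.ndarray  # bits per position
    skipped: int = 0


# ---------------------------------------------------------------------------
# allele frequency / cell fraction / timing

def allele_frequency(support_pairs: int, opposing_pairs: int) -> FrequencyEstimate:
    """AF = supporting / (supporting + opposing) read pairs; each pair counts
    once. Undefined (None) when no pairs overlap the site."""
    if support_pairs < 0 or opposing_pairs < 0:
        raise ValueError("pair counts must be non-negative")
    total = support_pairs + opposing_pairs
    af = support_pairs / total if total > 0 else None
    return FrequencyEstimate(support_pairs, opposing_pairs, af)


def cell_fraction(
    af: float,
    chrom: str,
    sex: str = "male",
    sex_chroms: Sequence[str] = DEFAULT_SEX_CHROMS,
    known_chroms: Sequence[str] | None = None,
) -> float:
    """Fraction of cells carrying the insertion.

    Autosomal insertions in diploid cells double the allele frequency
    (capped at 1); insertions on the hemizygous male X use the allele
    frequency directly.
    """
    if known_chroms is not None and chrom not in known_chroms:
        raise ValueError(f"unknown chromosome {chrom!r}")
    if chrom in sex_chroms and sex == "male":
        return min(af, 1.0)
    return min(2.0 * af, 1.0)


def classify_timing(insertion_cf: float, clonal_event_cf: float | None) -> TimingClass:
    """Pre-clonal when the insertion's cell fraction is at least that of the
    clonal (neoplasia-initiating) event, post-clonal otherwise."""
    if clonal_event_cf is None:
        raise ValueError("missing clonal event cell fraction")
    return TimingClass(insertion_cf, clonal_event_cf)


def estimate_site_frequency(
    alignments: Iterable,
    supporting_read_ids: set[str],
    chrom: str,
    point: int,
) -> FrequencyEstimate:
    """Count supporting vs opposing read pairs at a 0-based insertion point.

    A pair supports the insertion when any of its reads is in
    ``supporting_read_ids`` (cluster evidence); it opposes when it is a
    proper pair spanning the point with no junction clip on the spanning
    read and no TE evidence. Each read pair contributes once.
    """
    support: set[str] = set()
    opposing: set[str] = set()
    for aln in alignments:
        if aln.ref_name != chrom:
            continue
        if aln.read_id in supporting_read_ids:
            support.add(aln.read_id)
            continue
        if not aln.is_proper_pair:
            continue
        # spanning read: covers the point with aligned (non-clipped) bases
        if aln.ref_start < point < aln.ref_end and not aln.clip_left and not aln.clip_right:
            opposing.add(aln.read_id)
        elif aln.template_length:
            # pair-spanning without read overlap: fragment covers the point
            if aln.template_length > 0 and aln.ref_start < point < aln.ref_start + aln.template_length:
                opposing.add(aln.read_id)
    opposing -= support
    return allele_frequency(len(support), len(opposing))


# ---------------------------------------------------------------------------
# catalog summaries

def tsd_summary(catalog: Sequence[CatalogRow], min_insertions: int = 6) -> pd.DataFrame:
    """Per-family TSD length median/IQR for families with enough insertions
    (genotypes pooled)."""
    rows = [(r.te_family, r.tsd_length) for r in catalog if r.tsd_length > 0]
    df = pd.DataFrame(rows, columns=["te_family", "tsd_length"])
    if df.empty:
        return pd.DataFrame(columns=["te_family", "n", "median", "q25", "q75"])
    g = df.groupby("te_family")["tsd_length"]
    out = pd.DataFrame(
        {
            "n": g.size(),
            "median": g.median(),
            "q25": g.quantile(0.25),
            "q75": g.quantile(0.75),
        }
    ).reset_index()
    out = out[out["n"] >= min_insertions].sort_values("te_family").reset_index(drop=True)
    return out


def family_counts(
    catalog: Sequence[CatalogRow],
    group_by: Sequence[str] = ("te_family",),
    class_table: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Group-by counts over catalog rows; families absent from the class
    table are counted under class "unknown"."""
    if not catalog:
        return pd.DataFrame(columns=[*group_by, "count"])
    recs = []
    for r in catalog:
        d = {
            "sample_id": r.sample_id,
            "genotype": r.genotype,
            "tissue": r.tissue,
            "te_family": r.te_family,
            "te_class": (
                class_table.get(r.te_family, "unknown") if class_table is not None else r.te_class
            ),
        }
        recs.append(d)
    df = pd.DataFrame(recs)
    out = df.groupby(list(group_by)).size().reset_index(name="count")
    return out.sort_values(list(group_by)).reset_index(drop=True)


# ---------------------------------------------------------------------------
# flanks

def extract_flanks(
    calls: Sequence[CatalogRow],
    reference: Mapping[str, str] | Sequence[SequenceRecord],
    flank: int = 10,
    include_tsd: bool = False,
) -> MotifSummary:
    """Target-site flank windows around each insertion.

    Per call: the ``flank`` bases 5' of the TSD span, then (optionally) the
    TSD, then the ``flank`` bases 3' of the span. Calls too close to a contig
    end are skipped and counted.
    """
    if not isinstance(reference, Mapping):
        reference = {r.id: r.sequence for r in reference}
    flanks: list[str] = []
    skipped = 0
    for call in calls:
        seq = reference.get(call.chrom)
        if seq is None:
            skipped += 1
            continue
        span_start = call.position - 1  # 0-based first duplicated base
        span_end = span_start + call.tsd_length
        if span_start - flank < 0 or span_end + flank > len(seq):
            skipped += 1
            continue
        left = seq[span_start - flank : span_start]
        right = seq[span_end : span_end + flank]
        mid = seq[span_start:span_end] if include_tsd else ""
        flanks.append(left + mid + right)
    if flanks:
        width = max(len(f) for f in flanks)
        counts = np.zeros((width, 4))
        order = {b: i for i, b in enumerate("ACGT")}
        for f in flanks:
            for i, b in enumerate(f):
                if b in order:
                    counts[i, order[b]] += 1
        totals = counts.sum(axis=1, keepdims=True)
        totals[totals == 0] = 1
        freqs = counts / totals
        at = float((counts[:, 0].sum() + counts[:, 3].sum()) / max(1, counts.sum()))
        with np.errstate(divide="ignore", invalid="ignore"):
            plogp = np.where(freqs > 0, freqs * np.log2(freqs), 0.0)
        ic = 2.0 + plogp.sum(axis=1)
    else:
        freqs = np.zeros((0, 4))
        at = 0.0
        ic = np.zeros(0)
    return MotifSummary(flanks, freqs, at, ic, skipped)


def flanks_to_fasta(summary: MotifSummary, path) -> None:
    with open(path, "w") as fh:
        for i, f in enumerate(summary.flanks):
            fh.write(f">flank_{i}\n{f}\n")


# ---------------------------------------------------------------------------
# genic annotation

_CLASS_PRIORITY = ["CDS", "5UTR", "3UTR", "exon", "intron"]


def annotate_genic(
    calls: Sequence[CatalogRow],
    gene_models: Sequence[IntervalFeature],
    window: int = 500,
) -> list[dict]:
    """Label each call with the most specific overlapped feature class and
    the genes within +-window of it.

    Feature classes considered, most specific first: CDS (coding exon),
    5UTR, 3UTR, exon, intron; a call overlapping none is intergenic. Gene
    association uses gene-span features widened by ``window``.
    """
    trees: dict[tuple[str, str], IntervalTree] = {}
    gene_trees: dict[str, IntervalTree] = {}
    for f in gene_models:
        cls = f.feature_class
        if cls == "gene":
            gene_trees.setdefault(f.chrom, IntervalTree()).addi(
                max(0, f.start - window), f.end + window, f.name
            )
        else:
            if cls not in _CLASS_PRIORITY:
                raise ValueError(f"unrecognized feature class {cls!r} for {f.name!r}")
            trees.setdefault((f.chrom, cls), IntervalTree()).addi(f.start, f.end, f.name)
    out: list[dict] = []
    for call in calls:
        pos = call.position - 1
        label = "intergenic"
        for cls in _CLASS_PRIORITY:
            tree = trees.get((call.chrom, cls))
            if tree is not None and tree.overlaps_point(pos):
                label = cls
                break
        genes = sorted(
            {iv.data for iv in gene_trees.get(call.chrom, IntervalTree()).at(pos)}
        )
        out.append(
            {
                "chrom": call.chrom,
                "position": call.position,
                "te_family": call.te_family,
                "feature_class": label,
                "genes": genes,
            }
        )
    return out


# ---------------------------------------------------------------------------
# enrichment

def _interval_tree(track: Sequence[IntervalFeature]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for f in track:
        trees.setdefault(f.chrom, IntervalTree()).addi(f.start, f.end)
    return trees


def _points_in_track(points: Sequence[tuple[str, int]], trees: dict[str, IntervalTree]) -> int:
    n = 0
    for chrom, pos in points:
        t = trees.get(chrom)
        if t is not None and t.overlaps_point(pos):
            n += 1
    return n


def _sample_background_points(
    background: Sequence[IntervalFeature],
    n: int,
    rng: np.random.Generator,
) -> list[tuple[str, int]]:
    lengths = np.array([f.end - f.start for f in background], dtype=float)
    probs = lengths / lengths.sum()
    idx = rng.choice(len(background), size=n, p=probs)
    out = []
    for i in idx:
        f = background[i]
        out.append((f.chrom, int(rng.integers(f.start, f.end))))
    return out


def enrichment(
    calls: Sequence[tuple[str, int]],
    tracks: Mapping[str, Sequence[IntervalFeature]],
    background: Sequence[IntervalFeature],
    alpha: float = 0.05,
    p_threshold: float = 0.001,
    e_threshold: float = 1.5,
    background_factor: int = 100,
    seed: int = 0,
    mode: str = "sites",
) -> list[EnrichmentRow]:
    """Per-track overlap enrichment of insertion sites.

    ``calls`` are (chrom, 0-based position) points. For each track a 2x2
    table is built: calls in/out of the track vs background units in/out.
    In ``sites`` mode the background units are ``background_factor`` x
    len(calls) random points drawn (seeded) from the mappable background
    intervals; in ``bases`` mode they are the base-pair totals of the
    background inside/outside the track. Two-sided Fisher exact p-values are
    BH-adjusted across tracks (step-up, ``alpha``); a row is significant when
    the adjusted p is below ``p_threshold`` and the signed observed/expected
    enrichment exceeds ``e_threshold`` in magnitude.
    """
    rng = np.random.default_rng(seed)
    rows: list[EnrichmentRow] = []
    if mode == "sites":
        bg_points = _sample_background_points(background, background_factor * max(1, len(calls)), rng)
    track_names = sorted(tracks)
    total_bg_bases = sum(f.end - f.start for f in background)
    for name in track_names:
        trees = _interval_tree(tracks[name])
        a = _points_in_track(calls, trees)
        b = len(calls) - a
        if mode == "sites":
            c = _points_in_track(bg_points, trees)
            d = len(bg_points) - c
        else:
            c = 0
            for f in background:
                t = trees.get(f.chrom)
                if t is None:
                    continue
                for iv in t.overlap(f.start, f.end):
                    c += min(iv.end, f.end) - max(iv.begin, f.start)
            d = total_bg_bases - c
        untestable = c == 0
        if untestable:
            rows.append(EnrichmentRow(name, a, b, c, d, float("nan"), float("nan"), 1.0, untestable=True))
            continue
        odds, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
        obs = a / (a + b) if (a + b) else 0.0
        exp = c / (c + d)
        if exp == 0.0:
            r = math.inf if obs > 0 else 1.0
        else:
            r = obs / exp if obs > 0 else 0.0
        if r >= 1.0:
            signed = r
        elif r > 0:
            signed = -1.0 / r
        else:
            signed = -math.inf
        rows.append(EnrichmentRow(name, a, b, c, d, float(odds), signed, float(p)))
    testable = [r for r in rows if not r.untestable]
    if testable:
        adj = multipletests([r.p_fisher for r in testable], alpha=alpha, method="fdr_bh")[1]
        for r, q in zip(testable, adj):
            r.p_adjusted = float(q)
            r.significant = bool(q < p_threshold and abs(r.signed_enrichment) > e_threshold)
    return rows
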