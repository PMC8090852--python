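"""Cross-sample confirmation and panel-of-normals somatic filtering.

Candidates from different samples are linked by genomic position (within a
slop), TE family, and junction clip-sequence compatibility. A case-sample
candidate is somatic when no control (panel) candidate shares its link key
and the candidate carries a valid target-site duplication. Inverting the
case/control roles inverts the direction of exclusion, never the keys.
"""

from __future__ import annotations

from bisect import bisect_left, bisect_right
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .cluster_caller import InsertionCandidate, clips_match

__all__ = [
    "SampleManifest",
    "SomaticCall",
    "prefilter_support",
    "link_keys_match",
    "confirm_somatic",
    "classify_germline",
    "per_family_germline_mode",
]

DEFAULT_SLOP = 50


@dataclass(frozen=True)
class SampleManifest:
    sample_id: str
    individual_id: str
    tissue: str  # gut | head | other
    genotype: str = ""
    role: str = "case"  # case | control


@dataclass
class SomaticCall:
    candidate: InsertionCandidate
    sample_id: str
    shared_with: list[str] = field(default_factory=list)
    needs_review: bool = False


def prefilter_support(candidates: Iterable[InsertionCandidate]) -> list[InsertionCandidate]:
    """Retain candidates with both split-read and mate-pair support."""
    return [
        c
        for c in candidates
        if c.cluster.split_support >= 1 and c.cluster.mate_support >= 1
    ]


def link_keys_match(
    a: InsertionCandidate,
    b: InsertionCandidate,
    slop: int = DEFAULT_SLOP,
    match_family: bool = True,
) -> bool:
    """Do two candidates (possibly from different samples) describe the same
    insertion? Same chromosome (and family, unless ``match_family`` is off),
    positions within ``slop``, and no contradictory junction clip on either
    side."""
    if a.chrom != b.chrom:
        return False
    if match_family and a.te_family != b.te_family:
        return False
    if abs(a.insertion_point - b.insertion_point) > slop:
        return False
    ca, cb = a.cluster, b.cluster
    for side, x, y in (("5p", ca.clip_seq_5p, cb.clip_seq_5p), ("3p", ca.clip_seq_3p, cb.clip_seq_3p)):
        if x and y and not clips_match(x, y, side):
            return False
    return True


class _CandidateIndex:
    """Position-sorted per-(chrom, family) index for slop queries."""

    def __init__(
        self,
        candidates: Iterable[tuple[str, InsertionCandidate]],
        by_family: bool = True,
    ):
        self._by_family = by_family
        self._by_key: dict[tuple, list[tuple[int, str, InsertionCandidate]]] = {}
        for sample_id, c in candidates:
            key = (c.chrom, c.te_family) if by_family else (c.chrom,)
            self._by_key.setdefault(key, []).append((c.insertion_point, sample_id, c))
        for lst in self._by_key.values():
            lst.sort(key=lambda t: t[0])

    def near(
        self, cand: InsertionCandidate, slop: int
    ) -> list[tuple[str, InsertionCandidate]]:
        key = (cand.chrom, cand.te_family) if self._by_family else (cand.chrom,)
        lst = self._by_key.get(key, [])
        pos = [t[0] for t in lst]
        lo = bisect_left(pos, cand.insertion_point - slop)
        hi = bisect_right(pos, cand.insertion_point + slop)
        return [(s, c) for _, s, c in lst[lo:hi]]


def confirm_somatic(
    candidates_by_sample: Mapping[str, Sequence[InsertionCandidate]],
    panel_of_normals: Sequence[InsertionCandidate],
    manifest: Sequence[SampleManifest],
    slop: int = DEFAULT_SLOP,
    require_tsd: bool = True,
    match_family: bool = True,
) -> dict[str, list[SomaticCall]]:
    """Somatic call set per case sample.

    A candidate survives when (a) no panel candidate shares its link key and
    (b) it carries a valid TSD. Each surviving call is annotated with the
    other case samples sharing its key, and flagged ``needs_review`` when a
    linked sample's junction estimate disagrees by more than slop/2 (the
    machine stand-in for manual inspection of imprecise annotations).
    """
    roles = {m.sample_id: m.role for m in manifest}
    panel_index = _CandidateIndex(
        (("panel", c) for c in panel_of_normals), by_family=match_family
    )
    case_samples = [s for s in candidates_by_sample if roles.get(s, "case") == "case"]
    case_index = _CandidateIndex(
        ((s, c) for s in case_samples for c in candidates_by_sample[s]),
        by_family=match_family,
    )
    out: dict[str, list[SomaticCall]] = {}
    for sample in case_samples:
        calls: list[SomaticCall] = []
        for cand in candidates_by_sample[sample]:
            if require_tsd and cand.tsd is None:
                continue
            in_panel = any(
                link_keys_match(cand, pc, slop, match_family)
                for _, pc in panel_index.near(cand, slop)
            )
            if in_panel:
                continue
            shared: list[str] = []
            needs_review = False
            for other_sample, oc in case_index.near(cand, slop):
                if other_sample == sample or not link_keys_match(cand, oc, slop, match_family):
                    continue
                if other_sample not in shared:
                    shared.append(other_sample)
                if abs(oc.insertion_point - cand.insertion_point) > slop / 2:
                    needs_review = True
            calls.append(
                SomaticCall(
                    candidate=cand,
                    sample_id=sample,
                    shared_with=sorted(shared),
                    needs_review=needs_review,
                )
            )
        out[sample] = calls
    return out


# ---------------------------------------------------------------------------
# germline classification

def classify_germline(
    candidates_by_sample: Mapping[str, Sequence[InsertionCandidate]],
    manifest: Sequence[SampleManifest],
    site_coverage: Mapping[tuple[str, int], float] | None = None,
    min_median_coverage: float = 10.0,
    slop: int = DEFAULT_SLOP,
) -> list[dict]:
    """Classify linked sites as germline based on both-tissue evidence.

    A site with a TSD-valid call in both tissues of at least one individual
    is germline; it is discarded when its median coverage across samples is
    below ``min_median_coverage``. Germline sites present in every individual
    of a genotype are ``germline_shared``; in exactly one, ``germline_private``;
    in several but not all, ``germline``. Sites only seen in individuals
    lacking a second tissue are ``ambiguous``.
    """
    by_sample = {m.sample_id: m for m in manifest}
    individuals: dict[str, set[str]] = {}
    genotype_of: dict[str, str] = {}
    for m in manifest:
        individuals.setdefault(m.individual_id, set()).add(m.tissue)
        genotype_of[m.individual_id] = m.genotype

    # link all TSD-valid candidates across samples into sites (single linkage)
    items: list[tuple[str, InsertionCandidate]] = [
        (s, c)
        for s, cands in candidates_by_sample.items()
        for c in cands
        if c.tsd is not None and s in by_sample
    ]
    n = len(items)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    order = sorted(range(n), key=lambda i: (items[i][1].chrom, items[i][1].insertion_point))
    for a_i in range(len(order)):
        i = order[a_i]
        for b_i in range(a_i + 1, len(order)):
            j = order[b_i]
            if items[j][1].chrom != items[i][1].chrom:
                break
            if items[j][1].insertion_point - items[i][1].insertion_point > slop:
                break
            if link_keys_match(items[i][1], items[j][1], slop):
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[max(ri, rj)] = min(ri, rj)

    sites: dict[int, list[tuple[str, InsertionCandidate]]] = {}
    for i in range(n):
        sites.setdefault(find(i), []).append(items[i])

    out: list[dict] = []
    for members in sites.values():
        tissues_by_ind: dict[str, set[str]] = {}
        for sample_id, _ in members:
            m = by_sample[sample_id]
            tissues_by_ind.setdefault(m.individual_id, set()).add(m.tissue)
        germline_inds = sorted(
            ind for ind, ts in tissues_by_ind.items() if len(ts & individuals.get(ind, set())) >= 2
        )
        rep = members[0][1]
        site = {
            "chrom": rep.chrom,
            "position": rep.insertion_point,
            "te_family": rep.te_family,
            "individuals": sorted(tissues_by_ind),
            "germline_individuals": germline_inds,
        }
        if not germline_inds:
            both_tissue_possible = any(
                len(individuals.get(ind, set())) >= 2 for ind in tissues_by_ind
            )
            site["class"] = "ambiguous" if not both_tissue_possible else "not_germline"
            out.append(site)
            continue
        if site_coverage is not None:
            cov = site_coverage.get((rep.chrom, rep.insertion_point))
            if cov is not None and cov < min_median_coverage:
                site["class"] = "discarded_low_coverage"
                out.append(site)
                continue
        genos = {genotype_of[ind] for ind in germline_inds}
        n_inds = len(germline_inds)
        full_cohort = False
        if len(genos) == 1:
            geno = next(iter(genos))
            cohort = {ind for ind, g in genotype_of.items() if g == geno}
            full_cohort = set(germline_inds) == cohort
        if full_cohort and n_inds > 1:
            site["class"] = "germline_shared"
        elif n_inds == 1:
            site["class"] = "germline_private"
        else:
            site["class"] = "germline"
        out.append(site)
    out.sort(key=lambda s: (s["chrom"], s["position"]))
    return out


def per_family_germline_mode(
    candidates_by_sample: Mapping[str, Sequence[InsertionCandidate]],
    family: str,
    manifest: Sequence[SampleManifest],
    slop: int = DEFAULT_SLOP,
) -> dict[str, list[SomaticCall]]:
    """Family-private inherited calls: confirm the given family's candidates
    against a panel made of every *other* family's candidates."""
    families = {
        c.te_family for cands in candidates_by_sample.values() for c in cands
    }
    if family not in families:
        raise ValueError(f"unknown family {family!r}")
    focal = {
        s: [c for c in cands if c.te_family == family]
        for s, cands in candidates_by_sample.items()
    }
    panel = [
        c
        for cands in candidates_by_sample.values()
        for c in cands
        if c.te_family != family
    ]
    return confirm_somatic(focal, panel, manifest, slop=slop, match_family=False)
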