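"""Clustering, TSD inference, clip linkage, and candidate emission."""

import random

import numpy as np
import pytest

from teclone import cluster_caller as cc
from teclone import seqio, tagger
from teclone.cluster_caller import (
    EvidenceCluster,
    InsertDistanceInterval,
    call_tsd,
    clips_match,
    emit_candidates,
    estimate_insert_interval,
    find_clusters,
    link_softclips,
)
from teclone.seqio import AlignmentRecord
from teclone.tagger import TaggedRead, TeHit


def _pair_record(tlen, proper=True):
    return AlignmentRecord(
        read_id=f"r{tlen}_{random.random()}",
        mate_index=1,
        ref_name="c",
        ref_start=0,
        ref_end=100,
        strand="+",
        mapq=60,
        cigar=[("M", 100)],
        is_proper_pair=proper,
        template_length=tlen,
    )


class TestInsertInterval:
    def test_degenerate_distribution(self):
        alns = [_pair_record(250) for _ in range(10)]
        iv = estimate_insert_interval(alns)
        assert (iv.low, iv.high) == (250, 250)

    def test_matches_sorted_percentile_oracle(self):
        rng = np.random.default_rng(7)
        tlens = np.round(rng.normal(300, 30, size=1000)).astype(int)
        alns = [_pair_record(int(t)) for t in tlens]
        iv = estimate_insert_interval(alns)

        # oracle: linear-interpolated percentile computed by hand from sort
        def pct(sorted_vals, q):
            h = (len(sorted_vals) - 1) * q
            lo, hi = int(np.floor(h)), int(np.ceil(h))
            return sorted_vals[lo] + (h - lo) * (sorted_vals[hi] - sorted_vals[lo])

        s = np.sort(np.abs(tlens)).astype(float)
        assert iv.low == pytest.approx(pct(s, 0.025))
        assert iv.high == pytest.approx(pct(s, 0.975))

    def test_file_and_memory_representations_agree(self, tmp_path):
        rng = np.random.default_rng(8)
        alns = [_pair_record(int(t)) for t in rng.normal(300, 25, size=200)]
        for i, a in enumerate(alns):
            a.read_id = f"r{i}"
            a.query_sequence = "A" * 100
        p = tmp_path / "pairs.sam"
        seqio.write_alignments(alns, p, {"c": 10_000})
        from_file = estimate_insert_interval(seqio.parse_alignments(p))
        in_memory = estimate_insert_interval(alns)
        assert (from_file.low, from_file.high) == (in_memory.low, in_memory.high)

    def test_too_few_pairs_errors(self):
        with pytest.raises(ValueError, match="2 proper pairs"):
            estimate_insert_interval([_pair_record(250)])


def _split_read(rid, junction, side, clip, chrom="c", fam="rover", read_len=100):
    """A split TaggedRead whose clip sits at the given junction."""
    k = len(clip)
    if side == "5p":  # right-clipped, alignment ends at the junction
        start = junction - (read_len - k)
        cigar = [("M", read_len - k), ("S", k)]
        seq = "A" * (read_len - k) + clip
        aln = AlignmentRecord(rid, 1, chrom, start, junction, "+", 60, cigar,
                              query_sequence=seq, clip_right=clip)
        hit = TeHit("rover", fam, 0, k, read_len - k, read_len, "same", float(k))
    else:  # left-clipped, alignment starts at the junction
        cigar = [("S", k), ("M", read_len - k)]
        seq = clip + "A" * (read_len - k)
        aln = AlignmentRecord(rid, 1, chrom, junction, junction + read_len - k, "+",
                              60, cigar, query_sequence=seq, clip_left=clip)
        hit = TeHit("rover", fam, 0, k, 0, k, "same", float(k))
    return TaggedRead(aln, "self", hit)


def _mate_read(rid, start, strand, chrom="c", fam="rover", read_len=100):
    aln = AlignmentRecord(rid, 1, chrom, start, start + read_len, strand, 60,
                          [("M", read_len)], query_sequence="A" * read_len)
    return TaggedRead(aln, "mate", TeHit("rover", fam, 0, 50, 0, 50, "same", 50.0))


IV = InsertDistanceInterval(200, 400)


class TestFindClusters:
    def test_empty_input(self):
        assert find_clusters([], IV) == []

    def test_constructed_fixture_support_counts(self):
        reads = (
            [_split_read(f"f{i}", 1005, "5p", "CCCCCCCCCCCC") for i in range(3)]
            + [_split_read(f"r{i}", 1000, "3p", "GGGGGGGGGGGG") for i in range(3)]
            + [_mate_read(f"m{i}", 700 + 10 * i, "+") for i in range(2)]
            + [_mate_read(f"n{i}", 1100 + 10 * i, "-") for i in range(2)]
        )
        clusters = find_clusters(reads, IV)
        assert len(clusters) == 1
        cl = clusters[0]
        assert cl.split_support == 6
        assert cl.mate_support == 4
        assert cl.junction_5p == 1005
        assert cl.junction_3p == 1000

    def test_two_distant_implants_give_two_clusters(self):
        reads = [_split_read("a1", 1000, "5p", "C" * 15), _split_read("a2", 995, "3p", "G" * 15)]
        reads += [_split_read("b1", 11_000, "5p", "C" * 15), _split_read("b2", 10_995, "3p", "G" * 15)]
        clusters = find_clusters(reads, IV)
        assert len(clusters) == 2

    def test_disagreeing_clips_split_cluster(self):
        reads = [
            _split_read("x1", 1000, "5p", "CCCCCCCCCCCCCCC"),
            _split_read("x2", 1000, "5p", "GGGGGGGGGGGGGGG"),
        ]
        assert len(find_clusters(reads, IV)) == 2

    def _random_reads(self, rng, n):
        reads = []
        for i in range(n):
            kind = rng.choice(["5p", "3p", "mate+", "mate-"])
            pos = int(rng.integers(0, 5000))
            if kind in ("5p", "3p"):
                clip = "".join(rng.choice(list("ACGT"), size=int(rng.integers(5, 20))))
                reads.append(_split_read(f"s{i}", pos + 200, kind, clip))
            else:
                reads.append(_mate_read(f"s{i}", pos, "+" if kind == "mate+" else "-"))
        return reads

    def test_equals_brute_force_single_linkage(self):
        """On small instances, clustering equals exhaustive single linkage
        under the same pairwise compatibility predicate."""
        rng = np.random.default_rng(13)
        for trial in range(5):
            reads = self._random_reads(rng, 120)
            clusters = find_clusters(reads, IV)
            # oracle: O(n^2) union-find over all pairs
            evs = [cc._side_evidence(t) for t in reads]
            parent = list(range(len(evs)))

            def find(i):
                while parent[i] != i:
                    i = parent[i]
                return i

            for i in range(len(evs)):
                for j in range(i + 1, len(evs)):
                    if cc.reads_compatible(evs[i], evs[j], IV.high):
                        ri, rj = find(i), find(j)
                        if ri != rj:
                            parent[rj] = ri
            expected = {}
            for i, t in enumerate(reads):
                expected.setdefault(find(i), set()).add(t.alignment.read_id)
            got = {frozenset(t.alignment.read_id for t in cl.reads()) for cl in clusters}
            assert got == {frozenset(v) for v in expected.values()}

    def test_conservation_no_read_lost_or_duplicated(self):
        rng = np.random.default_rng(17)
        reads = self._random_reads(rng, 150)
        clusters = find_clusters(reads, IV)
        assigned = [t.alignment.read_id for cl in clusters for t in cl.reads()]
        assert sorted(assigned) == sorted(t.alignment.read_id for t in reads)

    def test_monotonicity_adding_read_never_shrinks_support(self):
        base = [_split_read(f"f{i}", 1005, "5p", "C" * 12) for i in range(3)]
        extra = _mate_read("extra", 900, "+")
        before = find_clusters(base, IV)
        after = find_clusters(base + [extra], IV)
        assert len(after) <= len(before) + 1
        assert sum(c.split_support + c.mate_support for c in after) == sum(
            c.split_support + c.mate_support for c in before
        ) + 1


class TestClipsMatch:
    def test_one_mismatch_in_ten_passes_ninety_percent(self):
        a = "ACGTACGTAC"
        b = a[:-1] + ("T" if a[-1] != "T" else "G")
        assert clips_match(a, b, "5p")

    def test_anchoring_five_prime_compares_shared_prefix(self):
        # 18/20 positions agree: passes 90%; wholesale disagreement fails
        assert clips_match("A" * 18 + "CG", "A" * 18 + "TT", "5p", min_len=10)
        assert not clips_match("CAAAAAAAAACGT", "GTTTTTTTTTCGT", "5p", min_len=10)

    def test_shorter_clip_compared_against_longer(self):
        # shorter (12) is a junction-anchored prefix of the longer (30)
        assert clips_match("ACGTACGTACGT", "ACGTACGTACGT" + "C" * 18, "5p")
        assert clips_match("C" * 18 + "ACGTACGTACGT", "ACGTACGTACGT", "3p")

    def test_short_clips_are_non_discriminating(self):
        assert clips_match("ACGT", "TTTT", "5p")


class TestCallTsd:
    @pytest.fixture
    def reference(self):
        rng = random.Random(2)
        return {"c": "".join(rng.choice("ACGT") for _ in range(2000))}

    def _cluster(self, p1, p2):
        cl = EvidenceCluster(chrom="c")
        cl.junction_5p = p1
        cl.junction_3p = p2
        return cl

    def test_duplicating_order_yields_tsd(self, reference):
        tsd = call_tsd(self._cluster(1005, 1000), reference)
        assert tsd.length == 5
        assert tsd.sequence == reference["c"][1000:1005]
        assert tsd.span == (1000, 1005)

    def test_non_duplicating_order_yields_none(self, reference):
        assert call_tsd(self._cluster(1000, 1005), reference) is None

    def test_span_beyond_max_tsd_rejected(self, reference):
        assert call_tsd(self._cluster(1061, 1000), reference, max_tsd=60) is None
        assert call_tsd(self._cluster(1060, 1000), reference, max_tsd=60) is not None

    def test_mate_only_cluster_has_no_tsd(self, reference):
        cl = EvidenceCluster(chrom="c")
        cl.junction_5p = 1002  # midpoint junction, no 3' estimate
        assert call_tsd(cl, reference) is None


class TestLinkSoftclips:
    def test_identical_clips_counted(self):
        cl = find_clusters([_split_read("a", 1000, "5p", "CCCCCCCCCCCC")], IV)[0]
        index = {("c", "5p", 1000): ["CCCCCCCCCCCC"] * 4}
        link_softclips([cl], index)
        assert cl.linkage_5p == 4

    def test_last_base_mismatch_counts_under_identity_rule(self):
        cl = find_clusters([_split_read("a", 1000, "5p", "CCCCCCCCCCCC")], IV)[0]
        index = {("c", "5p", 1000): ["CCCCCCCCCCCG"]}
        link_softclips([cl], index)
        assert cl.linkage_5p == 1

    def test_empty_index_zero_counts(self):
        cl = find_clusters([_split_read("a", 1000, "5p", "CCCCCCCCCCCC")], IV)[0]
        link_softclips([cl], {})
        assert cl.linkage_5p == 0 and cl.linkage_3p == 0


class TestEmitCandidates:
    def test_empty_clusters(self, tmp_path):
        cands = emit_candidates([], {"c": "ACGT" * 100})
        assert cands == []
        p = tmp_path / "x.gff3"
        seqio.write_gff([cc.candidate_to_gff(c) for c in cands], p)
        assert seqio.read_gff(p) == []

    def test_majority_family_and_ambiguity(self):
        reads = [_split_read(f"r{i}", 1000, "5p", "C" * 12, fam="rover") for i in range(7)]
        reads.append(_mate_read("m0", 800, "+", fam="copia"))
        rng = random.Random(4)
        ref = {"c": "".join(rng.choice("ACGT") for _ in range(2000))}
        (cand,) = emit_candidates(find_clusters(reads, IV), ref)
        assert cand.te_family == "rover"
        assert cand.ambiguity == pytest.approx(1 / 8)

    def test_insertion_point_follows_tsd_span(self):
        reads = [
            _split_read("a", 1005, "5p", "C" * 12),
            _split_read("b", 1000, "3p", "G" * 12),
        ]
        rng = random.Random(6)
        ref = {"c": "".join(rng.choice("ACGT") for _ in range(2000))}
        (cand,) = emit_candidates(find_clusters(reads, IV), ref)
        assert cand.tsd is not None
        assert cand.insertion_point == cand.tsd.span[0] + 1 == 1001

    def test_evidence_subset_matches_cluster_reads(self):
        reads = [_split_read(f"r{i}", 1000, "5p", "C" * 12) for i in range(5)]
        clusters = find_clusters(reads, IV)
        subset = cc.evidence_reads(clusters)
        assert len(subset) == sum(c.n_reads for c in clusters)
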