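"""Downstream statistics: AF/cell fraction/timing, summaries, flanks,
genic annotation, and enrichment testing."""

import math
from collections import Counter

import numpy as np
import pytest

from teclone.insight import (
    allele_frequency,
    annotate_genic,
    cell_fraction,
    classify_timing,
    enrichment,
    extract_flanks,
    family_counts,
    tsd_summary,
)
from teclone.seqio import CatalogRow, IntervalFeature


def _row(chrom="c", pos=100, fam="rover", tsd_len=5, sample="s1", genotype="g", tissue="gut"):
    return CatalogRow(
        sample_id=sample, genotype=genotype, tissue=tissue, chrom=chrom,
        position=pos, te_family=fam, tsd_sequence="", tsd_length=tsd_len,
    )


class TestAlleleFrequency:
    @pytest.mark.parametrize("s,o,expected", [(0, 12, 0.0), (5, 15, 0.25), (7, 0, 1.0)])
    def test_ratio(self, s, o, expected):
        assert allele_frequency(s, o).allele_frequency == expected

    def test_zero_depth_undefined(self):
        assert allele_frequency(0, 0).allele_frequency is None

    def test_negative_counts_error(self):
        with pytest.raises(ValueError):
            allele_frequency(-1, 2)

    def test_binomial_monte_carlo_calibration(self):
        rng = np.random.default_rng(3)
        true_af, depth, reps = 0.3, 60, 1000
        ests = [allele_frequency(int(k), depth - int(k)).allele_frequency
                for k in rng.binomial(depth, true_af, size=reps)]
        se_mean = math.sqrt(true_af * (1 - true_af) / depth) / math.sqrt(reps)
        assert abs(np.mean(ests) - true_af) <= 3 * se_mean


class TestCellFraction:
    def test_autosome_doubles(self):
        assert cell_fraction(0.25, "chr2L") == 0.5

    def test_male_x_unadjusted(self):
        assert cell_fraction(0.25, "chrX") == 0.25

    def test_capped_at_one(self):
        assert cell_fraction(0.6, "chr2L") == 1.0

    def test_unknown_chromosome_errors(self):
        with pytest.raises(ValueError, match="chrM"):
            cell_fraction(0.2, "chrM", known_chroms=["chr2L", "chrX"])


class TestClassifyTiming:
    def test_rule_branches(self):
        assert classify_timing(0.8, 0.6).label == "pre_clonal"
        assert classify_timing(0.1, 0.6).label == "post_clonal"
        assert classify_timing(0.6, 0.6).label == "pre_clonal"

    def test_missing_clonal_event_errors(self):
        with pytest.raises(ValueError, match="clonal"):
            classify_timing(0.5, None)

    def test_fractions_match_brute_force_tally(self):
        rng = np.random.default_rng(5)
        clonal = {f"s{i}": float(rng.uniform(0.3, 0.9)) for i in range(6)}
        pairs = [(f"s{int(rng.integers(0, 6))}", float(rng.uniform(0, 1))) for _ in range(200)]
        labels = [classify_timing(cf, clonal[s]).label for s, cf in pairs]
        expected = Counter(
            "pre_clonal" if cf >= clonal[s] else "post_clonal" for s, cf in pairs
        )
        assert Counter(labels) == expected


class TestSummaries:
    def test_tsd_median_matches_sort_oracle(self):
        rng = np.random.default_rng(7)
        rows, lengths = [], {}
        for fam, n in [("rover", 20), ("copia", 9), ("blood", 3)]:
            ls = [int(x) for x in rng.integers(2, 26, size=n)]
            lengths[fam] = ls
            rows += [_row(fam=fam, tsd_len=l) for l in ls]
        out = tsd_summary(rows, min_insertions=6)
        assert set(out["te_family"]) == {"rover", "copia"}  # blood below cutoff
        for fam in ("rover", "copia"):
            s = sorted(lengths[fam])
            n = len(s)
            med = s[n // 2] if n % 2 else (s[n // 2 - 1] + s[n // 2]) / 2
            assert out.set_index("te_family").loc[fam, "median"] == med

    def test_family_counts_equal_hash_tally(self):
        rng = np.random.default_rng(9)
        fams = ["rover", "copia", "I-element", "FB"]
        rows = [_row(fam=str(rng.choice(fams))) for _ in range(150)]
        out = family_counts(rows)
        tally = Counter(r.te_family for r in rows)
        assert dict(zip(out["te_family"], out["count"])) == dict(tally)

    def test_empty_catalog(self):
        assert family_counts([]).empty
        assert tsd_summary([]).empty

    def test_class_table_maps_unknown(self):
        rows = [_row(fam="rover"), _row(fam="mystery")]
        out = family_counts(rows, group_by=("te_class",), class_table={"rover": "LTR"})
        got = dict(zip(out["te_class"], out["count"]))
        assert got == {"LTR": 1, "unknown": 1}


class TestExtractFlanks:
    def test_exact_substring_window(self):
        ref = {"c": "ACGTACGTACGTACGTACGTACGTACGTAC"}
        call = _row(chrom="c", pos=11, tsd_len=0)  # 0-based point 10
        summary = extract_flanks([call], ref, flank=10)
        assert summary.flanks == [ref["c"][0:10] + ref["c"][10:20]]

    def test_tsd_excluded_by_default_included_on_flag(self):
        ref = {"c": "A" * 10 + "CGCGC" + "T" * 10 + "G" * 5}
        call = _row(chrom="c", pos=11, tsd_len=5)
        assert extract_flanks([call], ref).flanks == ["A" * 10 + "T" * 10]
        assert extract_flanks([call], ref, include_tsd=True).flanks == ["A" * 10 + "CGCGC" + "T" * 10]

    def test_at_rich_sites_exceed_genome_at(self):
        rng = np.random.default_rng(11)
        bases = np.array(list("ACGT"))
        chunks = []
        sites = []
        pos = 0
        for i in range(30):
            filler = "".join(bases[rng.integers(0, 4, 200)])
            at = "".join(np.array(list("AT"))[rng.integers(0, 2, 20)])
            chunks += [filler, at]
            sites.append(pos + 200 + 10)  # inside the AT block
            pos += 220
        ref = {"c": "".join(chunks)}
        calls = [_row(chrom="c", pos=p + 1, tsd_len=0) for p in sites]
        summary = extract_flanks(calls, ref, flank=5)
        genome_at = (ref["c"].count("A") + ref["c"].count("T")) / len(ref["c"])
        assert summary.at_fraction > genome_at

    def test_contig_edge_calls_skipped_and_counted(self):
        ref = {"c": "ACGT" * 20}
        calls = [_row(chrom="c", pos=2, tsd_len=0), _row(chrom="c", pos=40, tsd_len=0)]
        summary = extract_flanks(calls, ref, flank=10)
        assert len(summary.flanks) == 1 and summary.skipped == 1


GENES = [
    IntervalFeature("c", 1000, 5000, "geneA", "+", "gene"),
    IntervalFeature("c", 1000, 1200, "geneA", "+", "5UTR"),
    IntervalFeature("c", 1200, 1800, "geneA", "+", "CDS"),
    IntervalFeature("c", 1800, 3000, "geneA", "+", "intron"),
    IntervalFeature("c", 3000, 3600, "geneA", "+", "CDS"),
    IntervalFeature("c", 3600, 5000, "geneA", "+", "3UTR"),
]


class TestAnnotateGenic:
    def test_intron_containment(self):
        (ann,) = annotate_genic([_row(chrom="c", pos=2001)], GENES)
        assert ann["feature_class"] == "intron"
        assert ann["genes"] == ["geneA"]

    def test_window_boundary_at_500(self):
        near = annotate_genic([_row(chrom="c", pos=1000 - 499)], GENES)[0]
        far = annotate_genic([_row(chrom="c", pos=1000 - 501)], GENES)[0]
        assert near["genes"] == ["geneA"]
        assert far["genes"] == []

    def test_labels_match_brute_force_scan(self):
        rng = np.random.default_rng(13)
        calls = [_row(chrom="c", pos=int(p)) for p in rng.integers(1, 6000, 100)]
        anns = annotate_genic(calls, GENES)
        priority = ["CDS", "5UTR", "3UTR", "exon", "intron"]
        for call, ann in zip(calls, anns):
            pos = call.position - 1
            label = "intergenic"
            for cls in priority:
                if any(
                    f.feature_class == cls and f.start <= pos < f.end for f in GENES
                ):
                    label = cls
                    break
            assert ann["feature_class"] == label

    def test_malformed_feature_class_errors(self):
        bad = [IntervalFeature("c", 1, 10, "x1", ".", "promoter")]
        with pytest.raises(ValueError, match="x1"):
            annotate_genic([_row(chrom="c", pos=5)], bad)


def _bh_reference(pvals):
    """Reference BH step-up, written from the definition."""
    n = len(pvals)
    order = np.argsort(pvals)
    ranked = np.asarray(pvals)[order]
    adj = ranked * n / (np.arange(n) + 1)
    # enforce monotonicity from the largest down
    for i in range(n - 2, -1, -1):
        adj[i] = min(adj[i], adj[i + 1])
    out = np.empty(n)
    out[order] = np.minimum(adj, 1.0)
    return out


class TestEnrichment:
    def test_fisher_matches_hypergeometric_enumeration(self):
        from scipy.stats import fisher_exact

        a, b, c, d = 8, 2, 100, 900
        _, p = fisher_exact([[a, b], [c, d]], alternative="two-sided")
        # oracle: enumerate the hypergeometric support directly
        n_draws, k_success, total = a + b, a + c, a + b + c + d

        def pmf(x):
            return (
                math.comb(k_success, x)
                * math.comb(total - k_success, n_draws - x)
                / math.comb(total, n_draws)
            )

        p0 = pmf(a)
        expected = sum(
            pmf(x)
            for x in range(max(0, n_draws - (total - k_success)), min(n_draws, k_success) + 1)
            if pmf(x) <= p0 * (1 + 1e-7)
        )
        assert abs(p - expected) < 1e-12

    def test_track_covering_background_is_null(self):
        bg = [IntervalFeature("c", 0, 10_000)]
        tracks = {"all": [IntervalFeature("c", 0, 10_000)]}
        calls = [("c", int(p)) for p in np.linspace(100, 9_900, 25)]
        (row,) = enrichment(calls, tracks, bg, seed=1)
        assert row.signed_enrichment == pytest.approx(1.0)
        assert row.p_fisher == pytest.approx(1.0)

    def test_bh_adjustment_matches_reference_step_up(self):
        rng = np.random.default_rng(17)
        bg = [IntervalFeature("c", 0, 100_000)]
        tracks = {
            f"t{i}": [IntervalFeature("c", int(s), int(s) + 2000)]
            for i, s in enumerate(rng.integers(0, 90_000, 12))
        }
        calls = [("c", int(p)) for p in rng.integers(0, 100_000, 60)]
        rows = enrichment(calls, tracks, bg, seed=2)
        testable = [r for r in rows if not r.untestable]
        expected = _bh_reference([r.p_fisher for r in testable])
        got = [r.p_adjusted for r in testable]
        assert np.allclose(got, expected)
        # monotone: ordering of raw p-values preserved in adjusted ones
        order = np.argsort([r.p_fisher for r in testable])
        adj_sorted = np.asarray(got)[order]
        assert all(np.diff(adj_sorted) >= -1e-12)

    def test_depleted_track_reports_negative_signed_enrichment(self):
        rng = np.random.default_rng(19)
        bg = [IntervalFeature("c", 0, 10_000)]
        tracks = {"left": [IntervalFeature("c", 0, 5_000)]}
        calls = [("c", int(p)) for p in rng.integers(5_000, 10_000, 40)]
        (row,) = enrichment(calls, tracks, bg, seed=3)
        assert row.signed_enrichment < -1.5

    def test_type_one_error_controlled_on_uniform_calls(self):
        """Uniform random calls against random tracks: the fraction of
        significant rows stays within the nominal bound (small version; the
        acceptance suite runs the full 1,000 replicates)."""
        rng = np.random.default_rng(23)
        bg = [IntervalFeature("c", 0, 100_000)]
        n_sig = n_rows = 0
        for rep in range(100):
            tracks = {
                f"t{i}": [IntervalFeature("c", int(s), int(s) + 3000)]
                for i, s in enumerate(rng.integers(0, 95_000, 5))
            }
            calls = [("c", int(p)) for p in rng.integers(0, 100_000, 40)]
            rows = enrichment(calls, tracks, bg, seed=int(rng.integers(0, 2**31)), background_factor=50)
            n_rows += len(rows)
            n_sig += sum(r.significant for r in rows)
        assert n_sig / n_rows <= 0.05
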