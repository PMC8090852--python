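# Methods

This note documents the models, rules, and numerical choices behind
`teclone`, and what the simulation-based validation does and does not show.

## Evidence model for short reads

A non-reference TE insertion at reference point *p* with a target-site
duplication (TSD) of length *d* leaves two junction signatures after
alignment to the reference:

* reads from the **5′ side** align up to the insertion point and are
  soft-clipped there; their clips derive from the element's near end. Their
  alignments end at junction `p1 = p`.
* reads from the **3′ side** align from the *first* copy of the duplication
  onward (the reference carries the duplicated bases once); their alignments
  start at junction `p2 = p − d` with a leading soft-clip.

Hence the diagnostic geometry: the 3′ junction lies strictly upstream of the
5′ junction, and `reference[p2, p1)` is the duplication. `call_tsd` accepts
`1 ≤ p1 − p2 ≤ max_tsd` (default 60: observed family medians in flies reach
the mid-twenties, and a generous ceiling excludes artifactual overlaps
without truncating real calls). Junction coordinates are the modal clip
positions among split reads; mate-only clusters get the cluster midpoint and
no TSD, so they can never pass the TSD filter — matching the retention rule
that a valid TSD is required for a somatic call.

Tagging requires a TE alignment to overlap a soft-clip by ≥ 10 bases
(`min_clip`); shorter clips are dominated by base-call noise in simulations.
When several consensus sequences of one family hit a read, the best
alignment score is kept and the family is the unit of reporting; score ties
across families are broken lexicographically and flagged ambiguous.

## Clustering

Tagged reads are clustered by single linkage under a compatibility
predicate: same chromosome, gap ≤ the 97.5th percentile of the proper-pair
insert-size distribution, and — for two split reads on the same side —
identical junction coordinate and compatible clip sequences. Two clips are
compatible when the shorter is ≥ 10 bases and matches the longer at ≥ 90%
identity anchored at the junction (prefix for 5′ clips, suffix for 3′
clips). Clips shorter than 10 bases carry too little sequence to distinguish
co-located insertions and are treated as compatible with anything; a literal
"no match below 10 bases" rule would shatter genuine clusters. The
production implementation is a sorted sweep with union–find; tests verify it
against exhaustive O(n²) single linkage under the identical predicate.

All tie-breaks (modal junctions, consensus clips, majority family) are
lexicographic, making the caller deterministic for sorted inputs.

## Cross-sample confirmation

Candidates are linked across samples by chromosome, TE family, position
within a slop of 50 bases, and junction-clip compatibility (the same 90%
rule). The slop must exceed the junction jitter of mate-only evidence; 50
bases is well above the observed jitter in simulations while staying far
below the distance between independent insertions. A case candidate is
somatic iff it has both split and mate support, a valid TSD, and no link-key
match in the panel of normals (all control samples' candidates; swapping
case/control roles inverts the direction of exclusion, never the keys). The
original workflow's manual screenshot review is replaced by a
`needs_review` flag raised when linked junction estimates disagree by more
than slop/2 — nothing is silently discarded.

Germline classification links TSD-valid candidates across all samples: a
site evidenced in both tissues of an individual is germline; germline sites
with median coverage across samples below 10 are discarded; sites in every
individual of a genotype are `germline_shared`, in exactly one
`germline_private`, in several-but-not-all plain `germline` (the
intermediate class is an addition — the shared/private dichotomy alone
cannot label it). The per-family mode re-runs confirmation for one family
with the panel formed by all *other* families' calls, with family-agnostic
key matching, yielding family-private inherited calls.

## Allele frequency, cell fraction, timing

AF = supporting / (supporting + opposing) read pairs, each pair counted
once. Supporting pairs are the cluster's **5′-side** evidence only (falling
back to the 3′ side): the mutant allele exposes two junctions, so counting
both sides against reference pairs spanning the single insertion point
would nearly double the apparent frequency of long inserts. Opposing pairs
are proper pairs whose fragment spans the insertion point with no junction
clip and no TE tag (the "clipped-but-untagged reads are not opposing"
interpretation: a clipped read at the junction is ambiguous, not
reference-supporting). Cell fraction doubles the AF on autosomes (capped at
1) and uses it directly on the hemizygous male X. An insertion is
pre-clonal when its cell fraction is at least that of the clonal
(neoplasia-initiating) event, supplied as an external table because those
events come from structural-variant calls outside this package's scope.

## Long-read arm

Libraries are binned on a log2 grid (2 bins per octave) and each library is
subsampled without replacement to the per-bin minimum, which makes the
binned length histograms exactly equal — the normalization needed before
comparing singleton counts between libraries with different read-length
distributions. The binning scheme is a package choice; any log-spaced grid
serves, and half-octave bins balance resolution against per-bin counts.

Candidate inserts are CIGAR `I` segments and terminal soft-clips of ≥ 100
bases (`min_insert`) on alignments with mapq ≥ 40. Homology testing uses a
k-mer–seeded (k = 11) banded Smith–Waterman (band 48, linear gaps; match
+1, mismatch −2, gap −2; score threshold 25, safely above the random-score
floor for kilobase-scale comparisons). The banded DP is row-vectorized with
the prefix-max trick for horizontal gap chains (exact for linear gap
penalties); alignment starts come from a second pass on reversed prefixes.
Segments without any shared 11-mer produce no hit — a deliberate trade:
genuine TE homology at these lengths always contains exact 11-mers, and the
tests verify equality with a full-matrix Smith–Waterman on exact, reverse-
complemented, and random segments.

A reference-consistent alignment of a read carrying insert + TSD packs the
*second* duplication copy into the `I` segment and resumes matching at the
insertion point. TSD recovery therefore compares the segment's 3′ tail with
the reference immediately 5′ of the resume point (and the left-aligned
alternative at the 5′ head), preferring the length hinted by the TE
alignment's query coverage — raw sequence comparison alone would
occasionally extend a duplication by a chance-matching base.

One identifiability caveat: when the element's terminal base happens to
equal the adjacent reference base (or, for a 5′-truncated element inserted
in reverse, the next consensus base complements the first duplicated base),
the insert/duplication boundary is not determined by any sequence evidence;
the concatenated junction content is still recovered exactly, but the
reported TSD can differ from the generative one by a base. The validation
scenarios place implants with identifiable junctions, since an ambiguous
decomposition has no unique truth to score against.

Singletons require: `insert_cigar` events with both genome flanks ≥ 200
bases aligned, TE alignment covering ≥ 80% of the insert ("fully contained
in a read", while still admitting 5′-truncated elements), a valid TSD
(relaxable by flag), exactly one supporting read in the variant's own
tissue pool, and zero in the other pool. Grouping tolerance is 50 bases,
matching the short-read slop.

## Enrichment statistics

Insertion sites are points. The default background unit is matched random
site sampling — `background_factor` (default 100) × the number of calls,
drawn uniformly (seeded) from the mappable background intervals — giving a
2×2 table of calls vs background points in/out of each track; a base-pair
contingency mode is provided for parity with interval-overlap tools. Each
track gets a two-sided Fisher exact p-value; BH adjustment (step-up,
α = 0.05) runs across tracks. Signed enrichment is the observed/expected
call fraction ratio *r*, reported as *r* when *r* ≥ 1 and −1/*r* otherwise;
a row is significant when adjusted *p* < 0.001 **and** |enrichment| > 1.5.
The two thresholds are deliberately kept as stated, although BH-α and the
harder p-cut are partly redundant; both are exposed.

Flank extraction takes the 10 bases on each side of the TSD span and
excludes the duplication itself by default (flag to include): the
duplication is target sequence, but including it would over-weight
TSD-composition in motif discovery; exporting both variants lets motif
tools decide.

## The simulator

`simkit` emulates: a random toy genome of specified GC content; a
six-family consensus library spanning the four TE classes (LTR, LINE-like,
TIR, foldback) with lengths 0.5–3 kb; implants with TSD duplication
(`hap = ref[:p] + insert + ref[p−d:]`), strand, 5′ truncation, and cell
fraction with zygosity-aware allele fractions (heterozygous → cf/2);
paired-end reads at tens-fold coverage (default mirrors the ~47–50×
study design, 2×100 bp, insert 350 ± 35) and long reads with per-library
lognormal length distributions and ~85× default depth. Sequencing errors
are uniform substitutions only — enough to stress clip matching without
complicating truth bookkeeping; homopolymer indels, PCR duplicates, and
chimeric reads are not modeled.

Gold alignments are emitted directly from known read origins rather than by
running an aligner, so the suite has no binary dependencies and the truth
manifest is exact; real aligner BAMs are accepted anywhere a gold SAM is.
The cell population is realized as two fragment pools: a reference pool
thinned by the allele fraction near each implant, and per-implant mutant
pools covering both junctions and the insert interior, so flank coverage
stays at 1× and junction coverage equals the allele fraction. Long-read
carriers of rare insertions are placed explicitly (`implant_read_counts`),
emulating single-molecule support in pooled libraries. Long inserts are
encoded either as CIGAR `I` (with the duplication copy inside the segment,
as a reference-consistent aligner produces) or as soft-clips, switchable,
because real aligners emit both representations.

**What passing tests show — and don't.** Error-free gold-alignment
recovery demonstrates the correctness of the evidence logic, clustering,
TSD arithmetic, filtering, and bookkeeping, with exact oracles. It does not
exercise alignment ambiguity in repetitive regions, mapping-quality
artifacts, indel errors, or reference TE copies absorbing reads — the
failure modes real data adds. The negative control bounds the false-call
rate only under the simulator's error model.

## Validation problem sizes

The validation scenarios (shared by `tests/test_acceptance.py` and
`scripts/acceptance.py`) use: 1 Mb / 20 implants / 50× for clonal
end-to-end recovery; 300 kb / 12 implants / 50× × 10 seeds for the
subclonal (cell fraction 0.3, heterozygous) sensitivity and AF-calibration
checks — the same coverage and cell fraction at a genome size chosen to
keep the ten replicates quick; 300 kb insertion-free at 30× for the
negative control; 400 kb with 10 single-molecule implants of 0.5–3 kb for
the long-read arm; and 1,000 replicates × 20 tracks × 50 uniform calls for
the enrichment type-I bound. AF calibration asserts that ≥ 90% of
recovered implants estimate within 3 binomial standard errors of the true
allele fraction (3σ nominal coverage is 99.7%, so a handful of tail cases
among 120 implants is expected).

## Known limitations

* No genotyping of reference (fixed) TE copies, no CRAM, no aligner
  invocation, no assembly of full inserts from short reads.
* Family assignment is majority-vote per cluster; heavily chimeric evidence
  is reported with an ambiguity fraction rather than resolved.
* The banded aligner reports no hit for segments lacking an exact 11-mer
  match to any consensus; for diverged families lower `k` or raise `band`.
* Germline classification requires the manifest to pair tissues per
  individual; individuals with one tissue yield `ambiguous` sites.
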