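# teclone

Detection of **somatic transposable-element (TE) insertions** from short-read
and long-read DNA sequencing, with the downstream statistics used to
characterize them, and a built-in implant simulator that makes the whole
pipeline testable end-to-end without any external data.

The package targets the study design in which clonally amplified tissue
samples (e.g. *Drosophila* intestinal neoplasia driven by somatic *Notch*
inactivation in males) are sequenced at tens-fold paired-end coverage
together with matched control tissue (head), and pooled-tissue libraries are
additionally sequenced with long reads to catch rare insertions that never
clonally expanded.

## What it does

**Short-read arm** (per sample: one alignment against the reference genome,
one against a TE family consensus library):

1. `tagger` — annotate each genome alignment with TE-homology evidence: a
   soft-clipped read whose clip aligns to a consensus (*split-read* /
   junction evidence) or a read whose mate aligns to a consensus
   (*discordant-pair* / mate evidence).
2. `cluster_caller` — group tagged reads into per-locus evidence clusters
   within the 95% interval of the insert-size distribution, estimate the two
   junction coordinates, and call the **target-site duplication (TSD)**: for
   junctions `p2 < p1` with `1 ≤ p1 − p2 ≤ max_tsd`, the duplicated sequence
   is `reference[p2, p1)`.
3. `somatic_filter` — require both split and mate support, link candidates
   across samples by position / family / junction clip sequence, remove
   everything present in a **panel of normals** (control samples), require a
   valid TSD, and classify germline calls (both tissues of one individual;
   shared vs private across individuals; per-family mode where the panel is
   all *other* families).

**Long-read arm**: subsample libraries to a shared read-length distribution,
extract every CIGAR `I` segment and long soft-clip, test it for TE homology
with a seeded banded local aligner, recover the TSD from the
insert/reference duplication, and call **singletons** — insertions supported
by exactly one read in their own tissue pool and absent from the other pool.

**Statistics** (`insight`): allele frequency (supporting / supporting +
opposing read pairs, one count per pair), cell fraction (2×AF on autosomes,
AF on the hemizygous male X), pre-/post-clonal timing against the
neoplasia-initiating event's cell fraction, per-family TSD length summaries,
family/class counts, ±10 bp target-site flank extraction for motif tools,
genic annotation (±500 bp windows), and per-track interval enrichment
(two-sided Fisher exact test, Benjamini–Hochberg correction, signed
observed/expected enrichment, significance at adjusted *p* < 0.001 and
|enrichment| > 1.5).

**Simulator** (`simkit`): toy genomes, a six-family consensus library (LTR /
LINE-like / TIR / foldback), implants with TSDs, optional 5′ truncation,
strand, and per-implant cell fraction; paired-end and long-read simulation
with *gold* alignments emitted directly from the known read origins plus a
truth manifest, so every stage has an exact oracle.

## Worked example

```python
from teclone import simkit, pipeline, somatic_filter

genome = simkit.build_reference(1, {"chr2L": 100_000}, gc_fraction=0.42)
library = simkit.build_te_library(7)
specs = [simkit.ImplantSpec("rover", "chr2L", 50_000, tsd_length=5)]
by_chrom, truth = simkit.implant(genome, library, specs, seed=1)
gold = simkit.simulate_short_reads(genome, library, by_chrom, truth,
                                   coverage=50, seed=2)

reference = {g.id: g.sequence for g in genome}
candidates = pipeline.call_candidates(gold.genome_alignments,
                                      gold.te_alignments, reference)
for c in somatic_filter.prefilter_support(candidates):
    print(c.te_family, c.insertion_point, c.tsd.sequence,
          c.cluster.split_support, c.cluster.mate_support)
```

prints

```
rover 49996 AGTAT 88 172
```

one candidate: a `rover` insertion whose 5-bp TSD `AGTAT` starts at 1-based
position 49,996 (the implant was placed at 0-based 50,000 with `tsd_length=5`,
so the first duplicated base is 49,995 0-based — the call is exact),
supported by 88 junction-spanning reads and 172 discordant pairs at 50×.

The same stages are scriptable from the shell:

```bash
teclone sim --config sim.yaml --out-dir simout --seed 3
teclone tag --genome-bam simout/genome.sam --te-bam simout/te.sam --out-bam tagged.sam
teclone findcluster --tagged-bam tagged.sam --te-bam simout/te.sam \
    --reference simout/genome.fa --out-gff calls.gff3
```

`teclone tag` writes the evidence into a custom SAM tag `te`
(`consensus,family,aln_start,aln_end,query_start,query_end,orientation,source,score`),
viewable in IGV; untagged records pass through so the output stays a complete
alignment file.

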