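# Methods

This note records the models, algorithms and design choices behind each
stage, what the synthetic fixtures do and do not emulate, and the package's
known limitations.

## Sequence matching

Both screening rounds use the same seed-and-extend local matcher
(`conect.masker.KmerIndex`): exact k-mer seeds (default k = 16) extended
without gaps in both directions under an x-drop rule (match +1, mismatch −3,
drop 10), trimmed back to the best-scoring endpoints. A hit is kept when it
is at least `min_hit_len` (20 bp) long at `min_identity` (0.95) or better.
The extension crosses isolated substitutions — two mismatches a few bases
apart still extend — but terminates in sustained novel sequence, which is
what makes the masked/unmasked partition sharp. There are no gapped
alignments: an insertion or deletion inside a fragment fragments the hit
into co-diagonal pieces, which round 2's chaining re-joins when the query
and genomic gaps agree. This matcher is a deliberate, reproducible
substitute for general-purpose repeat-masking and long-read alignment
engines; all thresholds are exposed in `RunConfig`.

### Masking (round 1)

Fragments are screened in both orientations against the spliced transcript
database; the orientation with the greater total masked length wins (ties go
forward). Overlapping hits are merged into masked intervals whose gene lists
record every contributor — masking semantics, not attribution. Unmasked
segments touching a fragment terminus are classed `end5`/`end3` (a wholly
unmasked fragment is one `end5` segment by convention); the candidate rule
keeps terminal segments strictly longer than 10 bp and internal segments of
any length. No minimum is imposed on internal segments; downstream
splice/contiguity logic is the filter.

### Placement and classification (round 2)

Fragments with candidates are placed by chaining same-chromosome hits that
advance in both query and genome with genomic gaps below `max_link_dist`
(50 kb). Equal-scoring chains at distinct loci flag the placement
*ambiguous*; it is reported, never classified. Because ungapped extension
can overrun an exon/intron junction by a few bases when the genome happens
to agree with the fragment there, consecutive blocks may claim the same
fragment bases; overlaps are resolved at a mask-derived candidate boundary
when one falls inside the overlap (the masking step fixed the true
novel/known junction), otherwise at the left block's end. Each block's
genomic coordinates move along its own diagonal, so reconciled junctions are
exact.

Category assignment per candidate block: position relative to the linked
gene (upstream of the transcription start, downstream of the end, or inside
the body, with 5′/3′ following gene strand), then the contiguity test — a
shared boundary with an annotated exon means *extension*, an intervening gap
means *novel exon*. Novel exons validate every adjacent junction: the intron
must be at least `min_intron_len` (40 bp; shorter gaps are micro-gaps, not
introns) and read a canonical donor…acceptor (`GT…AG`; `GC` donors can be
enabled) on the transcribed strand. Extensions and fusions carry no splice
verdict. A placement whose known blocks overlap exons of two or more genes
additionally emits one `gene_fusion` row, reporting the annotated exons the
fragment joins. Candidates with no gene within `max_link_dist` are reported
as `intergenic_unlinked`, outside the seven categories.

One routing choice deserves note: a fragment consisting purely of two known
genes' exons is fully masked in round 1 and would never reach placement, so
fully masked fragments whose mask was contributed by two or more distinct
genes are also forwarded to round 2 as fusion suspects. Without this, read-
through fusions would be systematically invisible.

When one fragment supports both an extension and a novel exon at the same
terminus, both rows are emitted — categories partition candidate *blocks*,
not fragments.

## Tiling-array expression calling

Pipeline order is fixed: GC correction → quantile normalization → median
filter → threshold/calls.

* **GC correction** operates in log2 intensity with one bin per exact GC
  count of the 50-mer; the bin's random-probe median is subtracted and the
  grand random median added back, so the correction is a per-bin constant
  shift that preserves within-bin order. Empty bins borrow the nearest
  populated bin (logged).
* **Quantile normalization** maps each replicate onto the mean
  order-statistic distribution; ties are averaged (so the exact sorted-rows
  identity holds on tie-free data).
* **Median filtering**: the canonical filter is 3 probes × 3 replicates —
  one smoothed value per probe, windows truncated (never bridged) at
  chromosome boundaries. A per-replicate window-of-three variant exists for
  signal inspection. Random probes are excluded from filtering (they have no
  genomic order).
* **Background threshold**: the smallest genic intensity at which the
  estimated FDR — (random-tail fraction, add-one corrected) × N_genic /
  (genic count above) — drops to q = 0.02. The add-one correction keeps a
  finite random sample's empty upper tail from being read as FDR 0; under
  identical random/genic distributions the threshold is +∞ and every call is
  absent. Each replicate derives its own threshold from its own
  (normalized, unfiltered) random probes.
* **Calls**: a gene is present under a replicate's threshold when strictly
  more than 70% of its (3×3-filtered) probe signals are strictly above it;
  the consensus requires presence under all replicates. The filtered signal
  is shared across replicates by construction of the 3×3 filter; the
  replicates differ in their null, which is what the per-replicate
  thresholds capture. Genes with no probes are called NA. Exon levels are
  probe medians; isoform levels are unweighted means of exon levels
  (deliberately not length-weighted); isoform levels are reported but do not
  feed gene calls.
* **Signal tracks** subtract the 98th-percentile random-probe intensity and
  clamp negatives to zero, emitting 1-based GFF per replicate.

## Quantification and enrichment

Reads are assigned to the transcript with the highest total matched-base
score over both orientations; ties — duplicated genes in particular — go to
the lexicographically smallest transcript id, so duplicated targets never
lose reads to ambiguity. FPKM = count × 10⁹ / (length × total mapped);
gene-level collapse sums isoform counts over the exon-union length (the
plain isoform-length sum would double-count shared exons).

The depletion test models reads as falling on transcripts with probability
equal to each transcript's length share; the p-value is the lower binomial
tail at the observed count. The median variant replaces n with (number of
transcripts) × the median count of the other transcripts, damping the
influence of unusually efficient capture of any single competitor; it is
interpreted here as a robustness companion, not a replacement.

The compression fit regresses y on x and on x + x² by OLS and reports the
t-test on the quadratic coefficient (equivalent to the one-parameter nested
F test). A significantly negative quadratic term is the compression
signature: highly expressed genes attract proportionally fewer capture
reads. Inputs default to a log10(1 + v) transform; pass `transform=None`
for data already on a log scale.

## Synthetic fixtures

`generate_genome_and_genes` draws uniform-random chromosomes (default
2 × 250 kb) and places non-overlapping genes (default 60) with 2–6 exons of
90–300 bp, introns of 60–400 bp forced to `GT…AG` on the transcribed strand,
both strands, and a second exon-skipping isoform for about half of the
eligible genes. `plant_novel_features` plants 5 features per category by
default; novel exons are 129–135 bp, terminal novel exons sit 150–800 bp
from the gene with splice sites written into the genome, extensions are
60–150 bp (internal: 40–120 bp) of contiguous flanking sequence. Fusions
pair genomically adjacent same-strand genes. Internal features are planted
on single-isoform genes so the transcript continuation at each junction is
unambiguous.

Two collision-control mechanisms make planted truth a sharp oracle. First,
planted novel sequence is verified to share no seed k-mer (either strand)
with the rest of the fixture and re-drawn on violation. Second, the few
bases flanking each planted junction are constrained so that a hit cannot
extend across the junction by chance agreement with the transcript
continuation. Real data offer no such guarantees — paralogy, repeats and
sequencing artifacts all blur junction boundaries — so perfect noise-free
recovery demonstrates correctness of the bookkeeping, not expected
performance on a real transcriptome.

Fragments average 700 bp (isotig-like) with a singleton-sized minority
around 360 bp, half emitted reverse-complemented; each planted feature is
covered by 2 supporting fragments by default (3 in the error-robustness
runs — recall is scored per planted feature, recovered if any supporting
fragment classifies it). The optional error model is uniform substitution
only; 454-style homopolymer indels are not modelled, and the matcher's
ungapped extension would be the first casualty if they were.

Probe panels tile exons every 33 bp with 50-mers; random probes draw from a
log-normal null (log2 intensity ~ Normal(8, 1)); expressed genes sit
`snr` = 3 log2 units higher; a linear GC bias (0.1 log2 units per GC base)
exercises the correction. With 50 expressed / 50 silent genes this yields
consensus-call accuracy of roughly 0.97 on average (seed-to-seed range about
0.91–1.00 — short 2-exon genes carry as few as 4 probes and dominate the
misses) and empirical FDR at the threshold near zero. Quant read sets are
multinomial over transcript abundances with capture-excluded transcripts
zeroed and renormalized.

## Numerical and degenerate-input conventions

Internal coordinates are 0-based half-open everywhere; GFF3 converts at the
file boundary, BED is native. Percentages round to one decimal (two for
concordance); empty denominators report `NA`. Fragments with more than 10%
ambiguous bases are dropped at load with a warning. Zero mapped reads is an
error for FPKM and p-value 1 for the depletion test. The compression fit
refuses fewer than 10 finite pairs or zero-variance x.

## Limitations

* Ungapped matching: indels in fragments degrade block boundaries; at the
  package's fixture scale this is handled by coverage, not by alignment.
* One annotation in, one annotation out — no handling of annotation-release
  drift.
* The FDR threshold is a tail-ratio estimator against designed negative
  controls, not a density-modelling estimator; with few random probes it is
  conservative.
* Germline-specificity comparisons between two tissues are a report join
  (`conect compare`), not a statistical model.
* The gene-fusion call does not distinguish read-through transcription from
  trans-fusion, and requires the two genes' blocks to be co-linear on one
  strand within one placement.
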