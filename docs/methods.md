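# Methods

This note documents the models, parameter choices and numerical behaviour
of `isocouple`, and what the synthetic-data tests do and do not establish
about real data.

## Coordinates and end definitions

All internal coordinates are 0-based half-open; GTF input/output converts
by ±1, BED and STAR `SJ.out.tab` are converted at parse time. TSS and TES
positions are *boundary* coordinates: on '+' a TSS is an exon start and a
TES an exclusive exon end; on '−' the roles swap. This makes a
single-exon transcript's (TSS, TES) exactly its interval boundaries and
keeps end comparisons integer-exact.

## End clustering

Transcript 5′ and 3′ ends are clustered per gene by single linkage on the
sorted positions: consecutive positions are merged while the gap is
≤ window (defaults 50 nt for TSS, 150 nt for TES). Single linkage was
chosen because it is order-independent and matches the idea of collapsing
nearby ends into one transcription unit; its known property that chains
can extend beyond the window is deliberate and tested. The cluster
representative is the modal member position (the most frequently
annotated end), ties broken 5′-most in transcriptional direction. Cluster
identifiers are numbered 5′→3′ in transcriptional direction
(`gene:TSS1`, …) and renumbered if external end databases add clusters.

Candidate 5′–3′ isoforms are the full cross-product of TSS and TES
clusters with the TSS 5′ of the TES — not only the combinations realised
by annotated transcripts — so novel promoter/3′-end links are countable.

External promoter or 3′-end databases (BED6/GFF) are merged by assigning
each record to every gene whose window-extended span it overlaps on the
matching strand; records within one window of an existing same-kind
cluster are absorbed as members without moving the representative,
anything else founds a new cluster and pairs are re-enumerated.

## Full-length filtering

A read (primary alignments only; secondary/supplementary flags and
MAPQ < 10 excluded to avoid double-counting chimeric cDNA) is full length
for a gene when its aligned 5′ end lies within `representative ± tss
window` of some TSS cluster and its aligned 3′ end within
`representative ± tes window` of some TES cluster of that gene, on the
matching strand. Soft-clipped bases are ignored: only the aligned span
defines the ends. Among several matching clusters the nearest
representative wins (ties 5′-most); reads satisfying both ends in more
than one gene are dropped as `ambiguous_gene` so contingency tables stay
disjoint. The same windows govern database construction and read
assignment by default; assignment-time overrides exist for sensitivity
analyses. With `--ignore-strand` (for unstranded chemistries) the span
ends are re-oriented per candidate gene's strand.

Statuses (`full_length`, `no_tss`, `no_tes`, `ambiguous_gene`,
`unassigned`, `filtered`) partition every scanned read; this conservation
is asserted in code and tested. Widening the windows cannot decrease the
full-length count while cluster representatives are fixed; when widening
also *re-clusters* a database with chained clusters, representatives can
move and this monotonicity is no longer guaranteed — the property is
therefore stated (and tested) for fixed representatives.

## Independence testing

Per gene the TSS × TES table is tested conditionally on its margins:
null tables are drawn uniformly from the fixed-margin distribution
(Patefield's algorithm, via `scipy.stats.random_table`) and

    p = (1 + #{χ²_sim ≥ χ²_obs}) / (B + 1),   B = 2000 by default,

so the smallest attainable p is 1/(B+1) ≈ 5·10⁻⁴. A multinomial
(unconditional) null is available behind a flag for sensitivity analysis.
Zero-margin rows/columns are dropped before testing; Pearson residuals of
dropped cells are defined as 0, preserving the identity
Σ residual² = χ². Genes need ≥ 2 TSS clusters, ≥ 2 TES clusters, ≥ 2
non-empty rows and columns, and ≥ 20 full-length reads (`min_reads`,
chosen to avoid degenerate Monte-Carlo tests) to be tested.
Benjamini–Hochberg adjustment runs across all tested genes of a run;
pair-level coupling calls condition on gene-level significance
(q ≤ α = 0.01) plus |Pearson residual| ≥ 0.5 rather than re-testing each
pair, avoiding a second multiplicity layer. The residual cutoff applies
to Pearson residuals computed on counts; the transcriptome-wide scatter
plots log10 observed vs log10 expected pair frequencies.

Dominance fractions are column-normalised counts (per TES, the share of
each TSS); `dominant_tss` is set when the gene is significant and the top
fraction is ≥ 0.5 (configurable).

## Junction correction and exon couplings

Reference junctions are annotation introns (consecutive exons per
transcript) optionally unioned with short-read junctions supported by
≥ `min.jcounts = 2` unique mappers; STAR strand code 0 rows are dropped.
Each long-read intron must match exactly one reference junction with both
boundaries within `tol = 10` nt (chosen to exceed typical nanopore
splice-boundary wobble; exposed as a flag). Exact matches pass through;
zero candidates reject the read as `novel_junction`; multiple candidates
reject it as `ambiguous_junction` unless `--snap-closest` is given —
rejection is the default because silently choosing between near-identical
acceptors would bias alternative-splice-site counts.

For each reference junction within a gene, a full-length read counts as
*inclusion* when its corrected chain contains the junction and as
*exclusion* when the junction's intron interval lies inside the read's
aligned span but not in its chain (the read spliced differently there or
retained the intron); reads not spanning the junction contribute neither.
The exclusion rule is span-based rather than exon-block-based on purpose:
a read that skips an exon has no exonic block across the skipped
junctions, yet it is exactly the evidence that the junction was *not*
used — block-based exclusion would leave alternative splice forms
uncountable. The test unit is one junction against one axis (TSS or TES)
as a 2 × K inclusion/exclusion table, tested with the same Monte-Carlo χ²
and BH-adjusted across all tested (junction, axis) units; joint modelling
of whole chains is out of scope.

## Synthetic data

The simulator lays out non-overlapping genes on one contig (alternating
strands by default), each with configurable TSS/TES counts, internal
exons, and spacings that default to several times the assignment windows
(400/600 nt) so cluster recovery is unambiguous. Reads sample a TSS, a
TES from the gene's conditional coupling matrix, and internal-exon
inclusions conditional on the TSS; defaults are 200 reads/gene, end
jitter sd 10 nt truncated at half the window (so a zero-misassignment
regime exists by construction), 20% 5′ truncation placed beyond the TSS
window (emulating incomplete cDNAs, the dominant artefact of the
protocol), and ±3 nt junction wobble. Reads are emitted directly as
sorted, indexed BAM because the analysis contract starts at aligned data.
A per-read truth table (true clusters, true noiseless junction chain,
truncation flag) supports exact oracle comparisons at zero noise and
distributional checks otherwise.

What the simulator does **not** emulate: base-level sequencing errors
(only coordinate noise matters to this method), expression-level
variation across genes, internal-priming artefacts, multi-gene loci with
overlapping annotation, and replicate structure. Passing tests therefore
establish correctness of the counting and testing machinery and its
calibration under the stated noise model — not robustness to misannotated
or overlapping genes, which real applications must assess via the
read-status accounting the tool reports.

## Test and verification sizes

The test suite verifies clustering against a brute-force single-linkage
oracle (200 fuzzed instances plus property-based cases), Monte-Carlo
p-values against exhaustive enumeration of fixed-margin 2×2 tables and
against the asymptotic χ² tail at large counts (B = 20 000), type-I error
calibration on 500 independence genes with 3 × 3 tables at ~110
reads/gene (fraction of p ≤ 0.05 inside the 99% binomial band, and a
Kolmogorov–Smirnov uniformity check; 3 × 3 tables are used because the
conditional test's p-value distribution on 2 × 2 tables at this depth is
visibly discrete — an inherent property of the conditional null, not an
implementation artefact), detection power over 50 replicates of an
odds-ratio-9 gene at 200 reads, dominance recovery at 5000 reads
(L1 < 0.05), and monotone, saturating detection counts under nested
read-depth subsampling of a mixed coupled/uncoupled cohort. These sizes
were chosen to make binomial/KS bands tight enough to be informative
while keeping the suite fast.

## Known limitations

- Internal gene-body coverage is not required for the full-length call;
  only end-window membership is enforced. A read with a large internal
  deletion but correct ends still counts.
- Chained end clusters (dense annotations) make the representative ±
  window interval narrower than the cluster's member span; ends of
  annotated transcripts in the chain's tails may be missed.
- The per-junction 2 × K test treats junctions of a gene as separate
  units; mutually exclusive exons induce correlated tests that BH treats
  as independent discoveries.
- Pooling replicates before counting is an input-preparation step; the
  test models a single pooled table and is blind to replicate-level
  overdispersion.
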