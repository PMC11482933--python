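# Methods

## Assay model

The pipeline analyzes a two-library design: an **enrichment** library whose
fragments were captured by modification-specific beads (each bead transfers
its modification barcode, MBC, plus a UMI into the cDNA) and a **solution
control** in which every fragment is barcoded at random. Modified loci
appear as a coverage excess of the enrichment library over the control
within one MBC channel; an edited adenosine additionally appears as an A→G
mismatch because inosine base-pairs like guanosine. Spike-in sequences with
modification-specific segments tie the arbitrary enrichment-ratio scale to a
quantitative fold-enrichment per modification.

## Simulator

`epiplexkit.sim` generates every input the pipeline consumes, with complete
per-read ground truth.

**Transcriptome.** One chromosome of `n_genes` genes (default 20) laid out
with intergenic gaps, each with a 5'UTR/CDS/3'UTR partition of the exonic
length (default fractions 0.10/0.55/0.35, typical of mRNA) and 1–4 exons;
introns are inserted only inside the CDS so UTRs stay contiguous. Default
exonic lengths of 1.2–2.2 kb give a ~50–60 kb genome — a deliberately
desk-scale study that keeps a full two-replicate run under a minute.

**Modification landscape.** m6A sites are planted on DRACH-matching
adenosines (transcript strand; the methylated A at motif position 3) with a
0.8 probability of drawing from 3'UTRs; inosine sites on adenosines in
introns (weight 0.5) and UTRs (0.25 each). Stoichiometries are uniform on
[0.5, 1.0], the typical range for sites detectable by an enrichment assay.
Two resolvability constraints reflect that this is a peak-resolution assay:
sites of any modification are ≥ 500 nt apart (closer sites merge into one
peak and have no separable truth), and ≥ 200 nt from transcript termini
(coverage truncation at a boundary biases the position of the smoothed
coverage maximum, so truth planted on a terminus is not localizable at the
±50 nt evaluation tolerance).

**Libraries.** Fragments are drawn from contiguous gene-span (pre-mRNA)
coordinates — so intronic inosine receives coverage and truth alignments are
simple all-match records; spliced alignment is the upstream aligner's job
and out of scope. Lengths are Normal(140, 20) truncated at ≥ 1 nt. Each
molecule carries a Bernoulli(stoichiometry) modification status per
overlapped site. Enrichment capture accepts a molecule with weight
`1 + (capture_enrichment − 1) · (# modified sites)` (default multiplier 8)
and assigns the MBC of the capturing bead, chosen proportionally to the
per-modification modified-site counts; unmodified molecules are captured at
baseline with a random MBC, emulating background barcoding. The control
accepts everything with a random MBC. Inosine-modified molecules read G at
the site with probability `inosine_editing_rate` (default 0.8). Reads carry
a uniform 0.1% substitution error, 15% PCR duplication, and the adapter
layout MBC(8 nt) + UMI(10 nt) at the 5' end of read 2 (read 1 is the insert
in sense orientation); the default whitelist is two barcodes at Hamming
distance 8. Spike-in fragments (5% of reads) come from a reference with one
densely modified segment per modification (one site per ~30 nt, emulating
avidity-driven capture) plus an internal standard carrying a single site,
captured at single-site weight with a random MBC.

**Randomness design.** Every fragment attribute (gene, position, length,
acceptance, MBC) and every modification site's Bernoulli stream is an
independent counter-keyed `SeedSequence` stream. Removing one
modification's sites therefore leaves the other channel's fragments —
coordinates, acceptance decisions, barcodes — bit-identical, so the two
modification channels are decoupled by construction, as the corresponding
biological processes are. A seed fully determines all outputs
(byte-identical FASTQ/SAM/GTF on re-run).

**What the simulator does not model**, and hence what passing tests cannot
show about real data: spliced alignments and alignment errors, per-cycle
base-call error profiles, expression dynamic range across genes (genes are
sampled by length only), RNA secondary-structure-driven ADAR site selection,
polyA-selection artifacts, and barcode cross-talk between beads.

## Pipeline stages and defaults

**Barcode processing.** Read 2's first 8 nt resolve against the whitelist
with ≤ 1 Hamming error (ambiguous → "undetermined"); the next 10 nt are the
UMI. Read 1 is 3'-quality-trimmed (sliding window 4, mean Q < 20, then
trailing sub-threshold bases stripped); trimmed inserts < 30 nt are removed.
Deduplication keys on (reference, start, strand, MBC, UMI) — position-aware
by default because positionless UMI collapse across a transcriptome would
merge distinct molecules; a positionless mode is available behind a flag.
The representative is the highest mean base quality, ties broken by read
name.

**Spike-in scaling.** Counts per (segment, MBC, sample), midpoint
assignment with left-segment ties, normalized to reads per million mapped
deduplicated fragments within the sample's MBC channel (per-MBC by default;
a global mode exists). The enrichment factor is a pluggable monotone curve
(identity, linear, or piecewise-linear from a calibration TSV) applied to
the ratio of modification-segment to internal-standard normalized counts.
Zero standard coverage raises `spikein_failed`; the pipeline then continues
unscaled with a warning.

**Peak calling.** Coverage tracks are rescaled to genome-mean coverage 1
before forming the ratio. This normalization was chosen over
counts-per-million because it keeps peak calling *exactly* invariant to
uniform depth scaling of both libraries while giving the pseudocount
α = 0.5 a meaningful magnitude — half the genome-average coverage, acting
as a background floor that damps ratio noise in low-coverage regions (the
same role the genome-wide background estimate plays in conventional
enrichment peak callers). Smoothing is a centered moving average, window 51
nt (the window must be odd for a symmetric average). Candidate summits are
local maxima of the smoothed log2 ratio with prominence ≥ 0.5 and ratio
≥ 2; boundaries extend to where the ratio falls below half the summit ratio
or below 2, then are padded by half the smoothing window to undo the edge
erosion the smoother introduces; overlapping candidates merge keeping the
higher summit. The reported summit is the maximum of the smoothed *signal*
coverage inside the interval: the enrichment ratio is nearly flat across an
enriched region (signal and control share the same coverage ramp), so the
ratio's argmax follows background Poisson noise, whereas the signal apex
sits at the modified position. All parameters are echoed into a JSON
sidecar.

**Confidence filtering.** The FPR at cutoff c is the fraction of one
replicate's peaks at fold-enrichment ≥ c without a ≥ 1 nt overlapping peak
in the other replicate, averaged over both directions (a one-directional
mode exists). The default grid is 40 log-spaced cutoffs from 1 to the
99.5th percentile of fold-enrichment. The fit of
`A·exp(−k·c) + m·c + b` uses fixed initialization (A = max FPR, k = 1,
m = 0, b = min FPR) and bounds A ≥ 0, k > 0, so it is deterministic. The
linearity check fits a line to the upper half of the cutoff range and
requires RMSE ≤ 0.01 and slope ≥ −0.01; for the fallback the same check
runs on every suffix window of ≥ 5 points and the fallback cutoff is the
largest cutoff whose suffix passes. Cutoff selection: smallest grid cutoff
with modeled FPR ≤ 5%; fallback to the linearity cutoff; with fewer than 10
peaks above the smallest cutoff in either replicate the curve is not
estimable and the smallest grid cutoff is used (flagged
`insufficient_peaks`), leaving the depth rule as the effective filter.
High confidence = fold-enrichment ≥ c\* AND summit depth ≥ 5 (peaks are
flagged, never deleted).

**Variant calling.** The pileup walks aligned-pair coordinates restricted
to inosine peak intervals with a 20,000-read depth cap and a Q13 base
floor; base-alignment quality recalibration is not re-implemented — the
quality floor stands in, since that heuristic concerns alignment artifacts
orthogonal to the thresholding logic here. Variant rate is computed after
capping. Sites report as A→G on the transcript strand (ref T, alt C on
minus-strand peaks), requiring rate ≥ 10% (inclusive) and depth > 5
(strict) — the two thresholds are deliberately one inclusive, one
exclusive, and separately configurable. Output is 1-based VCF 4.2.

**Annotation.** Features are assigned at the summit with precedence
3'UTR > 5'UTR > CDS-exon > ncRNA-exon > intron across overlapping
transcripts (interval-overlap assignment exists behind a flag); the
precedence order is an implementation decision recorded in output metadata.
The metagene uses 30/60/30 bins over 5'UTR | CDS | 3'UTR with intronic
positions folded into the CDS segment by genomic position within the CDS
span. The motif-shift profile histograms the signed transcript-strand
distance from each summit to the nearest DRACH adenosine within ±500 nt
(bin width 10) against a null of positions drawn uniformly from gene spans.
Note a geometric limit: DRACH occurs every ~28 nt on a strand of random (or
real transcriptomic) sequence, so the *nearest-motif* null already
concentrates within ±50 nt and broad-window enrichment ratios saturate near
1; the informative contrast is the central ±10 nt, where exactly-localized
summits exceed the null several-fold.

**Differential analysis.** Loci are single-linkage merges of ≥ 1 nt
overlapping peaks across conditions (same modification); per-locus,
per-condition fold-enrichment is the max over contributing peaks, absent
conditions are 0 with a presence flag. Correlations use only co-present
loci (mirroring scatter-plot practice); condition-unique loci are reported
separately. The Wilcoxon rank-sum test is exact by full enumeration with
midrank ties when both n ≤ 8, otherwise a tie-corrected normal
approximation with continuity correction; identical samples give p = 1.
Gene scores are mean fold-enrichment per gene and condition, z-scored
across conditions (a flag transposes the axis), and clustered with
Ward-linkage agglomerative clustering on Euclidean distances; gene order is
lexicographic, so results are deterministic.

**Pipeline.** Stages run in a fixed dependency chain with a JSON marker per
stage; a re-run skips completed stages up to the first missing marker and
regenerates everything downstream. The manifest echoes every parameter;
`run.log` carries read accounting per stage. Alignment is pluggable:
user-supplied BAM/SAM per replicate and role, or the simulator's truth
alignments in test mode.

## Numerical and testing notes

- The acceptance script's fragment-length estimate uses the solution
  control: bead capture is length-biased (longer fragments overlap sites
  more often, a real property of enrichment assays), so the uniformly
  sampled control is the correct estimator of the fragmentation length.
- Noise-model parameter recovery is exercised noise-free on the default
  40-point grid (machine-precision recovery) and with 1% Gaussian noise on
  a denser 100-point grid spanning the full decay range (0.1–8): on a
  40-point grid confined to cutoffs ≥ 1 the exponential and linear terms
  are weakly identified at that noise level and no fitter can pin the decay
  rate to 10%.
- Degenerate inputs: empty libraries produce empty valid files; zero-length
  references raise; an all-zero FPR curve selects the smallest cutoff;
  peaks in regions where both tracks are empty cannot arise because the
  ratio there is α/α = 1.
- Problem sizes in the test suite (a ~50–60 kb genome, 40,000 fragments per
  library, two replicates) were chosen so the planted landscape is
  recovered at ~100× coverage, a scaled-down analog of a deeply sequenced
  mRNA experiment, while a full run stays under a minute.

## Known limitations

Single-nucleotide m6A assignment is out of scope (the assay is
peak-resolution for m6A); isoform-aware metagenes and spliced-alignment
handling are not implemented; enrichment-library A→G rates do not estimate
biological editing stoichiometry because capture enriches edited molecules;
the standard curve defaults to identity — quantitative cross-assay
comparison requires a measured calibration table.
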