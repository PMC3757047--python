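# Methods

## Insertion detection from mate pairs

**Model.** An insertion absent from the reference shows up in paired-end
data as pairs in which one read matches element sequence and the other maps
uniquely nearby. Only internal (non-LTR) element matches count as evidence:
LTR sequence also exists as solo LTRs and element-flanking repeats, so an
LTR match cannot distinguish a full-length insertion. Each such pair yields
an anchor — the genomic mate's proximal edge plus the direction it points
(a forward-strand mate points right, a reverse-strand mate points left).
Anchors are clustered per chromosome and direction by single linkage; a
rightward cluster converging with a downstream leftward cluster within the
pairing window becomes one insertion call, `confirmed` when both directions
contribute and total support reaches `min_support`.

**Mapper.** Reads are placed with an exact-seed (k = 21) and
verify-by-comparison scheme: seed k-mers at the read ends and midpoint
propose candidate loci; the full read is compared at each; a read is kept
only when a single locus attains the best mismatch count within
`max_mismatch_rate` (default 0.05). Two or more tied loci are discarded as
multi-mapping, never assigned arbitrarily. This mapper assumes
substitution-only divergence (no indels within a read) — appropriate for
the synthetic libraries the package generates and for high-identity
short-read data generally; it is not a general-purpose aligner.

**Classification thresholds.** A read counts as element-matching when at
least `min_match_len` = 40 bp of it aligns inside an exemplar's internal
span at ≤ 5% mismatches, on either strand. Published repeat-detection
pipelines rarely state their aligner thresholds, so both knobs are
explicit parameters rather than constants. Seeds are sampled every k bases,
so reads whose internal overlap is within a few bases of `min_match_len`
can occasionally be missed; at the coverages involved this costs a
negligible fraction of support.

**Breakpoint, TSD and orientation.** Junction-spanning reads — reads that
neither classify as element-internal nor map full-length — are split at the
element–genome boundary: the genomic part is located by seeding near the
call and extended exactly; the remainder must match an element terminus in
either orientation. Because reference sequence just past the target site
can coincidentally match the element's first base(s) (~1/4 of junction
sides per genome), the split point is backed off (up to 12 bp) until the
remainder matches a terminus. Per side, the modal genomic edge across reads
is taken. If the left edge ℓ (last reference base before the element) and
right edge r (first reference base after it) overlap by exactly 5 bases
(ℓ − r + 1 = 5), that pentamer is the target-site duplication; the call's
coordinates collapse to (r + 2, r + 3) — the third and fourth duplicated
bases, the package-wide convention. Edges that abut without overlap mean
integration without duplication (`tsd = absent`); any other overlap, or
disagreeing reads, leaves the TSD `undetermined` with a note. Orientation
follows from which exemplar end abuts the junction ("+" = element coding
strand on the reference top strand). Exact TSD recovery assumes error-free
junction reads; substitution errors shorten the usable flanks and degrade
TSD calls before they affect breakpoint localization.

**Structural anomalies.** Properly mapped pairs whose apparent insert
exceeds mean + z·sd (default z = 3) span sequence present in the reference
but missing from the sample (`deletion_in_sample`); clusters of orphan
reads — a uniquely mapped read whose mate is unmapped or discordant — mark
sample-only sequence (`insertion_in_sample`). Clusters below
`min_region_pairs` (default 2) are reported concordant with a low-coverage
note. Pairs with anomalously *short* inserts are not used as insertion
evidence: with ~6-kb elements and 2.8-kb inserts, no pair can straddle an
element, so the orphan signal dominates.

## Poisson completeness

Supporting reads per true insertion site are modeled as Poisson with mean λ
estimated by the sample mean (the MLE). Two distinct quantities are
reported: the per-site miss probability P(X = 0) = e^(−λ), and the
genome-wide probability that at least one of N sites went unsupported,
1 − (1 − e^(−λ))^N. At λ = 8.6 the per-site value is 1.84×10⁻⁴; the
genome-wide value over 28 sites is ≈ 5.2×10⁻³. The observed/expected
comparison table keeps bins 0..k_max, aggregating trailing bins whose
expected count falls below 1 into a `≥k` tail (survival function), so both
columns sum to the site count; bin 0 is always kept so that zero-class
misfit stays visible. No formal goodness statistic is attached by default —
the tests use a chi-square with bins re-aggregated to expected ≥ 2 — and no
zero-truncated correction is applied for sites that were never observed
(out of scope).

## DSB landscape

**Normalization.** Oligo tracks are per-position counts; normalization to
hits per million mapped reads (hpM = raw × 10⁶ / total_mapped) makes the
genome-wide sum 10⁶ and cancels library size, so all densities (hpM/kb) are
comparable across libraries. Normalization is idempotent; a track whose
counts are all zero can only be normalized if its mapped total is supplied
externally.

**Regions.** Elements closer than `merge_dist` (default 1 kb; the merged
pairs in the packaged catalog are at identical coordinates) are analyzed as
one region. The subtelomeric exclusion is a distance-from-chromosome-end
rule (default 20 kb) restricted by default to the Ty5 family: Ty5
integrase targets subtelomeric/silenced chromatin where meiotic DSBs are
independently suppressed, whereas other elements near assembly ends sit at
coordinates too uncertain to justify dropping them; pass `families=None`
for a family-blind rule. Control regions are reference-genome element
positions — potential integration sites without an element in the sample
strain — with any position closer than `min_dist` (default 2 kb) to a case
site removed, then merged and filtered identically.

**Windows.** Flanking windows of 500/1000/2000 bp abut the focal interval
on each side and never include element-internal sequence; windows truncated
by a chromosome end are flagged and use the effective length; a window
entirely off-chromosome is an error naming the region. For case sites the
focal interval is the two-coordinate insertion point (the element is absent
from reference coordinates); for reference-annotated elements it is the
element span — this keeps the flanking sequence comparable across site
types. When a region's members share a strand, each window is also
annotated 5′-LTR-side or 3′-LTR-side. Internal density uses the same
sum/length formula over the element's own span.

**Statistics.** The rank-sum test uses midranks for ties; for combined
n ≤ 12 the null distribution of the rank sum is enumerated exactly over all
C(n, n₁) assignments of the pooled ranks; otherwise a normal approximation
with tie-corrected variance (no continuity correction) is used, and the
two-sided p is twice the smaller tail, capped at 1. The ANOVA is the
standard fixed-effects decomposition; the all-constant degenerate case
returns F = 0, p = 1, and zero within-variance with nonzero between-variance
returns p = 0. No multiple-testing correction is applied across the three
window widths, which are reported separately. Intergenic context is decided
purely by the strands of the nearest flanking protein-coding genes
((−,+) divergent, (+,−) convergent, same-strand tandem), with a focal point
inside a gene classed intragenic and a missing flank (chromosome end)
undetermined.

**Burden arithmetic.** The conversion from an oligo fraction to percent DNA
broken is linear (slope, intercept) with coefficients that must come from
external calibration — they are deliberately not built in — divided by the
mapping strain's relative DSB efficiency (default 0.8). Reported
percentages are rounded to 2 significant figures. Per-cell conversions
assume at most one DSB per four chromatids (`cell_frac = 4 × per_dna_frac`,
valid while the product stays ≤ 100%) and an expected
`dsbs_per_cell × fraction/100` breaks per cell; the fraction used for the
per-cell expectation may include LTR-derived oligos (a separate argument)
while fold-suppression uses the element-internal fraction only.

## Synthetic data

The generator's defaults reproduce the experimental design it emulates at
reduced genome scale:
two 200-kb chromosomes carrying 10 planted insertions, rather than a
12.1-Mb genome with 30 — mapping a 16× library over 12 Mb in pure Python
is not interactive, and every downstream contract is exercised identically
at 400 kb. All rates and geometry keep their realistic values: 173-bp
reads, 2.8-kb ± 280-bp inserts (SGRP-like 4–5-kb libraries are one config
change away), 16× sequence coverage, 0.9 probability of targeting a
tRNA-bearing intergenic region, 5-bp TSDs, 330-bp LTRs on a 5.26-kb
internal region (~5.9 kb total), a Ty1-dominant family mix, and 15-fold
element-internal oligo suppression.

Specifics worth knowing:

- Insertions duplicate the *reference* pentamer at the target site, so the
  planted TSD is exactly recoverable from reference sequence; in the
  default `consensus` mode, candidate positions are weighted by an A/T-rich
  position-frequency matrix (a synthetic stand-in, not a measured matrix)
  so that consensus-recovery code paths see realistic bias; `uniform` mode
  removes the weighting. Planted sites keep ≥ 12 kb separation so anchor
  clusters cannot merge.
- The Ty1 exemplar LTR carries the diagnostic T at aligned position 284;
  the Ty2 LTR is the Ty1 LTR with that base deleted plus ~2% substitutions,
  so single-residue family typing behaves as on real alignments. Family
  internal sequences are unrelated random DNA — family discrimination by
  internal k-mers is therefore *easier* than for real Ty1/Ty2 (>70%
  identity); passing tests show the pipeline logic is right, not that 40-bp
  matches would separate real Ty1 from Ty2.
- Fragments are placed uniformly (no GC bias), inserts are normal truncated
  below at the read length, pairs are innie, and the optional error model
  is uniform per-base substitution. There are no chimeras, indels, or
  platform artifacts; recovery results on these libraries bound what the
  method can do on clean data, not what archived 454/Sanger reads deliver.
- Oligo tracks are Poisson per position: background rate 0.01/bp, promoter
  windows (250 bp upstream of each gene) multiplied by per-promoter
  lognormal intensities (σ = 1.2, long-tailed, giving ~100-fold flanking
  density ranges), element spans divided by the suppression factor.
  Real oligo maps have read-length autocorrelation and sequence-composition
  biases that this model omits.
- Every emitter draws from `numpy` generators seeded as
  `[config.seed, stream]`, so all outputs are bit-reproducible for a fixed
  seed and independent across streams.

## Known limitations

- The mapper and classifier are substitution-only and exact-seeded; real
  archives with indel errors need an external aligner feeding the same
  anchor/cluster/call machinery.
- Solo-LTR discovery is out of scope by construction (internal-only
  classification).
- TSD calling needs clean junction reads on both sides; one-sided evidence
  leaves candidates with interval breakpoints.
- The completeness model treats sites as exchangeable; support actually
  varies with local mappability, so e^(−λ̂) is a genome-average statement.
- ANOVA assumes fixed effects and roughly equal variances; with the small
  per-class counts typical of these analyses the p-values are indicative,
  not decisive.
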