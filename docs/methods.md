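# Methods

This note documents the models, parameter choices, numerical
conventions, and known limitations of `valvetag`. It describes what the
code computes and why; every number quoted here is produced by the test
suite or by `scripts/acceptance.py`, not asserted from memory.

## Tag-seq model

A Tag-seq (SAGE-seq) library represents each transcript by the 21-bp
sequence starting at the 3′-most NlaIII site (CATG) of its cDNA: 4 bases
of anchor plus 17 transcript-derived bases. The processing chain is:

1. **Quality filter.** Reads carrying the Illumina filter flag
   (`1:Y:…`) are removed. For FASTQ without flags the Chastity value is
   not recoverable from base calls, so a proxy is used: mean Phred
   quality over the 21-bp tag region ≥ Q20. The filter's downstream role
   is only to remove a known fraction of reads, which the proxy
   preserves; the threshold parameter (default 0.6) is retained in the
   interface for provenance.
2. **Tag extraction.** The tag is the first 21 bases, case-insensitive.
   Reads shorter than 21 bases, reads not beginning with CATG, and reads
   with `N` in the tag are discarded and tallied separately.
3. **Mismatch collapse.** Sequencing errors on an abundant tag produce
   "satellite" tags at Hamming distance 1. A tag *t* is removed iff some
   tag *u* with d(t,u) = 1 has count(u) ≥ 1000 (`parent_min`) and
   count(u) ≥ 100 × count(t) (`ratio`). "Highly expressed" is not a
   standard constant, so both knobs are config-exposed. Decisions are
   made against the original table in one pass (no chaining: a removed
   satellite cannot remove its own satellites), which makes the result
   independent of input order — a property test permutes the table.
   Neighbour search uses positional bucketing (21 × n 20-mers), linear
   in table size.
4. **Virtual-tag mapping.** Every CATG site of every transcript with 17
   downstream bases yields a sense virtual tag, ranked 3′-most first;
   the reverse complement is indexed as antisense. Only tags whose sense
   hits fall on exactly one gene contribute; ambiguous, antisense-only
   and unmapped tags are excluded and reported. All tags of a gene are
   summed (transcript variants collapse onto the gene).
5. **TPM.** tpm = raw × 10⁶ / denominator, exactly. The denominator is
   the per-library total of high-quality, anchored, post-collapse tag
   counts — the analogue of a printed "HQ tags" library size. The
   internal cross-check: a count of 5,577 in a library of 6,075,421 HQ
   tags gives 918.0 TPM at one decimal. Whether published library sizes
   were pre- or post-collapse totals is not always documented; both
   totals are available from the QC report.
6. **Expressed filter.** A tag or gene is expressed in a library iff its
   raw count is > 5 (≥ 6). The filter applies at tag level before
   mapping and is reused at gene level when selecting genes to test.

## Exact test at fixed dispersion

Replicate-free libraries cannot support dispersion estimation, so the
test fixes the negative-binomial dispersion at φ = 0.12 (variance
μ + φμ²; φ is config-exposed). Counts are first scaled linearly to a
common library size N\* (the geometric mean of the library sizes):
pseudo_i = count_i × N\*/size_i. This replaces the quantile-to-quantile
pseudo-data adjustment used by the reference Bioconductor
implementation; consequently published p-values and folds computed with
that implementation are reproduced only approximately when library
sizes differ (exactly when they are equal). Pseudo-count group sums are
rounded half-to-even before the conditional law.

Given rounded sums y_A, y_B with group sizes n_A, n_B, the test
conditions on s = y_A + y_B. Under H0 the sums are NB with means
n_A·μ̂, n_B·μ̂ at the pooled estimate μ̂ = s/(n_A+n_B), and dispersions
φ/n_A, φ/n_B (a sum of n iid NB(μ, φ) is NB(nμ, φ/n)). The two-sided
p-value is the small-probability method: the total conditional
probability of all k with P(k|s) ≤ P(y_A|s). The pmf is evaluated with
log-gamma arithmetic and normalized by log-sum-exp; ties are admitted
with relative slack 10⁻¹⁰ so the mirror outcome at n_A = n_B is always
included. s = 0 returns p = 1 by convention. The suite verifies
agreement with a brute-force enumeration oracle to < 10⁻¹⁰ over all
s ≤ 60 and group sizes in {1, 2}, and against frozen reference values
from the Bioconductor implementation of the same conditional test at
φ = 0.12.

Fold changes use a prior count c = 0.5 per library:
FC = ((y_A + n_A c)/n_A)/((y_B + n_B c)/n_B); the prior guarantees
finiteness and FC(A,B)·FC(B,A) = 1. Published fold values computed with
a different internal prior are matched in sign and ordering, not value.
Significance is raw p < α = 0.05 with no fold-change cutoff (fold sets
the direction only); Benjamini–Hochberg adjustment is available in the
set-analysis module but deliberately not applied to DE calls, matching
the replicate-free design this pipeline replicates.

## ChIP peak filtering

Peaks are maximal runs of coverage ≥ max(1, h_min/2); each reports its
maximum height and leftmost-maximum summit, and only peaks with height
≥ h_min are kept (default 10). The FDR-derived height threshold models
background coverage as per-base Poisson with rate λ = reads ×
read-length / genome-length and returns the smallest h at which
(expected background bases at ≥ h) / (observed peaks at ≥ h) ≤ FDR
(default 0.01) — an analytic stand-in for a Monte-Carlo peak-calling
FDR, monotone in sequencing depth. The default h_min = 10 is an explicit
constant so behaviour on real data does not depend on the model.

The input-control criteria are computed in a window of ±400 bp around
the summit (summit-centred by assumption; config-exposed). With scale
r = depth_chip/depth_control, λ = r × mean control coverage and
c_max = r × max control coverage in the window. The filter requires,
conjunctively with the height threshold:

- local z-score z = (height − λ)/√(λ+1) > 1.8. The exact z formula is
  a declared design choice: Poisson variance with a +1 guard so λ = 0
  degrades to a raw height difference rather than dividing by zero.
- control fold = height / max(c_max, 1) > 1.75, the floor again guarding
  empty control windows.

Passing peaks with height ≥ 30 are flagged high-confidence. Increasing
a peak's height with the control fixed can never flip a passing peak to
failing (z and fold are increasing in height; the suite asserts it).

Peak-to-gene association uses basal-plus-extension regulatory domains:
strand-aware basal interval [TSS−5000, TSS+1000), extended on each side
to the nearer of 1 Mb from the TSS or the adjacent gene's basal
boundary, clipped at chromosome ends, always containing the gene's own
basal interval. A peak associates with every gene whose extended domain
overlaps it (one-to-many is expected; abutting intergenic extensions
mean a midway peak hits both flanking genes). Coordinates are 0-based
half-open everywhere; BED round trips are bit-exact.

## ChIP-qPCR

Fold enrichment FE = 2^(cT_IgG − cT_antibody); values < 1 represent
depletion. Within each replicate, enrichments are divided by the
negative-control locus's FE; replicate summaries are the arithmetic mean
± sample SD of the normalized values (a geometric-mean mode exists but
is off by default, since the mean-of-ratios convention is what replicate
bar plots in this field report).

## Synthetic data generator

The generator emulates the study design the pipeline assumes: five
replicate-free regional libraries (avc, oft, atria, ventricles, and a
mutant avc_null), NB count noise at φ = 0.12, 21-bp anchored tags, 1-bp
error satellites, Chastity failures, and ChIP coverage with planted
peaks over a Poisson background.

- **Transcriptome.** One transcript per gene (default 300 nt), ending in
  prefix + CATG + unique 17-mer + 25 nt anchor-free tail, so the 3′-most
  tag is fully determined by construction. A configurable fraction of
  gene pairs shares a tag to exercise ambiguity handling (default 0).
  Genes sit every 5 kb (`gene_spacing`) on one synthetic chromosome with
  random strand; the TSS grid is what the regulatory-domain rule needs.
- **Expression truth.** Every gene expresses at `base_tpm` (default 10);
  a fraction `frac_enriched` (default 0.1) is multiplied by 2^`log2fc`
  (default 2) in the valve-role libraries. In the mutant library a
  fraction `frac_null_responsive` (default 0.5) of enriched genes
  reverts to baseline — modelling loss of an upstream activator, which
  is what makes the mutant-vs-wild-type comparison and the
  bound-and-regulated cross-tabulation non-trivial. Counts are
  NB(TPM × depth/10⁶, φ) draws; at the default depth of 5 × 10⁶ the
  baseline mean count is 50.
- **Reads.** One read per count unit: the gene's tag, per-base
  substitutions at `seq_error_rate` (default 10⁻³), filler to 36 nt
  (read length beyond the informative 21 bases is arbitrary; 36 matches
  common short-read lengths). Quality failures are extra reads flagged
  `1:Y:0:0` with low quality characters, making up `chastity_fail_rate`
  (default 0.2) of the library; the Chastity computation itself (raw
  intensities) is out of scope, the flag is authoritative.
- **ChIP.** Control and ChIP tracks are independent per-base
  Poisson(`chip_background_rate` = 3); ChIP additionally receives
  triangular bumps of height `peak_amplitude` = 40 and half-width 200 bp
  at summits within ±500 bp of selected TSSs (enriched genes first), so
  a planted summit is guaranteed to reach the amplitude over background.
- **qPCR.** cT tables with cT_IgG − cT_antibody = log2(enrichment) +
  Gaussian noise (default sd 0).
- **Determinism.** Each output stream draws from a child generator
  derived from the master seed and the stream's name (CRC32), so
  identical configurations give byte-identical files and regenerating
  one output does not perturb the others. The suite asserts
  byte-identity of FASTA, FASTQ, bedGraph and the whole pipeline output
  directory.

What the generator does **not** emulate: PCR amplification bias, adapter
chemistry, MmeI 20/21-bp cut-length variability, genome-wide mappability
structure, transcript-variant tag sharing (off by default), fragment-
size effects in ChIP, or amplification-efficiency differences in qPCR.
Passing tests therefore demonstrate correctness of the computational
rules under the stated statistical model, not robustness to every
artefact of real libraries.

## Scales and study conditions used in checks

The acceptance script and suite run at sizes chosen to exercise the
stated study conditions while staying desk-sized; all are the package's
own scenario definitions:

- Exact-test oracle sweep: all totals ≤ 60 (≤ 40 in the script), group
  sizes {1, 2}; agreement < 10⁻¹⁰ (measured ~10⁻¹⁴).
- Type-I calibration: 10,000 null genes, mean 50, φ = 0.12, α = 0.05;
  measured rejection ~0.044–0.048 across seeds (band 0.035–0.065). The
  conditional test is slightly conservative, as expected for a discrete
  exact test.
- Enrichment recovery: 2,000 genes, depth 5 × 10⁶, baseline mean 50,
  log2 fold 2, 200 enriched genes. Recovery is scored on the
  valve-vs-chamber grouping (avc+oft vs atria+ventricles) because that
  is the contrast the truth flag defines — enrichment is planted in both
  valve libraries. Measured recovery 0.94–0.985 across seeds; the
  narrower one-region-vs-chambers contrast has power ≈ 0.89 at this
  effect size. Library sizes in this experiment are the generative
  depths: realized totals are inflated by the planted enrichment itself
  and would attenuate the effective fold below the stated log2fc = 2
  (a compositional effect also present in real library-size
  normalization, which is why the reference workflow's quantile
  adjustment exists).
- ChIP recovery: 1 Mb genome (400 genes × 2.5 kb), 50 planted peaks of
  amplitude 40 over background 3. All 50 pass the 10/1.8/1.75 filter and
  no background region passes, across seeds.
- Tag pipeline: zero-error round trips are exact (byte-level count
  equality); at error rate 10⁻³ with ~2,000-count parents, all
  identified satellites (ratio ≥ 100, parent ≥ 1000) are removed and no
  abundant truth tag is lost.

## Known limitations

- Library-size equalization is linear, not quantile-based; exact
  numerical parity with the reference Bioconductor implementation holds
  only for equal library sizes (the regime in which the frozen reference
  values were generated).
- The peak caller is deliberately simple (contiguous-run segmentation
  with a single height statistic); it is not a reimplementation of any
  published caller, and sub-peak structure (shoulders, double summits)
  is not resolved.
- Fisher category enrichment consumes a user-supplied category → genes
  map; no ontology graph propagation is performed.
- Supplementary-table ingestion expects the canonical column schema
  documented in `valvetag.sets.SCHEMAS`; sheets with other layouts must
  be renamed to it first.
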