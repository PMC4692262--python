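# Methods

`nipt21` implements z-score based noninvasive prenatal testing (NIPT) for
chromosome 21 trisomy from low-coverage whole-genome sequencing of
maternal-plasma cell-free DNA (cfDNA), together with a synthetic cohort
generator that reproduces the statistical structure the analysis depends
on. This note documents the models, the defaults and the reasoning behind
the open design choices.

## The detection model

A maternal plasma sample contains a mixture of maternal cfDNA and
placental ("fetal") cfDNA; the fetal fraction *ff* is the fetal share of
molecules. If the fetus carries three copies of chromosome 21, fetal
molecules from chr21 are oversampled by 3/2, so the expected chr21 share
of all reads is multiplied by approximately 1 + *ff*/2 (exactly,
(1 + *ff*/2)/(1 + *ff*·p21/2) with p21 the euploid chr21 share — the
difference is below 0.2% for realistic values and the package simulates
the exact renormalized form).

Scoring standardizes a per-sample ratio

    r = count(chr21) / count(reference chromosome set)

against a euploid training cohort: with M and S the training mean and
standard deviation (n−1 denominator; unbiased choice, not otherwise
prescribed), z = (r − M)/S and a sample is called trisomic at z ≥ 3
(inclusive; the cut-off value itself is the field's convention). Three
reference schemes are implemented:

1. **all-autosome reference** — the 19 autosomes excluding chr13/18/21.
   Sex chromosomes are also excluded so scoring is independent of fetal
   sex (the scheme is described in the literature as "all chromosomes
   except 13, 18, 21" without addressing X/Y; excluding them is the
   fetal-sex-invariant reading).
2. **chr14 reference** — r = c21/c14.
3. **CV-optimal internal reference (IR)** — every non-empty subset of the
   19 eligible autosomes is evaluated: for each subset the training CV =
   S/M of the ratios is computed and the subset with the lowest CV wins.
   The search space is 2^19 = 524,288 combinations; the empty set is
   excluded from evaluation (ratio undefined), so 524,287 candidates are
   actually scored, and the result distinguishes the nominal search-space
   size from the evaluated count. Ties (possible only on constructed
   data) break to the lexicographically smallest set by chromosome
   number. The implementation enumerates subset sums by bit-indexed
   dynamic programming over a (2^19 × n_training) array; it is
   numerically identical to naive enumeration because subset sums of
   integer counts are exact in double precision, and the test suite
   checks agreement with an independent brute-force oracle on reduced
   universes.

**Fetal fraction.** For a confirmed trisomic sample the same ratio yields
the fetal-fraction estimate ff = 2(r − M)/M, equivalently ff = 2·z·CV
(held exactly by construction when M is the reference level; a
median-referenced variant is available via `reference_stat="median"`).
After in-silico size selection the estimate is the *effective* fetal
fraction — the fetal share among retained reads; the physical sample is
unchanged.

## Read processing

Reads arrive as SAM/BAM or a tabular read-record dialect. One record per
primary alignment; for paired-end data only the first mate of a proper
pair is kept, with effective length = |template length|; single-end
records carry the stored pre-trim read length (trimming itself is not
re-implemented). Processing order:

1. **downsample** raw records to at most 3 million per sample (uniform,
   seeded) — the cap applies to raw, pre-filter records so the 3M
   accounting matches the targeted raw yield;
2. **filter**: MAPQ ≥ 40, effective length ≥ 35 bp;
3. **deduplicate**: reads sharing (chromosome, 5′ position, strand)
   collapse to the single best (mapq, length) record. "Unique reads" is
   not defined more precisely by the protocols this mirrors;
   position-strand collapse is the standard PCR-duplicate proxy for
   single-end data. The three rules are applied jointly; per-rule passes
   commute whenever duplicates are true copies (the PCR-duplicate
   model), which is what the property test asserts.
4. **count** into fixed 50 kb half-open bins (0-based coordinates
   throughout; SAM positions converted on ingestion). Reads on
   chromosomes outside the modeled 24 (chrM, unplaced contigs) are
   dropped with a counted warning. Counts are additionally stratified by
   effective-length class on the sweep grid so any inclusive cutoff can
   be re-derived without re-reading records.

With the default MAPQ model of the simulator (~72% of reads at MAPQ ≥ 40)
a 3M-read sample collapses to ≈ 2.16M analyzable reads, matching the
regime the pipeline is designed for.

## GC correction

Coverage depends smoothly on bin GC content and the dependence varies
between runs; this inflates the between-sample variance of the chr21
representation. Correction is per-sample, with no cross-sample (intrarun)
normalization: a LOWESS curve (span 0.3, one robustness iteration,
interpolation delta 0.005 of the GC range) of bin count against bin GC is
fitted on autosomal bins excluding chr13/18/21 (they may carry signal),
and each bin is rescaled by median(fitted)/fitted(GC). Correction factors
are clamped to [0.2, 5] to bound the leverage of GC-extreme bins; fitted
values ≤ 0 (possible at sparse GC extremes) are clamped with a counted
warning. The 50 kb default bin size gives ≈ 35 reads/bin at 2.16M reads —
enough for a stable regression without zero-inflation; the bin size and
span are configurable. On unbiased data the correction is a near-identity
(per-chromosome change < 2% in the tests) and aggregate counts are
conserved within [0.8, 1.25].

The CV diagnostic mirrors the training diagnostic of the pipeline: for a
euploid cohort, CV of the *fractional* chr21 representation (chr21 /
reference sum), which is depth-invariant.

## The synthetic cohort generator

The generator emulates the data-generating process at the resolution the
ratio analysis sees; it does not simulate bases, sequencing errors or
alignment.

* **Genome**: hg19 chromosome sizes, 24 chromosomes, fixed bins.
  Chromosome-level GC means follow the human reference (chr19 ≈ 0.48,
  chr4 ≈ 0.38, …); within a chromosome, GC varies as a seeded smooth
  process (sd 0.04, correlation length 20 bins, clipped to [0.25, 0.70]).
  The chromosome-to-chromosome GC contrast is essential: without it a
  sample-specific GC bias would distort all chromosomes equally and
  cancel from every ratio.
* **Reads**: each read is fetal with probability *ff*; bins are drawn
  proportional to bin length × mappability × GC-bias factor, with the
  fetal chr21 mass × 1.5 for trisomy-21 samples; positions are uniform
  within the bin; MAPQ is a three-component mixture with P(MAPQ ≥ 40) ≈
  0.72 calibrated to the 3M → 2.16M filtering yield.
* **Fragment lengths**: discretized log-normals on 50–400 bp,
  parameterized by mode and sd — fetal mode 143 bp, maternal mode 166 bp
  (the nucleosome-with/without-linker landmarks), sd 20 bp for both. The
  full shape of the length distribution is not published for the regime
  this emulates, so the log-normal family and spread are a modeling
  choice; what matters downstream is the stochastic ordering (fetal CDF
  above maternal everywhere) and the ~25% retention at cutoffs near
  155–160 bp, both of which the defaults reproduce.
* **GC bias**: a per-sample log-quadratic factor exp(c·(GC − 0.41)²)
  with c ~ Normal(−3, 21) across samples. The spread 21 was calibrated
  (by quadrature over the genome model, then confirmed by simulation) so
  that the uncorrected chr21 CV of a 60-sample euploid training cohort at
  3M raw reads lands near 0.9% — the regime the pipeline's training
  diagnostics assume — decomposing into ≈ 0.53% counting noise and
  ≈ 0.73% GC-induced variance; after per-sample correction the CV falls
  to ≈ 0.6–0.7%.
* **Cohort defaults**: 106 euploid + 24 trisomy-21 samples, fetal
  fractions uniform in [8.12%, 42.62%] for both classes (euploid
  pregnancies carry fetal material too — only the dosage differs), 3M raw
  reads per sample, per-sample seeds spawned from the master seed (kept
  below 2^31), byte-identical truth tables under a fixed master seed.
* **Physical size selection** (optional flag): a double-sided logistic
  retention curve rising through 142 bp and falling through 166 bp, so
  the retained fetal+maternal mixture peaks near 155–160 bp and short
  fetal fragments survive preferentially; the effective fetal fraction is
  tilted accordingly. Only the read-length consequence of the bead
  protocol is modeled.

**What passing tests do and do not show.** The generator's reads are
conditionally independent given the sample parameters; real cfDNA has
correlated coverage structure (mappability holes, CNVs, maternal
mosaicism), GC effects that are not exactly quadratic in log, and
fragment-length distributions with di-nucleosomal mass around 320 bp.
Passing the cohort-level checks therefore demonstrates the correctness
and internal consistency of the analytical machinery under the stated
statistical assumptions, not clinical performance on real samples.

## In-silico size selection

`filter_by_length` keeps reads with effective length ≤ cutoff (inclusive
boundary, reading "reads up to 160 bp" literally). The sweep runs cutoffs
140–180 bp in 5 bp steps; for each cutoff the pipeline re-filters,
recounts, refits the GC curve (length filtering changes the GC
composition of the retained library; refitting is the safer default and
is switchable to reusing the all-reads curve), retrains on the euploid
training set and rescores. The chosen cutoff maximizes the mean z of the
known trisomic samples only — euploid dispersion is not part of the
objective — with ties broken to the smaller cutoff, and any cutoff
leaving fewer than 10^4 reads in some sample flagged unusable. Under the
default length models the optimum lands at 150–160 bp with ≈ 25–30% of
reads retained, and the mean trisomic z at the optimum exceeds the
unfiltered mean (the retained reads are fewer but much richer in fetal
material).

## Reporting

Sensitivity and specificity come from comparing calls at z ≥ 3 against
the truth table; confidence intervals are Clopper–Pearson exact binomial
(beta-quantile inversion of the binomial CDF), the method that reproduces
the printed bounds this pipeline is benchmarked against (85.75% for
24/24, 93.35% for 104/106, 94.86% for 105/106). Degenerate cohorts (no
positives, or no negatives) report NaN rather than raising. Cross-method
comparisons are reported descriptively (mean z differences); no
significance testing is performed.

## Problem sizes and numerical choices

* Default analyses run at the study scale: 130 samples × 3M raw reads,
  50 kb bins, 60 training samples. One full cohort analysis, including
  the nine-cutoff sweep with per-cutoff retraining, takes ≈ 6 minutes on
  one CPU core and < 1 GiB of memory.
* Multi-seed property checks in the test suite use reduced cohorts
  (e.g. 12 euploid + 8 trisomic at 600k reads, 200 kb bins) because the
  properties they assert — CV reduction, enrichment direction, sweep
  stability — are scale-free; depth-sensitive assertions (CV bands,
  fetal-fraction recovery) run at full depth.
* The IR search allocates the full (2^19 × 60) subset-sum array
  (~250 MB) rather than streaming, trading memory for a vectorized exact
  enumeration in a few seconds.
* Degenerate inputs: all-equal GC yields a constant correction curve
  (identity correction); zero reference denominators raise errors naming
  the sample; S = 0 training models refuse to score.

## Known limitations

* The simulator's GC bias family (log-quadratic, sample-varying
  coefficient) is one plausible shape; the correction module is generic
  (LOWESS) and does not assume it, but the calibration numbers above are
  specific to the default genome model and depth.
* Trisomy 13/18 and sex-chromosome aneuploidies are out of scope; those
  chromosomes are only ever excluded from references.
* Physical size selection is emulated only as a retention curve on
  fragment length; bead chemistry yields and losses are not modeled.
* The paper-scale cohort metrics (e.g. which chromosome subset the IR
  search picks) depend on the realized simulation draw; only their
  statistical regime, not their exact values, is reproducible without
  the original sequencing data.
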