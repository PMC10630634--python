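# Methods

This note documents the models implemented in `nasctx`, the defaults and
why they were chosen, the numerical details, and what the synthetic-data
generators do and do not emulate.

## Coordinates and strandedness

All internal coordinates are 0-based half-open (BED convention); GTF I/O
converts at the file boundary (GTF is 1-based inclusive). A single
internal convention eliminates a whole class of off-by-one errors when
mixing browser-style and BED-style inputs. Strandedness is mandatory
everywhere: unstranded (`.`) transcripts or coverage are rejected rather
than guessed, because antisense pairing, pausing windows and
strand-specific quantification are meaningless without strand.
Chromosome names are matched as exact strings; `chr1` and `1` are
different until the caller explicitly applies the alias mapping.

## Transcription-unit calling

Nascent run-on coverage marks transcribed bases directly, so units are
called by thresholding: maximal runs of depth ≥ `min_depth` in which
sub-threshold gaps of at most `max_gap` bp are bridged, discarding units
shorter than `min_length`.

* `min_depth` — reads/bp. Default: 4× the track-wide mean depth over the
  covered span. On real genomes signal regions are sparse, so the mean
  sits near the noise floor and 4× separates signal from background; on
  dense toy genomes an explicit threshold between the noise and signal
  depths is more appropriate and all tests set it explicitly.
* `max_gap` — 500 bp by default. Bridges pausing dips and mappability
  dropouts; 500 bp is small against the multi-kb transcription units the
  caller targets. Note the interaction with background noise: if the
  per-base probability of a spurious above-threshold base is non-trivial,
  chains of bridged noise can extend or merge units, so `max_gap` should
  be well below the expected spacing of noise exceedances.
* `min_length` — 200 bp, the conventional lower bound for a long
  noncoding RNA.

Units are emitted as single-exon (unspliced) transcripts: nascent
coverage covers introns and cannot resolve splicing. Ids are
deterministic (`TU_<chrom>_<start>_<strand>`).

When merging de novo units with a reference annotation, a novel unit is
dropped iff one same-strand annotated transcript covers at least
`dedup_overlap` (default 0.5) of the novel unit's length. Annotated
records are never modified.

## Quantification and pausing

Feature signal is total depth × bp on the feature's own strand, over the
whole interval (`gene`), the exon union (`exon`) or interval minus exons
(`intron`); exon + intron = gene exactly by construction. RPKM =
count / (length/10³) / (libsize/10⁶); log transforms use
log₂(RPKM + 1) so zero-expression features stay finite.

The pausing index contrasts the promoter-proximal window — the first
300 bp downstream of the TSS in the direction of transcription — with
the remainder of the annotated interval (no exclusion gap). Elevated
proximal/body density ratios indicate polymerase accumulation near the
promoter relative to productive elongation. The ratio is undefined
(NaN, flagged) when the body has zero signal. Group comparisons use
Welch's unequal-variance t test on per-replicate densities, after
scaling each replicate to its library size; Welch is the default
because equal variances across conditions is an assumption we cannot
check from two small groups.

## Differential expression

The stage reimplements the standard count-based DE design end to end.

* **Filter** — keep features with more than 10 counts in at least 70% of
  the samples of at least one group. The ">" is strict and the "≥ 70%"
  inclusive.
* **TMM normalization** — for each sample against a reference (the
  sample whose 75th-percentile count fraction is closest to the mean of
  those fractions), compute gene-wise M (log₂ ratio of normalized
  counts) and A (mean log₂ abundance) over genes nonzero in both, trim
  the 30% most extreme M and 5% most extreme A, and average the
  surviving M with inverse asymptotic-binomial-variance weights; the
  factor is 2 to that mean, and factors are rescaled to geometric mean 1.
  These are the canonical TMM defaults; the implementation agrees with
  edgeR's `calcNormFactors` to 5+ significant digits on test matrices.
* **Dispersion** — NB variance is μ + φμ². The common φ maximizes the
  Cox–Reid adjusted profile likelihood (the 0.5·log det X′WX penalty
  computed per group) summed over all features, optimized on log₁₀φ over
  [10⁻⁶, 10]. Tagwise values are method-of-moments estimates around the
  fitted group means — with the squared-residual sum inflated by
  n/(n − p) to undo the degrees-of-freedom loss, without which the
  moment estimate is biased low and the LRT runs anti-conservative —
  shrunk toward the common value with a fixed prior weight of 10
  residual degrees of freedom, then clamped to [10⁻⁶, 10]. This is an
  explicitly simple stand-in for full empirical-Bayes tagwise machinery;
  it reproduces its qualitative behavior (stable small-sample inference)
  and is fully specified.
* **Test** — per feature, a log-linear NB GLM with offsets
  log(effective library size), fit by Newton/Fisher scoring on the group
  means (at most 50 iterations, step tolerance 10⁻⁸, steps clipped to
  ±5 on the log scale for stability at zero counts). The LRT statistic
  2(ℓ₁ − ℓ₀) against the single-mean null is referred to χ² with 1 df.
  log₂FC comes from the fitted group means, logCPM from the mean
  normalized counts-per-million with pseudocount 0.5.
* **Calls** — Benjamini–Hochberg over the filtered (tested) features
  only; `up` iff log₂FC ≥ 0.7 and FDR < 0.01, `down` iff log₂FC ≤ −0.7
  and FDR < 0.01. The fold-change boundary is inclusive, the FDR
  boundary exclusive.

Calibration, measured by the test suite: under a 4-vs-4 null with
φ = 0.1 and 2000 features the raw p < 0.05 rate stays within
[0.03, 0.07] and essentially nothing is called at the thresholds above;
with 10% of features at |log₂FC| = 2 the pipeline reaches recall ≥ 0.8
at empirical FDR ≤ 0.05.

## Antisense pairing and regulation classes

Pairs are formed between coding genes and opposite-strand transcripts
with gene-body (TSS→TTS) interval overlap — not exon unions, because
nascent transcription covers introns and the relevant overlap is
locus-level. The retention rule is overlap_bp / antisense_length ≥ 0.10,
inclusive; the denominator is the antisense transcript's length (a
reciprocal mode is a flagged option). Topology: `nested` if one interval
contains the other, otherwise `convergent` when the two TSSs point into
the shared region and `divergent` when they point away.

Classification from DE calls: **ASRG** iff both members are differential
with opposite-sign fold changes; **NARG** iff both differential with the
same sign; otherwise not regulated. Requiring both members to pass the
DE thresholds is the default and the stricter reading; a looser
directional mode (antisense DE alone, class from signs) is available
behind `require_both_de=False`. The class pattern is symmetric under
swapping the condition labels (global sign flip).

The pair-level Pearson correlation of fold changes takes the pair set as
an explicit argument — all expressed pairs and DE-only pairs are both
legitimate choices and give different values; the caller decides.

## HRE scanning

The hypoxia response element core consensus is RCGTG (R = A/G). The scan
reports every match on the forward strand and every position whose
reverse complement matches (reported with strand `-` and the
reverse-complemented 5-mer), 0-based relative to the supplied promoter
offset, including overlapping matches. `N` never matches.

## qPCR and kinetics

ΔΔCT assumes amplification efficiency 2 (perfect doubling): ΔCT =
CT_target − CT_reference per sample, ΔΔCT = ΔCT − mean calibrator ΔCT
(per target), relative expression = 2^−ΔΔCT. By construction the
calibrator group's relative expression has geometric mean 1. All
replicate statistics (Welch t tests, Bonferroni adjustment
p·m capped at 1) operate on the additive ΔCT scale, never on fold
changes, whose distribution is log-normal and skewed.

Approach-to-equilibrium labeling: for labeling times well below the
transcript's turnover time, labeled abundance grows linearly, so the OLS
slope of abundance on time is a synthesis-rate proxy. The fit keeps a
free intercept — background capture and offsets are real even though
zero label is expected at t = 0 — and the slope comparison is the
two-sided t test on the condition×time interaction in the pooled linear
model, which is robust to intercept differences. Under an equal-slope
Gaussian null this test is exact; the suite verifies its type-I error
and its agreement with a stratified label-permutation reference.

## Synthetic data

Each generator is deterministic in `(seed, params)` and records its
ground truth in a `TruthManifest`.

* **Toy genome** — non-overlapping plus-strand coding genes with
  log-uniform lengths 2–60 kb and intergenic gaps of 2–8 kb; a chosen
  fraction of genes carries one minus-strand antisense unit anchored at
  the host gene's 3′ end (convergent geometry) whose overlap fraction of
  its own length is drawn from a configurable range (default
  0.10–0.90). 500 genes per chromosome.
* **Coverage** — per-base Poisson around planted means: gene-body depth
  proportional to expression, the first 300 bp downstream of the TSS
  multiplied by the pausing ratio, plus a uniform background mean depth
  on both strands.
* **Counts** — NB with variance μ + φμ², matching the inference model
  exactly so recovery tests are well-posed; per-sample depth factors;
  planted log₂ fold changes applied in the condition group.
* **Labeling** — abundance = slope × time × (1 + N(0, σ)), floored at 0,
  on the 15/30/45/60-minute grid.
* **qPCR** — CT_target = base − log₂(fold) + N(0, σ_CT), a stable
  reference gene, CT noise independent per well.

**The default scene** (seed 42) is the canonical integration fixture:
3000 genes, antisense fraction 0.10 (~300 units), 4+4 replicates,
φ = 0.05, and 25 planted inverse pairs. Pair effect sizes are chosen for
unambiguous recovery — antisense up uniform(2, 4), sense down
uniform(1.5, 2.5) log₂ units, with pair-member baselines of 100–500
counts — so that each member sits several standard errors beyond the
call thresholds and the planted ASRG set is recovered exactly with high
probability at any seed. Remaining pairs receive small positively
correlated effects (bivariate normal, sd 0.35, correlation 0.35),
emulating the loose coregulation typical of sense–antisense pairs while
keeping the chance of an accidental both-DE opposite-sign pair
negligible; 150 unpaired coding genes get background fold changes of
0.8–2.5 in either direction. These sizes keep the full scene (generation
plus the complete DE/pairing analysis) under a second of CPU.

What the generators do **not** emulate: mappability and GC bias,
splicing and isoform structure, fragment-level counting with ambiguous
gene overlap, polymerase directionality artifacts (antisense
bleed-through), reference-gene instability in qPCR, and label-uptake
saturation at long labeling times. Passing tests therefore demonstrate
that the statistics are implemented correctly and calibrated under the
stated models — not that those models capture every artifact of real
libraries.

## Known limitations

* The dispersion shrinkage uses a fixed prior weight rather than
  estimating the prior from the data; very heterogeneous dispersions
  will be over-shrunk.
* The GLM supports a single grouping factor (two-group contrasts); no
  covariates, no quasi-likelihood F tests.
* The transcription-unit caller is threshold-based and single-scale; it
  does not separate closely spaced units transcribed at similar depth,
  nor detect bidirectional (eRNA-style) pairs.
* BED/GTF support covers the Ensembl-style attribute dialect used here,
  not every dialect in the wild; bigWig I/O is out of scope (coverage
  enters as bedGraph).
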