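# Methods

`modscreen` re-implements, as a tested library, the statistical procedures
used to find and characterize modifiers of TDP-43 protein levels from a
pooled CRISPRi FACS screen and its companion assays: dual-guide read
filtering, cross-screen fixed-effect meta-analysis with novelty calling,
single-timepoint dSILAC protein turnover, cryptic splice-junction
classification, and a bulk RNA-seq normalization/noise-filter chain. Every
stage can be exercised on synthetic data with planted ground truth, so each
statistic is testable without any external download.

## Screen harmonization and meta-analysis (`modscreen.meta`)

Inputs are per-screen gene tables with a native-scale effect (log2 fold
change of guide abundance between fluorescence bins, or a phenotype score)
and a two-sided p-value. Screens are harmonized to a shared scale:

- **beta** — the effect column z-scored across the screen's genes
  (`beta_mode="zscored_effect"`, the default). Screens whose effects are
  already standardized can pass through unchanged
  (`beta_mode="raw_effect"`). The standardized effect and the reported
  p-value are the two pieces of evidence the meta-analysis combines; beta
  defined as the z itself would force SE ≡ 1 and make the inverse-variance
  weights uninformative, which is why the rank-free z-scoring of the native
  effect is used.
- **p truncation** — p is clamped to `[1e-300, 1 − 1e-16]` before quantile
  conversion so the normal quantile stays finite at double precision;
  truncation only ever makes results more conservative. Both bounds are
  configurable.
- **z, se** — `z = sign(beta)·Φ⁻¹(1 − p/2)` and `se = |beta| / |z|`, the
  standard error under which the standardized effect reproduces the
  reported evidence. A gene with beta exactly 0 has no defined SE; it gets
  an epsilon effect (1e-8) and a flag rather than an exception.

Pooling per gene over the k screens of a combination is the classical
fixed-effect model: `w_i = 1/se_i²`, `β̂ = Σwβ/Σw`, `SE = (Σw)^(−1/2)`,
`z = β̂/SE`, Cochran's `Q = Σw(β − β̂)²` on k−1 df and
`I² = max(0, (Q − df)/Q)`. Heterogeneity is reported, never used to drop
genes. All subsets of ≥ 2 screens can be evaluated; genes missing from a
screen are pooled only in combinations where they are present (no
imputation). Benjamini–Hochberg FDR is computed within each combination
over its gene intersection, and per screen over each screen's full gene
universe.

**Novelty** of a gene in a combination: BH-adjusted p ≥ α in *every*
constituent screen and BH-adjusted meta p < α (α = 0.05 default). **Hits**
additionally require directionality: novel and
`|beta_pooled − reference| ≥ 1` (inclusive, threshold configurable), where
the reference defaults to the mean pooled effect over all genes of the
combination; mean-over-novel-genes is available as an option since the
population-reference definition admits both readings.

A caveat established by the null simulations: BH's familywise rejection
probability at the global null equals α, so over many null replicates a
small number of pooled discoveries — and hence novelty flags — are
expected even with nothing planted. Novelty flags are always a subset of
the FDR-controlled discovery set; the guarantee that is actually exact is
that genes carrying per-screen-significant signal are never flagged novel.

## Dual-guide read filtering (`modscreen.dualguide`)

Dual-guide lentiviral cassettes recombine during reverse transcription, so
a read pair is trusted only when the guide found in read 1 (position A)
and in read 2 (position B) belong to the same construct. Detection is
exact substring match within a configurable window (default: whole read);
error-tolerant matching is deliberately not attempted, as the conservative
default. Pairs whose two guides map to different constructs are
*recombined*; a flag relaxes "same construct" to "same target gene". The
accounting invariant `total = matched + recombined + unmapped` is asserted
on every run. Construct tables can be filtered at a minimum total count
(default 10; the source procedure removes low-count guides without naming
a number).

The permutation gene scorer is plumbing so the synthetic pipeline runs end
to end without external screen software — it is not a re-implementation of
RRA. Per construct: `log2((high + 1)/(low + 1))` after per-bin library-size
normalization; per gene: the median over its constructs; p: the fraction
of `n_perm` random same-size construct sets with at least the observed
absolute median, with the +1/(n_perm + 1) correction that keeps null
p-values sub-uniform.

## dSILAC turnover (`modscreen.turnover`)

After the switch to heavy media, steady-state turnover gives the peptide
relation `R = 2^(ts/t½) − 1`, inverted as `t½ = ts·ln2/ln(1 + R)` (days).
The product reading of the printed formula would make half-life increase
with heavy-label incorporation, contradicting the labeling kinetics, so
the quotient form is used. Peptide filters (strict inequalities):
contaminant-flagged rows, intensity below 1000, H/L ratio below 0.01 or
above 100. Note an interaction worth knowing: at ts = 7 d the ratio cap
removes every peptide of proteins with t½ below ≈ 1.05 d, so very
short-lived proteins are unmeasurable by design at that timepoint.

Protein half-life is the harmonic mean over *unique* peptide sequences
(repeated measurements of one sequence collapse to their median first;
charge states count as the same peptide). Peptides are pooled within
condition by default; per-replicate rollup is available and is what the
differential test consumes. Differential turnover/abundance: Welch t-test
on log2 values with BH adjustment; significance requires both
`|log2FC| ≥ threshold` (0.5 for half-lives, 1 for abundance and
phosphosites) and adjusted p < 0.05. The global turnover shift is the
median paired log2 half-life ratio over shared proteins with a Wilcoxon
signed-rank test.

## Cryptic splicing (`modscreen.splicing`)

From per-sample PSI values: `ΔΨ = mean(KD) − mean(control)` (missing
values excluded), control presence = fraction of control samples with
PSI ≥ 0.01 (the detection floor is configurable; the source defines
"present" without one). A junction is significant when |ΔΨ| > 0.10 and
cryptic when `(ΔΨ > 0.10 and presence < 0.05)` or
`(ΔΨ < −0.10 and presence > 0.10)` — all strict, transcribed exactly as
published, including the asymmetric negative clause (a config override
exists in case it is a transcription artifact). Categorization against an
exon annotation (0-based half-open, strand-symmetric): canonical (both
ends at annotated sites, no exon inside), exon skipping (both ends
annotated, ≥ 1 annotated exon fully inside), cryptic exon (≥ 1 end at an
unannotated position inside an annotated intron), intron retention (the
record represents intronic inclusion, carried by its `within_intron`
status — a junction between adjacent splice sites shares its coordinates
with the intron, so retention cannot be inferred from coordinates alone).

## RNA-seq chain (`modscreen.rnaseq`)

In order: counts per kilobase of gene length; per-sample scaling to one
million (columns sum to 1e6 exactly); additive pedestal of 2; log2; cyclic
loess — per sample pair, the M-vs-A trend is lowess-smoothed (span 0.4,
2 robustifying iterations) and half the fit moved between members, cycling
3 times over all pairs. Identical samples are untouched by construction.

The noise model fits, per condition, a lowess curve of the per-gene CV
(sd/mean of the linearized values across replicates) against mean log2
expression. The CV curve uses a narrower span (0.2) than the MA trends:
the detection threshold lives where the CV drops sharply, and a wide span
smears that transition. The threshold is the smallest mean at which the
fitted CV falls below 0.5 (boundary conventions: low edge when below
everywhere, high edge when never below); the final threshold is the max
over conditions, and a gene survives when its mean expression reaches it
in at least one condition. Differential expression is a per-gene Welch
t-test on the normalized log2 values with BH adjustment; direction is
assigned only to significant genes. `ddct` implements qPCR relative
quantification, fold change = 2^−ΔΔCt.

## Synthetic data (`modscreen.simulate`)

One global seed; each generator draws from an independent substream keyed
by a stable hash of its stage name, so stages are reproducible in
isolation and byte-identical under a fixed config.

- **Screens** — null gene effects are standard normal with
  `p = 2(1 − Φ(|effect|))`, so null p-values are uniform and the effect
  scale matches what the harmonizer targets (the real screens' null
  distribution is unknown; this is a modeling convention). Planted
  classes: *shared* hits (mean |effect| 4.0, sd 0.3, random sign, every
  screen), *specific* hits (one screen), *distributed-weak* genes
  (mean |effect| 2.2, every screen) — individually below per-screen FDR
  significance at 5,000 genes yet jointly detectable, which is what the
  novelty rule is meant to find.
- **Reads** — guides (20 nt, unique per position) embedded at random
  offsets in 50 nt reads; a configured fraction of pairs takes guide B
  from a construct targeting a different gene, making them recombined
  under either reading of the filter. Truth records intended
  per-construct counts and the realized recombined tally.
- **Peptides** — per-protein true half-lives uniform on 0.5–30 d,
  multiplicative log-normal ratio noise (CV 0.05 default), log-normal
  intensities, optional contaminant and out-of-range injections.
- **Junctions** — three-exon toy genes on one forward-strand chromosome
  give each category an unambiguous geometry; cryptic junctions have
  control PSI exactly 0 and KD PSI 0.5; Gaussian PSI noise (sd 0.02)
  clipped to [0, 1].
- **Counts** — negative binomial with `var = μ + φμ²` (φ = 0.05 default),
  log-normal baseline means, gene lengths 300–10,000 bp, a fraction of
  genes shifted by ±2 log2 units in KD.

What the generators do **not** emulate: guide-efficacy distributions
(one effect per gene), correlated screens, peptide-level missingness
structure and charge-state redundancy of real MS data, PSI estimation
uncertainty from read depth, and library-composition artifacts. Passing
tests therefore demonstrate the correctness and calibration of the
statistics under their stated models, not performance on any particular
deposited dataset.

## Problem sizes and numerical choices

The test-suite and the acceptance script use: 2,000–5,000 genes per
screen, 4 screens, 20 global-null replicates; 200 proteins with 3–8
peptides; 20,000 read pairs per recombination setting; 400 junctions; 500–
2,000-gene count matrices with 4 replicates per condition. DE power is
evaluated at the low-dispersion planting (φ = 0.01) the power analysis is
defined for; null calibrations use the defaults. Ties and degenerate
inputs: constant groups in the Welch test yield p = 1; beta = 0 genes get
the epsilon-SE guard; `i2` is defined as 0 when Q = 0; hit-direction
boundaries are inclusive; all peptide-filter and splicing inequalities are
strict.

## Known limitations

- The permutation scorer ignores guide-level count overdispersion; it is
  adequate for planted-effect recovery, not for real-screen inference.
- The half-life differential uses plain Welch tests; a moderated-variance
  (limma-style) option is not implemented for non-phospho data, where the
  source is silent on moderation.
- Fixed-effect pooling assumes one common true effect per gene;
  heterogeneity is quantified (Q, I²) but no random-effects model is
  offered.
- The noise threshold's definition (smoother span, CV cutoff, max-over-
  conditions combination) is a documented implementation choice; other
  conventions would shift which low-expression genes are filtered.
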