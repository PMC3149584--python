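# Methods

## Units and covariates

Three unit definitions are supported. *Transcript* units use each
spliced cDNA directly. *Gene* units summarise a gene's isoforms by the
per-covariate median: median cDNA length (log-transformed after the
median), median GC, and the median of each dinucleotide frequency taken
column-wise — the 16 medians are deliberately **not** renormalised, so a
gene-unit "frequency vector" need not sum to 1. *SINO* units restrict
gene units to single-isoform genes whose genomic span (min exon start to
max exon end) intersects no other gene's span on the same chromosome,
strand ignored — a conservative overlap notion, since antisense overlap
also creates counting ambiguity.

Annotation coordinates are 1-based inclusive on disk (GTF/GFF3) and
0-based half-open in memory; minus-strand cDNAs are reverse-complemented.
`N` bases are excluded from both numerator and denominator of GC content,
and dinucleotide windows containing `N` are skipped (the denominator
shrinks). An all-`N` sequence is an error, not a zero.

## Quantification

A read is assigned by its start position — the 5' end in sequencing
orientation, i.e. the leftmost aligned base of a forward alignment and
the rightmost of a reverse alignment. Every unit with an exon containing
that position is incremented, so reads in regions shared by two genes are
double counted rather than allocated probabilistically; this is a feature
of the simple counting scheme, kept deliberately. Each reported
alignment of a multi-mapped read contributes one count. RPKM is
`C·10⁹/(N·L)` with `N` the lane's mapped total and `L` the unit's cDNA
length in nt.

## The correction

1. Drop zero-expression units (no pseudocount; they are passed through
   unchanged and flagged) and take natural logs.
2. Correlation-matrix PCA of the 17 composition covariates: columns are
   centred and scaled, so heterogeneous scales cannot dominate; `K` is
   the smallest component count whose cumulative variance share is
   ≥ 0.95 (ties count as reached). Signs follow a fixed convention (the
   largest-magnitude loading of each component is positive) so runs are
   reproducible across platforms. Constant columns are dropped with a
   warning.
3. Penalized additive fit of log expression on `log L` and the `K`
   scores. Each term is a cubic B-spline basis (~10 functions, via
   statsmodels) with a second-derivative penalty; for Gaussian errors the
   fit is the closed-form solve `(X'X + S)b = X'y`. Penalty weights are
   selected by GCV with two deterministic safeguards: the model degrees
   of freedom in the GCV score carry the standard ×1.4 inflation that
   counters GCV's tendency to undersmooth, and among penalties whose GCV
   lies within 0.5% of the minimum the smoothest is preferred (the
   `lambda.1se` idea), because GCV profiles are often nearly flat between
   a wiggly and a smooth fit and taking the literal argmin lets the
   surface flip between near-tied basins on small data perturbations.
   A bounded continuous refinement then removes grid quantisation. The
   whole procedure is deterministic given the data.
4. Corrected log expression = grand mean of log Y + residual. The grand
   mean is taken on the **log** scale so the stated sum is dimensionally
   coherent and the corrected values preserve the observed mean exactly;
   both log and linear (`exp`) outputs are emitted. The intercept is a
   single global α — a per-gene intercept would be unidentifiable with
   one observation per gene. A `length_linear` switch replaces the
   length smooth by a bare linear term for users who want the strictly
   linear-length variant of the model.

### Per-term significance

Drop-one F-tests at the GCV-selected penalties are anticonservative
(selection leaks into the test; we measured 7–10% null rejection at
nominal 5%). Hypothesis testing is therefore decoupled from estimation:
each term is tested in models where **every** smooth is a fixed ~4-edf
reference smoother (the classical fixed-df additive-model F-test; the
per-term penalty is found by bisection against the term's marginal edf,
not by the data). Because penalized smoothers shrink rather than
project, the RSS difference is a weighted χ² mixture, not χ² — so both
the numerator and the residual degrees of freedom are Satterthwaite
two-moment matched, using traces of hat-matrix polynomials computed
entirely in coefficient (p×p) space. Measured null rejection is 2.5–7.5%
at nominal 5% (within the binomial CI over 200 replicates) with
essentially full power against a sine-shaped smooth effect of amplitude
1 at n=500. Raw p-values are reported; no multiplicity adjustment is
applied.

## Bias diagnostics

Binned-median trends sort units by one covariate (stable sort), cut
consecutive bins of 500 units (the last may be smaller; fewer units than
one bin degrade to a single bin with a warning) and report per-bin median
covariate vs median log expression plus the OLS slope through the bin
medians — the slope mirrors what the bias plots display, which is why it
is fitted on bin medians rather than unit-level values. Constant
covariates are flagged degenerate, not fatal.

The platform-specificity test takes expression for the same genes
measured on two platforms and two samples, standardises within each
platform×sample group (removing scale differences between, say, ΔCT and
log FPKM), and fits one joint OLS model with the covariate, both
indicators, and covariate×platform and covariate×sample interactions.
The reported p-values are the two-sided t-tests of the two interaction
coefficients — "does the platform (or sample) change the slope?" — which
operationalises trend-specificity; main effects are also available in the
returned coefficient table. An alternative design would test platform
and sample in separate models; the joint model is used so each
interaction is adjusted for the other.

## Evaluation procedures

*Stratified cross-platform correlation*: genes are split into three
equal-count strata (tertiles; sizes differ by ≤1, ties broken by unit id)
of |corrected − uncorrected| log expression, plus an overall row; Pearson
r against the reference platform is computed before and after correction
and summarised as `100·(r_after − r_before)/r_before`, rounded to one
decimal for reporting. Degenerate strata are flagged rather than fatal.

*Depth robustness*: lanes are pooled cumulatively (k = 1..L), expression
is recomputed and corrected at each k, and a gene counts as stable at k
when its before/after log fold change is within ±5% (relative) of the
final-lane value, with an absolute ±tolerance band when the final value
is below 1e−6. Genes are stratified into tertiles of final corrected
log expression. Two design choices make the curve a clean measurement
of convergence: the gene universe is fixed to genes detected in the
first lane (so the same model is fit at every depth), and the smoothing
penalties are selected once on the full-depth data and held fixed for
the partial-depth fits — otherwise the penalty optimiser's near-tied
choices between overlapping datasets dominate the curve. Because the
per-gene stability indicator is noisy at exactly the scale of the
late-lane increments, a single realisation's fractions can wobble by
±0.01–0.03; the systematic curve is estimated by averaging a few
replicate simulations wherever monotone convergence is the claim being
examined.

## The synthetic-data generator

The generator emulates the statistical structure the method assumes:

* **Sequences**: a two-state (GC/AT) first-order Markov chain with
  stationary GC equal to the gene's target (drawn uniformly from
  0.35–0.65) and state autocorrelation ρ = 0.2, so dinucleotide
  frequencies carry signal beyond GC alone. Up to 8 candidate sequences
  are drawn and the realized-GC-closest kept, so delivered GC tracks the
  target (±0.03 at ≥1 kb). Lengths are log-normal (median ≈ 1.5 kb,
  log-sd 0.6, clipped to 0.2–20 kb). Genes are laid out with intergenic
  spacers; optional exon-skipping isoforms and planted genomic overlaps
  exercise the SINO logic and double counting.
* **Expression**: true log expression ~ N(0, 1.5²), independent of all
  sequence covariates by construction.
* **Counts**: per gene and lane, Poisson with rate
  `depth · exp(true_log_expr) · L · B`, following the random-sampling
  model in which expected counts scale with abundance×length; the
  multiplicative bias is
  `B = exp(β_L·logL + c₁·(GC−½) + c₂·(GC−½)² + Σ_d γ_d·f_d)`. The
  canonical planted bias (β_L=−0.8, c₁=6, c₂=−15) gives a bias SD of
  ≈0.7 log units against the expression SD of 1.5 — a clearly visible
  bias of the kind the correction exists for. Optional gamma-mixed
  overdispersion, off by default.
* **Alignments**: fixed-length single-end reads whose start positions in
  exons are drawn proportionally to configurable start-dinucleotide
  weights (reference orientation, reverse-complemented for reverse
  reads); a configurable fraction is emitted as NH=2 record pairs.

What it does **not** emulate — and hence what passing tests do not show
about real data: positional bias profiles along the read beyond the
first two bases, PCR duplicates, sequencing errors and quality strings,
paired-end fragments, lane-to-lane protocol drift, and any dependence of
expression on sequence (so, e.g., the stability of the correction cannot
differ between expression strata in these simulations, whereas on real
data lowly expressed genes are reported slightly more depth-sensitive).

## Default parameters

| parameter | default | meaning |
|---|---|---|
| `threshold` | 0.95 | cumulative variance share the kept PCs must reach |
| `n_splines` | 10 | B-spline basis functions per smooth term |
| GCV γ | 1.4 | df inflation in the GCV score |
| parsimony window | 0.5% | GCV margin within which the smoothest penalty wins |
| test edf | 4 | fixed reference-smoother size in per-term F-tests |
| `bin_size` | 500 | genes per bin in trend diagnostics |
| `tolerance` | 0.05 | relative stability band in depth robustness |
| `min_positive` | 100 | minimum positive-expression units for a fit |

## Problem sizes

The seeded suites run at desk scale: 2000 genes for parameter-recovery
and no-op checks, 6000 genes × 7 lanes at ~100 reads/gene/lane (the
per-gene depth of a typical flow-cell lane) for depth robustness, 200
replicates for null calibrations, and 100 for power checks.

## Known limitations

* Each sample is corrected separately; the unequal variance of
  length-normalised counts across genes (shorter genes noisier) is not
  addressed, so differential-expression variance modelling is out of
  scope.
* Base-level positional reweighting schemes are complementary, not
  replaced; no adapter to them is provided beyond operating on their
  output expression tables.
* The GAM smooths are additive in the PC scores; bias surfaces with
  strong interactions between components are captured only through their
  additive projections.
* P-values are raw; users scanning many covariates should apply their
  own multiplicity control.
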