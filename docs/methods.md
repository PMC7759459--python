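# Methods

## Scope

`sohscan` estimates genetic-diversity summaries from the variant callset
of a *single* diploid genome assembled into a fragmented draft, and
relates such summaries to extinction risk across a species panel. Its
pieces are:

1. site- and scaffold-level QC filters for genotype calls,
2. overall heterozygosity (het calls per callable bp),
3. the segments-of-homozygosity (SoH) estimator — a windowed mixture
   model usable when scaffolds are shorter than runs of homozygosity,
4. cross-species panel statistics (IUCN ordinal regression,
   wild/captive comparison, phenotype screen),
5. a Poisson model of chance-invariant alignment columns, and
6. simulators for diploid variant landscapes and species panels with
   known ground truth.

## Genotype and scaffold QC

High-confidence heterozygous sites are calls with genotype `het`,
GQ > 20 and 6 < DP < 100, all bounds strict; records missing GQ or DP
are dropped and tallied. The callable genome is the merged union of
positions with genotype quality above 15. When quality arrives as gVCF
bands (0/10/20/30/40/50/99) the >15 rule means band ≥ 20 is callable —
the threshold falls between the 10 and 20 bands, so no finer decision
is needed.

Scaffolds are analysed only if longer than 10 kb (strict) and if their
mean depth lies within [0.5×, 2×] of the genome-wide average depth
(inclusive); the average is length-weighted over the input scaffolds so
that it matches an average over mapped coverage. This removes sex
chromosomes and collapsed repeats without needing chromosome labels.

Overall heterozygosity is `n_het_sites / callable_bp` on the
depth-filtered scaffolds. Allelic balance is defined per site as
`|ref_reads − alt_reads| / (ref_reads + alt_reads)` and averaged
unweighted over high-confidence het sites: it is symmetric, bounded in
[0, 1], and 0 for perfectly balanced read support. Under unbiased
sampling at depth ~40 its expectation is ≈ 0.126 (half-normal mean of
the binomial imbalance), so panel values approaching 0.36 indicate
systematic bias. Sites whose AD sums to zero are skipped; a panel mean
over zero usable sites is an error, not a silent 0.

## SoH: windowed mixture with a zero-truncated component

ROH in inbred populations can exceed the scaffold N50 of a short-read
draft, so run-based callers cannot see them. SoH instead works at the
window level:

* **Windowing.** Scaffolds ≥ 50 kb are cut into ⌈L/50 kb⌉ equal windows
  (integer boundaries; the last window absorbs the remainder — for
  L ≥ 50 kb the equal split always stays above 25 kb). Scaffolds of
  20–50 kb form a single window; shorter scaffolds are skipped. The
  equal-split rule keeps every window inside the 20–50 kb range with no
  tiny remainder windows.
* **Window rate.** h_w = het sites / callable bp in the window (plain
  window length if no mask is given). Windows with under half their
  length callable are dropped, with a logged count.
* **Mixture.** The h_w values enter as unweighted observations of the
  density `w1·f1 + (1−w1)·f2` on x ≥ 0. f2 is a free normal. f1 is a
  normal *renormalized on [0, ∞)* by `1/(1 − Φ(−μ1/σ1))`: window
  heterozygosity cannot be negative, and without the correction a
  component hugging zero leaks probability mass below it and its
  posteriors are miscalibrated. μ1 may legitimately fit negative, in
  which case f1 is a monotone decreasing density hugging zero — the
  natural shape when ROH windows carry (almost) no residual
  heterozygosity.
* **EM.** Responsibilities use the truncated f1 density. The M-step is
  exact for w1 and component 2; for the truncated component the
  weighted truncated-normal likelihood is maximized numerically
  (Nelder–Mead on (μ, log σ), warm-started at the weighted moments, and
  the best of {previous parameters, moment update, optimizer result} is
  kept). The moment update alone is *not* a valid M-step once the
  truncation correction is in the E-step density, and measurably
  produced decreasing log-likelihoods; the candidate-max construction
  makes the procedure a generalized EM, so the log-likelihood is
  non-decreasing by construction (asserted per iteration in the tests).
  Initialization: μ1 = mean of the lowest decile of h, μ2 = median,
  both σ = pooled s.d., w1 = 0.25; μ1 ≤ μ2 is enforced each iteration
  by component swap. Convergence: relative log-likelihood change
  < 1e−8 (cap 1000 iterations; non-convergence is reported, not
  raised). σ is floored at 1e−8 to survive an exact zero-spike of h.
  Optional restarts jitter the initial means from a seeded generator
  and keep the best log-likelihood.
* **Classification and SoH.** Each window goes to the component with
  the larger posterior; SoH = summed length of low-component windows /
  summed length of all windows. The denominator is the *windowed*
  genome (scaffolds ≥ 20 kb after depth QC), not the full callable
  genome — the quantity is a property of the territory the model
  actually saw.
* **Degenerate outcomes.** SoH is reported undefined (never 0) when the
  components overlap — overlap coefficient `OVL = ∫ min(f1, f2) dx`
  of the *normalized* densities > 0.9 — when w1 < 1e−3, or when every
  window lands in one component. OVL is 1 for coinciding components
  and is evaluated on a 20 001-point grid over [0, max(μ + 8σ)].
  A weighted variant of the overlap integral was considered and
  rejected: it is bounded by min(w1, 1−w1) ≤ 0.5 and can never signal
  complete overlap. Zero-het windows receive no special handling
  before the fit; they are simply observations at 0.

**Known bias.** A window straddling an ROH boundary carries enough
heterozygosity from its non-ROH side to classify high, so SoH is biased
low by approximately `window_len · f_roh / mean_roh_len` (first order).
With 40 kb windows this is ~1% for megabase ROH at moderate f_roh, but
grows to ~5% when mean ROH length falls toward 10× the window — the
estimator assumes ROH ≫ window, and the simulations bear the formula
out.

## Cross-species panel statistics

QC exclusions run sequentially: genomes with heterozygosity > 0.02 are
removed first (assembly/contamination artifacts); then genomes with
allelic balance strictly above mean + 1 s.d., with mean and s.d.
computed on the post-het-rule panel (sample s.d., ddof = 1). The
allelic-balance cut is a *fixed panel-level threshold*: it is derived
once and recorded in the exclusion report, and re-applying the rules
with the recorded threshold is a no-op. Recomputing it on its own
output would ratchet (each pass shrinks the spread and moves the
threshold down), which is not the intended semantics of a one-shot
panel QC.

IUCN categories are coded ordinally LC=0, NT=1, VU=2, EN=3, CR=4; DD
and EW records are excluded and counted. The regression is OLS of the
metric on the integer rank, reporting slope, R², and the two-sided
slope t-test p-value. Linear integer coding is the conventional reading
of an ordinal predictor in a linear model; alternative strictly
increasing codings would change R²/p, which is why the coding is fixed
and documented. A constant metric returns slope 0, R² 0, p 1 rather
than NaN.

The wild/captive comparison is a two-sided pooled-variance
independent-samples t-test (Welch behind a flag). The phenotype screen
computes pairwise-complete Pearson r and two-sided p per (phenotype,
metric) pair, restricted by default to least-concern species, with a
Bonferroni threshold α/m, m = #phenotypes × #metrics (configurable, 42
for the default 21 phenotypes × 2 metrics); rows with fewer than 3
complete pairs are emitted with r undefined.

## Simulators

### Diploid genome

Scaffold lengths are log-normal, parameterized by arithmetic mean/s.d.
(defaults 55 kb / 45 kb, giving N50 in the 40–110 kb range typical of
short-read drafts). ROH are laid down per scaffold by an alternating
two-state renewal process with exponential segment lengths; the
non-ROH mean defaults to `mean_roh_len · (1 − f_roh) / f_roh` so the
stationary ROH fraction equals the target f_roh (the start state is
drawn at the stationary probability). Heterozygous sites are a Poisson
process at rate `theta_out` outside ROH and `theta_in` inside
(duplicate positions are collapsed; the collision rate at these
densities is negligible). Each site draws DP ~ Poisson(scaffold depth),
alternate reads ~ Binomial(DP, ab_bias), and a banded GQ. Quality
failure is block-wise: 1 kb tiles fail independently at `gq_fail_rate`,
failed tiles leave the callable mask, and sites inside them get a
failing band (0/10) while the rest draw 30/50/40/99 — mimicking locally
bad mapping rather than salt-and-pepper noise. Scaffold mean depths
vary with c.v. 0.1 so the depth filter has (rare) work on default
draws.

Defaults describe a least-concern mammal on a ~40× short-read draft:
`theta_out` 2.6e−3 (a typical LC median heterozygosity), `f_roh` 0.171
(a typical LC median SoH), `mean_roh_len` 500 kb, `theta_in` 5% of
`theta_out` (residual within-ROH heterozygosity is poorly constrained
empirically; 5% keeps ROH windows clearly separated without being
exactly zero), depth 40×, `gq_fail_rate` 0.05 (≈95% callable).
Everything is reproducible from one integer seed through a single named
generator; no global state.

What it does **not** emulate: read-level errors and mapping (no FASTQ),
coalescent correlation structure of ROH (segments are memoryless —
no ROH length model is imposed beyond a tunable mean), selection,
sequence content, or genotype-caller pathologies beyond the banded-GQ
failure model. Passing tests therefore demonstrate the estimator's
behavior under a clean Poisson/renewal landscape, not robustness to
caller-specific artifacts.

### Species panel

Per species with IUCN rank r: heterozygosity
`H = baseline_het · exp(−beta_het · r + ε)`, ε ~ N(0, 0.35²), and
`SoH = baseline_soh + beta_soh · r + ε′` clipped to [0, 1],
ε′ ~ N(0, 0.1²). Defaults: category counts (75, 4, 12, 9, 5) — a
105-species panel dominated by least concern; baseline_het 0.0026;
beta_het 0.10 per rank; baseline_soh 0.171; beta_soh 0.04 per rank.
A contaminated 15% of species draws allelic balance ~ N(0.45, 0.06)
(clean: N(0.22, 0.07)), ~1.5% draw artifact heterozygosity > 0.02, and
7% of SoH values are set undefined (the mixture-overlap failure mode);
callable percentage co-varies negatively with heterozygosity, making
the confounder check meaningful. Birth population is captive with
probability 0.5. The 21 phenotype columns carry PanTHERIA-style names
and are drawn *independently* of the diversity metrics (log-normal,
with 10% missing) — the screen's null is true by construction.

Because heterozygosity and SoH noise terms are independent given rank,
their cross-correlation in simulated panels is much weaker than in real
data, where both are driven by the same demographic history; the panel
generator validates the statistical machinery, not the empirical
effect sizes.

## Poisson constraint-power model

A single homogeneous rate per site: the chance a site is invariant
across the whole tree is `e^(−L)`, and `G · e^(−L)` positions are
expected invariant by chance in a genome of G bp. A per-site rate
vector is accepted, in which case the mean of `e^(−L_i)` is used. The
inverse, `L = ln(G/target)`, answers alignment-design questions
("how much branch length until only one chance-invariant site
remains?") and round-trips with the forward model to 1e−6 relative.
The within-species analogue (expected fraction of positions with no
variation in a cohort) is the same `e^(−λ)` with a user-supplied λ; no
attempt is made to derive λ from cohort size here.

## Problem sizes and numerical conventions

Tests and the acceptance script run on ~30 Mb simulated genomes
(600 scaffolds, ~850 windows) and 105-species panels — large enough
that Poisson/CLT tolerances (3 s.d.) are tight, small enough to be
rerun casually. Interval arithmetic is 0-based half-open everywhere
inside the package; VCF's 1-based positions are converted exactly once
at the I/O boundary. Statistical routines delegate to scipy
(`linregress`, `ttest_ind`, `pearsonr`); the mixture EM, window logic
and simulators are implemented here and cross-checked in the test
suite against closed-form oracles, permutation nulls, Monte-Carlo
zero-class counts and (where the truncation is inert) scikit-learn's
Gaussian mixture.

## Limitations

* SoH is undefined, by design, when the two mixture components overlap;
  on real panels a few percent of genomes end up without an SoH value.
* The boundary-window bias above means SoH slightly underestimates the
  ROH fraction when ROH length approaches the window scale.
* Single-genome metrics say nothing about population structure or
  recent demography; they are a triage signal, not a substitute for
  population sampling.
* The panel regressions are non-phylogenetic (no independent
  contrasts); shared ancestry among species is not modelled.
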