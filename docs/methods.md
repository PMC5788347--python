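# Methods

This note documents the models behind `scqpcr`: what the simulator
generates, what each quantification step assumes, the numerical and design
choices made where the problem was genuinely open, and what the test suite
does and does not demonstrate about real instrument data.

## The chip's data-generating process, as simulated

A run is `n_subarrays × units_per_subarray` cell-processing units, each
read out in `chambers_per_unit = 20` detection chambers over 40 qPCR
cycles. The simulator models five stages per unit:

1. **Template capture.** For purified-RNA runs, per-unit molecule counts
   are Poisson with a mean set per subarray (a dilution series loads one
   concentration per linear array). For cell runs, each cell's per-gene
   rate is lognormal with the panel's coefficient of variation, made
   dependent across genes by a Gaussian copula with the panel's correlation
   matrix; bimodal genes (e.g. a miRNA silenced in a subpopulation) are
   switched off per cell by a Bernoulli indicator; counts are Poisson
   around the rate. Traps marked `debris`/`empty` carry no template.
2. **Reverse transcription** is binomial thinning with `rt_efficiency`.
3. **Pre-amplification** is a Galton–Watson branching process: each
   molecule independently duplicates per cycle with probability
   `preamp_per_cycle_efficiency`, for 7 (two-step miRNA) or 12 (one-step
   mRNA) cycles. This preserves the single-molecule variance structure
   that deterministic scaling would erase; a deterministic mode
   (`deterministic_preamp=True`) exists for speed.
4. **Splitting.** Every post-amplification molecule lands in chamber *j*
   with probability `split_fraction_per_chamber`; the remainder stays in
   the pre-amplification chamber and is discarded. Conservation holds by
   construction. The default fraction is the volumetric ratio
   0.15 nL / 50 nL = 0.003 per chamber (6% metered in total); a 1%-per-
   chamber variant (~20% total) is selectable. The volumes are the only
   bit-exact geometry available, so the volumetric value is the default.
5. **Detection qPCR.** Each chamber yields
   `f(c) = (baseline + plateau·σ((c − c_mid)/w))·(1 + ε_c)`,
   ε_c ~ N(0, noise_sd²), a four-parameter logistic with multiplicative
   noise. The midpoint is `c_mid = c_ref − log(t)/log(1 + e)` for template
   count `t ≥ 1` and per-cycle detection efficiency
   `e = qpcr_per_cycle_efficiency`; at `e = 1` the midpoint advances
   exactly −1 cycle per template doubling, and `c_ref` anchors the CT of a
   single template molecule (default 21.5). Empty chambers are flat
   baseline. The trace shape itself is a modelling convenience — only the
   induced CT values matter downstream, and the −1-cycle-per-doubling
   contract is the tested property. `qpcr_per_cycle_efficiency` extends
   the pure-doubling model so that standard-curve efficiency estimation is
   a genuine parameter-recovery problem (fitted efficiency ≈ 100·e).

**Randomness.** One root seed (`ChipConfig.seed`); `SeedSequence(seed)` is
spawned into `n_units + 1` children — child 0 drives truth generation,
child *i*+1 drives unit *i*'s RT, pre-amplification, splitting, and trace
noise in chamber order. Identical config ⇒ bit-identical runs.

**Defaults that are not instrument calibrations.** RT efficiency 0.5 and
pre-amplification per-cycle efficiency 0.9 are plausible mid-range values
for enzymatic conversion and early-cycle PCR, chosen once for the
simulator; they are not measured properties of any device.

## CT calling

* Baseline window: cycles 3–10 (1-based, inclusive), skipping cycle-1/2
  optical settling; overridable per run because heavily pre-amplified
  samples can cross as early as CT ≈ 9.5. Correction subtracts the window
  mean and is idempotent.
* One chip-wide threshold, as on the instrument display. The automatic
  rule — 10 × the median baseline SD, clipped below the 10th percentile of
  positive-trace plateaus — is a deterministic, scale-equivariant stand-in
  for the original (unpublished) instrument heuristic. A chip with no
  amplification anywhere is an error, not a threshold.
* CT is the first *sustained* crossing (the next cycle must also exceed
  threshold; the final cycle needs no confirmation), linearly interpolated
  between the bracketing cycles. Single-cycle spikes are rejected. Calls
  are restricted to cycles after the baseline window.
* Because the chip-wide threshold generally sits below the half-plateau
  level, absolute CTs carry a common offset relative to the sigmoid
  midpoint. This is immaterial: every downstream quantity (cutoff, copy
  number) is anchored to the measured single-molecule CT, so only CT
  differences enter.

## Quantification

* **Single-molecule cutoff**: mean + z·SD (sample SD, n−1) of CTs from
  units detected in *all* chambers; z = 2.5758 = Φ⁻¹(0.995) captures 99%
  of the fitted normal two-sidedly. `preamp_cycle_offset` shifts the
  cutoff between workflows that differ in pre-amplification depth (+5
  cycles from a 12-cycle to a 7-cycle workflow: 2⁵ ≈ the gain ratio).
* **Positivity**: strictly more than 75% of chambers strictly below the
  cutoff — with 20 chambers, ≥ 16 positive, 15 is negative. Both
  inequalities are strict by specification of the rule.
* **Digital estimate**: λ̂ = −ln(1 − k/N); the 95% CI is a Wilson score
  interval on k/N (Clopper–Pearson optional) mapped through
  p ↦ −N·ln(1 − p). The mapping is monotone, so interval endpoints map to
  interval endpoints. k = N is flagged saturated: the point estimate is
  unbounded and only the lower CI limit is meaningful.
* **Copy numbers**: copies = 2^(CT_ref − CT); `UNDETECTED` ⇒ 0 copies.
  The reference defaults to the *mean* single-molecule CT (the expected CT
  of one molecule), not the 99% tail bound; both are exposed. Note a
  small upward bias intrinsic to mean-CT anchoring: E[log t] < log E[t]
  (Jensen), and the inequality bites harder for one-molecule units (high
  branching/splitting CV) than for abundant templates, so copy numbers
  anchored on an *empirically estimated* single-molecule mean CT run
  ~5–10% high at the defaults. The recovery tests anchor the reference
  analytically (through the same deterministic gain and split) to measure
  the pipeline's own error without this estimation bias.
* **Standard curve**: WLS of CT on log₁₀(concentration), one weight per
  concentration equal to 1/SD of its replicate CTs (weights multiply
  squared residuals, the R `lm` convention). A zero-SD group's weight is
  capped at 10 × the largest finite weight (all weights equal, i.e. OLS,
  when every group is degenerate). Efficiency = 100 × (10^(−1/slope) − 1):
  the only reading of the efficiency formula consistent with a
  perfect-doubling slope of −3.3219 mapping to 100%. The SE range is the
  efficiency evaluated at slope ± SE(slope).
* **Precision**: 100 × SD/mean (n−1 SD). CT noise of SD s cycles maps to
  a copy-number CV of √(exp((s·ln2)²) − 1); s = 0.22 gives ≈ 15.3%.
* **Variance partition**: per-unit SDs over detected chambers versus
  pooled per-array SDs, compared with a Wilcoxon rank-sum test. At
  limiting dilution the 20 chambers of a unit share one template while
  units differ by Poisson sampling, so within-unit SDs sit far below the
  array SD; with abundant template the two coincide. Power requires more
  than one array-level SD (several subarrays or replicate runs).

## Expression statistics

* **Detection**: a gene is detected in a cell iff *every* replicate
  chamber is below the cutoff; under independent chamber false positives
  at rate q the per-cell false detection rate is q^replicates.
* **Differential expression**: two-sided Mann–Whitney/Wilcoxon rank-sum
  per gene with tie correction (exact null for small untied samples), BH
  adjustment across genes, flags at adjusted p < 0.01. A gene constant
  across both groups is all ties: p = 1.
* **Clustering**: distance (1 − Pearson r)/2 between cells' log₁₀(x+1)
  profiles (pseudocount 1, since "log-scaled" leaves zeros undefined);
  Ward linkage on the precomputed dissimilarities (the ward.D2
  construction); labels from the k = 2 cut. A zero-variance cell has
  undefined correlations; its distances are set to the maximum 1 with a
  warning.
* **Co-expression**: Spearman rho on copies within each population (cells
  as observations; average ranks for ties). Significance from a
  permutation null — one gene's vector permuted across cells, which breaks
  the pairing while preserving both marginals — with a two-sided,
  +1-smoothed p-value (hence exactly super-uniform under the null) and BH
  across all assessable pairs of the analysis. 10,000 permutations by
  default; fewer than 100 is refused as the p-resolution becomes coarser
  than any usable threshold. Pairs where either gene is undetected in all
  cells of a population are reported non-assessable (rho = NA) and
  excluded from the adjustment.
* **Pooled vs grouped**: the same machinery applied to the pooled cells
  and to each population, with a sign-reversal flag when both group rhos
  share a sign opposite to the pooled rho — Simpson's paradox. Whether
  the pooled null should permute across all cells or within populations is
  ambiguous; both schemes are exposed (`scheme="pooled"` default,
  `"within"` preserves between-population structure under the null).

## What the synthetic data does and does not show

The generator reproduces the statistical skeleton the analysis relies on:
Poisson partitioning, binomial RT loss, branching-process amplification
noise, multinomial splitting, −1 cycle per template doubling, lognormal
cell-to-cell heterogeneity with copula correlation and bimodal
subpopulations. The two-population generator used in tests spans ~2.5
decades of base abundance and shifts marker genes *reciprocally* (some up,
some strongly down), emulating the mutually biased marker expression of two
distinct cell types; clustering-recovery results are conditional on that
separation structure. Not modelled: optical crosstalk and image
segmentation error, inhibition and chemistry failures, variable RT
efficiency across templates, chamber-to-chamber volume variation, or
contamination between units. Passing tests therefore validate the
*analysis*, not the instrument.

## Problem sizes and tolerances in the test suite

Simulated chips in tests use 8–52 units per subarray and 1–3 replicate
runs — large enough for the asymptotics each check relies on while keeping
the whole suite fast. Parameter-recovery margins: per-cycle efficiency
within ±5 points over e ∈ {0.8, 0.9, 1.0}; median copy-number relative
error < 10% at 64 molecules over 500 units; clustering agreement ≥ 95%;
co-expression FDR ≤ 1% over 10 null datasets of 45 pairs (5,000
permutations each, so BH's rank-1 threshold is reachable); Simpson
reversal in ≥ 95% of 20 seeded runs. Numerical details: sample SD uses
n−1 throughout; the digital estimator is checked against a bounded
golden-section ML oracle to |Δλ| < 10⁻⁶; permutation comparisons use an
absolute-value tolerance of 10⁻¹² to avoid float-tie artefacts; the CT
interpolation is exact for a logistic crossed at half-plateau midway
between cycles and otherwise accurate to ~10⁻³ cycles.

## Known limitations

* The automatic threshold is a stand-in; real runs with curated thresholds
  should pass `threshold=` explicitly.
* Copy numbers inherit the Jensen bias of mean-CT anchoring described
  above, and say nothing about absolute RNA→cDNA conversion efficiency,
  which the pipeline deliberately does not model.
* Digital CIs are binomial intervals mapped through the Poisson link, not
  a bespoke construction; near saturation (k = N − 1, N) they are wide and
  asymmetric, and at k = N only the lower limit is reported as meaningful.
* The rank-sum test's exact small-sample null is used only when samples
  are small and untied (scipy's switching rule); heavily tied data fall
  back to the corrected normal approximation.
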