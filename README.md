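# scqpcr

Quantification and population statistics for **highly multiplexed single-cell
RT-qPCR chips**, together with a stochastic simulator of the chip's
data-generating process.

The device this package analyses captures single cells in four linear
subarrays of cell-processing units. Each unit takes one cell through lysis,
reverse transcription (10 nL), low-cycle multiplexed pre-amplification
(50 nL, 7 cycles for miRNA or 12 for mRNA panels), metering into twenty
0.15-nL splitting chambers, and twenty independent 6.4-nL qPCR detection
chambers imaged over 40 thermal cycles. A full run is 4,000 qPCR reactions.
The package is for anyone analysing such runs — or validating analysis code
for them — starting from per-chamber fluorescence traces or pre-called CT
tables; the simulator makes every downstream stage testable against known
ground truth without any instrument data.

## What it computes

* **CT calling** — baseline subtraction over an early-cycle window, then the
  first sustained, linearly interpolated crossing of a single chip-wide
  threshold; chambers that never cross within 40 cycles are `UNDETECTED`.
* **Single-molecule cutoff** — from units that amplified in *all* twenty
  chambers, CT<sub>cutoff</sub> = mean + z·SD with z = Φ⁻¹(0.995) = 2.5758,
  capturing 99% of the single-molecule CT distribution. A unit is a positive
  single-molecule event when more than 75% of its chambers (≥ 16 of 20) fall
  strictly below the cutoff.
* **Digital estimation** — the digital response curve for an N-chamber
  array: λ̂ = −ln(1 − k/N) per unit and N·λ̂ molecules total, with a 95%
  binomial CI (Wilson score) mapped through the same transform.
* **Copy numbers** — copies = 2^(CT<sub>single&nbsp;molecule</sub> − CT),
  with a pre-amplification cycle offset when a cutoff derived under one
  workflow is applied to another (e.g. +5 cycles from 12-cycle mRNA to
  7-cycle miRNA pre-amplification).
* **Standard curves** — weighted least squares of CT on log₁₀ concentration
  with 1/SD weights per concentration; efficiency
  = 100 × (10^(−1/slope) − 1), so a perfect-doubling slope of −3.32 is 100%.
* **Precision** — the coefficient of variation 100 × σ/μ of copy-number
  measurements, and a within- versus between-unit variance partition that
  attributes low-concentration scatter to Poisson template sampling.
* **Expression statistics** — all-replicate detection calls, Wilcoxon
  rank-sum differential expression with Benjamini–Hochberg control (FDR
  0.01), hierarchical clustering of cells on a (1 − Pearson r)/2 distance of
  log-scaled profiles with Ward linkage, permutation-calibrated Spearman
  co-expression within populations, and a pooled-versus-grouped comparison
  that flags Simpson's-paradox sign reversals.

## Worked example: counting molecules at limiting dilution

Simulate a prototype chip (4 × 52 units) loaded with a dilution series of
purified template, call CTs, estimate the single-molecule cutoff from
fully-detected units, and convert positive-unit counts into molecules:

```python
import numpy as np
from scqpcr import (ChipConfig, simulate_chip_run, call_run, CTMatrix,
                    single_molecule_cutoff, classify_units, digital_estimate)

cfg = ChipConfig(units_per_subarray=52, preamp_cycles=12,
                 rt_efficiency=1.0, seed=42)
run = simulate_chip_run(cfg,
                        molecules_per_unit_mean=np.array([1.0, 0.5, 0.25, 0.06]),
                        noise_sd=0.01, c_ref=26.0)
ctm = CTMatrix.from_long(call_run(run))
cutoff = single_molecule_cutoff(ctm.fully_detected_cts())
print(f"single-molecule CT: mean {cutoff.mean_ct:.2f}, SD {cutoff.sd_ct:.2f}; "
      f"cutoff (99%) = {cutoff.cutoff_ct:.1f}  [n = {cutoff.n} chamber CTs]")
positive = classify_units(ctm, cutoff)
for sa in (1, 2, 3, 4):
    m = ctm.subarray == sa
    est = digital_estimate(int(positive[m].sum()), int(m.sum()))
    true = run.truth.counts[m.nonzero()[0], 0].sum()
    print(f"subarray {sa}: {est.k:>2}/{est.n} units positive -> "
          f"{est.total_molecules:5.1f} molecules "
          f"(95% CI {est.ci95[0]:.1f}-{est.ci95[1]:.1f}); true count {true}")
```

prints

```
single-molecule CT: mean 17.35, SD 0.89; cutoff (99%) = 19.6  [n = 1380 chamber CTs]
subarray 1: 32/52 units positive ->  49.7 molecules (95% CI 34.0-69.1); true count 51
subarray 2: 26/52 units positive ->  36.0 molecules (95% CI 23.9-51.9); true count 37
subarray 3: 11/52 units positive ->  12.4 molecules (95% CI 6.8-21.6); true count 11
subarray 4:  4/52 units positive ->   4.2 molecules (95% CI 1.6-10.4); true count 4
```

Each subarray's digital estimate brackets the simulator's true molecule
count; the absolute CT level depends on the chip-wide threshold, but every
downstream quantity is anchored to the *measured* single-molecule CT, so
only CT differences matter.

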