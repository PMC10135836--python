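# Methods

## The measurement and the statistic

Each egg carries four electrodes: 1 and 2 at the broad and narrow ends
(height axis), 3 and 4 diametrically opposite on the width
circumference. An impedance analyzer sweeps 20 Hz–10 MHz at 100 mV rms,
100 points, 80 ms per point, recording |Z| per electrode pair per
incubation day (day 0 is the pre-incubation baseline; the statistical
analysis uses days 1–13). The sweep grid is taken as logarithmically
spaced — the natural choice for a 6-decade sweep — with exact 20 Hz and
10 MHz endpoints; linearly spaced grids remain loadable because
`read_sweeps` can infer any strictly increasing grid from the data.
|Z| magnitude is the analyzed quantity throughout; phase is carried in
the data model but unused.

The discriminative statistic is the within-egg, within-session ratio
`r = |Z|_{2-3} / |Z|_{2-4}`. Any multiplicative factor common to both
pairs — egg size, shell thickness, cabling, analyzer gain — cancels, so
the ratio is comparable across eggs without any cross-day baseline
division. Orientation is fixed (2–3 over 2–4; male ratios > 1); the
reciprocal orientation is accepted by the tools but flips the
classifier's sign convention, so the default is used everywhere.
(Egg, day) combinations missing one of the two pairs are dropped and
reported, never imputed.

## Electrode QC

The carbon-epoxy electrode is modeled as a resistive film plus a cloth
contact: `R = rho*l/A + r_contact/A`. With the nominal rho = 40 Ohm*cm,
A = 1 cm^2 and r_contact = 0.05 Ohm, a film thickness of l = 0.05 cm
gives the published 2.05 Ohm total. Geometrically, a 40 uL drop over
1 cm^2 is 0.04 cm thick and gives 1.65 Ohm; the 2.05 Ohm value is only
consistent with l = 0.05 cm. The default spec uses 0.05 cm to match the
published figure and both are plain parameters, so the discrepancy is
visible rather than hidden.

Electrode stability is judged by the relative standard deviation of |Z|
across repeat sweeps of the same egg/pair: pass iff RSD < 5% at every
grid point ≥ 100 Hz. Below 100 Hz electrode polarization dominates and
the band is excluded from the criterion. All SDs in the package use the
sample (n−1) denominator.

## The scan

Per (day, frequency) cell, male vs female ratios are compared with an
independent two-sample t-test. The default is **Welch, two-tailed**:
recomputing the published per-day p-values from the published group
means/SDs (n = 8 + 8) matches a Welch two-tailed test within ~3%
relative on 12 of the 13 days, which pins the variant. The exception is
day 9, whose published p = 0.006125 is not reproducible from the
published day-9 summaries under any two-tailed variant (Welch and
pooled both give ≈ 0.013; one-tailed Welch gives ≈ 0.0066 — plausibly a
one-tailed value slipped into a two-tailed column). The package
reproduces the other days and treats the printed day-9 p as
unverifiable; it is excluded from exact checks. Pooled-variance and
one-tailed tests are selectable. Degenerate zero-variance cells return
p = 1 with a warning instead of aborting the scan.

Persistence: a frequency discriminates from day *d* onward iff p < α at
that same grid point on **every** day from *d* through the final day
(13). The onset day is the smallest such *d* over all frequencies; the
band is the longest contiguous grid-index run of frequencies persisting
from that onset (ties toward lower frequency), and the best frequency
minimizes p on the onset day within the band (ties toward lower
frequency). No multiple-testing correction is applied by default — the
per-cell α = 0.05 with the persistence rule as the implicit guard
mirrors how the discriminative window was originally identified; a
Bonferroni flag exists for sensitivity analysis. Under a null
simulation the per-cell rejection rate is ≈ α (checked by test).

`t_test_raw` delegates to `scipy.stats.ttest_ind`; `t_test_summary`
implements the Welch/pooled formulas directly from (mean, SD, n). The
two agree to 1e−12 on random data (tested), and the summary route is
what reproduces published tables where only summaries survive.

## The classifier

In the discriminative window, male ratios sit above 1 and female below,
with overlap. `classify_egg` thresholds the ratio at one grid frequency
(default: day 9, the grid point log-nearest 376 kHz, threshold 1.0). A
ratio exactly at the threshold — or within an optional ± margin — is
*indeterminate*, not forced into a class; indeterminates are excluded
from accuracy denominators and counted separately. A band-average
variant (mean ratio over 376 kHz–2.79 MHz) is available, since the
ratio is stable across that band. Under normal group models the
sensitivities have the closed form Phi((mu_m − thr)/sd_m) and
Phi((thr − mu_f)/sd_f); at the calibrated day-9 parameters these are
0.861 (male) and 0.646 (female), balanced 0.754 — per-egg accuracy
claims in this package are simulation-based, from these calibrated
distributions, not measured-cohort results.

## PCR ground truth

The reference method amplifies the CHD locus: a single 552 bp gel band
is male (ZZ), 358 + 552 bp is female (ZW). Band matching uses a ±15 bp
tolerance (gel size estimates are approximate; configurable). A
bandless record is *unknown* unless a survival flag marks the egg
unfertilized. The embedded 17-egg reference survey tallies 8 male,
8 female, 1 unfertilized.

## The synthetic generator

The generator produces what the analysis assumes about real eggs, so
the full pipeline is testable without raw data.

* **Carrier spectrum** — a Cole dispersion
  `Z = R_inf + (R0 − R_inf)/(1 + (i 2 pi f tau)^alpha)` with defaults
  R0 = 10 kOhm, R_inf = 200 Ohm, tau = 1 us, alpha = 0.85: a falling
  |Z| with the dispersion inside the sweep range, qualitatively like
  measured egg spectra. No published circuit values exist, so these are
  illustrative, not fitted, and nothing downstream depends on them (the
  ratio statistic cancels the carrier).
* **Noise** — multiplicative log-normal, independent per frequency, SD
  0.05 below 200 kHz and 0.005 above: the shell blocks low-frequency
  current, so measured spectra are visibly noisier below ~200 kHz.
  An optional AR(1)-in-log-frequency correlation was considered and
  rejected as invented precision; independence is a stated
  simplification.
* **Sex effect** — injected at the ratio level, the only level with a
  published quantitative calibration (the day-9 group statistics: male
  1.122262 ± 0.112674, female 0.953107 ± 0.124892). Each egg draws
  **one** effect ratio from its group's distribution, applied to the
  2–3 trace at in-band frequencies from the onset day (9) onward; the
  2–3 trace is the 2–4 base curve times this target, so the noise-free
  ratio equals the target exactly (the 2–3 entry of `pair_gain` is
  therefore inert by construction). Outside the band and before onset,
  a per-(egg, day) baseline ratio ~ Normal(1, 0.12) applies — 0.12
  matches the published pre-onset dispersions (0.07–0.18). Draws are
  truncated to [0.5, 2] as a guard (log-warned; unreachable at the
  defaults).
* **Reproducibility** — one `SeedSequence(seed, spawn_key=(egg,))`
  substream per egg; identical seeds give bit-identical cohorts.

What the generator does **not** emulate: day-to-day within-egg ratio
correlation before onset, frequency-smooth noise, electrode drift or
failures, sex effects outside the planted band (the real pre-onset male
means sit slightly above 1 on every day — the generator plants an exact
null there). Passing tests therefore demonstrate the pipeline's
correctness and calibration under its stated assumptions, not field
accuracy on real eggs.

## Statistical power and the recovery experiment

At the calibrated day-9 effect (difference 0.169, SDs 0.113/0.125,
n = 8 + 8, Welch two-tailed, α = 0.05) the exact noncentral-t power is
**0.753** (noncentrality 2.844, df 13.85). Because each egg's effect
draw is shared across days 9–13 and across in-band frequencies,
per-cohort detection is essentially one draw of that test, so the
probability that a seeded 8+8 cohort yields onset day 9 with an
overlapping band is bounded near 0.75 — measured at 75/100 seeds. A
≥95% recovery rate is not attainable at the reference cohort size; it
would require roughly n ≈ 16 per group (power 0.97). The recovery test
asserts the 95% level and is expected to fail, deliberately: it
documents that the published single-cohort discovery sits in a
power regime where one cohort in four would have missed the window.

## Problem sizes and numerical choices

Simulation-based checks use: 100 seeded 8+8 cohorts for band recovery,
2,000 replicates for type-I calibration, 2,000 sampled permutations per
dataset for the permutation cross-check, a 10,000-egg day-9 cohort for
classifier convergence (tolerance 0.02), and 60 cohorts for generator
calibration — sizes at which Monte-Carlo error is well below each
test's tolerance. Frequency matching uses log-space nearest-neighbor
with ties toward the lower index; note the grid point log-nearest the
nominal 376 kHz is 363.8 kHz, which lies just *below* a band starting
exactly at 376 kHz — synthetic-cohort classification therefore
evaluates at an interior band point (1 MHz). p-values are floored at
the smallest positive float so they stay in (0, 1] even for infinite t.
CSV floats are written at shortest round-tripping precision and parsed
with round-trip parsing, making write→read bit-exact.
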