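# Methods

This note records the statistical model behind each stage, the defaults and
why they were chosen, what the synthetic-data generator does and does not
emulate, and the numerical conventions a maintainer needs to know.

## Variability and aVMP selection

Per-probe variability at each sample is the squared deviation from the local
mean, `σ²_l = (β_l − ⟨β⟩_l)²`, where `⟨β⟩_l` averages all samples whose age
lies within ±5 years (inclusive) of the sample's own age — a centered
10-year sliding window evaluated at every sample, with truncated (never
padded) edge windows. The window always contains the sample itself, so it is
never empty. σ² is regressed on age by OLS and the two-sided slope t-test is
the "age dependence" test everywhere in the package; p-values are
Benjamini–Hochberg adjusted within each (dataset, sex) stratum over all
probes entering that test. aVMPs require adjusted p < 0.001 in the
cross-sectional cohort **and** p < 0.05 in the longitudinal cohort (the
looser longitudinal threshold compensates its narrower age span). Sexes are
analysed separately; a probe's aVMP status is per-sex.

## Signal-to-noise ratios

* **Trajectories.** Individuals with ≥ 3 measurements at distinct ages are
  fitted by OLS in age; `SNR_z` is the mean of fitted-value/|residual|
  ratios along the trajectory, and the probe statistic is the unweighted
  mean over eligible individuals (visit counts do not weight the average).
  Two points would fit exactly and make the statistic degenerate, hence the
  three-point rule.
* **Twin pairs.** Only same-sex pairs are used. Visit schedules are
  synchronized: where one twin lacks a measurement at the other's visit age,
  its value is linearly interpolated from the two bracketing visits when the
  age lies strictly inside its observed span; no extrapolation. Pairs need
  ≥ 2 synchronized points. Per point the signal is the twin mean and the
  deviation half the absolute difference.
* **Clouds.** All points pooled, signal = 10-year window mean, deviation =
  |β − window mean|.

Deviations below `epsilon = 1e−8` are excluded from the ratio mean (a
zero-residual point would be an infinite ratio); a series whose every
deviation is excluded — a perfect fit — maps to the cap `snr_cap = 1e6`,
which also bounds every reported SNR. Exclusion-plus-cap keeps the statistic
finite and monotone in the noise level. A probe is **deterministic** iff
`SNR_trajectories > SNR_cloud` strictly; ties (possible only at degenerate
capped values) fall to stochastic.

## aDMPs, direction classes and variance–mean scaling

aDMPs per sex satisfy |OLS slope| > 0.001 per year (≥ 0.1 beta over a
century) and R² above the 99th linear-interpolation percentile of the R²
distribution over all probes tested in that sex. aDaVMPs additionally have
BH-adjusted σ²-slope p < 0.001, adjusted within the aDMP set. Direction
classes are the four sign pairs of (β slope, σ² slope); zero slopes cannot
survive the selection gates and raise an error if forced.

For each aDaVMP, `CV² = σ²/⟨β⟩²` and `F = σ²/⟨β⟩` are regressed on age
(BH within the aDaVMP set, per statistic). When the β and σ² slopes have
opposite signs both statistics are normalized to `1 − ⟨β⟩` instead, since
the variability then tracks the demethylated fraction. The inferred law is
`σ² ∼ β²` when the CV² test fails to reject (adjusted p ≥ 0.001), else
`σ² ∼ β` when the Fano test fails to reject, else NA. When both fail to
reject, the quadratic law wins: CV² flatness is the dominant empirical class
and is tested first.

## Nonlinear trend classification

Three models per probe: `β = k·age + b`; `ln β = α·ln age + p` (power law);
`ln β = γ·age + q` (exponential). The nonlinear fits are least squares in
their own (log) axes — no retransformation bias correction is applied — but
all three are scored on the original beta scale, `R² = 1 − RSS/TSS` with
back-transformed fitted values, so nonlinear R² can be negative. Betas are
floored at 1e−6 before logs (floored values are retained, not dropped, so
every model sees the same n); ages must be strictly positive for the power
model and cohorts containing age 0 are rejected for this analysis.

Both β and 1 − β are fitted; the complementary orientation is adopted when
its best nonlinear R² is at least 5 % higher. "5 % higher" is multiplicative
(`R² ≥ 1.05 · R²_ref`) because it is phrased as a percentage of the
coefficient; when the reference R² is ≤ 0 an absolute margin of 0.05 is used
instead (a percentage of a non-positive R² is meaningless). The same margin
separates the classes: strong nonlinear (best nonlinear R² ≥ 1.05 × linear
R²; power vs exponential by the larger R², ties to power), weak nonlinear
(within ±5 %), else linear. Note a consequence worth knowing: a *pure* power
curve `age^α` over an adult-only span (e.g. 14–94 years) has a best-line R²
above 0.952 for any α, so no noise level can make it strongly nonlinear
under the 5 % rule — strong calls on adult-only data require genuinely
saturating shapes. The package's power-law recovery benchmark therefore uses
a lifespan design (ages 1–94), where `age^0.3` has a noiseless best-line R²
of 0.925 and the rule separates cleanly. Likewise the complementary
orientation only wins for probes saturating toward a bound, which is exactly
the case it exists for.

## Cell-composition adjustment

Betas are regressed per probe on the five leukocyte fractions (CD8T, CD4T,
NK, B cells, granulocytes) plus an intercept, separately per sex; residuals
are shifted up by |smallest residual| whenever that minimum is negative, so
downstream log fits see non-negative values. The shift is per probe within
each sex stratum, mirroring the stratified regression. Rank-deficient
designs (e.g. constant fractions) are handled by the pseudoinverse, which
yields the same residuals as dropping collinear columns. Residual cohorts
are marked `value_type="residual"` and are exempt from the ≤ 1 bound.

## Synthetic cohorts: what they emulate

Two canonical designs: a cross-sectional cohort (default 700 individuals,
one visit at a uniform age in 14–94, both sexes) and a longitudinal cohort
(default 150 individuals, 4 visits at 3-year spacing, first visit uniform in
48–89, optional same-sex twin fraction). Twins share sex, visit ages and —
for divergence probes — the trajectory draw up to an intra-pair jitter of
10 % of the heterogeneity scale; jitter zero would collapse twin SNR onto
trajectory SNR, and the chosen 10 % places it strictly between trajectory
and cloud SNR, as observed in real twin data.

Per probe, the mean trajectory follows one of four laws (linear, power,
exponential, constant; optionally on 1 − β), validated to stay inside [0, 1]
over the configured span. Visit-level noise can scale with the mean to
realize each variance–mean law: `sd = c·μ` (constant CV, σ² ∼ β²),
`sd = √(c·μ)` (constant Fano, σ² ∼ β), constant sd, or `sd = √(c·μ³)` (a
σ² ∼ β³ control that neither normalization flattens). Two variability
mechanisms:

* **Divergence** — per-individual slope and intercept perturbations
  (default sd 0.001/yr, anchored at age 0) around the population trend:
  individual lines fan out, variance grows ∝ age², trajectories stay clean.
  Default visit noise sd 0.005.
* **Random walk** — each individual starts on the population curve plus a
  stable personal offset (default sd 0.0225; stable set-point differences
  that an individual's own regression absorbs), then drifts with the trend
  increment while accumulating steps of sd `step_sd·√Δt` (default
  0.001/√yr), with baseline visit noise (default sd 0.001) and one episodic
  excursion per individual — a transient perturbation of magnitude uniform
  in 0.02–0.05 with random sign at a random visit, emulating incidental
  environmental hits (illness, exposure, batch). The episodic component is
  essential: because each individual's OLS line is fitted in-sample, purely
  Gaussian fluctuation always leaves trajectory residuals *smaller* than
  cloud deviations and would be classified deterministic; transient
  excursions contaminate whole trajectories while leaving most pooled
  points near the population mean, which is what makes the SNR ratio settle
  near 1. The offset and excursion scales were calibrated once, jointly
  across independent seeds, so that the fluctuation-dominated regime yields
  a median log₁₀ SNR ratio just below 0 with a solid majority of stochastic
  calls, and were then frozen.

Betas are clipped to [1e−6, 1 − 1e−6] so logarithmic fits are always
defined. The generator does not emulate array chemistry, batch effects,
detection p-values, missing values, or genome coordinates (probe ids are
arbitrary labels); passing tests on synthetic cohorts therefore validates
the statistical machinery, not robustness to technical artifacts of real
arrays.

## Canonical benchmark sizes

The validation benchmarks (`methylvar.validation`, used by the test suite
and `scripts/acceptance.py`) run at sizes chosen to be decisive yet
desk-scale: mechanism classification on 200 divergence + 200 random-walk
probes (150 individuals × 4 visits); SNR ordering on 100 divergence probes
with 40 twin pairs; scaling-law recovery on 100 probes per law at n = 700
(trend 0.2 + 0.005·age, coefficients 0.1 / 0.0025 / 0.01 — beta noise sd
0.02–0.06, typical of blood 450k variability); power-law recovery on 100
probes with α = 0.3 and 1 % multiplicative noise against 100 linear
controls, ages 1–94.

## Numerical conventions and edge cases

* Constant series: R² and slope are defined as 0, slope p-value 1; perfect
  fits give p = 0.
* BH adjustment delegates to `statsmodels` (`fdr_bh`); Fisher's exact test
  and the two-sample KS test delegate to `scipy.stats` (two-sided,
  asymptotic KS p). The test suite checks each against brute-force
  oracles (step-up definition, exact-rational hypergeometric enumeration,
  ECDF enumeration).
* The Fisher odds ratio is reported as the sample odds ratio `(a·d)/(b·c)`
  (∞ when only the cross product vanishes, NaN when both do); the
  enrichment background is the analysed universe minus the probe list, and
  unannotated probes are excluded from both margins and logged.
* Window bounds are closed: ages exactly `half_width` apart share windows.
* File round trips write 17 significant digits and parse with pandas'
  round-trip float parser, so cohorts survive write/read bit-exactly.
* The pipeline records an exclusion ledger (individuals with < 3 usable
  visits, opposite-sex or unsynchronizable twin pairs, unannotated probes)
  because these silent drops change denominators.

## Known limitations

* The SNR ratio is estimated by means of heavy-tailed point ratios; probes
  with near-zero deviations can inflate either SNR, which is why the
  epsilon/cap policy exists and why calls very close to ratio 1 should not
  be over-interpreted.
* The weak-nonlinearity class is intentionally permissive (±5 %); on adult
  spans nearly all trending probes fall in it, and discriminating the true
  law needs either a lifespan design or longitudinal trends.
* Cell-composition adjustment assumes linear dependence of beta on
  fractions; reference-based fraction estimation itself is out of scope
  (fractions are inputs).
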