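# Methods

## Specific-energy distributions

A cell population exposed to a macroscopic dose D receives per-nucleus
specific energies z = ε/m whose distribution f(z, D) is represented as a
uniformly binned probability mass vector. Uniform binning is mandatory:
dispersion, RMSE and convolution are only comparable across distributions on
a common equal-width grid. Bins are half-open [left, right) with the last
bin closed; the default histogram range is [0, max(sample)], padded up to an
integer number of bins when a bin width is requested.

Summary statistics are the mean z̄, the population standard deviation σ
(divisor N — the dispersion describes the enumerated population, not an
estimate from a subsample), and the dispersion σ/z̄. Across replicate
simulation runs, per-bin error bars are instead the *sample* standard
deviation (divisor N−1) of the per-bin probabilities, since there they
estimate a sampling spread from repeated independent runs. Moments of a
binned distribution use bin midpoints; when raw per-cell values are
available they are preferred (the binned mean is within half a bin width of
the raw mean, and tests assert this).

### Convolution

With D₁ the dose per initial particle, the event count at cumulative dose D
is v = D/D₁, which must be an integer; non-integer ratios (beyond a relative
1e-6) are rejected rather than silently rounded. The multi-event spectrum is
the v-fold self-convolution of the single-event spectrum f₁, computed by
binary exponentiation (O(log v) convolutions); a test asserts equality with
the literal sequential convolution.

Grid convention: bin masses are treated as atoms at bin midpoints, so the
index convolution places the sum mass at (k + v/2)·w on a [0, v·z_max]
output grid of the native width w. For odd v these are interior midpoints;
for even v they fall exactly on bin edges and each atom is split half/half
between the two adjacent bins. The split keeps mean(f_v) = v·mean(f₁) exact
and adds at most w²/4 to the variance (0.4% relative at v = 2 with the test
spectrum, shrinking as 1/v) — assigning edge atoms to one side instead would
bias the mean by w/2, which at v = 2 is a 3% error. Renormalization to unit
mass guards floating-point drift only; discrete convolution conserves mass.

Support grows to v·z_max; an explicit mass-preserving rebin (proportional
overlap, implemented as interpolation of the cumulative mass) maps results
onto coarser grids for comparison or plotting. RMSE never rebins silently:
mismatched grids are an error.

Empirical checks sample sums of v draws from f₁ treating each bin as
uniform density (the continuous distribution a histogram represents); with
midpoint atoms instead, all even-v sums would sit exactly on bin edges and
the comparison would test tie-breaking, not the convolution.

### Normal reference and truncation

The matched normal distribution uses the mean and standard deviation of the
distribution under study, binned as CDF differences on the same grid and
renormalized over the binned range. The renormalization handles the low-dose
inconsistency that specific energies (and expression ratios) cannot be
negative while the matched normal extends below zero; at dispersions below
~30% the truncated mass is negligible and the reference is effectively the
untruncated normal.

## Synthetic per-cell dose sampler

Each cell receives the sum of v independent single-event draws divided by
its relative nucleus mass (lognormal, mean 1, coefficient of variation
`mass_cv`), analytically normalized so the population mean is unbiased. The
single-event family defaults to gamma (shape 2) — non-negative and
right-skewed like photon single-event spectra; lognormal and tabulated
spectra (for imported Monte-Carlo output) are supported. The mean nucleus
specific energy is `nucleus_dose_ratio` (default 1.2) times the macroscopic
dose: cell nuclei receive somewhat more dose than the surrounding medium.

The sampler exposes the two variance components separately: event
stochasticity (shrinks as 1/√v) and cell-mass heterogeneity (dose
independent). With `mass_cv = 0` the sampler converges to the convolution
prediction (cross-checked at n = 10⁵ cells, max per-bin deviation < 0.01);
with `mass_cv > 0` the population dispersion plateaus at ≈ mass_cv instead
of vanishing, which is why a pure convolution of a low-dose spectrum
underestimates the population dispersion at high cumulative dose.

## Synthetic single-cell experiment

Counts are negative binomial, the standard overdispersed model for UMI
counts: counts[g, c] ~ NB(mean μ_g·L_c, size s_g) with per-cell library
factors L (lognormal, mean 1, CV 0.1 by default). Per-gene baseline means
are lognormal across genes (median 3, log-sd 0.8) and shared across groups,
so expression differences are driven only by the planted schedules. Default
shape follows the study conditions: 23,517 genes × 10,000 cells per group at
0/10/100/1000 mGy; tests and the acceptance experiments run a reduced
2,000 × 300 configuration, which keeps every distributional signature while
fitting interactive runtimes.

Planted classes (all parameters recorded in the ground-truth table):

* **A** — NB size grows 4-fold per irradiated dose step, mean unchanged:
  the expression-difference dispersion (the per-group CV) strictly
  decreases with dose. Since CV² = 1/μ + 1/s, the 1/μ term is dose-constant,
  so the size schedule must dominate; planted signal genes therefore have
  their baseline mean floored at 2 (their real-data counterparts — ribosomal
  protein genes — are among the most highly expressed genes in any cell).
* **B** — the same schedule reversed (dispersion increases with dose).
* **C** — null, exchangeable with control (the unassigned remainder).
* **D** — mean fold change 2.0 in every irradiated group.
* **E** — fold changes (1.5, 2.0, 0.6): up-regulated at low dose with the
  differential growing with dose, down-regulated at the highest dose.
* **AD** — class A dispersion schedule and class D fold change combined:
  the genes the full screen is designed to find.

All generators are pure functions of (config, seed); replicate/group streams
are spawned from the master seed via `numpy.random.SeedSequence`, so results
are bitwise reproducible and block size in the chunked count generation does
not affect the stream.

## Expression differences and the screen

Ratios are computed on raw counts by default (an optional per-cell
median-library normalization switch exists); zeros participate as 0, with no
imputation. Genes with zero control mean have no defined ratio and are
excluded with a reason rather than propagated as NaN. Dividing a gene's
counts by its control mean makes every downstream metric invariant to
per-gene scale, which is asserted as a property test.

Per gene, the distributions of ratios in the 10 and 100 mGy groups are
binned on a shared [0, max ratio across groups] grid (50 bins by default);
dispersion and mean use the raw ratios. Genes with σ = 0 are flagged; they
fail the microdosimetric merge instead of erroring the pipeline.

The screen:

1. *Statistic merge* — FC = group mean / control mean; two-sided gate
   (FC ≥ 1.2 or ≤ 1/1.2 — down-regulated genes count as differential) and
   Welch's t-test on per-cell values at p < 0.05 (Wilcoxon rank-sum
   optional). Raw p-values by default, matching common FC/p screening
   practice; Benjamini–Hochberg adjustment is available and recommended when
   the result feeds further analysis. A gene passes if significant in at
   least one irradiated group; per-group membership and the all-group
   intersection are both reported.
2. *Microdosimetric merge* — dispersion strictly decreasing along the
   low-dose groups (strict, because a non-strict rule would admit null genes
   through ties; ties have probability ~0 on continuous dispersions).
3. *Ranking* — candidates passing both merges are sorted ascending by the
   mean RMSE-to-normal over the low-dose groups (max is available), ties
   broken lexicographically by gene id for reproducibility; the top 50 are
   the multi-filtered set, and per-group top-100 lists are also emitted.

## Pipeline, configuration, determinism

Configurations are YAML/JSON validated strictly: unknown keys are errors
(protects threshold fidelity against typos) and violations name the field
path. `run_all` simulates both input kinds, runs the screen, and writes a
manifest with a SHA-256 hash of every output file; reruns with the same
configuration are byte-identical (no timestamps; input directories are
recorded by basename). On failure the partial outputs are removed and the
failing stage named.

## Choices in the acceptance experiments

* Null calibration pools the Welch rejection rate per irradiated group over
  20 seeds × 2,000 genes and requires each group within 3 binomial standard
  errors of 0.05.
* The planted-recovery experiment plants 100 dual-signature (AD) genes and
  100 class B genes among 2,000 and selects with `top_n_multifiltered =
  100` — one selection slot per planted signal gene, so precision and recall
  are measured on equal footing (a top-50 cap would bound recall at 0.5 by
  arithmetic alone).
* Problem sizes (10⁵ draws for spectra, 2,000 × 300 × 4 groups for screens,
  10–20 seeds) were chosen so each experiment's Monte-Carlo error is well
  below the tolerance it is compared against.

## Known limitations

* No radiation transport: single-event spectra are parametric or imported;
  geometry, materials and the 1.2 nucleus-to-medium ratio are inputs, not
  results.
* The count simulator omits UMI/read-level noise, doublets, ambient RNA and
  batch effects; passing recovery tests show the screen finds the planted
  distributional signatures under NB noise, not that it is robust to every
  real-data artifact.
* Dispersion of expression differences equals the per-group CV of counts, so
  the microdosimetric merge cannot distinguish a genuine variance change
  from a mean change at constant variance; class E genes (rising mean) pass
  it legitimately.
* The convolution assumes independent, identically distributed events per
  cell and ignores cell-to-cell mass variation; use the dose sampler with
  `mass_cv > 0` for the population-heterogeneity regime.
* Wilcoxon support is provided for heavy-tailed counts, but the null
  calibration is asserted for the Welch default only.
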