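# Methods

## Precursor kinetics

Body-water deuterium enrichment is modelled as a first-order rise to
plateau, `p(t) = pss·(1 − exp(−kp·t))`, with `kp` in 1/day and `pss` a
fraction. The fit is unweighted nonlinear least squares over all serum
records (replicate animals enter as separate residuals), initialised at
`pss₀ = max` observed enrichment and `kp₀ = 1/day`, bounded to
`kp ∈ [10⁻³, 100]` and `pss ∈ (0, 0.5]` — a robust configuration for
rise-to-plateau curves. Time is in days throughout; enrichment is stored as
a fraction and rendered as percent only in reports. With the standard
sampling design (days 0, 1, 3, 6, 15, 31, 63, 127) only two points lie on
the rising limb, so `kp` is weakly constrained under noise while `pss` is
tight; downstream peptide fits depend mainly on `pss`, which keeps this
benign. Raw GC-MS intensity ratios can be converted to enrichment through
an ordinary least-squares standard curve; predictions outside the
standards' range are flagged as extrapolated.

## Peptide chemistry

Peptide elemental composition is the residue sum plus one terminal water
(computed via pyteomics), optionally adjusted by fixed carbamidomethyl and
variable oxidation modifications. The natural monoisotopic abundance `a` is
the product over elements of (light-isotope abundance)^(atom count), using
current IUPAC abundances (¹²C 0.9893, ¹⁴N 0.99636, ¹⁶O 0.99757, ³²S 0.9499,
¹H 0.999885) shipped as a user-replaceable CSV. By default hydrogen is
excluded from `a` (the heavy-element convention for C/N/O/S); a flag
includes natural deuterium, which lowers `a` by ~1–2% for typical peptides.
The labelling-site count `N` is the sum of per-residue literature values
for rat (A 4.00 … Y 0.42), also a replaceable CSV; fractional `N` is
expected. The fully-labelled plateau is `a·(1 − pss)^N`, the zero-success
term of a binomial over `N` sites at enrichment `pss` — the brute-force
binomial convolution is kept in the test suite as an oracle.

## Turnover model and fitting

The M0 relative abundance under first-order turnover with a rising
precursor is

    A0(t) = a·[e^(−k t) + k·∫₀ᵗ e^(−k(t−s)) (1 − p(s))^N ds].

For integer `N` the integral is evaluated in closed form by binomial
expansion; term `j` contributes
`C(N,j)(1−pss)^(N−j) pss^j · k(e^(−j·kp·t) − e^(−k t))/(k − j·kp)`, with the
analytic limit `k·t·e^(−k t)` when `k → j·kp` (implemented via a stable
`expm1(x)/x` form inside a |x| < 10⁻⁴ window to avoid cancellation). For
fractional `N`, substituting `v = e^(−k(t−s))` removes the boundary layer
at `s = t` and a 64-node Gauss–Legendre rule evaluates the smooth
transformed integrand; an adaptive-quadrature route of the untransformed
integral is retained as an independent cross-check and agrees with both
paths to ≲10⁻¹² relative.

`k` is fitted per peptide by unweighted least squares on all records
(replicates are separate residuals; `n_timepoints` counts distinct times),
with bounds `[10⁻⁵, 10]`/day and a multi-start search from 8 log-spaced
initial values in `[10⁻⁴, 1]`/day; the best final residual wins, ties going
to the smaller `k`. Goodness of fit is `R² = 1 − SSR/SST` (defined as 1 for
a perfect fit to a constant series, 0 otherwise) and the standard error of
estimate `SE = sqrt(SSR/(n−1))` (one fitted parameter). Degenerate,
non-decaying series end at the lower `k` bound and pass the filter only if
their diagnostics do.

Two alternative fitting modes are provided: a two-exponential
fractional-synthesis approximation
`A0(t) = a − (a − plateau)·f(t)` with
`f(t) = 1 − (kp·e^(−k t) − k·e^(−kp t))/(kp − k)` (exact for N = 1), and a
plateau-constrained single-exponential "manual" fit
`A0(t) = A0_plat + (a − A0_plat)·e^(−k t)` that ignores the precursor rise.
The manual mode is deliberately biased on non-steady-state data — the
package quantifies the method discrepancy as the mean symmetric percent
difference `|k₁−k₂|/((k₁+k₂)/2)·100`, chosen because the base of a plain
percent difference would be ambiguous.

Acceptance filter: a peptide contributes to protein-level summaries iff it
is observed at ≥ 4 distinct time points and (R² ≥ 0.8 or SE ≤ 0.05), all
thresholds inclusive and configurable. "Data points" is read as distinct
time points rather than spectral matches; residuals are unweighted because
no intensity-weighting scheme is defined for this data model.

## Aggregation and phase comparison

Protein-level turnover is the median of accepted peptide `k` and the
unscaled median absolute deviation (no 1.4826 consistency factor — MAD is
reported as a plain dispersion, not a normal-SD estimate), with half-life
`ln 2/k_median` in days. A minimum-unique-peptides gate (default 1, set 2
to mirror stricter identification practice) is configurable.

Phase comparisons require ≥ 3 values per group. Normality is checked per
group by a Kolmogorov–Smirnov test against a normal with the sample mean
and SD (a Lilliefors-style usage: estimating parameters from the sample
makes the nominal p conservative, which here only biases the choice toward
the parametric test). Paired data use a paired t-test when both groups pass
and the Wilcoxon matched-pairs test otherwise (zero differences split
between signs, so identical groups give p = 1); unpaired data use
Mann–Whitney, with an optional t-test variant when both groups are normal.
The peptide-level FM/IFM comparison pairs by identical peptide sequence
observed in both phases. No multiple-testing correction is applied across
proteins.

## Synthetic data generator

The generator emulates the labelling-study design: sampling days
0, 1, 3, 6, 15, 31, 63, 127 with 3 animals per time point; serum following
the default curve (kp = 0.7913/day, pss = 0.0558) with additive Gaussian
noise of SD 0.002 enrichment fraction (chosen to match the small error bars
typical of GC-MS standard-curve measurements; the true magnitude is not
prescribed); per-peptide M0 series on the exact forward model with additive
Gaussian noise (default SD 0.01 relative abundance — a fixture choice, not
an empirical claim) clipped to (0, 1], and whole time points dropped with
probability 0.1. Protein-level FM rate constants are lognormal with median
0.010/day and log-SD ln(1000)/(2·1.96) ≈ 1.76, so the central 95% of
proteins spans ~1000-fold; every IFM rate is the FM rate × 1.8, matching
the 0.018 vs 0.010 median contrast. 55 peptides (configurable) appear in
both phases as the basis for paired tests; the rest are assigned to one
phase with 2:1 FM weighting.

Peptide chemistry is derived from generated tryptic-like sequences (random
8–22-mers ending in K/R), rejection-sampled so `a ∈ [0.3, 0.95]` and
`N ∈ [5, 40]`; deriving `(a, N)` from sequence rather than drawing them
directly keeps the generator consistent with the analysis pipeline, which
recomputes chemistry from sequence — enabling exact end-to-end identity
checks at zero noise. An optional envelope mode emits isotopomers M0–M5 as
a mixture of the surviving unlabelled pool (natural envelope) and the new
pool (natural envelope convolved with a binomial over round(N) sites at the
synthesis-weighted mean enrichment), truncated to six peaks and
renormalised, mirroring relative quantification over observed peaks.

What the generator does **not** emulate: chromatographic peak integration,
identification error and FDR, intensity-dependent (heteroscedastic) noise,
inter-animal biological variation in `k`, and isotope-envelope fine
structure. Passing tests therefore demonstrate correctness of the
estimation machinery under the stated noise model, not robustness to every
artefact of real LC-MS data.

## Problem sizes and numerical choices

The test suite and acceptance script use 200 synthetic peptides with true
`k` log-uniform over [7×10⁻⁴, 0.7]/day for recovery checks (median relative
error ≈ 3% at noise SD 0.01; ≲10⁻¹²% noiseless), a 20-protein × 6-peptide
two-phase study for the end-to-end run, 200 replicates for phase-effect
power and 1000 for null calibration — sizes chosen to make Monte-Carlo
error small relative to the margins being checked. Optimiser tolerances are
1e-12 (xtol/ftol/gtol); all simulations and stochastic tests take explicit
seeds (default 20200512).

## Known limitations

- Only the M0 trace drives fitting; multi-isotopomer joint likelihoods are
  out of scope (the envelope mode exists for data generation, not fitting).
- The `kp` estimate is fragile under serum noise with the default sampling
  grid (two points on the rising limb); studies wanting a tight `kp` need
  denser early sampling.
- The KS normality gate uses estimated parameters without the Lilliefors
  correction; with the small group sizes typical here it rarely rejects,
  so the parametric test is chosen liberally.
- Exact tie/continuity conventions of other statistics software are not
  reproduced; scipy defaults are used.
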