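# Methods

## Model and assumptions

The transfer of Pb from soil to corn grain is summarised by the
bioconcentration factor BCF = C_grain / C_soil (both mg/kg, grain dry
weight) and modelled log-linearly:

    log10 BCF = a·pH + b·log10 OM + c·log10 CEC + k

pH enters untransformed (it is already a log quantity); OM (g/kg) and CEC
(cmol/kg) are log10-transformed on their native units. All logarithms in
the package are base 10. The intercept k is interpreted as the cultivar's
intrinsic sensitivity — its propensity to accumulate Pb independent of
soil — and the slopes as soil-chemistry effects (acidity mobilises Pb,
organic matter sorbs it), assumed shared across related corn cultivars.
That sharing is the cross-species extrapolation assumption: to carry a
fitted model to another cultivar, only k is refitted.

Measurement error is treated as multiplicative on the BCF, i.e. additive
Gaussian on log10 BCF, which is the residual structure OLS on the log
scale assumes.

## Fitting

Predictors are chosen from {pH, log10 OM, log10 CEC} by forward-entry /
backward-removal stepwise OLS on partial t-test p-values. Defaults
alpha_enter = 0.05 and alpha_remove = 0.10 are the classic stepwise
defaults; they are exposed as parameters. Ties at entry are broken by the
larger |t|, then by predictor name, so selection is deterministic.
alpha_enter ≤ alpha_remove is enforced, which (together with the
deterministic tie-break) rules out enter/remove cycling. Zero-residual
(noiseless) fits make the usual t statistics degenerate; a coefficient
with zero standard error is scored p = 0 when it is non-null (|β| >
1e-10) and p = 1 otherwise, so exact data are handled without special
cases elsewhere. A condition number above 1e8 on the standardised
candidate design triggers a collinearity warning. Models are fitted per
dose level on the model cultivar's records; control pots (no added Pb)
are not modelled. Records with non-detect (zero) grain Pb are excluded
from log-space modelling with a logged count rather than imputed.

Intercept refitting for a non-model cultivar minimises the squared
prediction error. In log space the optimum is the closed form
k = mean(log10 BCF_i − slope terms_i); this is the default because the
objective is exactly quadratic there. A linear-space objective
(sum of squared BCF differences) is available as a sensitivity check and
is minimised by bounded scalar search within ±3 log units of the
log-space solution, a bracket far wider than any plausible offset.

## Dose assignment

Exogenous Pb doses follow the GB15618-1995 Grade Two limit for the soil's
pH class: 250/300/350 mg/kg ("high") and half that ("low") for pH <6.5,
6.5–7.5, >7.5 respectively. Both printed band edges (6.5, 7.5) are
assigned to the middle class, reading the middle band as the closed
interval.

## Normalization and variability

A measured BCF at soil s is moved to reference condition r by

    BCF_norm = BCF · 10^(pred(r) − pred(s))

This multiplicative adjustment is the unique choice under the log-linear
model for which noiselessly generated BCFs normalize to exactly one value
per cultivar, making "normalized endpoints should be equal" a testable
identity. The default reference (pH 7.0, OM 20 g/kg, CEC 20 cmol/kg) is
central to the reference panel's property ranges and always overridable;
it is recorded in every output. Intra-species variability is the sample
coefficient of variation f = sd(BCF; n−1) / mean(BCF); the drop from
f_raw to f_norm measures the soil-driven variance the model removes. With
the generating model, f_norm converges on the noise-only CV
sqrt(exp((sd·ln 10)²) − 1), e.g. 0.116 at sd = 0.05.

## Synthetic data

The generator emulates the pot experiment the analysis presumes: soil
properties drawn independently and uniformly over the reference panel's
observed ranges (pH 4.90–8.65, OM 8.57–47.69 g/kg, CEC 8.12–31.11
cmol/kg, background Pb 23.12–37.97 mg/kg); log10 BCF = truth-model
prediction + cultivar offset + N(0, noise_sd); soil Pb = background +
assigned dose; grain Pb back-solved as BCF × soil Pb. Defaults: 17 soils,
the published low-dose model as truth, six non-model cultivars with
intercept offsets at the published magnitudes (−0.401 to +0.071 log
units), noise_sd = 0.1 log10 units — a residual scale consistent with the
reported R² ≈ 0.86–0.91 of the published fits over these property ranges.
Uniform sampling (rather than resampling the literal panel rows) avoids
inheriting the panel's property correlations; the literal 17-soil panel is
available via `use_reference_panel` for exact-recovery fixtures. One
integer seed drives all draws through spawned substreams, so bundles are
bitwise reproducible.

What the generator does not emulate: soil aging kinetics and speciation,
within-pot replicate structure (one record per soil × cultivar × level),
detection limits, and any non-log-linear dependence of uptake on
properties. Passing tests therefore demonstrate the statistical machinery
is correct and calibrated, not that the log-linear form is adequate for
any particular real soil.

At noise_sd = 0.1 the OM effect is only marginally detectable at n = 17
(its contribution spread across the panel is ≈ 0.03 log units), so
stepwise selection legitimately returns a pH-only model in many noisy
replicates; parameter-recovery checks are therefore run on the known-true
predictor set, the estimator stepwise coincides with when selection is
correct.

## Numerical choices

- Exact-recovery assertions use 1e-8 on coefficients; "equal" normalized
  values are asserted to ~1e-12 relative, since 10^a·10^(r−a) reproduces
  10^r only to machine precision.
- The grid-search oracle for the intercept closed form is centred on a
  median-based (hence independent) start and spans ±0.5 log units at 1e-6
  steps.
- Fold deviations are max(pred/meas, meas/pred) ≥ 1; the 2-fold boundary
  counts as inside.
- Analysis drivers use a fixed default seed (20140108) so their printed
  tables are reproducible; replicate counts in tests (500 recovery fits,
  200 variability replicates, 120 calibration panels) keep the whole suite
  in a few seconds while leaving Monte-Carlo error well inside the
  asserted tolerances.

## Known limitations

- Sample CV is a slightly biased estimator of the population CV at n = 17;
  comparisons against the noise-only CV use a 15% band that absorbs this.
- Linear-space intercept fitting weights large BCFs more heavily than the
  log-space default; the two agree only in the noiseless limit.
- The package takes no position on whether the low- or high-dose model
  extrapolates better; both are fitted and reported side by side.
- Extrapolation is within-crop (corn cultivars); transfer to other crops
  or metals is out of scope.
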