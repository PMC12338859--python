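# Methods

## Weak-acid partition model

A monoprotic weak acid HA ⇌ H⁺ + A⁻ with dissociation exponent pKa has
protonated fraction `f(pH) = 1/(1 + 10^(pH−pKa))`. The accumulation model
makes three assumptions, stated explicitly because each one bounds what the
output means:

1. **Infinite reservoir.** The extracellular compartment is so much larger
   than the cytosol that uptake does not deplete it (true for gut lumen vs
   epithelium; approximately true for culture medium vs adherent cells).
2. **Permeant neutral species only.** Only HA crosses the membrane, and at
   equilibrium its concentration is equal on both sides. Anion transport
   (e.g. monocarboxylate transporters) is not modelled.
3. **No sinks.** Metabolism, esterification and active export are ignored.

Under these, `[SCFA]_I = [SCFA]_E · (10^(pH_I−pKa)+1)/(10^(pH_E−pKa)+1)`.
The result is therefore an *equilibrium upper bound*: live cells metabolise
and export the acid, so measured intracellular concentrations will sit below
it. The bound is linear in dose and exponential in the pH gradient; for
pKa well below both pH values the accumulation factor approaches
`10^(pH_I−pH_E)` from below, and approaches it faster the lower the pKa.

The constants table ships only pKa values with a stated source (butyrate
4.82, lactate 3.86); any other species requires a user-supplied pKa (the
CLI takes `--pka` or a YAML species list). Concentrations are millimolar
throughout; no temperature correction is applied to pKa.

Tests check the closed form against an independent numerical equilibrium
solver that root-finds the speciation mass balance per compartment and then
the intracellular total whose protonated-species concentration matches the
extracellular one (relative tolerance 1e-9 over 1000 random parameter
tuples).

## Synthetic image generator

The generator emulates the calibration and treatment experiments that the
imaging chain consumes, with full per-cell ground truth. Its stated world:

- **Buffer series** pH 3.5, 4.77, 5.5, 6.0, 6.5, 7.0, 7.5, 8.0 — the
  standard MES/HEPES defined-pH series for probe calibration. For a
  surface-anchored probe the sensed pH equals the buffer pH, so every cell's
  ground truth is the buffer value.
- **15 cells per field**, matching typical per-condition counts in
  published calibrations of this probe class.
- **Cells** are non-overlapping ellipses (semi-axes 8–14 px in a 256×256
  field) of uniform interior intensity, separated by a ≥3 px gap:
  transiently transfected cells are sparse, and whole-cell means are the
  quantity of interest, so no nucleus/cytosol substructure is modelled.
- **Expression heterogeneity**: per-cell brightness uniform over a 4×
  range (2000–8000 counts). The 405/488 ratio is expression-independent,
  as for a true ratiometric probe.
- **Sensor response** is a four-parameter logistic in pH
  (`R_min 0.3, R_max 2.5, pH_half 6.5, slope 1`), midpoint chosen near the
  apparent pKa typical of pHluorin-class probes. The direction (ratio
  increasing vs decreasing with pH) is configurable and *not* assumed by the
  downstream fit, since real probes differ. These parameters are a synthetic
  stand-in; they do not claim to reproduce any measured instrument curve.
- **Noise**: Poisson shot noise on total counts, Gaussian read noise
  (sd 5 counts), uniform background 100 counts, quantized to 16-bit TIFF.
  A float debug mode disables quantization so noiseless fidelity can be
  asserted to 1e-9.

What a green test on this world does **not** establish: robustness to
optical blur (no PSF), uneven illumination, touching/overlapping cells,
z-variation, photobleaching, or motion. The segmentation defaults would need
re-tuning for real confocal data (in particular `smooth_sigma > 0`).

Determinism: each field's random stream is seeded by (master seed, CRC32 of
the field id), so outputs are byte-identical per seed and independent of
rendering order.

## Quantification

Segmentation runs on the 488 nm channel (the brighter channel for an
increasing-ratio probe; a channel-sum option exists): Otsu threshold **in
log intensity** — a linear Otsu is biased past the dimmest cells when
expression spans a wide range — then hole filling, a 50 px minimum-area
filter, and connected-component labelling. Background per channel is the
median of unlabeled pixels. The per-cell ratio is the ratio of
background-subtracted channel *means* (robust to dark pixels; a pixelwise
mean-of-ratios mode exists behind a flag). QC rejects cells below the
minimum area, with 488 signal under 2× background, with >1% saturated
pixels, or with a non-positive 488 denominator. `select_cells` reproduces
"cells of similar fluorescence intensity" selection deterministically: rank
by |log(488 signal) − condition median| and keep the n closest, ties broken
by (field, cell) id.

## Calibration

The ratio-vs-pH response is fitted with the four-parameter monotone logistic
`R(pH) = R_min + (R_max−R_min)/(1 + 10^(s(pH_half−pH)))` with signed
steepness `s`; the sign (direction) is inferred from the data. The logistic
family is the standard choice for ratiometric pHluorin-class calibrations
and is closed-form invertible. Fitting is deterministic: initial values are
the 5th/95th ratio percentiles, the buffer pH nearest the mid-ratio, and
|s| = 1; Levenberg–Marquardt least squares on per-cell points (per-pH means
optional). At least 4 distinct buffer pH levels are required (4 free
parameters). A slope whose ~95% CI spans zero sets `monotone_warning_`.

Inversion is closed-form inside the open interval (R_min, R_max); ratios at
or beyond an asymptote, or mapping outside the fitted buffer range, are
clamped to the nearest valid-range endpoint and flagged `extrapolated`
(with a 1e-9 grace band so endpoint round-trips do not flag on float
rounding). Each experiment/batch gets its own curve.

## Treatment analysis

Per-cell pH values are summarized per (buffer pH × treatment) condition as
mean ± SEM. For acid-dosed conditions the equilibrium intracellular
concentration is computed **per cell and then averaged** (default): the
partition model is convex in pH_I, so applying it to the condition mean
understates the expectation (Jensen); the condition-mean variant is one flag
away (`--mean-ph`) for comparison. Cells flagged extrapolated stay in pH
summaries but are excluded from concentration estimates, where a clamped pH
would enter an exponential.

Group comparison: two-way fixed-effects ANOVA (pH_E × treatment) on
per-cell pH with type-II sums of squares (order-invariant for unbalanced
designs), plus pooled-variance pairwise treatment contrasts within each
buffer-pH level, family-wise corrected by Bonferroni (raw p × number of
contrasts, capped at 1). Design cells with <2 observations skip their
contrast with a warning. A one-way ANOVA + Dunnett many-to-one utility is
provided for externally measured tables; it is not part of the imaging
chain.

## Numerical choices

- Pixel coordinates are 0-based, row-major everywhere.
- Measurement tables are canonically sorted by (field_id, cell_id), making
  outputs byte-stable under any field-processing order.
- The logistic fit swaps asymptotes and flips the sign of `s` if the
  optimizer converges to the mirrored parametrization (the two are
  equivalent), so reported parameters always satisfy `R_max > R_min`,
  `slope > 0` with an explicit direction.
- Background-subtracted channel means are clamped at 0; ratios with a
  non-positive denominator are NaN and QC-failed rather than infinite.
- SEM is reported only for n ≥ 2; concentration estimates are NaN when no
  unflagged cells remain.

## Known limitations

- The equilibrium bound ignores all kinetics; it cannot be read as a
  measured intracellular concentration.
- The simulator's geometry is deliberately easy (sharp, separated ellipses);
  segmentation accuracy numbers from it do not transfer to real confocal
  data.
- The two-way ANOVA pools cells across fields, treating cells as
  independent; field-level (nested) variance components are not modelled.
- Organelle-targeted probes are handled as ordinary conditions; no
  compartment-specific logic exists.
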