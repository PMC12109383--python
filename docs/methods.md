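# Methods

This note records the models implemented, the defaults and units, what the
synthetic-data generators do and do not emulate, and the numerical and
design choices made where the design was genuinely open.

## Quenching analysis

The Stern–Volmer fit regresses y = F0/F on [Q] by ordinary least squares
(`scipy.stats.linregress`). The intercept is **free by default**: real
baselines drift, and a free intercept exposes that drift instead of folding
it into the slope. The theoretical model pins the intercept at 1, so a
deviation beyond 0.05 raises a warning, and a `fix_intercept` mode fits the
slope alone through (0, 1). Kq = Ksv/τ0 is an exact identity in every fit;
τ0 defaults to 10⁻⁸ s (the standard biopolymer lifetime scale) and is
configurable.

The double-log fit uses **decadic** logarithms throughout, matching the
field's "lg" notation; the slope n is base-invariant but the intercept
(lg Ka) is not. Points with [Q] = 0 or F ≥ F0 carry no information under
the transform and are dropped with a warning rather than erroring; fewer
than three survivors is a fit error that lists what was dropped.

Mechanism classification: primary rule is min Kq vs the diffusion limit
2.0×10¹⁰ L·mol⁻¹·s⁻¹ (above ⇒ static, at/below ⇒ dynamic); the Ksv-vs-T
trend is secondary evidence only, and a primary/secondary disagreement is
recorded as a discordance note without changing the label. The ±5% band
around the threshold that yields "ambiguous" is a package convention — the
underlying literature rule gives no tie-break.

**Response definition.** Whether F is the per-spectrum maximum or the
intensity at a fixed wavelength is an open choice in practice; both are
implemented. The default is the per-spectrum maximum ("peak"), the common
literature reading; "fixed_wavelength" (intensity interpolated at the
ligand-free peak position) is available for sensitivity analysis. With the
~2 nm band shift the two differ slightly but both recover the generating
Ksv within 2%.

## Dilution arithmetic

Two volume conventions: "nominal" divides by the base volume alone,
"additive" by base + aliquot. Nominal is the default because the ladder
this design is built around (20–80 μL of 10⁻³ M stock into 3.0 mL,
top concentration 26.7 μM) is only consistent with dividing by 3.0 mL.
Protein concentration is carried as mg/mL metadata only; no molar protein
concentration is computed (no molecular weight is assumed).

## Van't Hoff thermodynamics

ln Ka is regressed on 1/T; ΔH = −R·slope, ΔS = R·intercept, ΔG = ΔH − TΔS.
Internal units are J/mol and J/(mol·K) everywhere; only the report layer
prints kJ. With exactly two temperatures the line is determined and
standard errors are reported as NaN. Points are never reweighted or
reordered.

A decreasing Ka(T) series **forces** ΔH < 0 under this model. When an
externally reported enthalpy disagrees in sign with the fitted one,
`discrepancy_notes` attaches a machine-readable note to the report rather
than silently preferring either number — the package computes faithfully
from the regression and surfaces the conflict.

Force classification uses the (ΔH, ΔS) sign quadrant with zero bands
|ΔH| ≤ 100 J/mol and |ΔS| ≤ 1 J/(mol·K) (package conventions; any sign
inside a band yields "indeterminate" rather than a coin-flip call).

## Peak detection and synchronous analysis

Peak calls are grid argmax with ties broken toward the smaller wavelength
(deterministic) and a warning; a flat spectrum warns and returns the
smallest wavelength. Optional 3-point parabolic refinement (general
uneven-grid vertex formula, clamped at grid boundaries) is **off by
default** so whole-nm instrument reporting reproduces exactly; shift calls
in the synchronous module therefore operate at integer-nm resolution.
Percent declines are computed exactly and rounded only at presentation.
Residue labels follow the Δλ convention (15 nm → Tyr, 60 nm → Trp); other
offsets are accepted and labelled "custom".

## CD secondary structure

The proprietary neural-network deconvolution used with most bench CD
instruments is replaced by a transparent estimator: nonnegative least
squares of the signal on four reference component spectra, interpolated to
the **sample** grid (so residuals live in measurement space), with the
coefficients renormalized to sum to one. The pre-normalization residual is
reported, so both the linear-model misfit and the size of the
normalization correction are visible. Sum-to-one via post-normalization
(rather than a constrained solve) keeps the estimator one `nnls` call and
makes its error observable.

The shipped basis is synthetic: sums of Gaussian bands at the canonical
positions (helix: +193, −208, −222 nm; sheet: +196, −218 nm; a weak turn
band; coil: −198 nm), in arbitrary millidegree-like units per unit
fraction. It supports exact recovery of known mixtures and qualitative
composition tracking; absolute structure fractions of real proteins
require a measured basis (loadable from CSV). Consequently published
structure tables are treated as generator settings and qualitative
context, never as quantitative validation of this estimator.

## Antioxidant assays

The three response formulas are implemented exactly as defined; responses
outside [0, 100]% (or negative reducing power) are **warned, never
clipped** — truncation would hide assay failure. TEAC conversion uses an
OLS Trolox curve with a free intercept (whether bench workflows force a
zero intercept varies; the free intercept is strictly more general and the
standards' own responses invert to their concentrations either way). A
curve with r² < 0.99 warns.

## Synthetic-data generators

All generators are pure functions of (parameters, seed) — bitwise
repeatable — and their outputs satisfy the domain-type invariants.

* **Emission titrations**: single Gaussian band, center 345 nm, σ = 25 nm,
  F0 = 5000 a.u. (no absolute intensity is published for this design, so a
  mid-range photon-count scale was chosen once), peak amplitude
  F0/(1 + Ksv[Q]), red shift 2·Ksv[Q]/(1+Ksv[Q]) nm, multiplicative
  Gaussian noise (default studies use σ = 1%, a typical fluorometer
  stability figure). Bandwidth is held constant — quenching acts on
  amplitude only.
* **Static scenario**: Ksv = 0.50/0.49/0.40 × 10⁵ L·mol⁻¹ at 298/304/310 K
  over the 0–26.7 μM ladder. **Dynamic scenario** (for classifier
  recovery): Ksv = 50/80/120 L·mol⁻¹ over a 1000× (mM-range) ladder —
  with Kq capped below the diffusion limit, a μM ladder yields
  F0/F − 1 < 0.005, unmeasurable at 1% noise, exactly why collisional
  quenchers are titrated at mM on the bench.
* **Synchronous series**: band centers/amplitudes interpolated linearly in
  concentration between ligand-free and top targets (Trp: 274→270 nm,
  3311→1592 a.u.; Tyr: 303 nm fixed, 746→400 a.u. — the Tyr band position
  is a package assumption from the canonical Tyr emission region, not a
  measured value), Gaussian band σ = 12 nm on a 200–350 nm grid.
* **CD**: linear basis mixtures plus additive noise scaled to the peak
  amplitude (detector noise on a CD trace is absolute, not relative).
* **Assays**: sample responses drawn from a Trolox curve (percent assays:
  slope 1.5 %/(mg·L⁻¹), intercept 2%; FRAP: slope 0.02 abs/(mg·L⁻¹),
  intercept 0.05 — plausible bench magnitudes chosen once) and inverted
  into the absorbance roles of each assay; standards at 5/10/20/40 mg/L.

What the generators do **not** emulate: fluorescence lifetimes, FRET,
inner-filter effects, instrument response functions, asymmetric band
shapes, baseline drift, or pipetting error. Passing recovery tests
therefore demonstrates estimator correctness under the stated noise model,
not robustness to every artifact of real instruments.

## Problem sizes and numerical choices

Recovery suites use 50–100 seeded replicates per property (each a
sub-second fit), 500 random tables for the OLS closed-form oracle, and a
two-stage simplex grid search (0.02 coarse, 0.001 local refinement) as the
independent oracle for the NNLS estimator — a single-pass 0.001 grid over
the 4-simplex would be ~10⁸ points for no additional resolution near the
optimum. The Van't Hoff noise-recovery property is evaluated with 10⁴
replicates because the population median error (≈4.8% at σ = 0.02 on
ln Ka) sits close to the 5% bound, and a small-sample median estimate of
it is dominated by its own sampling noise. Ties and degenerate inputs
(flat spectra, zero signals, rank-deficient bases, duplicate temperatures)
are handled explicitly with deterministic rules or typed errors, never
silently.

## Known limitations

* The CD estimator's absolute accuracy on real proteins depends entirely
  on the supplied basis; the synthetic default is for recovery testing and
  qualitative trends.
* No inner-filter correction is applied (the modelled design verified it
  negligible); data needing it must be corrected upstream.
* Modified (Lehrer) Stern–Volmer plots, sphere-of-action models, nonlinear
  Van't Hoff (heat-capacity) terms and lifetime-resolved analysis are out
  of scope.
* Warnings are advisory; the pipeline reports, it does not censor.
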