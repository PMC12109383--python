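# quenchlab

Analysis chain for protein–ligand interaction studies done by optical
spectroscopy: intrinsic-fluorescence quenching titrations, binding
thermodynamics, synchronous-fluorescence microenvironment probes, far-UV
circular-dichroism (CD) secondary structure, and antioxidant capacity in
Trolox equivalents. It is written for the common experiment in food and
protein chemistry where a small phenolic ligand (here, a flavonoid binding
whey protein) quenches a protein's tryptophan fluorescence and the
titration series is worked up into binding constants, thermodynamic driving
forces and conformational read-outs.

Because raw instrument exports for such studies are rarely deposited, the
package ships seeded synthetic-data generators with known ground truth for
every input type, so the full pipeline is testable offline and every
estimator's recovery error is measurable.

## The models

**Stern–Volmer quenching.** For quencher concentration [Q],

    F0/F = 1 + Kq·τ0·[Q] = 1 + Ksv·[Q]

The slope Ksv (L·mol⁻¹) is fit by OLS; Kq = Ksv/τ0 with τ0 = 10⁻⁸ s. If the
minimum Kq across temperatures exceeds the diffusion-controlled limit
(2.0×10¹⁰ L·mol⁻¹·s⁻¹) the quenching is called *static* (ground-state
complex); the temperature trend of Ksv (decreasing ⇒ static, increasing ⇒
dynamic) is reported as corroborating evidence.

**Binding constant and stoichiometry.** The double-logarithmic plot

    lg[(F0 − F)/F] = lg Ka + n·lg[Q]

gives the apparent binding constant Ka and binding-site number n.

**Van't Hoff thermodynamics.** From Ka at several temperatures,

    ln Ka = −ΔH/(R·T) + ΔS/R,   ΔG = ΔH − T·ΔS,   R = 8.314 J·mol⁻¹·K⁻¹

ΔG < 0 means spontaneous binding, and the (ΔH, ΔS) sign quadrant is read
with the Ross–Subramanian rules (+,+ hydrophobic; −,+ electrostatic; +,−
electrostatic+hydrophobic; −,− van der Waals + hydrogen bonds).

**Synchronous fluorescence.** Series at excitation–emission offsets of
15 nm (tyrosine) and 60 nm (tryptophan) are summarized by per-concentration
peak positions, intensity declines relative to the ligand-free spectrum,
and a red/blue shift call.

**CD deconvolution.** A far-UV spectrum is modelled as a nonnegative linear
combination of four reference components (α-helix, β-sheet, β-turn, random
coil), solved with `scipy.optimize.nnls` and renormalized to the simplex.
The shipped basis is synthetic (parametric curves with the canonical band
positions), suitable for mixture recovery and composition tracking; a
measured basis can be supplied by CSV.

**Antioxidant assays.** ABTS rate (A0−A1)/A0×100, DPPH rate
(Ab−At−Ac)/Ab×100, FRAP reducing power At−A1−A0, each converted to mg/L
Trolox equivalents (TEAC) through an OLS standard curve.

## Worked example

Generate a synthetic study (three temperatures, 0–26.7 μM ligand ladder,
1% noise) and run the full analysis:

```
python analysis/01_simulate.py
python analysis/02_fit_quenching.py
```

which prints

```
 temperature_K  ksv_per_M  kq_per_M_s   r_sv  ka_per_M  n_sites   r_dl
           298  5.125e+04   5.125e+12 0.9999 6.155e+04    1.018 0.9999
           304  4.854e+04   4.854e+12 0.9998 8.317e+04    1.051 0.9996
           310  4.014e+04   4.014e+12 0.9998 4.403e+04    1.009 0.9997

mechanism: static (min Kq 4.01e+12 L/mol/s, Ksv trend decreasing)
```

The recovered Ksv sit within ~2% of the generator's ground truth
(0.50/0.49/0.40 × 10⁵ L·mol⁻¹), every Kq is far above the 2×10¹⁰ diffusion
limit, so the mechanism call is static, and n ≈ 1 indicates a single
binding site. `analysis/03_thermodynamics.py` then fits the Van't Hoff
line (here ΔH < 0 because Ka falls with temperature — see the discrepancy
note it prints), `04`–`06` run the synchronous, CD and TEAC stages. The
same pipeline runs from one entry point on any dataset directory:

```
quenchlab simulate --seed 42 --out-dir data/
quenchlab report --data-dir data/ --out report.json --markdown report.md
```

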