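# Methods

## Models and procedures

**Quenching analysis.** Fluorescence read-outs are reduced to per-step
intensities either at each spectrum's own emission maximum (default) or at a
fixed wavelength (e.g. 347 nm for site-marker comparisons). A positive
`bandwidth` averages the signal over ±bandwidth nm around the read position;
because every titration step shares the emission band shape, any such linear
read-out is proportional to the band amplitude, so all intensity *ratios*
(and hence K_SV, K_a, n) are invariant to the choice while point noise is
suppressed by √m for m averaged grid points. Band-averaged reading is the
recommended mode for noisy spectra and is what the acceptance study uses
(±25 nm, roughly the band σ).

The Stern–Volmer regression is unweighted OLS of F₀/F on [Q] over the
quencher-present points, with a *fitted* intercept: forcing the line through
1 would hide calibration offsets that the correlation coefficient is meant
to reveal. k_q = K_SV/τ₀ exactly; τ₀ defaults to 10⁻⁸ s, the canonical
single-tryptophan protein lifetime scale, and is configurable. Mechanism
classification uses strict monotonicity of K_SV across ≥ 2 temperatures;
no k_q-threshold rule is applied by default, but the fit can annotate
whether k_q exceeds the diffusion-controlled limit (2×10¹⁰ M⁻¹s⁻¹).

The double-log fit regresses log₁₀((F₀−F)/F) on
log₁₀([L_T] − (F₀−F)[P_T]/F₀). Points with F ≥ F₀ (apparent enhancement —
noise) or a non-positive free-ligand term are dropped with a logged warning
rather than failing the fit; at least three points must survive. A
non-positive slope is flagged on the result instead of raising, since it is
a legitimate (if unphysical) regression outcome the caller should see.

**Thermodynamics.** ln K_a is regressed on 1/T (OLS); ΔH = −R·slope,
ΔS = R·intercept with R = 8.314 J mol⁻¹ K⁻¹. ΔG is computed from the fitted
ΔH and ΔS — not from −RT ln K_a — so the identity ΔG ≡ ΔH − TΔS holds
exactly in every report; the per-temperature difference
|−RT ln K_a − (ΔH − TΔS)| is emitted as a consistency diagnostic (it equals
the regression residual scaled by RT). Force classification follows the
Ross–Subramanian sign rules with a configurable near-zero band for ΔH
(default 4 kJ/mol ≈ RT) inside which the electrostatic clause applies
regardless of sign.

**Inner-filter correction.** The scalar form of the correction is the
default: A_ex at the excitation wavelength, A_em read once per step at the
emission maximum of the ligand-free spectrum and held fixed across the
titration. A point-wise mode (A_em per emission wavelength) is available
for strongly sloped absorbance. The absorbances are the plain absorbances
of each titration solution.

**CD.** The printed-units form MRE = θ·MRW/(10·c·l) (θ in mdeg, c in
mg/mL, l in cm, MRW in Da, default 110) is the default because it is the
only form that yields deg·cm²·dmol⁻¹ from those units; an alternate
molar-concentration × residue-count form is provided
(`mre_from_ellipticity_molar`). Helix percentages from the 208 nm two-point
estimator are clamped to [0, 100] for reporting, with the raw (unbounded)
value retained, since the linear estimator has no intrinsic bounds.

**Peak finding.** Grid maximum with ties broken to the smallest abscissa;
optional parabolic refinement through the maximum and its neighbours, on by
default only for voltammetry where peaks are broad relative to the sampling
step. Synchronous shift tables use the sign convention
shift = position(step) − position(step 0), so blue shifts are negative;
height changes are signed percentages of the step-0 height.

**EEM peak tables.** Cells within ±halfwidth (default 15 nm) of the
first-order (λ_em = λ_ex) or second-order (λ_em = 2λ_ex) Rayleigh lines are
masked; remaining cells that are strict local maxima over their unmasked
8-neighbourhood and positive are reported, ordered by descending intensity.
Ridge shoulders just outside the mask can appear as weak entries; consumers
take the top peaks, which the round-trip tests show are undisplaced by the
masking to within one grid step.

## Synthetic data

The generator emulates a serum-albumin titration as performed on a
spectrofluorometer: 3 μM protein, excitation 280 nm, a Gaussian tryptophan
emission band centred at 347 nm (σ = 28 nm), ligand from 0 to 80 μM in
10 μM steps, temperatures 287/298/307 K. Two mechanisms are available:
`dynamic` applies F(Q) = F₀/(1 + K_SV·Q) directly; `static_binding` defines
F per step implicitly through the depletion-corrected double-log isotherm,
solved by fixed-point iteration to 10⁻¹² of F₀ (error after 10⁴
iterations), which makes the double-log estimator *exactly* consistent with
the generator — there is no independent binding isotherm to emulate, so the
generator adopts the estimator's own model. Optional inner-filter
attenuation multiplies by 10^(−(A_ex+A_em)/2) with absorbances from
configurable ligand molar absorptivities, and matching absorbance spectra
are attached so the correction inverts the effect exactly. Gaussian noise
(relative to the F₀ amplitude) is applied to signal values only, last; a
seed fully determines the output.

What the generator does **not** emulate: photobleaching, instrument drift,
scatter other than idealised Gaussian Rayleigh ridges, pH effects,
multi-site or cooperative binding beyond the Hill-type n, wavelength-
dependent detector response, and correlated noise. Passing round-trip tests
therefore demonstrates the correctness of the estimators' arithmetic under
the stated models, not robustness to every artefact of real instruments.

CD spectra are a helix basis (double minima at 208/222 nm, scaled to
−33,000 at 208 for a pure helix) plus a coil basis (−4,000 at 208), weighted
by the configured helix fraction and converted to mdeg by the inverse MRE
normalisation — by construction the pipeline returns the configured
fraction. EEMs are sums of 2-D Gaussians plus optional Rayleigh ridges;
voltammograms are Gaussian peaks on a linear baseline.

## Numerical choices

- Regressions use `scipy.stats.linregress`; r is reported signed (negative
  for a falling Van't Hoff line).
- CSV serialisation uses 17 significant digits, making read–write–read
  round trips lossless to double precision.
- Concentration column headers are parsed as μM and converted to mol/L
  internally; all equations run in molar units, kelvins and joules.
- Degenerate inputs (constant signal, flat K(T), zero absorbance) resolve
  to documented values: first-point tie-break, ΔH = 0, correction no-op.
- The noise-recovery study runs 200 seeds per mechanism with 1% (of F₀)
  noise; with the ±25 nm band read-out the median relative errors on K_SV
  and K_a are ~0.3–0.5%.

## Problem sizes

Emission spectra use a 1 nm grid over 300–450 nm (151 points, 9 titration
steps); EEMs use the 220–350 nm (5 nm) × 220–500 nm (1 nm) grids
(27 × 281); voltammograms a 2 mV grid over 0.6–1.3 V. These match the
stated acquisition design and keep the full test suite and the acceptance
script in the seconds range.

## Known limitations

- No modified (Lehrer) Stern–Volmer, lifetime fitting or FRET analysis.
- Van't Hoff assumes temperature-independent ΔH and ΔS (no ΔCp term);
  only regression standard errors are propagated, not raw-spectrum noise.
- CD analysis is the two-point 208 nm estimator, not a full deconvolution
  (CONTIN/SELCON-class methods are out of scope).
- Vendor binary formats are not read; the CSV dialect is fixed.
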