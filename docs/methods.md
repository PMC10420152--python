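# Methods

This note documents the models behind `albind`, the defaults and
numerical choices, what the synthetic generators do and do not emulate,
and the known limitations.

## Quenching and binding model

Intrinsic protein fluorescence (tryptophan emission, band near 337 nm) is
quenched by a bound or colliding ligand. The package fits two standard
laws to inner-filter-corrected peak intensities:

- **Stern–Volmer**: F₀/F = 1 + K_SV[Q] = 1 + K_q·τ₀[Q]. Fitted as an
  ordinary least-squares line *with a free intercept*; K_SV is the slope.
  Pinning the intercept at 1 would silently absorb inner-filter
  under-correction; instead an intercept deviating from 1 by more than 5%
  raises a data-quality warning. K_q = K_SV/τ₀ holds exactly in every
  result record; τ₀ defaults to 10⁻⁸ s (typical unquenched tryptophan
  lifetime) and is overridable.
- **Double-logarithm isotherm**: log₁₀[(F₀−F)/F] = log₁₀K_a + n·log₁₀[Q],
  with [Q] in mol/L throughout, so K_a = 10^intercept is in M⁻¹. The
  logarithm is base 10 — the antilog-intercept convention of this
  literature. Points with F ≥ F₀ carry no quenching signal on the log
  scale; they are excluded and counted, and excluded + used always equals
  the number of nonzero concentrations supplied. The fit is invariant to
  common rescaling of all intensities. The fitted n is reported as-is; it
  is a Hill-type cooperativity index and is *not* rounded to an integer
  site count.

Peak intensities are read at the fixed grid point of the ligand-free
spectrum's emission maximum, for every member of the titration — this
avoids conflating genuine band shifts with quenching. Lookup is
nearest-grid-point without interpolation: at the ≤ 1 nm grids of this
domain, interpolation would change nothing measurable while making
results depend on the interpolant. Duplicate concentrations are averaged
before fitting (equivalent to OLS on replicates, cleaner reporting).

The inner-filter correction is F_cor = F_obs·exp[(A_ex + A_em)/2]; the
absorbances are the total system absorbances at the excitation and
emission wavelengths (Beer–Lambert, 1 cm cell by default).

**Mechanism classification.** Static evidence: every K_q exceeds the
diffusion-limited 2×10¹⁰ L·mol⁻¹·s⁻¹. Dynamic evidence: K_SV strictly
increases with temperature. Both → mixed; one → that mechanism. The rule
table leaves the (low K_q, non-increasing K_SV) cell open; the package
returns *dynamic* there — a quenching rate at or below the diffusion
limit is itself dynamic evidence — with an ambiguous-trend warning. A
single-temperature verdict uses the K_q magnitude alone and is flagged
low-confidence.

## Van't Hoff thermodynamics

ln K is regressed on 1/T by ordinary least squares: ΔH⁰ = −slope·R,
ΔS⁰ = intercept·R, with R = 8.314 J·mol⁻¹·K⁻¹, and
ΔG⁰(T) = ΔH⁰ − T·ΔS⁰ evaluated at each design temperature. K here is the
association constant K_a from the double-log fit. Two temperatures give
an exact line (zero residual) and are flagged. Temperature-dependent ΔC_p
variants are out of scope. Force classification follows the
Ross–Subramanian sign rules — (−,−) hydrogen bonding/van der Waals,
(+,+) hydrophobic, (−,+) electrostatic; the (+,−) quadrant is outside the
rule table and reported *unclassified* rather than guessed.

## Förster energy transfer

The overlap integral J = ΣF(λ)ε(λ)λ⁴Δλ / ΣF(λ)Δλ is a discrete sum over
the donor grid with λ expressed in cm and ε in L·mol⁻¹·cm⁻¹, giving J in
cm³·L·mol⁻¹ — the only unit convention under which the prefactor in
R₀⁶ = 8.8×10⁻²⁵·K²·N⁻⁴·φ·J is standard. The acceptor absorbance is
converted to ε = A/(c·l) and linearly interpolated onto the donor grid
(zero outside its support): the donor emission defines the weighting
measure. Δλ is the local grid spacing (`np.gradient`), so non-uniform
grids are handled; on smooth spectra the sum agrees with trapezoid
quadrature to well under 0.1%. Defaults K² = 2/3 (freely rotating
dipoles), N = 1.336 (aqueous buffer), φ = 0.118 (tryptophan in albumin),
all overridable. E = 1 − F/F₀ and r = R₀(1/E − 1)^{1/6} are exact
inverses of E = R₀⁶/(R₀⁶+r⁶); distances under 8 nm are flagged as
non-radiative transfer.

When both an overlap-derived R₀ and a user-supplied R₀ are available they
can disagree (published J/R₀ pairs are not always mutually consistent);
the package reports both — `R0_nm` drives the distance, `R0_from_J_nm`
is kept alongside — and does not attempt to reconcile them.

## Amide-I deconvolution

The amide-I envelope (restricted to 1600–1700 cm⁻¹ after removing a
linear baseline anchored at the interval endpoints) is modelled as a sum
of Gaussian component bands. Band shape is a deliberate choice — the
field uses Gaussian, Lorentzian and Voigt variants interchangeably — and
matches the synthetic generator, which keeps recovery tests well-posed.

Initialization: candidate centers are minima of the second derivative of
a smoothed copy (quadratic Savitzky–Golay, 11 cm⁻¹ window). Two
robustness filters apply: candidates closer than 6 cm⁻¹ to a stronger
candidate are discarded (real amide-I components sit ≥ ~8 cm⁻¹ apart;
closer minima are derivative noise), and a candidate needs prominence of
at least 1% of the strongest curvature peak. The nonlinear refinement
(lmfit, least squares) then constrains each center to ±5 cm⁻¹ of its
initial position and — by default — shares one common width across all
components. Both constraints address the same failure mode: overlapping
Gaussian mixtures are ill-posed with fully free parameters, and a weak
component migrating across the window redistributes area between
structure classes without improving the fit. Shared bandwidth is a
standard regularization in amide-I curve fitting; set
`share_width=False` to release it. Bands whose center still leaves
[1600, 1700] are dropped with a warning and the remainder refitted.

Assignment uses left-closed right-open intervals extended to cover
[1600, 1700] completely: β-sheet [1600, 1640), random coil [1640, 1650),
α-helix [1650, 1658), β-turn [1658, 1700]. The 1658–1660 sliver, not
claimed by any textbook range, goes to β-turn for deterministic total
coverage. Class fractions are class area over total area and are
renormalised to sum to exactly 1. Published composition tables sometimes
swap row labels relative to these wavenumber definitions; the package
always reports by range.

On synthetic seven-band envelopes (component σ = 4.5 cm⁻¹, realistic
areas) the full auto pipeline recovers class fractions to < 1 point
noiseless and < 2 points at 1% multiplicative noise. Recovery degrades
intrinsically as components broaden: beyond σ ≈ 6 cm⁻¹ neighbouring
bands merge in the second derivative and an explicit `n_bands` is needed.

## CD helix content

MRE = θ_obs(mdeg)/(10·C_p·n·l) with the path length in cm (1 mm → 0.1
cm; only this convention gives MRE magnitudes ~10⁴, consistent with the
helix anchors), then α-helix% = (−MRE₂₀₈ − 4000)·100/29000, clamped to
[0, 100] with clamping logged. Defaults C_p = 2×10⁻⁶ M, n = 585 residues
(HSA), l = 1 mm. Basis-set CD deconvolution (CDSSTR/SELCON) is out of
scope.

## Peak-shift tracking

Within a user window, each spectrum's peak is the argmax refined by a
parabola through the three surrounding grid points, so sub-grid shifts
(e.g. a 2 nm drift reported from a 0.5 nm grid) are resolved;
the refinement is equivariant under axis translation. A spectrum whose
in-window maximum sits on the window edge has no local maximum there and
is flagged and excluded. The intensity trend is a strict all-pairs
monotonicity verdict (every later intensity below every earlier one →
decreasing), not an endpoint comparison.

## Synthetic generators and what they show

`generate_titration` produces Gaussian emission bands (center 337 nm,
σ = 25 nm, F₀ = 1000 a.u. by default) whose noiseless corrected peak obeys
the mixed law F₀/F = (1 + K_D[Q])(1 + K_a[Q]^n); observed spectra are
attenuated by exp[−(A_ex+A_em)/2] with A = ε[Q]·1 cm so the standard
correction inverts the attenuation exactly. Recovery fixtures use pure
regimes (one factor off) because the two laws are fitted independently.
Noise is i.i.d. multiplicative Gaussian per intensity sample
(photomultiplier shot noise is signal-proportional at these levels); a
fixed seed gives bit-identical output.

The recovery benchmark (20 parameter sets: K_a ∈ {10⁴, 3×10⁴, 10⁵} M⁻¹ ×
n ∈ {0.85…1.25}, plus five K_SV sets; 8 nonzero concentrations; 1%
noise) places concentrations geometrically so K_a[Q]^n spans 3–1000,
i.e. the titration brackets its own binding transition. That design
choice is what makes a 5% K_a recovery achievable: K_a is the isotherm's
value at log[Q] = 0, several decades outside any physically realistic
concentration range, so its error is dominated by extrapolation leverage,
which shrinks as the sampled span widens and the quenching deepens. A
titration confined to weak quenching (F₀/F ≲ 1.2, as in many real
experiments) cannot determine K_a to 5% at 1% intensity noise — a
limitation of the measurement, not of the estimator.

What the generators do **not** emulate: wavelength-dependent instrument
response, scattering baselines, temperature-dependent band shapes,
correlated (1/f) noise, and ligand depletion (free [Q] is taken as total
[Q]). Passing recovery tests therefore demonstrates correctness of the
inference chain under the stated noise model, not robustness to every
instrument artefact.

## Degenerate inputs and tie-breaks

Nearest-grid-point ties break toward the lower index. Duplicate
concentrations are averaged. A featureless amide-I spectrum seeds a
single band at its maximum. Stern–Volmer with a negative fitted slope
warns (flag `negative_Ksv`) rather than raising — the record stays
inspectable. Fits with fewer than the minimum usable points (3 for the
line fits, 2 temperatures for Van't Hoff) raise `InsufficientDataError`.

## Pipeline

`run_study` executes each configured stage independently and isolates
failures — the assays are experimentally independent, so a corrupt FT-IR
file must not cost the thermodynamics. All randomness (simulation only)
flows from the single config seed; analysis stages are deterministic.
Reports are JSON with units embedded in field names.

## Sizes and runtimes

The default suite and the acceptance script run in seconds on one CPU:
the line fits are closed-form, the only nonlinear steps are the amide-I
band fits (~100 points, ≤ 8 components, < 1 s each). The recovery
benchmark uses 20 quenching titrations of 9 spectra × 201 wavelengths
and three noisy amide-I envelopes of 141 points.
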