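# albind

Spectroscopic inference of small-molecule binding to serum albumin.

When a drug or pesticide binds human serum albumin (HSA) — the main
carrier protein of blood plasma — the event leaves quantitative traces in
solution spectra: the protein's intrinsic tryptophan fluorescence is
quenched, its UV-vis bands shift, its amide-I infrared envelope and CD
ellipticity change shape. `albind` turns those traces into binding
parameters. It is written for the people who produce such data —
pesticide toxicologists, pharmacologists, biophysical chemists — and
covers the complete standard analysis chain:

- **Fluorescence quenching** — inner-filter correction
  F<sub>cor</sub> = F<sub>obs</sub>·exp[(A<sub>ex</sub>+A<sub>em</sub>)/2];
  Stern–Volmer fit F₀/F = 1 + K<sub>SV</sub>[Q] = 1 + K<sub>q</sub>τ₀[Q];
  mechanism classification (dynamic / static / mixed) from the K<sub>q</sub> ≷
  2×10¹⁰ L·mol⁻¹·s⁻¹ diffusion limit and the temperature trend of K<sub>SV</sub>.
- **Binding constants** — double-logarithm isotherm
  log[(F₀−F)/F] = log K<sub>a</sub> + n·log[Q].
- **Thermodynamics** — Van't Hoff fit ln K = −ΔH⁰/RT + ΔS⁰/R,
  ΔG⁰ = ΔH⁰ − TΔS⁰, and binding-force classification from the signs of
  ΔH⁰/ΔS⁰ (Ross–Subramanian rules).
- **FRET distance** — overlap integral J = ΣFελ⁴Δλ/ΣFΔλ, critical
  distance R₀⁶ = 8.8×10⁻²⁵K²N⁻⁴φJ, efficiency E = 1 − F/F₀ =
  R₀⁶/(R₀⁶+r⁶), donor–acceptor distance r.
- **Secondary structure** — amide-I (1600–1700 cm⁻¹) Gaussian band
  deconvolution with class assignment by band center (β-sheet 1610–1640,
  random coil 1640–1650, α-helix 1650–1658, β-turn 1660–1700 cm⁻¹), and
  CD helix content via MRE₂₀₈: α-helix% = (−MRE₂₀₈−4000)·100/29000.
- **Peak-shift tracking** — sub-grid red/blue-shift detection and strict
  monotone intensity trends for UV-vis and synchronous-fluorescence series.
- **Synthetic data** — generators for all of the above with known ground
  truth, so every analysis stage is testable without instrument data.

The fit-shaped operations are scikit-learn-style estimators
(`SternVolmerRegression`, `DoubleLogBinding`, `VantHoffRegression`,
`AmideIDeconvolution`) with plain-function wrappers; everything is also
reachable from the `albind` command line.

## Worked example

```python
import numpy as np
from albind import (QuenchingGroundTruth, generate_titration, titration_design,
                    analyze_titration, vant_hoff_fit, analyze_fret)

# a synthetic titration with known truth: Ka = 3e4 M⁻¹, n = 1.05, 1% noise
gt = QuenchingGroundTruth(Ka_per_M=3e4, n_sites=1.05, noise_sd_rel=0.01, seed=42)
series = generate_titration(gt, titration_design(3e4, 1.05), temperature_K=296.0)
sv, binding = analyze_titration(series)
print(f"Ka  = {binding.Ka_per_M:.3e} M^-1   n = {binding.n_sites:.3f}")

# Van't Hoff chain on measured binding constants at three temperatures
thermo = vant_hoff_fit([296.0, 303.0, 310.0], [4923.0, 664.0, 158.0])
print(f"dH = {thermo.dH_kJ_per_mol:.2f} kJ/mol   dS = {thermo.dS_J_per_mol_K:.2f} J/(mol K)")
print(f"dG(310 K) = {thermo.dG_kJ_per_mol_by_T[310.0]:.3f} kJ/mol   forces: {thermo.force_class.value}")

# energy-transfer distance from a 3.67% donor-intensity drop
fret = analyze_fret(F=0.9633, F0=1.0, R0_nm=1.170)
print(f"E = {fret.E*100:.2f}%   r = {fret.r_nm*10:.2f} A   nonradiative: {fret.nonradiative}")
```

prints

```
Ka  = 3.001e+04 M^-1   n = 1.047
dH = -187.61 kJ/mol   dS = -563.79 J/(mol K)
dG(310 K) = -12.833 kJ/mol   forces: hbond_vdw
E = 3.67%   r = 20.17 A   nonradiative: True
```

The recovered K<sub>a</sub> and n sit within the noise of their ground
truth. The Van't Hoff line over the three binding constants is strongly
exothermic with a large entropy penalty — the (ΔH⁰ < 0, ΔS⁰ < 0)
quadrant, i.e. hydrogen bonding and van der Waals contacts dominate — and
binding stays spontaneous at body temperature (ΔG⁰ < 0). A 3.67%
transfer efficiency at R₀ = 1.170 nm places the ligand 20.17 Å from the
donor tryptophan, well inside the 8 nm limit for non-radiative energy
transfer.

The same chains from the shell:

```bash
albind simulate --out-dir demo --seed 1      # synthetic study + YAML config
albind run --config demo/study.yaml          # full multi-stage report (JSON)
albind fret --f-ratio 0.9633 --r0 1.170      # one stage at a time
```

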