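# quadbind

Quantitative binding analysis for protein–nucleic-acid interactions probed
by NMR titration, isothermal titration calorimetry (ITC) and circular
dichroism (CD) — built around the workflow used to characterise how the
RGG-box and UP1 domains of hnRNPA1 recognise and unfold TERRA RNA
G-quadruplexes.

## Who this is for

Biophysicists and structural biologists who titrate a labelled protein (or
a folded RNA/DNA) with its partner and need dissociation constants and
thermodynamics out of three standard experiments:

- **2D ¹H–¹⁵N HSQC titrations** in the fast-exchange regime: per-residue
  chemical shift perturbations (CSPs), apparent per-residue K_d's, and a
  global shared-K_d fit.
- **One-site ITC**: n, K_d and ΔH from per-injection heats, with ΔG and
  TΔS derived, heat-of-dilution correction, and Wiseman-c diagnostics.
- **CD spectroscopy of G-quadruplexes**: molar ellipticity per residue,
  relative foldedness at the 262 nm parallel-G4 band during a protein
  titration, percent-decrease comparisons between constructs, and
  two-state van't Hoff melting (T_m) fits.

Every analysis stage has a matched synthetic-data generator with known
ground truth, so the full pipeline is testable end to end without
instrument data.

## The models

**CSP titration.** The combined shift perturbation per residue is

δ_obs = √( (Δδ_H)² + (Δδ_N / 5)² )

and, under fast exchange with 1:1 binding and ligand depletion,

δ_obs = Δδ_max · ( [P]_T + [L] + K_d − √( ([P]_T + [L] + K_d)² − 4[P]_T[L] ) ) / (2[P]_T)

where [P]_T is the total protein concentration and [L] the total ligand
added at each step. The global fit shares one K_d across residues with a
free Δδ_max per residue; uncertainty comes from the asymptotic covariance
plus an optional residue-resampling bootstrap.

**ITC.** The single-site Wiseman model with overflow-cell (ΔV/2V₀)
concentration bookkeeping: the cumulative heat after injection *i* is
Q_i = n[M]_i V₀ ΔH f_i with f_i the fraction of sites occupied from the
same exact 1:1 quadratic; differential heats are corrected for the
displaced volume and normalised per mole of injectant. ΔG = RT ln K_d
(1 M standard state, R = 1.987×10⁻³ kcal mol⁻¹ K⁻¹) and TΔS = ΔH − ΔG.

**CD melting.** θ(T) = (θ_f + m_f T)·f(T) + (θ_u + m_u T)·(1 − f(T)) with
folded fraction f from a two-state van't Hoff equilibrium; f(T_m) = ½.

See `docs/methods.md` for assumptions, defaults and numerical choices.

## Worked example

```python
import numpy as np
from quadbind import (CspSimConfig, gen_csp_experiment, compute_csps, fit_global_kd,
                      ItcSimConfig, gen_itc_experiment, build_isotherm, fit_one_site,
                      derive_thermodynamics)

# HSQC titration: 14 residues of a 138 uM 15N-labelled protein titrated
# with RNA to 3x molar excess; true Kd = 11 uM
series = gen_csp_experiment(CspSimConfig(seed=42))
res = fit_global_kd(compute_csps(series), series, n_bootstrap=200, random_state=42)
print(f"global Kd = {res.kd:.1f} +/- {res.kd_bootstrap_stderr:.1f} uM (bootstrap)")
print(f"mean of individual Kds = {res.individual_kd_mean:.1f} uM")

# ITC: 20 x 2 ul of 200 uM protein into 5 uM RNA, one-site fit
schedule, heats = gen_itc_experiment(ItcSimConfig(seed=42))
fit = fit_one_site(build_isotherm(schedule, heats))
thermo = derive_thermodynamics(fit, temperature=298.15)
print(f"n = {fit.n:.2f}, Kd = {fit.kd:.2f} uM, dH = {fit.dH:.1f} kcal/mol")
print(f"dG = {thermo.dG:.2f} kcal/mol, TdS = {thermo.TdS:.2f} kcal/mol, c = {fit.c:.0f}")
```

prints

```
global Kd = 12.3 +/- 1.2 uM (bootstrap)
mean of individual Kds = 13.2 uM
n = 0.84, Kd = 0.84 uM, dH = -40.6 kcal/mol
dG = -8.29 kcal/mol, TdS = -32.29 kcal/mol, c = 5
```

The CSP experiment was generated at K_d = 11 μM with 0.005/0.025 ppm peak
noise — the global fit recovers it within its bootstrap error, and the
mean of the 14 noisier per-residue fits sits nearby. The ITC run was
generated at (n = 0.82, K_d = 0.92 μM, ΔH = −41.88 kcal/mol) with 2% heat
noise; the fit recovers all three, the derived ΔG/TΔS satisfy
ΔG = ΔH − TΔS exactly, and c = 5 means the isotherm shape constrains the
parameters adequately (fits with c < 1 are flagged).

## Command line

```bash
quadbind simulate --modality itc --seed 7 --outdir run/
quadbind itc-fit --data run/run.csv --out fit.json
quadbind simulate --modality csp --seed 7 --outdir csp/
quadbind csp-fit --config csp/run.yaml --global --out csp.csv
quadbind cd-melt --trace melt.csv --out tm.json
quadbind cd-fold --series scans/ --out curve.csv
quadbind cd-compare --ref up1.csv --alt up1rgg.csv --at 25
```

All file formats are plain text (Sparky-style `.list` peak lists, CSVs
with key/value comment headers); see the module docstrings in
`src/quadbind/io.py`.

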