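# Methods

This note records the models, defaults and numerical choices behind
quadbind, and what the synthetic generators do and do not emulate.

## Binding model

All fitting rests on one primitive: the exact 1:1 ligand-depletion
("quadratic") isotherm. For total protein P, total ligand L and
dissociation constant K_d (all in one shared concentration unit, μM
canonically), the fraction of protein bound is

f = (P + L + K_d − √((P + L + K_d)² − 4PL)) / 2P.

No excess-ligand (Langmuir) approximation is made anywhere: in an HSQC
titration the labelled protein (≈138 μM here) is comparable to or exceeds
the ligand at early steps, and in ITC the cell macromolecule is depleted
as the syringe titrant binds. The implementation evaluates the
numerically stable conjugate form f = 2L / (P + L + K_d + √(…)), which
avoids catastrophic cancellation when f is small, and clamps the
discriminant at zero (it can reach −ε by round-off when P ≈ L and
K_d → 0; tolerance well below 10⁻¹²). In the P → 0 limit this reduces to
the Langmuir form L/(L + K_d) to better than 10⁻⁶ relative; tests verify
agreement with a brute-force mass-balance root solve to 10⁻¹⁰ over 1,000
random parameter triples.

Thermodynamic identities use a 1 M standard state with
R = 1.987×10⁻³ kcal mol⁻¹ K⁻¹ and a default temperature of 298.15 K
(experiments at 25 °C): ΔG = RT ln(K_d/1 M), TΔS = ΔH − ΔG. Both 298 K
and 298.15 K reproduce the packaged reference table to its printed
precision; 298.15 K is adopted. One TΔS entry of that table (UP1:TERRA-24)
is inconsistent with its own ΔH − ΔG by ~16 kcal/mol — a typographical
error in the source; the dataset flags it (`tds_consistent`) and the
identity tests treat it as such.

## CSP titration fitting

The combined CSP is δ_obs = √(Δδ_H² + (Δδ_N/5)²); the ¹⁵N scaling factor
5 is the conventional weighting for amide nitrogen dispersion and is
exposed as a parameter. Shifts are referenced to the ligand-free first
point, which makes the statistic invariant to any uniform reference
offset. Residues missing at any step are dropped with a warning, not an
error.

Fitting is uniform-weight least squares of Δδ_max · f(P, L, K_d) against
δ_obs (no per-point errors are available from peak lists). The global fit
shares one K_d with a free Δδ_max per residue; per-residue fits are the
single-column special case and agree with the global fit exactly when
given one residue. Initialisation: Δδ_max⁰ = max observed CSP, K_d⁰ = the
ligand concentration at half-maximal CSP of the strongest responder
(linear interpolation). Bounds: K_d ∈ (10⁻³, 10⁵) μM, Δδ_max ∈ (0, 5) ppm;
a fitted K_d within 10⁻⁶ of a bound, a non-converged optimiser, or an
all-zero trajectory each set an explicit flag on the result instead of
failing silently. "Global fit" is implemented as simultaneous shared-K_d
regression — the standard practice — with the mean of the individual
K_d's reported alongside as a secondary statistic, since plain averaging
is the other defensible reading of the phrase. Because ~14 residues is a
small sample for asymptotic standard errors, a residue-resampling
bootstrap (seeded, off by default, 200–500 replicates typical) is offered
for the global-K_d uncertainty.

Ligand concentrations are taken as supplied per step; no automatic
dilution correction is applied to the protein concentration (the
per-step protein column lets users supply dilution-corrected values).
Only the fast-exchange 1:1 regime is modelled — no exchange-broadening or
lineshape analysis, and peak matching across steps is by identical label
(automatic minimum-distance tracking is out of scope).

Perturbed/unperturbed classification offers three rules on the final-point
CSP: a population rule (mean + k·SD with an absolute floor, default
0.01 ppm) suited to a minority of responders; an iteratively trimmed
variant of the same (the conventional CSP-cutoff recipe); and a pure
absolute-floor rule. No population statistic can isolate responders when
they are the majority of residues — in that regime the absolute rule is
the right tool, and the tests exercise each rule in its regime.

## One-site ITC

Concentration bookkeeping uses the conventional overflow-cell
approximation: at cumulative injected volume ΔV into cell volume V₀,
[M] = M₀(1 − ΔV/2V₀)/(1 + ΔV/2V₀) and [X] = X_s(ΔV/V₀)/(1 + ΔV/2V₀).
This matches the vendor-software family and agrees with an exact
stepwise-dilution recursion to <1% for 40 μl injected into 200 μl (the
tests check this against the exact oracle). Cell volume is not a quantity
the reference experiments report; the default is 200 μl (iTC200 class)
and it is configurable.

Predicted heats: Q_i = n[M]_i V₀ ΔH f_i with f_i the occupied-site
fraction from the quadratic isotherm (site concentration n[M]_i, titrant
[X]_i); ΔQ_i = Q_i − Q_{i−1} + (dV_i/V₀)(Q_i + Q_{i−1})/2 adds back the
heat content of the displaced volume; normalisation is per mole of
injectant, plus a constant baseline (residual dilution heat). All four
parameters (n, K_d, ΔH, baseline) float, initialised from the molar ratio
at the steepest heat change (n⁰), the first-minus-last heat (ΔH⁰) and the
cell concentration (K_d⁰). Standard errors are asymptotic (from the
least-squares covariance); support-plane errors are not implemented. The
Wiseman parameter c = n·[M]/K_d is reported and c < 1 raises a
``low_c`` flag — below that the isotherm is too shallow to determine n
and K_d independently with confidence, which is exactly the situation for
the weak RGG-box:TERRA-24 interaction (c ≈ 0.6 at 5 μM cell).

Heat-of-dilution correction subtracts either a matched titrant-into-buffer
control run or the mean of the last k (default 3) saturated injections.
The tail average also absorbs any residual binding heat still present at
the end of the titration; for incompletely saturated runs the control
mode is the better choice. First-injection discard is available but off
by default.

Pre-integrated per-injection heats are the primary input; a secondary
raw-thermogram path integrates a (time, power) trace per injection with a
linear baseline drawn between the mean power levels just before
consecutive injections (anchored at the averaging-window midpoints so a
drifting baseline stays unbiased) and the trapezoidal rule. It assumes
each injection peak relaxes to baseline within the injection spacing.

## CD analysis

Molar ellipticity per residue: [θ] = θ_mdeg/(10·l_cm·c_M·N_res).
Relative foldedness is the plain ratio F(c) = θ₂₆₂(c)/θ₂₆₂(0) at the
parallel-G4 262 nm band, read at the nearest sampled wavelength within
1 nm (no spectral interpolation); values are not clipped, so noise can
push F slightly above 1. A min–max variant against a fully-unfolded
reference spectrum is available behind a flag; the plain ratio is the
default because the underlying normalisation procedure is ratio-shaped
and an unfolded reference is rarely measured. Percent decrease between
constructs is 100·(F_a − F_b)/F_a at a common concentration, linearly
interpolating each curve.

Melting uses the two-state van't Hoff model with sloped linear folded and
unfolded baselines (flat-baseline option for short traces). The folded
fraction is ½ at T_m by construction. T_m is initialised at the extremum
of a Savitzky–Golay-smoothed derivative (window ≈ one sixth of the trace,
used only for initialisation and transition detection — the data are
never smoothed for fitting); a derivative peak at a scan edge or one less
than 5× the median absolute derivative flags ``no_transition``. The fit
is invariant to affine rescaling of the ellipticity axis. Note that for a
stable G4 melting near 80 °C in a 10–100 °C scan, the unfolded baseline
is only marginally sampled; the T_m standard error is then honestly
~0.5–1 °C at 2% amplitude noise, dominated by baseline–T_m correlation
rather than point noise, and single-trace fits scatter accordingly while
replicate medians are accurate to ~0.1 °C.

## Synthetic generators

Each generator forward-simulates the exact model its fitter inverts, so a
zero-noise simulation round-trips to numerical tolerance — the strongest
internal consistency check available — and all randomness flows through a
single mandatory seed (reproducible across runs and platforms).

- **CSP**: each residue receives a reference peak position in the amide
  region and a fixed unit direction in the scaled (Δδ_H, Δδ_N/5) plane,
  drawn once per seed, so its peak moves colinearly across steps — the
  fast-exchange signature. Per-residue Δδ_max defaults to Uniform(0.05,
  0.30) ppm; the design is 138 μM protein at protein:RNA ratios
  0/0.2/0.5/1/2/3; noise is Gaussian per spectral dimension, 0.005 ppm
  (¹H) and 0.025 ppm (¹⁵N) — plausible instrument-class values. Noise is
  applied to the reference point too, so small CSPs acquire the same
  positive (folded-noise) bias real data have.
- **ITC**: the 20 × 2 μl, 200 μM-into-5 μM geometry with defaults at the
  strongest-binding reference parameter set (n = 0.82, K_d = 0.92 μM,
  ΔH = −41.88 kcal/mol); noise is Gaussian per injection with
  σ = max(2% of |heat|, 0.02 μcal); an optional constant dilution heat
  exercises the correction paths.
- **CD**: titration spectra are a parameterised parallel-G4 shape (a
  positive Gaussian band at 262 nm, a trough at 240 nm) scaled by a
  foldedness that decays exponentially to a residual plateau
  (F = 0.1 + 0.9·e^(−c/25 μM) by default); melts use the two-state model
  with T_m = 80.5 °C and ΔH_vH = 45 kcal/mol, a realistic cooperativity
  for an intramolecular RNA G-quadruplex; noise is 1–2% of the band or
  transition amplitude.

What the generators do **not** emulate: peak overlap, broadening or loss
(intermediate exchange), baseline drift and instrument artifacts (ITC
first-injection anomaly must be added by hand, as one test does),
scan-rate hysteresis in melts, or concentration errors. Passing recovery
tests therefore demonstrate correctness of the estimators under the
stated models and noise, not robustness to every pathology of real data.

## Problem sizes

The recovery studies use 20 replicate CSP titrations (14 residues × 6
points each), 50 replicate ITC isotherms (20 injections) and melting
traces of 181 points — comfortably converged for median-based recovery
statements while keeping the whole suite fast.

## Known limitations

- One class of binding sites only; no cooperative, multi-site or
  competitive models, and no intensity-based (peak-height) NMR analysis.
- ITC standard errors are asymptotic; heavy parameter correlation at low
  c is flagged but not resolved (a support-plane or profile-likelihood
  analysis would be the extension).
- CD foldedness assumes the 262 nm band reports G4 content linearly and
  that protein absorbance/scattering does not distort the band.
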