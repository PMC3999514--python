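# Methods

## Model

The package models and analyses a dye-equilibration redox titration. A
cuvette holds one heme protein (couple Fe³⁺/Fe²⁺, electron number n_p,
midpoint potential E_m,p) and one indicator dye (n_d, E_m,d), both defined
as `RedoxSpecies` with oxidized/reduced molar-absorptivity spectra.
Xanthine oxidase injects electrons slowly; spectra are scanned once a
minute; after the titration stabilises, excess dithionite gives the
fully-reduced endpoint.

**Quasi-equilibrium.** Electron exchange between the couples in bulk
solution is assumed fast relative to injection, so at every scan both
couples share one solution potential E. Given cumulative injected electrons
e(t), E is the unique root of the electron balance

    Σ_i n_i C_i f_red,i(E) = e(t),   f_red,i(E) = 1/(1 + exp(n_i F (E − E_m,i)/RT)),

solved by bracketed Brent root finding (the balance is strictly monotone in
E); electron conservation holds to < 1e-9 µM. The boundary pools e = 0 and
e = capacity map to E = ±∞ with exact 0/1 fractions. No protein↔dye rate
constants are modelled; the validity of the quasi-equilibrium assumption on
real data is the user's responsibility.

**Electron injection.** The enzymatic source is abstracted to a profile:
`constant` (default; zero-order turnover at saturating substrate, rate in
µM electrons·min⁻¹) or `exponential_approach` (substrate depletion). Both
are capped at the electron budget and at the total couple capacity. The
default rate delivers the full budget over the first three quarters of the
titration, so the last ~10 min of a default 40-scan run are constant —
matching the stability criterion an operator applies before adding
dithionite. Michaelis–Menten kinetics and O₂-scavenging chemistry
(glucose/glucose oxidase/catalase) are deliberately outside the model; the
simulated cuvette is anaerobic by construction.

**Spectra.** Mixture spectra are Beer–Lambert:
A(λ) = path · Σ_i C_i [(1−f_i) ε_ox,i(λ) + f_i ε_red,i(λ)]. All band shapes
are synthetic package constants (no published extinction coefficients are
reproduced): the ferric heme has a Soret band at 413 nm (σ 11 nm, 0.150
AU·µM⁻¹·cm⁻¹) plus a weak 533 nm band; the ferrous form shifts to 430 nm
with increased amplitude (σ 12 nm, 0.170) plus a 556 nm band. Dyes are a
single Gaussian band (0.08 AU·µM⁻¹·cm⁻¹ peak) in the 500–700 nm window
with a colourless reduced (leuco) form. Protein concentration defaults to
4 µM (Soret absorbance ≈ 0.6, inside the 0.1–1.0 range a practitioner
targets); the dye dose is auto-titrated so its band maximum matches the
protein's Soret maximum, mirroring bench practice. Instrument noise is iid
Gaussian per (λ, t), default sd 0.002 AU; wavelength-correlated drift and
baseline error are not emulated. Temperature enters only through RT/F
(default 298.15 K).

**What passing tests show — and don't.** Because the generator's noise is
iid and its bands are clean Gaussians, parameter-recovery results here
demonstrate the correctness and calibration of the analysis chain, not its
robustness to real-instrument artefacts (drift, scatter, incomplete
anaerobiosis at early scans, dye–protein binding, pH drift).

## Analysis pipeline

1. **Wavelength choice** — within configurable windows (protein 400–420 nm,
   dye 500–700 nm) pick the wavelength maximising |A(first titration scan)
   − A(dithionite endpoint)|; ties to the lower wavelength; no
   interpolation (traces stay exact matrix columns).
2. **Endpoints** — A_ox is the mean of the first k titration scans (k = 1
   default); A_red is the mean of the stable tail of the dithionite block.
   Stability means the trace's range over at least 5 min (the post-dithionite
   constancy criterion; the titration-phase criterion is 10 min) stays within
   a tolerance. The default tolerance is adaptive: 8× an RMS
   successive-difference noise estimate from the block itself, because the
   *range* of ~10 noisy scans routinely reaches several σ and a fixed
   few-mAU tolerance would fail stochastically on perfectly resting data
   (false-failure rate ~6e-5 by Monte Carlo; a noiseless block must be
   exactly constant). A fixed tolerance can be supplied instead.
3. **Fractions** — f_ox(t) = (A(t) − A_red)/(A_ox − A_red); raw values are
   kept unclipped, and clipping exists only for display. The pipeline
   requires |A_ox − A_red| > 5× the trace noise scale.
4. **Pairing/filtering** — keep titration scans with BOTH raw fractions in
   [0.1, 0.9] (log-ratios amplify endpoint noise without bound outside it;
   the window is configurable and reported), emit x = log10(f_ox/(1−f_ox))
   for the dye and y for the protein; ≥ 4 points are required.
5. **Fit** — y = s·x + b with s fixed at n_p/n_d (default; electron counts
   are known chemistry) or free (stoichiometry diagnostic: a fitted slope
   off the theoretical ratio exposes a wrong n). Then
   E_m,p = E_m,d − b·k/n_p with k = RT ln10/F. Ordinary (unweighted) least
   squares: both axes carry comparable noise but no weighting scheme is
   assumed; Deming regression is out of scope. Log base 10 throughout.
6. **Uncertainty** — (a) residual-based SE of b propagated to E_m with a
   Student-t 95% interval; (b) a seeded bootstrap percentile interval.

**Endpoint-aware bootstrap.** Pure case resampling of (x, y) pairs is blind
to the dominant error term of this design: the endpoint absorbances (A_ox
especially, a single noisy scan by default) rescale and shift *every*
fraction of a run coherently, so pair resampling understates the E_m
uncertainty (measured coverage 64/100 under the package's own noise model).
The pipeline's bootstrap therefore combines case resampling (per-point
noise) with one parametric endpoint-error draw per resample — ε_ox ~
N(0, σ̂/√k), ε_red ~ N(0, σ̂/√m) per species, σ̂ estimated from the
dithionite block, log-ratios re-derived via
f′ = (f·ΔA − ε_red)/(ΔA + ε_ox − ε_red) — restoring honest coverage
(91–95/100 across seed batches). Resamples whose perturbed fractions leave
(0, 1) count as failures; more than 10% failures sets a `widened` flag and
emits a warning. The plain case bootstrap remains available by omitting the
endpoint-noise term.

## Defaults that matter

| parameter | default | why |
|---|---|---|
| temperature | 298.15 K | standard assay temperature (25.0 °C) |
| scan cadence / count | 1 min × 40 titration + 10 dithionite scans | typical full titration of ~40 min with an endpoint block |
| wavelength grid | 350–750 nm, 1 nm | common UV-vis acquisition convention; not an instrument fact |
| noise sd | 0.002 AU | typical scan-to-scan photometric noise |
| protein n | 1 | one-electron Fe³⁺/Fe²⁺ couple |
| dye n | 2 | conventional two-electron organic dye couples; explicit, per-run overridable — never silently assumed |
| fraction window | [0.1, 0.9] | standard guard against unbounded log-ratio noise |
| k_ox | 1 | first scan as the oxidized reference; raise for noisy data |
| bootstrap B | 1000 | percentile-interval stability |

All randomness descends from a single user-supplied seed; a seed is
mandatory for any stochastic simulation or bootstrap.

## Validation problem sizes

The repository's validation suite uses: 100 random configurations for the
equilibrium solver against a 0.001 mV grid-search oracle (agreement ≤
0.002 mV); 20 noiseless end-to-end recoveries spanning ±300 mV (identity to
0.01 mV, slope to 0.001); 100 seeded noisy replicates per reference
protein/dye pair with the median recovered E_m compared at the ±2 mV
precision of the reference values; and 100 replicates for bootstrap
coverage (≥ 90/100).

## Known limitations

* Single protein + single dye only; no multi-dye global fits, no three-way
  spectral unmixing (an optional two-component check could be added, but
  the single-wavelength endpoint method is the default and the contract).
* Midpoint potentials are treated as fixed at the run's pH and temperature;
  no Pourbaix/pH-dependence modelling of protein or dye.
* The noisy-replicate medians carry a small residual bias (≲ 0.2 mV at a
  44 mV protein–dye separation) from the nonlinearity of log-ratios in the
  endpoint noise; it is far inside the ±2 mV reporting precision.
* The fully-oxidized reference is the first scan; on real data trace O₂ can
  make the earliest scans imperfectly oxidized. Documented, not modelled.
* Dithionite reduction is rendered instantaneous; the reagent's own
  absorbance and any slow settling are not emulated.
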