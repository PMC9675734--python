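# Methods

`redoxkit` implements the quantitative analysis chain of a single-molecule
study of inter-protein electron transfer (ET) between the redox partners
cytochrome *c*₁ and cytochrome *c* (wild type and a phosphomimetic variant):
electrochemical tunneling spectroscopy, blink conductance, dynamic force
spectroscopy, SPR binding kinetics, and an ionic-environment model of the
aqueous gap between the partners. Every analysis stage is paired with a
synthetic generator that produces data with exactly the statistical
structure the stage assumes, so the whole chain is validated by parameter
recovery rather than by fixtures.

## Distance-decay analysis (`redoxkit.decay`)

**Model.** During probe retraction at fixed bias the tunneling current
decays exponentially from the set point down to a distance-independent
faradaic leakage floor:

    I(z) = A e^{−βz} + I_leak ,

with z the retraction distance (nm) and β (nm⁻¹) the distance-decay
factor. Small β (~1 nm⁻¹) signals long-distance ET through the aqueous
gap; β ≳ 3 nm⁻¹ indicates an abrupt decay over ≤ 3 nm.

**Window selection.** The instrument's exponential-window heuristic is not
published, so the package defines its own, parameter-light rule: the
leakage is estimated as the median of the final 10 % of samples; the fit
window is the contiguous run of points with I > 3·I_leak, skipping the
first two points after feedback-off (transient). Fewer than 8 usable
points raises `NoDecayRegion`. The fit is nonlinear least squares in
linear current space with the leakage free (initialized at the estimate);
if it fails, a log-linear regression on I − I_leak with the leakage fixed
is the fallback. Fits with R² < 0.8 are flagged, never dropped.

**Population model.** Per-curve β values are modelled with 1- and
2-component Gaussian mixtures fitted on the raw values (not a histogram);
BIC selects the component count and all candidate scores are reported.
Group comparisons use the Student (pooled-variance) two-sample t-test with
df = n₁ + n₂ − 2. Gate aggregation reports per-gate mean ± s.d. of β and
the gate of minimum mean β; gate groups with a single curve are dropped.

## Blink analysis (`redoxkit.blinks`)

Feedback-off current–time traces show telegraph-like excursions (blinks)
when a conductive junction forms spontaneously between the tethered
partners. The pipeline:

1. **Baseline** — centered rolling median (default window 0.5 s), robust
   to excursions occupying < 50 % of any window and tracking slow drift.
   Traces whose longest dwells approach half the window need a longer
   window; the estimator does not try to detect this case.
2. **Detection** — hysteresis segmentation: an event is a contiguous run
   above the exit threshold (baseline + k/2·σ) that contains at least one
   sample above the entry threshold (baseline + k·σ), with k = 5 by
   default; σ is the median-absolute-deviation noise of below-threshold
   samples. Events shorter than 3 samples are discarded. A noiseless
   trace (σ = 0) falls back to half-amplitude thresholds. A hidden-Markov
   segmentation would add free parameters without benefit for two-level
   data and is left as future work.
3. **Conductance** — G = I_blink/V_bias expressed in units of the
   conductance quantum G₀ = 2e²/h (77.48 µS, exact CODATA value). The
   default histogram is per-sample (every in-blink sample contributes one
   G value, matching the very large counts of published 2D blink maps);
   per-event plateaus are available. One sample is trimmed at each event
   edge, since partially-risen samples bias the plateau low. The
   main peak is fitted with a local Gaussian (see "peak fitting").
4. **Maps** — events re-timed to a common onset and histogrammed over
   (time, baseline-subtracted current), normalized so the maximum bin is
   100 counts.

## Force spectroscopy (`redoxkit.forcespec`)

**Detection.** The zero-force baseline and force noise come from the
far-retraction tail (last 20 % of samples; median and MAD). A rupture is
a negative (adhesive) excursion that terminates in a discontinuous jump
back to baseline: > 3σ within ≤ 3 samples, returning above the detection
threshold. Two guards reject noise artefacts: the excursion must last ≥ 4
samples and reach 5σ below baseline. The rupture force F_r is a short
linear extrapolation of the pre-jump ramp (less noisy than a single
sample), the rupture length l_r is the separation at the jump, and the
loading rate is the local pre-jump |dF/dt| over 20 samples; the nominal
k_eff·v is available as a fallback and agrees with the local slope on
synthetic data (28 000–224 000 pN·s⁻¹ at 0.5–4 µm·s⁻¹ with
k_eff = 56 pN·nm⁻¹).

**Bell–Evans model.** For a single sharp barrier under constant loading
rate r, the most probable rupture force is

    F* = (k_BT/x_u) · ln( x_u r / (k⁰_u k_BT) ),

with k⁰_u the zero-force unbinding rate and x_u the distance to the
barrier; F* = 0 when the logarithm's argument is ≤ 1 (spontaneous
dissociation outpaces loading). The DFS fit regresses F* on ln r and
inverts exactly: x_u = k_BT/b and k⁰_u = (1/b)·e^{−a/b} for slope b and
intercept a, so the noiseless round trip is the identity. The regime is
*kinetic* iff the slope is positive and significant (p < 0.05); otherwise
*near-equilibrium*, where rebinding outpaces pulling, rupture force is
rate-independent, and the kinetic parameters are undefined. k_BT is
4.114 pN·nm at 298 K.

**Statistics.** Rupture-force distributions report both a local Gaussian
fit of the main histogram peak and the raw arithmetic mean; experimental
distributions are right-skewed, so the two differ and the Gaussian center
is the comparable quantity. (l_r, F_r) contour maps use a Gaussian KDE
with Scott bandwidth.

**Generator.** Rupture forces come either from a truncated Gaussian
(near-equilibrium phenomenology) or from the Bell–Evans first-passage
density sampled through its analytic inverse CDF,
F = ln(1 − ln(U)/c)/a with a = x_u/k_BT, c = k⁰_u k_BT/(x_u r) — exact
dwell statistics, no stochastic-ODE integration. Each sawtooth loads
linearly at k_eff up to the drawn force at the drawn length. Default
contact/retraction geometry: 30 nm span, 2000 points, 5 pN force noise.

## SPR kinetics (`redoxkit.binding`)

The 1:1 Langmuir model has a closed form, so the global fit uses it
directly rather than integrating the ODE:

    association:  R(t) = R_eq(C)(1 − e^{−(k_on C + k_off)t}),
                  R_eq(C) = R_max C/(C + k_off/k_on)
    dissociation: R(t) = R(t_assoc) e^{−k_off (t − t_assoc)} .

k_on, k_off and (by default) R_max are shared across sensograms recorded
at distinct analyte concentrations; per-curve R_max is optional. The fit
is initialized from the log-linear dissociation slope (k_off) and a
k_obs-vs-concentration regression (k_on), and parameter standard errors
come from the fit covariance. K_D = k_off/k_on is always recomputed from
the fitted rates, never stored independently. Mass-transport limitation
is not modelled. Default generator conditions: 5 and 2.5 µM analyte,
300 s association, 600 s dissociation, R_max = 100 RU.

## Ionic environment (`redoxkit.ionfield`)

This channel is a deliberately desk-scale stand-in for the study's
all-atom simulations; it reproduces directions and consistency
relations, not absolute molarities.

- **Density maps** — per-voxel mean ion occupancy over frames converted
  to molarity, c = ⟨N⟩/(N_A V_voxel); the map conserves the mean ion
  count to machine precision. Default voxel 1 Å. Prism averages weight
  partially covered voxels by overlap volume; a 15 × 43 × 20 Å prism has
  the reference volume 12.9 nm³.
- **Electrostatics** — linearized screening (Debye–Hückel superposition
  of Yukawa potentials) in place of a nonlinear Poisson–Boltzmann
  solver: φ(x) = Σ q_i l_B e^{−r_i/λ_D}/r_i in thermal units kT/e, with
  λ_D ≈ 1.36 nm at 50 mM 1:1 salt. Potentials are clamped at a 0.3 nm
  ionic core radius (finite ion size); voxels inside the core are
  flagged NaN. Contours default to 0.2 kT/e (potential) and 0.15 M
  (concentration) spacing.
- **Ion frames** — rejection sampling with Boltzmann weight e^{−qφ(x)};
  the core clamp bounds the weight, and the bound is taken from a dense
  probe grid with a 25 % margin. Acceptance below 1 % raises
  `PathologicalField`. The number of ions per frame is
  round(c_bulk N_A V_box): concentrations are therefore quantized for
  small boxes, and the "bulk" reference for consistency checks is the
  realized mean count, not the nominal concentration. Water is an
  implicit dielectric continuum — frames have Boltzmann structure but no
  solvation shells, finite-size ion correlations, or protein surface
  detail, so passing tests validate the estimators, not solvent physics.
- **Boltzmann consistency** — `boltzmann_consistency_slope` regresses
  ln(c/c_bulk) on qφ after aggregating voxels into potential-quantile
  bins inside a moderate-field window (default −0.5 < qφ < −0.05 kT):
  per-voxel regression is attenuated by Poisson noise, and voxels close
  to a charge mix strong within-voxel field variation into the bin mean.
  Equilibrated frames give a slope of −1 ± 0.1.
- **Association rates** — a centrosymmetric two-body reduction of
  rigid-body Brownian dynamics. Trajectories start on a b-surface and
  run under an isotropic interaction potential U(r) (kT units) with
  adaptive Euler–Maruyama steps (rms step 5 % of the distance to the
  absorbing surface, capped at 0.35 nm, shrunk where |∇U| is large; a
  step that would traverse ≳ kT raises `StepTooLarge`). The
  recombination probability P(d) of reaching separation ≤ d before
  escaping past the q-surface is converted to a rate with the standard
  b/q truncation correction,
  k(d) = k_D(b)P/(1 − (1 − P)k_D(b)/k_D(q)), where k_D(·) is the
  diffusion-limited rate to an absorbing sphere computed by quadrature
  of 4πD/∫ e^{U(s)}/s² ds (Smoluchowski 4πDrN_A for U = 0, 4.54·10⁹
  M⁻¹s⁻¹ at 0.6 nm with D = 10⁻⁹ m²/s). The estimator agrees with the
  quadrature oracle within Monte-Carlo error for free diffusion and for
  screened-Coulomb attraction. Because the reduction discards shape,
  orientation and desolvation, absolute rates of the protein system are
  out of scope; the curve's two standard read-outs are the contact
  criterion (0.6 nm) and the ET trigger distance (2.5 nm).

## Peak fitting

Conductance and rupture-force histograms are summarized by a *local*
Gaussian fit: Freedman–Diaconis bins, then a Gaussian fitted only to the
contiguous bins around the highest peak with counts ≥ 20 % of the peak
(plus a two-bin margin). This keeps secondary populations and skewed
tails from pulling the center. Degenerate histograms (single occupied
bin) fall back to the peak-bin center with zero/bin width.

## Problem sizes and tolerances

The validation suite runs ensembles of 100–200 curves, 10–30 blink
traces of 10–200 s at 10 kHz, a few thousand ion frames, and 1–3·10³
Brownian trajectories; these sizes put Monte-Carlo error comfortably
inside the 10 % recovery bands while keeping the full suite under a
minute. Noiseless inputs must reproduce the closed forms to optimizer
precision (10⁻³ relative or better; the Bell–Evans inversion to 10⁻⁹).
Seeded generators are bit-reproducible: identical config + seed gives
identical output.

## Known limitations

- The exponential-window rule is a reconstruction; instrument vendors'
  implementations differ in the transient cut and leakage estimate, so
  absolute β values from third-party data may shift by a few percent.
- The blink baseline assumes dwells short relative to the rolling
  window; bursts of long blinks require widening it.
- Rupture detection assumes a single dominant loading ramp per
  excursion; cascaded multiple-bond ruptures within one excursion are
  reported as one event at the final jump.
- The 1:1 SPR model has no mass-transport or drift terms; data with
  transport limitation will bias k_on low.
- The ionic module's contrasts (depletion between like charges,
  accumulation between opposite ones) are directional stand-ins for the
  solvated-protein calculations; its molarities are not comparable to
  all-atom values.
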