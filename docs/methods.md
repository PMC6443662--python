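# Methods

This note documents the models, estimators and numerical conventions
implemented in `ubfret`, the defaults chosen where the underlying
experimental protocol leaves the choice open, and what the synthetic-data
tests do and do not demonstrate about real measurements.

## Burst extraction

Photon arrival times from a confocal smFRET experiment are binned into
half-open, 0-based bins of width 1 ms (configurable). A burst is a
maximal run of consecutive bins whose summed donor-excitation counts
(donor + acceptor emission) reach a per-bin threshold; the default is
4 counts/bin, with the useful working range 3–5 under low background and
up to ~10 when background fluorescence is high. No sliding-window or
inter-photon-time burst search is implemented: the per-bin gate is the
whole detection model, which keeps it exactly enumerable in tests.

When an acceptor-excitation (PIE) channel is present, bursts with fewer
than `pie_min_aex` (default 1) direct-excitation acceptor photons are
discarded; this removes donor-only and acceptor-bleached molecules, which
otherwise pile up as a spurious near-zero-efficiency peak.

Per-burst efficiency is the proximity ratio E = n_A/(n_A + γ·n_D) with
γ = 1 by default — an *uncorrected* efficiency. No leakage,
direct-excitation or detection-efficiency corrections are applied; if a
calibrated γ exists it can be supplied, but all defaults assume the same
convention is used consistently on both the simulated and analysed side.

Known limitation: overlapping transits of two molecules merge into one
burst; the generators place bursts without overlap, so the tests do not
probe that failure mode.

## Gaussian-mixture decomposition

Burst efficiencies are modelled as K overlapping Gaussian species,
p(e) = Σ w_j N(e | μ_j, σ_j²). The EM fit operates on the burst-level
samples, not on a binned histogram — the likelihood is then well defined
and independent of binning. Samples outside [0, 1] are clipped first and
the count recorded.

Numerical conventions:

* **Free parameters** K centers, K widths, K−1 weights → k_params = 3K−1.
  BIC = k_params·ln n − 2·lnL and AIC = 2·k_params − 2·lnL, both
  minimised; ties in model selection break toward smaller K.
* **Width floor** 0.01 efficiency units, preventing a component's
  variance from collapsing onto a single sample (which would send lnL to
  +∞).
* **Initialisation and restarts** quantile-spaced centers, equal
  weights, pooled-SD widths; 10 restarts by default, subsequent starts
  jittered by the seeded generator; best final likelihood wins. All
  restarts run as one vectorised batch. On the three-state test model,
  10 and 40 restarts reach identical optima, so the landscape is benign
  at these sample sizes.
* **Convergence** ΔlnL < 1e-6 nats (absolute) between iterations,
  capped at 500 iterations; the lnL trajectory is stored and its
  monotonicity asserted in tests.
* **Diagnostics** histogram R² (empirical density vs mixture density at
  bin centers, 30 bins default) is reported alongside BIC/AIC as a
  secondary, binning-dependent measure.

Replicate measurements are combined by `replicate_summary`: components
matched by descending center, populations and centers averaged with SD
across fits. This mirrors the triplicate-measurement protocol. It
matters statistically: with free widths, the 0.74 and 0.57 species
overlap strongly (2.4σ apart at width 0.07), and the single-fit MLE of
the high-FRET weight has an intrinsic spread of ≈ 3.4 points at 5,000
bursts — this is likelihood-surface geometry, not an optimizer artifact.
Averaging three replicates brings the spread to ≈ 2 points, which is what
makes a ±5-point recovery claim robust.

Fixed-width fitting (`fix_widths`) is provided for constrained
comparisons, e.g. against a dense grid-enumeration oracle in the tests.

## Binding isotherm

Species-population titrations are fit with the exact two-state binding
isotherm including ligand depletion: with S = C_partner + C_diUb + K_D,

    ΔP(C) = P_max · (S − √(S² − 4·C_partner·C_diUb)) / (2·C_diUb).

The labeled-species concentration C_diUb (150 pM in the reference
experiments) is three orders of magnitude below typical K_D values, and
the literal expression above cancels catastrophically in that regime; the
implementation therefore evaluates the algebraically identical
rationalised form ΔP = P_max·2C/(S + √(S² − 4·C·C_diUb)). Both forms
agree to ≥ 10 significant digits wherever the literal form is
well-conditioned (C_diUb within 100× of K_D), which is asserted in tests.

Fitting uses nonlinear least squares in log(K_D), log(P_max) — enforcing
positivity without active bounds — and reports asymptotic 1-SD errors
propagated back to the linear scale by the delta method. Initial values
are the median nonzero concentration and the maximum observed ΔP. A
series with ΔP identically zero is rejected (P_max ≈ 0, nothing to fit).
Concentrations are parsed from explicit unit strings (pM/nM/µM/mM/M) and
held in molar internally; unit ambiguity is the dominant practical
failure mode of this analysis and is deliberately made impossible.

Saturation is rarely reached experimentally, so `calibrate_pmax` pins
P_max from a single known on-curve point (e.g. a 9-point enrichment at
100 nM with K_D = 119 nM) before forward-predicting other points.
Competition experiments are summarised as percent inhibition
(100·decrease/enrichment) rather than by a full ternary equilibrium
model, because only population decreases are measured.

## Förster conversion and ensemble averaging

E(r) = 1/(1 + (r/R₀)⁶) with R₀ = 52 Å by default (Alexa488/Cy5);
r(E) = R₀·((1−E)/E)^{1/6} is its exact inverse (round trip asserted to
1e-10). For a conformer ensemble the summary reports five quantities:
mean and SD of r, r_eff = ⟨r⁻⁶⟩^{−1/6}, mean and SD of E(r_i), and the
point values E(⟨r⟩) and E(r_eff). Both averaging conventions are always
computed because published back-calculations are often ambiguous about
which was used; for a Normal(43.2 Å, 5.8 Å) ensemble the ensemble mean
⟨E⟩ ≈ 0.73 while the point value E(43.2) ≈ 0.75 — the difference is pure
Jensen/concavity, and r_eff ≤ ⟨r⟩ always holds by the power-mean
inequality.

Distances from structures are measured between geometric centers of two
user-specified atom selections (`chain:resnum:atomname` lists, e.g. dye
pseudo-atoms or aromatic-ring atoms), one distance per PDB MODEL. Dye
linkers are not modelled — no accessible-volume clouds, no κ²
treatment; the selections are taken at face value.

## NMR interface mapping

CSPs combine the ¹H and ¹⁵N dimensions as Δδ = [0.5(Δδ_H² + 0.2Δδ_N²)]^½.
Peaks present in the free state but absent in the complex are flagged
`disappeared` and always counted as interfacial (intermediate-exchange
broadening). The interface threshold — drawn as a dotted line in typical
CSP plots, rarely printed — defaults to mean + 1 SD after trimming the
largest 10% of values (so strong perturbations do not inflate their own
cutoff); it is a stated convention, overridable by argument.

PRE rates use the two-time-point scheme,
Γ₂ = ln[(I_a^para·I_b^dia)/(I_b^para·I_a^dia)]/(t_b − t_a), which is the
difference of para- and dia-magnetic single-exponential decay rates and
is invariant to overall scaling of either spectrum. A vanished
paramagnetic peak yields no finite Γ₂ and is flagged broadened. A
single-delay fallback Γ₂ ≈ −ln(I_para/I_dia)/T is provided and labelled
approximate. The "very large PRE" cutoff defaults to 20 s⁻¹ —
a convention matching the dynamic range of typical intermolecular PRE
plots, not a measured value.

## Synthetic data: what it does and does not emulate

The generators reproduce the *statistical* structure the estimators
assume: mixture-weighted state assignment, binomial shot noise
(SD = √(E(1−E)/N)) or Gaussian state broadening, Poisson background,
non-overlapping 1–3-bin bursts with shifted-Poisson (mean 50) photon
totals, exact-isotherm titrations with additive Gaussian noise, truncated
Normal distance ensembles, and step-profile CSP/PRE tables. Burst
brightness and background defaults are fabricated plumbing — the
reference experiments do not state them — and are marked as such.

Not emulated: diffusion through the confocal volume (burst-size/duration
correlation), photophysics (blinking, bleaching within a burst), spectral
crosstalk, acceptor direct excitation, instrument dead time, exchange
broadening lineshapes. Passing tests therefore demonstrate correctness of
the estimators under their own assumptions, not robustness to these
instrument effects.

The canonical test model (`StateModel.diub_76c_0c`) places three states
at efficiencies 0.74/0.57/0.23 with populations 48/39/13% — the measured
decomposition for the 76C/0C labeling sites — with a per-state width of
0.07 efficiency units, which is a modeling choice (per-species widths are
not published). All generators draw from a single explicit
`numpy.random.default_rng(seed)`; a fixed seed reproduces outputs
byte-identically.

## Problem sizes

Default analysis sizes were chosen to match the regime the estimators are
meant for while keeping any run on one CPU in the seconds-to-minutes
range: 5,000 bursts per smFRET measurement, 10-point titration ladders
spanning 0.1–30 × K_D, 100,000-conformer distance ensembles, 20-seed
repetitions for stochastic recovery claims.
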