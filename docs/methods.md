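# Methods

`comptrack` models a deep-silicon photon-counting CT detector with no
tungsten shielding, in which a single incident x-ray photon can produce a
*chain* of interactions: zero or more Compton scatters, optionally terminated
by a photoelectric absorption, or ended by the scattered photon leaving the
detector.  Given the unordered set of registered interactions (3-D position,
deposited energy), the package estimates the incident photon energy
E<sub>γ</sub> and entry position (x<sub>γ</sub>, y<sub>γ</sub>).  This note
records the model, its parameters, the numerical choices, and what the
synthetic benchmark does and does not demonstrate.

## Detector and transport model

The detector is a silicon slab of depth L<sub>d</sub> = 80 mm along the beam
(+z), unbounded in x and y, so photons can only escape through the entry or
exit face.  The beam is monoenergetic and perpendicular to the entry face;
incident positions are sampled uniformly over a 10 × 10 mm² area.

Photon transport uses the Beer–Lambert law with the silicon linear
attenuation coefficient μ(E).  Interaction types are drawn from the relative
photoelectric/incoherent cross sections

&nbsp;&nbsp;P(photo | E) = σ_photo / (σ_photo + σ_Compton),

Rayleigh scattering never produces an event (no energy deposit); whether its
cross section contributes to μ for free-path sampling is the
`include_coherent_in_mu` flag (default on, matching the total attenuation
coefficient of the standard reference tables).  The zero-interaction
fraction of a 60-keV beam in 80 mm of silicon is sensitive to this choice
(~0.25% with the coherent term, ~0.44% without).

### Attenuation data

`data/silicon_attenuation_synthetic_xcom.csv` is a synthetic XCOM-style
decomposition: its *totals* reproduce the standard-grid silicon mass
attenuation coefficients (e.g. μ/ρ = 0.3207 cm²/g at 60 keV, giving
μ = 0.0747 mm⁻¹), while the split into photoelectric / incoherent / coherent
components is reconstructed — exact Klein–Nishina incoherent part with a
smooth empirical binding correction, a power-law coherent part saturating at
low energy, photoelectric as the remainder.  The reconstruction is pinned to
physically meaningful anchors: photo/Compton parity near 57 keV, a
photoelectric share of 46.2% at 60 keV, a coherent share of ~11% at 60 keV.
Interpolation between the 14 grid nodes is log-log linear; queries outside
5–200 keV raise.  Likelihood evaluation can encounter residual photon
energies below 5 keV, where the table is clamped at its edge
(`mu_clamped`): at those energies the mean free path is tens of micrometres,
so any finite leg is numerically opaque and the clamp is inconsequential.

## Effective Compton scattering model

Single-scatter kinematics are exact: a scatter at polar angle θ of a photon
of energy E deposits

&nbsp;&nbsp;E_d(E, θ) = E² (1 − cos θ) / (m_e c² + E (1 − cos θ)),

with m_e c² = 511 keV; the Compton edge E_d(E, π) is 38.3 keV at 120 keV and
11.41 keV at 60 keV.

Two empirical surfaces complete the model, and both are deliberately
pluggable (callables or CSV tables):

* **Angle density P(θ | E).**  Default: the Klein–Nishina differential cross
  section converted to a per-angle density (× 2π sin θ), multiplied by a
  one-parameter stand-in for the incoherent scattering function S(q, Z = 14),
  S/Z = u/(1+u) with u = (x/0.55 Å⁻¹)^1.7 and x = E sin(θ/2)/hc, then
  renormalized on [0, π].  The suppression removes the unphysical low-angle
  excess of the free-electron cross section for bound silicon electrons.
* **Deposit broadening σ_Ed(θ, E).**  At fixed angle the deposit is spread
  around the kinematic value by Doppler broadening (and, in a real detector,
  unresolved intermediate Rayleigh deflections).  The deposit density is an
  equal-weight two-term Gaussian centred on E_d with widths σ₁ = σ_Ed and
  σ₂ = 0.18 σ₁, truncated to [0, E) and renormalized.  Default surface:
  σ_Ed = 0.15 + 1.2 (E/60 keV) sin(θ/2) keV — of order 1 keV at
  (π/2, 60 keV), vanishingly small transfer spread at small angles with a
  0.15-keV floor.  A calibration hook (`sigma_ed_fn`) accepts any refitted
  surface.

Sampling discretizes θ in 0.1-rad bins (bin midpoints) and energies on a
0.1-keV grid with a 0.1-keV floor; the azimuth φ is uniform and continuous.
An optional Gaussian angular-smearing kernel (`angular_smear_rad`)
approximates the angle distortion caused by invisible intermediate Rayleigh
scatters; it is **off by default**, which is a documented limitation: the
default chains are geometrically cleaner than real (or full-transport
Monte Carlo) data.

## Chain likelihood and maximum-likelihood estimation

For an ordered candidate chain the likelihood of a trial E<sub>γ</sub> is a
product of: a position factor μe^(−μℓ) per leg at the energy remaining on
that leg; a Compton type factor and the joint density P(E_k, θ_k | ·) for
each non-terminal interaction (θ_k fixed by the event geometry); and a
terminal bracket — photoelectric absorption of the remaining energy (energy
delta softened to a 0.5-keV Gaussian) plus a final Compton deposit
marginalized over the unknown outgoing angle times the probability that the
scattered photon escapes, a double quadrature over θ (0.1-rad midpoint rule,
weighted by the angle posterior) and φ (64-node periodic trapezoid).  The
containment factors 1 − e^(−μ·L_exit) cancel algebraically against the
conditional position densities; the cancelled form is implemented and the
uncancelled transcription retained as a test oracle.

Observed chains are unordered, so the likelihood is evaluated for all N!
permutations; each term is maximized over the incident-energy grid
(15–120 keV, 0.1-keV steps — the same range as the benchmark's uniform
incident prior; the estimator applies no spectrum weighting, though a
multiplicative spectrum hook is exposed by evaluating the returned curves)
and the term with the largest maximum supplies Ê<sub>γ</sub> and the (x, y)
of its assumed first interaction.  Ties between terms break toward the
lexicographically first permutation, grid ties toward the lower energy.

Limited detector resolution (σ_E = 0.5 keV; σ_x = 10 μm,
σ_y = σ_z = 500 μm) is handled by Monte Carlo integration: Gaussian-
perturbed copies of the observed chain are generated, per-permutation
likelihood curves averaged over copies, and the selection applied to the
averaged curves.  Realizations in which any perturbed energy rounds to
≤ 0 keV are skipped and excluded from the average (skip-and-renormalize, no
resampling); perturbed depths are clipped to the slab.  The default copy
count is 1500; the scaled benchmark uses 200.

### Numerical choices

* Per-permutation curves are accumulated in log space and exponentiated once.
* Evaluation is restricted to grid energies where every non-terminal deposit
  factor lies within 12 σ₁ of its kinematic mean; outside that intersection
  the product is below e^(−72) of its peak and is reported as exactly 0.
  Terminal deposit × angle weights are masked at 9 σ₁ (a sum, not a product,
  so the cut is per-term).  Verified against unmasked evaluation at the
  1e-10 relative level on reference chains.
* The escape factor is smooth in the trial energy and is evaluated on a
  1-keV subgrid with linear interpolation (`escape_grid_step`; 0 restores
  exact per-node evaluation, which the scalar `chain_likelihood` operation
  always uses).  Measured subgrid-vs-exact curve deviations are below 1e-30
  relative on reference chains.
* Angle posteriors with a marginal deposit density below 1e-30 /keV flag an
  impossible (E, E_γ) pair: posterior and escape contribution are zero.
* Chains longer than `max_events` (default 6) are rejected rather than
  truncated; the benchmark analyzes chains of up to 4 events.

## Simpler estimators

The *alternative* method uses no scattering kinematics: events at or above
38.3 keV (the 120-keV Compton edge — no single Compton deposit in the
15–120 keV spectrum can exceed it) are labelled photoelectric.  If any event
is so labelled the energy estimate is the plain sum of deposits; otherwise it
is the posterior argmax of P(E_γ | E_tot) obtained by Bayes inversion of a
simulated P(E_tot | E_γ) table under a uniform 15–120 keV prior.  The
position estimate is the single event's position (N = 1), else the mean
position of Compton-labelled events; a multi-event chain in which *every*
event exceeds the threshold (undefined in the protocol, possible only for
distorted chains) falls back to the mean over all events.  The *baseline*
treats each event as its own photon: posterior argmax of the per-event table
P(E_γ | E), position of the event itself.

Lookup tables default to a 0.5-keV incident-energy column spacing with
linear interpolation of posteriors between columns and 0.1-keV deposit bins
(a desk-scale version of the 0.1-keV × 10,000-photon tables the protocol
describes; both knobs are configurable).  Posterior argmax ties break toward
the lower energy.

## Benchmark protocol and the synthetic conditions

`run_benchmark` simulates n monoenergetic 60-keV photons, forms observed
chains (event order shuffled; in realistic mode Gaussian noise applied once
and the identical realizations fed to every estimator), runs the requested
estimators, and reports per-chain-type and aggregate mean/RMS errors with
standard errors, plus primary-identification rates for the ML method.
Energy and position errors are measured against the true incident energy and
entry (x, y); the baseline contributes one estimate per event.  Standard
errors: mean → sample std/√n; RMS → RMS/√(2n), the large-sample χ² result
(the corresponding printed reference uncertainties back-calculate to this
form).  Chain types absent from a scaled run are reported absent, not as
zero error.

The default scaled benchmark is 500 photons with 200 Monte Carlo
realizations and 1-keV lookup tables, sized for a desk-scale run
(≈10 minutes single-core); the full-fidelity settings (10,000 photons, 1500
realizations, 0.1-keV tables) are plain configuration values.

Because simulator and estimator share one `ComptonModel` and one attenuation
table, the benchmark is *self-consistent* (an inverse-crime design): it
isolates estimator performance from model error, exactly as a benchmark
built on a single fitted surface does.  Passing it demonstrates the
correctness and statistical efficiency of the estimation machinery under the
stated physics — it does **not** demonstrate robustness to scattering-model
mismatch, electron transport, charge sharing, pile-up, or real Rayleigh
transport, none of which are simulated.  With the default (sharper,
Rayleigh-free) surfaces the estimator separates interaction orders more
cleanly than a fit to full-transport data would: aggregate RMS energy errors
land in the 2-3.5 keV range depending on the random draw of Compton-only
chains, with the expected structural behaviour (exact recovery of
photoelectric-terminated chains, negative bias confined to single-Compton
chains, perfect ordering of two-event photo-terminated chains, RMS ordering
ML ≤ alternative ≤ baseline).

## Known limitations

* The two scattering surfaces are physics-motivated defaults, not fits to a
  full-transport Monte Carlo; users with such fits should load them through
  the pluggable interfaces.
* No Rayleigh transport: angular distortion by invisible elastic scatters is
  only available as the optional smearing kernel.
* Sub-5-keV photons are absorbed locally (table floor; mean free path far
  below the spatial resolution), and scattered photons with less than
  0.2 keV remaining are absorbed at the scatter site (0.1-keV grid closure).
* One photon per time frame is assumed throughout; multi-photon
  disambiguation and pile-up are out of scope.
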