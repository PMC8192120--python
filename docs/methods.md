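# Methods

## The model

`monokin` simulates the transport cycles of the plasmalemmal monoamine
transporters DAT, NET, and SERT as continuous-time Markov chains over a
small number of conformational states. The occupancy vector p(t) evolves
under the master equation

    dp/dt = Q(t) · p,      Q[j,i] = effective rate i → j,

with columns of Q summing to zero (probability conservation). Effective
rates combine three multiplicative factors:

1. **Base rate constant** k⁰ (s⁻¹ unimolecular, M⁻¹·s⁻¹ bimolecular).
2. **Voltage factor.** Each transition carries an equivalent charge zQ
   (elementary charges moved inward during the forward step). With a
   symmetric Eyring barrier the forward rate is scaled by
   exp(−zQ·F·V/2RT) and the reverse by the reciprocal factor, so the
   product of the two directions is voltage-independent. V is the membrane
   potential (inside minus outside, volts); F = 96 485 C·mol⁻¹,
   R = 8.314 J·K⁻¹·mol⁻¹, T = 293 K.
3. **Ligand concentration** (pseudo-first-order mass action) for
   directions that bind Na⁺, K⁺, H⁺, Li⁺, or substrate from one side of
   the membrane. Cl⁻ is treated as co-bound throughout the cycle (state
   names carry "Cl") with no Cl⁻-coupled transition, reflecting its
   modulatory rather than stoichiometric role.

### Scheme topology

All three transporters share a sequential-binding core: outward-open
binding of Na⁺ then substrate, occlusion, inward opening, electrogenic
Na⁺ release, substrate release. They differ in the return leg:

* **DAT/NET** bind intracellular K⁺ to the inward-open state (TiClK,
  electrogenic binding) but shed it again into the cytosol on the way to
  the occluded state (ToccClK → ToccCl, a reduced-affinity site); the
  empty occluded transporter then returns outward carrying the protein's
  intrinsic negative charge (zQ = +1 inward-equivalent on the return, so
  hyperpolarization accelerates it). A parallel direct occlusion path
  TiCl → ToccCl supports cycling when no K⁺ is present. DAT and NET share
  the scheme and every parameter except substrate binding/release rates;
  NET's slower substrate kinetics produce its much smaller turnover.
* **SERT** carries K⁺ through occlusion and releases it extracellularly
  (antiport). The K⁺-loaded return step is electroneutral, and the full
  K⁺ loop has Σ zQ = 0, which renders SERT's turnover essentially
  voltage-independent. An alternative H⁺-antiport branch (binding of
  intracellular H⁺ at ~10⁻⁷·²  M with a diffusion-limited on-rate)
  sustains slower cycling when K⁺ is absent; an empty, electrogenic
  return also exists but is slow. A Li⁺ dead-end binding to the
  inward-open state is available as a variant flag.

A conducting state (Tcond), in rapid equilibrium with the K⁺-bound
inward-facing conformation, models the uncoupled Na⁺ conductance as a
channel: I = P_o·γ·NC·(V − V_rev) with γ = 2.4 pS, V_rev = +100 mV and
P_o the Tcond occupancy. NET omits Tcond by default (no detectable steady
current); a flag restores it.

### Observables

* Coupled current: I = −F·NC/N_A · Σ zQ_ij (p_i k_ij − p_j k_ji), summed
  over all transitions, with NC = 4×10⁶ transporters per cell. Inward
  current is negative.
* Uncoupled current: the channel expression above.
* Substrate uptake: the net flux of the intracellular substrate-release
  step, (p_TiClS·k_off − p_TiCl·k_on·S_in)·NC molecules·s⁻¹, integrated
  to give the cumulative fluorescence signal. S_in defaults to 0
  (the cell is an effectively infinite sink — recordings show linear
  accumulation); a finite S_in enables back-reaction studies.

## Thermodynamic consistency

Rate constants are not free: around every closed reaction loop the
product of forward/reverse rate ratios (at 1 M standard state, 0 mV) must
be 1, or the scheme would do work at equilibrium. The model builders
enforce these Wegscheider conditions exactly by solving for one reverse
rate per fundamental cycle (the reduced-affinity K⁺ on-rate and the
return reverse rate for DAT/NET; the extracellular K⁺/H⁺ re-binding rates
and the empty-return reverse rate for SERT). Consequently every loop's
free energy, ΔG_loop = −RT·Σ ln(k_fwd_eff/k_rev_eff), is exactly zero
under collapsed gradients at 0 mV, and at working conditions equals the
chemiosmotic driving energy: the ion/substrate gradient terms plus
Σ zQ·F·V. The energetics module exposes per-step and cumulative ΔG along
arbitrary walks; the identity ΔG(V) − ΔG(0) = +Σ zQ·F·V follows
algebraically from the symmetric-barrier rate law (moving positive charge
inward at negative potential releases energy).

Free-energy profiles of the substrate-translocating loop are computed
with 30 µM external substrate and a nominal 30 nM internal substrate
(0.1%): a strictly zero internal concentration would make the release
step's reverse rate zero and the loop total undefined; any small value
leaves the cycle total negative, which is the meaningful statement.

## Numerical choices

* Stiff integration: `scipy.integrate.solve_ivp` (LSODA) with the exact
  Jacobian Q(t), rtol 1e−8, atol 1e−10. Occupancies are verified, never
  renormalized inside the solver; total-probability drift beyond 1e−6
  raises. Rate constants span ~6 orders of magnitude, which rules out
  explicit steppers.
* Solution exchange is never instantaneous: protocol segments relax
  external concentrations exponentially with τ_app = 10 ms (configurable),
  matching a fast superfusion system. Integration is split at segment
  boundaries.
* Steady states come from the SVD null space of Q, normalized and checked
  for non-negativity; a multidimensional null space (disconnected scheme)
  raises.
* Initial occupancies default to the steady state at the holding
  potential in the pre-application solution, mirroring a voltage-clamped
  cell before superfusion.
* Curve fits use `scipy.optimize.curve_fit` with fixed, documented
  initialization rules (hyperbola: Ymax from the extreme response, K_M
  from the half-maximum crossing; mono-exponential: log-linear regression
  toward the plateau; Boltzmann: asymptotes from the data range). No
  random restarts: identical inputs give identical fits. The line/F-test
  machinery is closed-form least squares with nested-model RSS F
  statistics (slope equality tested first, then intercepts).

## Protocols

* **Concentration–response**: 15 s applications over 1–600 µM; uptake
  slopes and steady currents normalized to the 600 µM response; K_M from
  a rectangular-hyperbola fit.
* **Current–voltage**: default grid −90…+30 mV in 20 mV steps at 30 µM.
  Uptake slopes normalize to −90 mV; currents to −60 mV (falling back to
  the most negative voltage when absent from the grid). Boltzmann and
  line fits are both computed; the lower-residual family is flagged,
  since neither is mechanistic.
* **Two-pulse recovery**: 0.5 s substrate pulses (2 s for NET, whose
  kinetics are ~25× slower) separated by a variable wash; peak currents
  are baseline-subtracted inward (negative-going) extrema within 200 ms of
  onset — restricting the sign keeps the slowly decaying conducting-state
  tail of the previous pulse from masquerading as a test response at short
  washes. The wash grid is log-spaced over ~5 recovery time constants
  (estimated from the slowest relaxation eigenvalue of the wash-condition
  generator) with a floor of 5 solution-exchange time constants; the
  estimate only places the grid — the reported rate always comes from the
  mono-exponential fit of the simulated recovery itself.
* **Ion sweeps** repeat any protocol across intracellular presets
  (physiological 163 mM K⁺/6 mM Na⁺; NMDG⁺ replacement; 163 mM Na⁺;
  163 mM Li⁺; internal pH 5.6) and emit tidy long-format tables.

Peak windows (200 ms) and the steady-state window (final 20% of the
application) are analysis conventions chosen to separate the exchange
transient from cycling behavior; uptake-slope fits exclude 0.5 s at each
window edge to stay clear of the solution-exchange artifacts.

## Calibration of the shipped fixtures

Only a handful of rate constants are printed observables (APP⁺ k_on/k_off
per transporter; F, R, T, NC, γ, V_rev, τ_app). The remaining per-edge
rates and the zQ allocation are constrained collectively by measured
quantities: catalytic rates from two-pulse recovery at −60 mV
(DAT 3.74 s⁻¹ with K⁺_in, 4.45 s⁻¹ without; NET 0.15 s⁻¹; SERT 1.61 s⁻¹
with and 0.74 s⁻¹ without K⁺_in), uptake ratios +30 mV/−90 mV
(≈ 25 / 35 / 80 % for DAT / NET / SERT), the DAT APP⁺ K_M (≈ 28 µM), and
the qualitative current structure (a peak exceeding the steady current in
DAT; SERT's steady current collapsing without K⁺_in).
`scripts/calibrate_models.py` runs the full virtual protocols inside a
least-squares loop over log-parameters (return rate, occlusion rates, K⁺
site affinity, the substrate-release and translocation charges, NET's
cognate off-rate, the Tcond equilibrium; SERT's K⁺- and H⁺-branch rates)
and the resulting values are frozen as the defaults in `monokin.models`.

Two structural lessons from the calibration are worth recording. First,
charge placed on steps upstream of a slow substrate-release step acts on
the cycle through a quasi-equilibrium factor, so NET (slow release) is
far more sensitive to "chain" charge than DAT; reproducing the shallower
voltage dependence of NET against the steeper one of DAT therefore forces
most of the voltage dependence onto the return step and the K⁺-site
trapping rather than onto the loaded half-cycle. Second, the standard-state
imbalance of a cycle must be spread across its conformational equilibria:
concentrating it on the return edge (via the Wegscheider solve) creates a
large reverse return rate that floods the inward states at depolarized
potentials and destroys both the resting availability and the uptake
ratios.

## What the synthetic data do and do not emulate

`generate_recording` produces the two channels an acquisition system
records: total current plus Gaussian noise (default SD 1 pA), and
brightness-scaled cumulative uptake plus a bath artifact — the free-dye
fluorescence that rises and falls with solution exchange, modeled as a
square pulse relaxed with τ_app and scaled (by default) to ~3× the 15 s
transporter ramp, reflecting that only a small fraction of the imaged
field is covered by the cell — plus Gaussian noise (default ~2% of the
ramp) and optional linear drift. Identical seeds give bit-identical
recordings. Not modeled: photobleaching, shot-noise statistics,
amplifier/capacitive artifacts, cell-to-cell expression variability, and
intracellular APP⁺ compartmentalization. Passing the recovery harness
therefore shows that the analysis pipeline is unbiased for data whose
noise is additive and Gaussian; it does not validate those extraction
choices against the full complexity of real recordings.

## Known limitations

* The fixtures are calibrated to reproduce aggregate observables, not
  per-edge measurements; individual rate constants (and the zQ split
  beyond the loop totals) are not identifiable from the calibration
  targets and should not be over-interpreted. Only loop-level quantities
  (total charge per cycle, loop ΔG) are meaningful.
* In the absence of K⁺, SERT's H⁺-driven return is close to equilibrium
  (the pH gradient contributes only ~1 kJ·mol⁻¹), so the simulated
  test-pulse recovery plateaus below full amplitude even though its rate
  matches the measured 0.74 s⁻¹.
* The net charge moved per DAT/NET cycle is constrained only by the
  voltage-dependence targets; the shipped allocation sums to ~+1.4
  equivalent charges over the outer loop.
* The substrate-evoked DAT current rises within ~300 ms to its steady
  level rather than showing a dominant early peak: with the catalytic
  rate pinning the steady cycling flux, the NET uptake ratio capping the
  charge movable during the loaded half-cycle, and the uptake–voltage
  ratios pinning the return charge, the synchronized first-wave transient
  lands at roughly the steady amplitude for every charge allocation
  compatible with the calibration targets. Peak extraction still works as
  an availability readout (the two-pulse protocol is unaffected), but the
  pronounced peak-over-steady structure of real DAT recordings is not
  reproduced by the shipped fixture.
* Gillespie-style stochastic simulation, asymmetric barrier positions,
  and temperature dependence beyond the fixed T are out of scope.
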