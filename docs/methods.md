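# Methods

## The kinetic model

All reactions are elementary mass action; a mass balance per species gives
the ODE system, integrated deterministically (no stochastic simulation —
the copy numbers in membrane/solution assays make fluctuations
irrelevant). The hormone-bound receptor is the ground state: the
experiments the model describes use saturating agonist (100 µM), so
apo-receptor and hormone-binding steps are deliberately lumped into HR′.
Likewise the G protein's nucleotide states are consolidated; the model
stops at ternary complex formation, which is the rate-limiting part of the
cascade being studied.

Base network (species HR′, HR\*, G, HR′G, HR\*G):

| reaction | forward | reverse |
|---|---|---|
| HR′ ⇌ HR\* | k_act_f | k_act_r |
| HR′ + G ⇌ HR′G | k_on_G | k_off_weak |
| HR\* + G ⇌ HR\*G | k_on_G | k_off_strong |
| HR′G ⇌ HR\*G | k_actG_f | k_actG_r |

A single association rate k_on_G serves both receptor states: the measured
off-rates and figure-level K_D values imply per-state association rates
agreeing within ~25% (0.3/30 ≈ 0.006/0.75 µM⁻¹s⁻¹), so affinity
differences are carried entirely by dissociation. Default
k_on_G = 0.01 µM⁻¹s⁻¹, overridable.

**Thermodynamic closure.** The four states form a cycle, so only three of
the four equilibrium constants are free: K_actG = α·K_act with
α = k_off_weak/k_off_strong. By default the user supplies k_actG_f and the
package derives k_actG_r = k_actG_f/(α·K_act). Explicit overrides of both
rates are allowed — some numerical experiments need them — but any
override whose cycle product deviates from 1 by more than 10⁻⁶ relative
raises a `DetailedBalanceWarning`. Every builder's conservation groups
(receptor-, G-, E-, N-containing species) are checked symbolically against
the stoichiometry matrix, and a species-name audit enforces that G never
coexists in a species with E or N (they compete for the same receptor
surface).

**Extended (effector) network** adds E, HR′E, HR\*E: E binds HR′ and HR\*
with a single K_E (the data motivating the model give one effector
affinity; equal-affinity binding is the closure that makes the E-bound
cycle consistent automatically), and the E-bound interconversion runs at
γ_E·k_act_f / γ_E·k_act_r — a pure catalyst that leaves K_act unchanged.
γ_E defaults to 100 so that the catalysed rate γ_E·k_act = 0.2 s⁻¹ falls
inside the 0.1–0.7 s⁻¹ range reported for G-protein-catalysed receptor
transitions in prior single-molecule work. E-bound receptor forms no
ternary complex.

**Quench network** models the stopped-flow assay: the tethered sensor is
pre-equilibrated with agonist (integrated to steady state), then a
nanobody N is injected that captures free receptor (HR′ + N → HR′N,
HR\* + N → HR\*N, k_on_N = 1 µM⁻¹s⁻¹). Capture is treated as irreversible
(k_off_N = 0) — the nanobody is a high-affinity active-state binder and
the decay is interpreted as unidirectional; a nonzero k_off_N adds the
reverse reactions.

**Tethered-sensor mode.** The biosensor's G-peptide is linked to the
receptor by an ER/K helix and has no free concentration; binding is
pseudo-first-order at an effective concentration C_eff. C_eff is not
experimentally determined; the default 10 µM is a conventional value for
ER/K-linker effective concentrations and is config-exposed. In this mode
there is no free-G species and the G component is (correctly) not a
conserved group.

## Default parameters

| parameter | default | unit | why |
|---|---|---|---|
| k_off_weak | 0.3 | s⁻¹ | measured weak-state off-rate |
| k_off_strong | 0.006 | s⁻¹ | measured strong-state off-rate |
| k_on_G | 0.01 | µM⁻¹s⁻¹ | gives K_D = 30 µM with the measured off-rate |
| k_act_f, k_act_r | 0.002 | s⁻¹ | below the measured ≤0.007 s⁻¹ bound; K_act = 1 |
| k_actG_f | 0.002 | s⁻¹ | same bound applies to the G-bound transition |
| k_ns | ln2/15 | s⁻¹ | nonspecific decay half-life 15 s |
| K_E | 100 | µM | weak-effector regime (K_E ≫ K_D/α) |
| γ_E | 100 | — | catalysed rate 0.2 s⁻¹, within 0.1–0.7 s⁻¹ |
| C_eff | 10 | µM | tethered-peptide effective concentration |
| R_total | 0.1 | µM | trace receptor relative to peptide pools |
| G_total / E_total | 30 / 10 | µM | the sequestration-assay concentrations |

The exact spontaneous/bound interconversion rates and several totals are
not printed in the source experiments; the defaults above are
constrained-but-not-identical stand-ins chosen once to satisfy every
printed constraint, and all are overridable through the YAML config
(values carry unit strings that are validated on load).

## Numerics

- Integrator: `scipy.integrate.solve_ivp`, LSODA with an analytic
  mass-action Jacobian; rtol 10⁻⁸, atol 10⁻¹² µM. The rate scales span
  0.006–10 s⁻¹ effective, so a stiff-capable method is required.
- Steady state: integrate in geometrically growing time blocks
  (10², 10³, … s) until max|dC/dt| ≤ 10⁻¹⁰ µM/s, cap 10⁷ s;
  non-convergence returns a flagged state, not an exception. Steady states
  agree with an independent algebraic equilibrium solve (conservation +
  equilibrium relations, root-finding; in the test suite) to well within
  0.1%.
- Negative concentrations: values above −10⁻¹⁰ µM are clipped at
  reporting; anything below −10⁻⁸ µM raises, signalling solver
  misconfiguration.
- Transient readouts use 300 s wherever the motivating assays say "~5 min".

## Stopped-flow fitting

Stage 1 fits the agonist-only control to `y = a·e^(−bx) + c`; stage 2 fits
the quench decay to `y = a·e^(−bx) + c·e^(−dx) + f·e^(−gx) + h` with a and
b *fixed* (not re-estimated) to the control values. Unweighted nonlinear
least squares (lmfit/Levenberg–Marquardt); rates bounded to
[10⁻⁵, 10²] s⁻¹; multistart over log-spaced rate seeds (1, 0.1, 0.01 s⁻¹;
the 3×3 (d, g) grid restricted to d > g), best residual wins. Components
are reported fast-first (d > g) and the slow-state proportion is
f/(c+f) over the specific components only. Degeneracies are flagged rather
than silently reported: a rate collapse (d ≈ g within joint uncertainty)
or a slow amplitude consistent with zero marks the fit "unresolved", and
flagged fits are excluded (and counted) by the replicate summariser.
Negative specific amplitudes are flagged post-fit. Fits operate on the
trace's own time origin; the recorded start offset (injection at t = 2 s
in the motivating protocol) or the provided maximum-descent detector can
set it.

The interconversion bound is the reciprocal of the slow component's
lifetime (two lifetimes can only be resolved if exchange between the bound
states is no faster), displayed at one significant figure with full
precision retained: a 150 s lifetime gives 1/150 ≈ 0.00667 → 0.007 s⁻¹.

## Synthetic data

The generator emulates the acquisition statistics of the stopped-flow
assay: two channels (constant 475 nm donor level of 1000 counts; the
signal rides on the 525 nm acceptor), independent additive Gaussian noise
per channel per injection, 5 injections averaged, 4 ms sampling over
115 s, ratio formed from the averaged channels. The control ratio is
1.0 + 0.2·e^(−k_ns·t); the quench ratio shares the identical nonspecific
component and adds specific components of total amplitude 0.3 split
75%/25% slow/fast — so both traces start at the same t = 0 ratio.
Replicate "membranes" multiply rates and the two specific amplitudes by
independent log-normal factors (relative SD 0.05), which also jitters the
slow proportion; replicate seeds derive deterministically from the master
seed. The channel noise SD (2 counts per sample per injection) was chosen
once so the measured parameter set is recoverable at this acquisition
geometry, and is part of the default spec.

What the generator does *not* emulate: photophysics (bleaching,
inner-filter), instrument dead-time transients, correlated noise, or the
true (unpublished) instrument noise statistics. Passing round-trip tests
therefore demonstrate the estimator's correctness and conditioning at
plausible SNR, not instrument realism. The pulldown generator draws
truncated-Gaussian fraction-bound values in [0, 1] around a
model-predicted 5-min ternary fraction.

## Scripted experiments

- **Steady-state impossibility.** For ≥100 random thermodynamically
  consistent extended-model draws (K_E log-uniform 0.01–1000 µM, γ_E
  1–10³, totals and interconversion rates randomized), the steady-state
  ternary fraction with effector never exceeds the effector-free value
  beyond 10⁻⁶. As a power check, a deliberately broken model — a one-way
  effector catalyst (γ_E,f ≫ γ_E,r), i.e. a thermodynamically impossible
  pump — is screened in the regime of low spontaneous activation and
  sub-saturating G, where it visibly inflates ternary complex and is
  flagged.
- **Priming.** 30 µM G ± 10 µM weak effector, read at 300 s vs at steady
  state; the transient fold exceeds 1 while the steady-state fold does
  not.
- **Efficacy interplay.** Agonist efficacy is modelled as the HR′ affinity
  (K_D) with the HR\* affinity K_D/α held at 0.75 µM; off-rates are
  adjusted at fixed k_on_G. The effector-induced fold-enhancement at
  K_D = 300 µM exceeds that at 30 µM.
- **Resolvability.** Both G-bound interconversion rates are set to the
  swept value — a symmetric kinetic probe of interconversion *speed*,
  deliberately outside the detailed-balance closure (the probed question
  is kinetic, not thermodynamic; the quench is irreversible and far from
  equilibrium anyway). Eigenanalysis of the bound two-state subsystem
  shows why the observable metric must be lifetime-aware: fast
  interconversion does not shrink the slow component's *amplitude*, it
  shifts its *rate* from 0.006 s⁻¹ up to ~0.13 s⁻¹ (lifetime 150 s → 8 s).
  The strong interaction is therefore counted as observed only when the
  fitted slow component's lifetime exceeds half the 115 s acquisition
  window; that long-lived amplitude fraction is nonincreasing in the
  interconversion rate, resolved at ≤0.007 s⁻¹ and zero above 0.1 s⁻¹.

## Problem sizes

Acceptance and test runs use 4 replicate membranes of 28 751-sample traces,
100 random draws for the impossibility check, 5-point resolvability
sweeps, and 25-draw oracle comparisons — sizes at which every result above
is stable across seeds while the full suite runs in seconds.

## Known limitations

- No nucleotide cycling, no apo-receptor/hormone-binding kinetics, no
  continuum of conformational states: the two-state lumping is the point
  of the model, not an approximation to be refined here.
- Whether the effector binds HR′ and HR\* with equal affinity is unknown;
  the single-K_E default is one admissible closure (independent rates can
  be supplied, with a detailed-balance warning when they break the cycle).
- The mapping from species occupancy to the FRET ratio
  (baseline + 0.3·bound fraction + 0.2·e^(−k_ns·t)) is one admissible
  observable; it is isolated behind `quench_observable` so alternative
  weightings are drop-in.
- cAMP and other downstream readouts have no model equation and are out of
  scope; the model's experimental counterparts (pulldown fractions, FRET
  fold-changes) are wet-lab quantities the simulation is compared to only
  qualitatively.
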