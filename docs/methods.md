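# Methods

## Model and assumptions

The simulator implements a closed-loop negative-feedback model of
acinar-cell digestive-enzyme synthesis with two dynamic pools:

* **N** — occupied ACh receptors on the acinar population. Incoming
  vagal ACh occupies free receptors instantaneously: the model carries
  no free-ACh pool and no association/dissociation constants, so one
  ACh-unit of input is identified one-to-one with one occupied
  receptor. Occupancy integrates input minus hydrolysis.
* **B** — interstitial BCHE mass. A fixed fraction `F` of total
  synthesis is exported basolaterally; loss to the lymphatics is
  first-order with rate `J`.

Synthesis is `S = G·N` (optionally passed through a first-order lag,
below); hydrolysis removes bound ACh at `k_cat·B·N/(N+ε)`. Units are a
consistent nondimensional scheme: time in minutes; N in receptor counts
(≡ ACh molecules); enzyme and BCHE amounts in arbitrary units. No
quantity in the model requires absolute units; all reported
relationships (fixed points, ratios, classifications) are invariant to
the unit choice.

**Saturation.** The receptor count is finite. Occupancy is hard-clamped
at the usable receptor count `N_max_eff`; ACh arriving while every
receptor is occupied is routed to a cumulative overflow accumulator
instead of occupancy. The clamp (rather than a smooth `1 − N/N_max`
occupancy factor) is chosen so the unsaturated fixed point is exactly
`S* = r_in/H` with no distortion near the working point.

**Hydrolysis smoothing.** The hydrolysis law is zero-order in ACh
(`k_cat·B`) whenever `N ≫ ε`; the factor `N/(N+ε)` with small
`ε = epsilon_h` (default 1e−3 occupancy units) makes the rate vanish
smoothly at depletion, preventing negative occupancy and solver
stiffness. Its only systematic effect is a relative shift of order
`ε/N*` in the realized fixed point (≤ 1e−4 at the default working
point).

**Synthesis lag.** A single first-order lag compartment with time
constant `tau_syn` (the simplest causal lag) can stand between the
synthesis command `G·N` and the realized output; `tau_syn = 0` (the
default) recovers the lag-free model. Note a genuine dynamical
consequence: linearizing around the unsaturated fixed point gives the
characteristic polynomial `s³ + (J + 1/τ)s² + (J/τ)s + J·r_in/τ`, so
the lagged loop is stable only for `r_in < J + 1/tau_syn`. Above that
drive the loop rings in a bounded relaxation oscillation instead of
settling — one reason the default preset is lag-free, and why the lag
test operates at moderate drive and loop gain.

**Interventions** are instantaneous multiplicative steps on `k_cat`
(cholinesterase inhibition), `G` (acinar damage) or the usable receptor
count (blockade); no pharmacokinetics are modeled, and repeated steps on
one target compose multiplicatively. When a receptor block lowers the
cap below the current occupancy, the displaced bound ACh is added to the
overflow accumulator so the ACh balance
`input = hydrolyzed + ΔN + overflow` holds across the discontinuity.

## Steady-state algebra

`static_transfer` evaluates the memoryless block diagram
`output = input·G/(1 + G·H)` by computing the summing-junction signal
`X = input/(1 + G·H)` first, so `output = G·X` is exact in floating
point. The integrating dynamics instead pin hydrolysis to the input,
giving the G-free fixed point `S* = r_in/H`, `N* = S*/G`,
`B* = F·S*/J`. The package treats `S*` as the reference fixed point of
the dynamic model and reports the static-vs-integrating discrepancy —
exactly `1/(1 + G·H)` — as `approx_error` rather than reconciling the
two. Saturation (`N* ≥ N_max`) is reported as a flag; no clamped fixed
point is solved, since the algebra is only meaningful unsaturated.
`H = 0` (open loop) raises an error: the fixed-point denominator goes to
zero and occupancy is bounded only by the receptor count.

## Numerical scheme

Integration uses `scipy.integrate.solve_ivp` (LSODA by default,
rtol 1e−8, atol 1e−10) with dense output evaluated on a uniform user
grid (default 1-min spacing). The integrator restarts at every schedule
breakpoint and intervention time so step discontinuities are exact.
Receptor saturation is handled by event-based mode switching: a
terminal event detects the upward crossing of the cap, after which a
"saturated" right-hand side holds `dN/dt = min(r_in − hydrolysis, 0)`
and accrues the positive excess as overflow; a second event detects
hydrolysis overtaking the input and switches back. The state vector
carries cumulative hydrolysis and overflow so the ACh balance is checked
at solver accuracy (observed residuals ~1e−14 relative).

Degenerate inputs: a zero schedule from a rest state yields an exactly
zero trajectory; a full receptor block forces `N = S = 0` from the block
time onward; `N_max_eff = 0` routes the entire drive to overflow.

## Assessment conventions

The pancreatitis call is operationalized as *sustained Golgi packaging
overflow*: `overflow(t) = max(S − S_max, 0)` must be positive for at
least `overflow_duration_min` minutes (default 30) on the output grid.
The mechanism being proxied is overproduction → packaging failure →
osmotic disruption; no histology or water flux is modeled, and the
threshold is an explicit artifact choice reported alongside every call.
The serum-marker proxy is `serum_gain·(F·S + overflow)` — the
physiological basolateral leak plus overflow — an appearance-rate proxy
with no clearance kinetics; it is nonzero under any active synthesis,
matching the observed nonzero baseline serum enzymes at physiological
stimulation. Rest detection reports the earliest output time after the
input has ceased at which `N` falls below `tol·N_max` and `B` below
`tol·max B` (default tol 1e−6). Peak occupancy fraction is reported
relative to the *base* receptor count, so the Diazinon runaway reports
1.0 and a blocked group reports its small pre-block transient.

## Default parameters and scenario conventions

The `canine-default` preset (G=0.5, F=0.02, J=0.2/min, k_cat=50,
N_max=1000, S_max=30, tau_syn=0, ε=1e−3) is a nondimensional working
point chosen so the loop is unsaturated and healthy at a drive of 100
ACh-units/min (S*=20 < S_max, N*=40 ≪ N_max, loop gain 2.5) while full
cholinesterase inhibition drives `G·N_max = 500 ≫ S_max`. The
`high-activity` preset anchors `k_cat` to the reported canine BCHE
turnover of 5000 ACh molecules per second per enzyme molecule
(×60 = 3.0e5 per minute with one BCHE-unit ≡ one molecule).

In the three-group virtual experiment the secretin infusion is mapped to
a constant background drive `r_in` — an explicit modeling assumption,
since the model has a single secretagogue channel. Doses are represented
by saturating fractions (full inhibition, full blockade) because no
dose–response curve is available; the dose time (t=60 min), the
atropine pre-dose lead (1 min) and the 500-min horizon are artifact
choices. The optional cohort mode draws per-replicate lognormal jitter
on `G` (seeded, default seed 20240712) for dispersion-style output; the
core experiment runs one deterministic trajectory per group. `F` is held
constant within a run; any dose dependence of the basolateral fraction
must be expressed by setting `F` per scenario, as no functional form is
available.

## What the synthetic conditions do and do not show

All inputs are generated programmatically (piecewise-constant drives,
ramped meal staircases, step interventions); there is no empirical
time-series data in the loop. Passing tests therefore demonstrate the
internal consistency of the model — convergence to its own analytic
fixed point, G-independence, conservation, and the qualitative
reproduction of the three-group outcome pattern — not a calibration to
measured canine kinetics. Absolute serum assay values, histological
endpoints, and human two-secretagogue (ACh + CCK) physiology are out of
scope.

## Problem sizes

The test suite and the acceptance script integrate 500–1200 model
minutes per run at 1–5-min output spacing; the randomized oracle sweep
uses 100 parameter sets drawn log-uniformly over roughly one decade per
rate parameter with target occupancy 10–120 receptors (safely
unsaturated), horizon `max(400, 50/J)` minutes so the slowest loop mode
(decay rate J/2) has ≥ 10 e-foldings to settle.
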