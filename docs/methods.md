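# Methods

## The regulatory-unit chain model

A thin-filament strand is modelled as a linear chain of `n_units`
regulatory units (default 26, one actin₇–Tm–Tn span each, free ends).  Each
unit occupies one of three states — blocked (B), closed (C), myosin-bound
(M) — and every unit is in exactly one state at every step.  Transitions
are first order:

| transition | rate | meaning |
|---|---|---|
| B → C | `a = k_on_max·ca^n_tn/(ca^n_tn + ca50_tn^n_tn) + θ·k_act` | Tm shift, driven by Ca²⁺-occupied troponin and by bound MyBP-C fragment |
| C → B | `k_off` | Tm return |
| C → M | `f_app` | apparent crossbridge attachment |
| M → C | `g_app` | apparent crossbridge detachment |

Ca²⁺ binding to troponin is treated as an instantaneous Hill equilibrium
(it is fast relative to the Tm shift), so calcium enters only through the
B→C rate.  A MyBP-C N-terminal fragment binds with occupancy
`θ = c/(c + kd_frag)` and adds a calcium-independent B→C component `θ·k_act`
— this is the mechanism by which the fragments activate filaments even at
pCa 9, where troponin is empty.  Fragment inhibition is a separate,
multiplicative velocity drag `(1 − drag·θ)` applied only where filaments
slide (motility, twitch shortening), because fragment incubation leaves
maximal isometric force essentially unchanged.

Cooperativity: a unit's B→C rate is multiplied, and its C→B rate divided,
by `gamma` per neighbour in C or M.  The chain therefore behaves as a
nucleation–growth switch.  A useful design rule (used to fix the defaults)
is the domain-wall balance: an active domain grows when
`a·gamma² > k_off·g_app/(f_app + g_app)` and retreats otherwise, so
physiological behaviour requires `a_diastole·γ² < k_off·g/(f+g) <
a_peak·γ²`.

### Simulation

Fixed-timestep kinetic Monte Carlo: transition probability = rate × dt,
with synchronous updates on the state at the start of each step and a
stability guard `max total exit rate × dt ≤ 0.1` (violations raise an
error that names the largest admissible dt; `dt=None` selects
`min(1e-4 s, guard limit)` automatically).  One seeded PCG64 generator
drives each run; identical (parameters, seed) pairs give bit-identical
state sequences, and the seed is recorded in every trace header.  The
inner loop is JIT-compiled with numba when available; all random numbers
are drawn outside the kernel, so the pure-Python fallback is
stream-identical.  Fixed steps were chosen over event-driven simulation
because the twitch protocol has a continuously varying Ca drive; the
discretization bias is first order in rate·dt (≤1% at the guard limit) and
is bounded in the tests against the analytic single-unit solution.

The uncoupled (γ=1) chain is validated against the closed-form stationary
distribution of the linear chain B↔C↔M (`π_C = π_B·a/b`,
`π_M = π_B·a·f/(b·g)`, normalised), and the release–restretch protocol
against the two-state limit k_tr → f_app + g_app when B is negligible.
Because single-run k_tr fits carry ~5–7% Monte-Carlo scatter even at 2000
units, the acceptance check fits the seed-averaged recovery curve.

### Protocols

* **force–pCa**: independent chains per pCa level, time-averaged occupancy
  over the second half of a 3–10 s run.  Near the cooperative threshold the
  chain is metastable, so the curve position depends mildly on run length;
  the same grid and duration are always compared against each other.
* **k_tr**: run to steady state, instantaneously set every M unit to C
  (mechanical detachment; Tm states untouched), continue; the returned
  trace starts at the release.
* **twitch**: the chain is driven by a two-exponential calcium transient
  `Ca(t) = Ca_dia + A(e^{−t/τ_decay} − e^{−t/τ_rise})` (defaults 30 ms/200 ms,
  diastolic pCa 7, peak pCa 5.8 — a 1-Hz paced rat ventricular myocyte at
  room temperature), including ≥1 s of diastolic settling before the
  stimulus.  Sarcomere length obeys
  `dSL/dt = −v_max(1 − drag·θ)·π_M + k_restore(sl_rest − SL)`
  (unloaded shortening with a passive restoring force and no
  force-generating elements), integrated exactly for piecewise-constant
  π_M.  Defaults `sl_rest = 1.8 µm`, `v_max = 2 µm/s`,
  `k_restore = 5 s⁻¹` give ~5–10% peak shortening.

### Default parameters

`k_on_max = 40 s⁻¹`, `k_off = 60 s⁻¹`, `f_app = 10 s⁻¹`, `g_app = 4 s⁻¹`
(k_tr ≈ 14 s⁻¹ at saturating Ca), `γ = 2.5`, `ca50_tn = 3.16 µM`
(pCa 5.5), `n_tn = 1`.  Isoform fixtures: `k_act` = 2.0 / 1.0 / 0.25 s⁻¹
and `drag` = 0.516 / 0.12 / 0.516 for cardiac / slow-skeletal /
fast-skeletal, all with `kd_frag = 0.05 µM`.  The k_act ordering encodes
the graded capacity to shift tropomyosin (cardiac > slow > fast); the drag
values encode strong, similar velocity inhibition by the cardiac and
fast-skeletal fragments and weak inhibition by slow-skeletal.  The cardiac
drag and kd_frag are set so that at the 0.25 µM working concentration the
encoded velocity inhibition is exactly 43% (`0.516 × 0.25/0.30`).  These
fixtures were calibrated once, against the domain-wall design rule above
and the qualitative orderings (low-Ca activation cardiac ≥ slow ≥ fast ≥
none; twitch relaxation τ largest for cardiac), and then frozen.  One
known consequence: the cooperative chain's apparent force–pCa midpoint
(~pCa 6.5–7) sits left of skinned-fiber pCa₅₀ values (~5.8); the twitch
and low-Ca protocols require the activation threshold to lie between
diastolic and peak Ca, and no analysis in this package depends on the
absolute midpoint.

## Fitting choices

* **Hill fits** (force–pCa, motility dose–response): four-parameter
  logistic in pCa with base-10 exponent, ceiling parameterised as
  floor + delta (delta ≥ 0).  Five deterministic starts over a
  (pCa₅₀, n_H) grid; ties broken by lower RSS then lower n_H.  Fits whose
  delta is <5% of the data span are reported as degenerate errors rather
  than numbers.
* **k_tr**: single rising exponential from the release, skipping two
  samples to avoid the restretch artifact; initial rate from the 63%
  crossing.
* **ATPase**: baseline slope from the pre-injection segment; calibration
  steps measured as 1-s medians before/after each injection *on the
  slope-detrended record* (otherwise the ongoing NADH consumption leaks
  ~50% of a window length into each step).  Each 50 nl injection of 10 mM
  ADP delivers 5×10⁻¹⁰ mol.
* **Relaxation τ**: log-linear regression of ln(SL_rest − SL) versus time
  from peak shortening ("logarithmic fit"), excluding samples within 2% of
  baseline (noise floor); a direct nonlinear exponential fit agrees within
  5% on clean data.  Resting SL is the median of the 100 ms before the
  stimulus — robust to drift without a detrending model.
* **Recovery-time convention**: "p% baseline" means p% of the peak
  deflection recovered toward resting SL, interpolated linearly between
  samples.  Metrics a truncated beat does not reach are reported as
  missing, never extrapolated.
* **Mobility classification**: a track is mobile iff its mean
  frame-to-frame velocity ≥ 0.3 µm/s *and* its net-displacement/path-length
  straightness ≥ 0.5 (both inclusive, both configurable).  With 95 nm
  per-frame localization jitter the velocity of a stuck filament at
  2 frames/s is ~0.34 µm/s — above any usable velocity threshold — so the
  straightness criterion does the real work of separating diffusive jitter
  from processive sliding.  Mean velocity is computed over mobile filaments
  only, so the product statistic does not penalise stuck filaments twice.

## Synthetic data

Generators draw from declared ground truth with i.i.d. Gaussian noise and
mandatory seeds (no global random state); every generator returns (data,
GroundTruth) and the truth can be serialised as a JSON sidecar.  Study
conditions baked into the defaults: the seven-point fiber pCa series
(4.50–6.00 plus 10.00), 10 frames/s movies of 300 filaments down-sampled
to 2 frames/s, 95 nm/frame localization jitter, triplicate movies per
condition, 50 nl × 10 mM ADP calibration injections, 1-Hz pacing and
2.0 µm/1.8 µm resting sarcomere lengths for fiber/myocyte records.

What the generators do *not* emulate: photobleaching, filament crossing
and tracker linking errors, non-Gaussian localization error, instrument
drift beyond a linear baseline, motion blur, and beat-to-beat variability
of the calcium transient.  Passing round-trip tests therefore shows the
analyzers are unbiased under the declared noise model, not that they are
robust to every artifact of real recordings.

## Problem sizes

Test and acceptance runs use 26–2000 units and 3–40 s simulations, 300
filaments × 3 seeds per motility condition, 200 replicates for the Hill
recovery study and 50 for the τ/k_tr recovery studies; these sizes make
the Monte-Carlo standard errors small relative to every tolerance tested
while keeping the whole suite fast on one CPU.

## Known limitations

* No strain-dependent crossbridge kinetics, length-dependent activation,
  lattice mechanics or loaded contraction: the simulator targets unloaded,
  force-free protocols only.
* The solution chemistry collapses multi-species speciation (Mg²⁺, ATP,
  CrP, pH and temperature corrections) into a single apparent Ca:EGTA K_d
  chosen so the equimolar activating solution is pCa 4.50.
* Fragment binding is assumed persistent during activation; whether bound
  fragments stay through solution exchanges is an experimental unknown.
* Fitted Hill coefficients of strongly cooperative simulated curves are
  grid-limited: transitions sharper than the pCa sampling interval are not
  identifiable, and are treated as saturated in the cooperativity tests.
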