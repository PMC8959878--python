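# Methods

## Model structure

The simulator represents one isopotential membrane patch with capacitance
`C` (nF) carrying eleven conductance-based mechanisms, keyed `na, k, cl,
na_leak, k_leak, a, m, ahp, kca, ca_t, ca_l`.  Two update laws are
implemented:

* **Current clamp** — `C dV/dt = I_applied − Σ I_n`, integrated with forward
  Euler.  The scheme is fully explicit: the voltage update uses
  start-of-step gate values, and gates and calcium advance at the
  start-of-step voltage.  No operator splitting.
* **Voltage clamp** — ideal clamp with instantaneous settling (no series
  resistance or electrode model).  Voltage is pinned to the commanded
  waveform; gates and calcium relax at the held voltage; the recorded net
  current is `−Σ I_n`.  The sign follows the convention that outward ionic
  current is positive and the clamp current mirrors it; a
  `printed_sign=False` switch exposes the opposite recording convention.

Ohmic channels use `I = g_max · Π x_i^{p_i} · (V − E)`; µS × mV gives nA
directly.  The T- and L-type calcium channels use the constant-field (GHK)
current with reduced voltage `u = zFV/RT`:

```
I = p_max · Π x_i^{p_i} · u · (c_in − c_out e^{−u}) / (1 − e^{−u})
```

`p_max` is a lumped permeability scale (membrane area and the `z²F²/RT`
prefactor folded in) chosen so that mM concentrations and mV voltages yield
nA; its zero is exactly the calcium Nernst potential.  The removable
singularity at `V = 0` is evaluated with the 4th-order series
`u/(1−e^{−u}) = 1 + u/2 + u²/12 − u⁴/720` for `|u| < 1e−4`, and the flux
falls back to its asymptotic limbs `u·c_in` / `u·c_out` for `|u| > 500`,
where the exponential would overflow — this only matters when a divergent
trajectory is about to be diagnosed.

## Gating kinetics

Every gate is a (steady state, time constant) pair:

* steady state: Boltzmann sigmoid `1/(1+exp(−(V−V½)/k))` (negative `k` for
  inactivation), optionally multiplied by a calcium Michaelis factor
  `ca/(ca+Kd)`;
* time constant: `τ_min + τ_amp · exp(−((V−V_peak)/σ)²)`, strictly positive.

This parametric family was chosen because it is smooth, bounded, and each
constant has a direct physiological reading; all constants live in the
per-channel parameter table (`ionclamp.channels._GATE_TABLE`) and every one
is overridable from the config file (`channels.<key>.gates.<name>.<field>`).

Per-channel model cards (defaults; voltages mV, times ms):

| channel | gates | key constants | character |
|---|---|---|---|
| na | m³ (V½ −30, k 7, τ 0.04–0.34), h (V½ −55, k −7, τ 0.5–6.5) | g 1.2 µS, E_Na | fast transient Na |
| k | n⁴ (V½ −30, k 9, τ 0.5–5) | g 0.36 µS, E_K | delayed rectifier |
| cl | none (ohmic; an optional activation gate would default open) | g 0.001 µS, E_Cl | minimal voltage-gated Cl |
| na_leak / k_leak | none | 0.0003 / 0.002 µS | resting conductances |
| a | two components, each m·h; m (V½ −45, k 8), h1 τ 5–15, h2 τ 30–90 (both V½ −70, k −6); weights 0.6 / 0.4 | g 0.05 µS, E_K | transient A current with two inactivation time constants |
| m | m (V½ −35, k 10, τ 30–100) | g 0.005 µS, E_K | slow non-inactivating M |
| kca | voltage gate (V½ −20, k 12) × ca/(ca+0.5 µM) | g 0.01 µS, E_K | Ca- and V-dependent K |
| ahp | purely calcium-gated, ca/(ca+0.5 µM), τ 80 | g 0.005 µS, E_K | slow after-hyperpolarization |
| ca_t | m² (V½ −52, k 5), h (V½ −72, k −5) | p 0.002, GHK | low-threshold transient Ca |
| ca_l | m² (V½ −20, k 6), no inactivation | p 0.002, GHK | high-threshold sustained Ca |

The KCa gate multiplies a voltage-dependent Boltzmann by the calcium factor
(minimal multiplicative coupling); the AHP gate is purely calcium-dependent
with a fixed slow time constant.  The Cl channel is kept ohmic — the minimal
model consistent with a "voltage-gated chloride" roster entry absent any
published kinetics for it.

Conductance magnitudes are the classic squid-scaled densities mapped to a
patch with `C = 0.01 nF` (area `1e−5 cm²` at 1 µF/cm²): 120 mS/cm² Na →
1.2 µS, 36 mS/cm² K → 0.36 µS, with the leak split between K, Na, and Cl so
the model rests near −71 mV.  Default concentrations are mammalian
(Na 145/15, K 5/140, Cl 110/10, Ca 2/5e−5 mM out/in) at 295 K; reversal
potentials are computed by Nernst at model build time.  No Q10 temperature
scaling of kinetics is applied — temperature enters the Nernst and GHK
relations only.

## Calcium pool

A single well-mixed submembrane pool couples the calcium channels to KCa and
AHP:

```
d[Ca]/dt = −φ · (I_CaT + I_CaL) − ([Ca] − Ca_rest)/τ_Ca
```

Defaults: `Ca_rest = 5e−5 mM` (50 nM), `τ_Ca = 20 ms`, `φ = 5e−4
mM·nA⁻¹·ms⁻¹`.  φ was set so that a sustained 0.1 nA calcium influx raises
the pool to ~1 µM at steady state — the range where the 0.5 µM Michaelis
constants of KCa/AHP respond.  These are modeling conveniences, not measured
constants; all three are config-overridable (`calcium:` block).

## Numerics

* **Integrator** — forward Euler at `dt = 0.01 ms` by default.  A stability
  guard rejects `dt > 0.1 ms` unless explicitly overridden: during the spike
  upstroke the membrane time constant falls to `C/g_Na ≈ 0.008 ms`, and
  coarse explicit steps diverge.  Divergence is diagnosed (non-finite state
  → error naming the step and advising a smaller dt), never silent.
* **Gate clamping** — an Euler step that overshoots [0, 1] is clamped, with
  a debug-level log.  The reference integrator does not clamp; the smooth
  ODE keeps gates in range.
* **Reference integrator** — a hand-written classical fixed-step 4th-order
  Runge–Kutta over the identical right-hand side, used only in tests as an
  independent oracle.  It deliberately shares no stepping code with the
  Euler path.
* **Resting potential** — the zero of the steady-state net current
  (all gates at `x_∞(V)`, calcium at rest), located by a 0.5 mV scan of
  [−90, −40] mV for the most hyperpolarized sign change followed by Brent
  refinement.
* **Protocols** — segment boundaries are half-open, left-inclusive, so step
  counts are exact when dt divides the durations.  In voltage mode the
  pre/post segments hold the membrane (at the located rest when no baseline
  is given) rather than free-running.  Total time is capped at 1,000 ms;
  every step is recorded (no decimation), so the longest trace is ~100k
  samples.
* **Chord conductance** — CSV conductance columns report `g_max · Π x_i^p`
  for ohmic channels (identical to current over driving force) and
  `I/(V − E_Nernst)` for the GHK channels, zero where the driving force is
  below 1e−9 mV.

## Test problem sizes

The order-of-accuracy study runs the Na+K+leak subset over a 20 ms
single-train protocol (2/15/3 ms, 0.3 nA) at `dt ∈ {0.004, 0.002}` against
an RK4 reference at 0.0005 ms, checking that the max-norm voltage error
halves with dt; these steps sit inside the first-order asymptotic regime of
the scheme (coarser steps mix in spike-timing phase error, finer ones hit
round-off).  Spike-count agreement compares Euler at 0.01 ms with the same
reference.  The randomized gate-bound property runs 200 short protocols
(≤ 5 ms) on the full model.  These sizes are the package's own choices for a
fast, convincing suite.

## What the simulations do and do not show

The default parameter set produces textbook behavior — rest near −71 mV,
overshooting spike trains under suprathreshold current steps, the classic
inward-Na/outward-K voltage-clamp separation — and every quantitative test
is against analytic closed forms or the independent higher-order integrator.
The gating constants themselves are canonical literature-style values, not
fits to any particular recorded cell, so trace-level agreement with a
specific preparation (or with any other simulator's unpublished parameter
set) is not claimed.  Markov-state channels, stochastic gating,
multi-compartment cables, synaptic input, and temperature-dependent kinetics
are out of scope.
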