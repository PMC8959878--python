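# ionclamp

A single-compartment, conductance-based ion-channel simulator for teaching
and exploratory electrophysiology.  One isopotential membrane patch carries
eleven Hodgkin–Huxley-style mechanisms — fast transient Na, delayed-rectifier
K, voltage-gated Cl, Na and K leaks, the two-component transient A current,
the slow M current, calcium-activated KCa and AHP currents, and T- and L-type
calcium channels modeled with the Goldman–Hodgkin–Katz constant-field
relation.  Protocols are three-segment current or voltage clamps; the ODEs
are integrated with forward Euler; traces export to spreadsheet-ready CSV.

It is aimed at students and instructors who want to inject a current, hold a
voltage, and see which channels carry the resulting currents — scriptable
from Python or from a thin command line.

## Model

Under current clamp the membrane voltage obeys Kirchhoff's current law,

```
C dV/dt = I_applied − Σ_n I_n
```

with capacitance `C` (default 0.01 nF) and one ionic current per mechanism.
Ohmic channels follow `I_n = g_n · Π_i x_i^p_i · (V − E_n)` where each gating
variable relaxes as `dx/dt = (x_∞(V) − x) / τ(V)`; reversal potentials come
from the Nernst equation at the default mammalian concentrations and room
temperature (295 K).  The A current inactivates with two time constants: a
fast component contributing 60% of the gating weight and a slow component
contributing 40%.  The calcium currents use the constant-field flux (the
L-type does not inactivate), feed a well-mixed intracellular calcium pool,
and the pool in turn gates the KCa and AHP conductances.  Under voltage
clamp the voltage is pinned (ideal clamp) and the recorded net current is
`I_net = −Σ_n I_n`.

Units everywhere: mV, nA, ms, µS, nF, mM.

## Worked example

`examples/current_clamp_spikes.py` builds the default membrane, locates its
resting potential, and injects a 0.5 nA step for 50 ms:

```
resting potential: -71.15 mV
spikes during the 50 ms, 0.5 nA step: 9
voltage range: -78.2 .. 53.4 mV
```

The cell rests near −71 mV, fires a train of nine overshooting action
potentials during the step (regenerative Na activation followed by
delayed-rectifier repolarization), and after-hyperpolarizes below rest.
The other example scripts show voltage-clamp current separation, CSV
round-tripping, and config-file parameter overrides.

The same run from the shell, with a figure:

```
ionclamp run --mode current --amplitude 0.5 --auto-rest \
    --out trace.csv --plot trace.png
```

writes 7001 rows × 25 columns (time, voltage, net current, then current and
chord conductance per channel).  `ionclamp channels` lists the eleven
mechanisms with their defaults, `ionclamp rest` prints the resting
potential, and `ionclamp validate-config` checks a YAML parameter file.

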