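"""Current clamp: inject a depolarizing step and count action potentials.

Builds the default 11-channel membrane, finds its resting potential, then
drives it with a 0.5 nA step for 50 ms (the default 10/50/10 ms protocol).
The printed numbers are the resting potential, the number of upward
0 mV crossings (action potentials), and the voltage extremes of the trace.
"""

from ionclamp import (
    SimulationConfig,
    build_default_model,
    default_protocol,
    find_rest,
    run,
    spike_count,
)

model = build_default_model()
v_rest = find_rest(model)
print(f"resting potential: {v_rest:.2f} mV")

protocol = default_protocol("current", amplitude=0.5)  # nA
result = run(model, protocol, SimulationConfig(auto_rest=True))

n_spikes = spike_count(result.voltage)
print(f"spikes during the 50 ms, 0.5 nA step: {n_spikes}")
print(f"voltage range: {result.voltage.min():.1f} .. "
      f"{result.voltage.max():.1f} mV")
print("A train of overshooting spikes (peak above 0 mV) from a rest near "
      "-70 mV is the expected regenerative Na/K response.")
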