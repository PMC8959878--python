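"""Config files: override channel parameters and see the effect on rest.

A YAML document can change any conductance, reversal, gate constant, or
calcium-pool setting.  Here the potassium leak is doubled, which pulls the
resting potential toward E_K (about -85 mV with the default mammalian
concentrations).
"""

import io

from ionclamp import find_rest, load_config

baseline = load_config(io.StringIO(""))
v0 = find_rest(baseline.build_model())
print(f"default resting potential: {v0:.2f} mV")

doc = """
channels:
  k_leak: {g_max: 0.004}
"""
modified = load_config(io.StringIO(doc))
v1 = find_rest(modified.build_model())
print(f"with doubled K leak (0.004 uS): {v1:.2f} mV")
print("More resting K conductance hyperpolarizes the cell toward the "
      "potassium Nernst potential, as textbook membrane theory predicts.")
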