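"""Repeat the configuration-A experiment at 0, 30 and 700 mg of adsorbent.

More suspended microspheres regenerate the dialysate faster (they strip
free bilirubin from it), keeping the blood-to-dialysate driving force
high: the outlet concentration drops monotonically with adsorbent mass.
"""

import numpy as np

import hepadial as hd

config = hd.default_config_a()
schedule = np.arange(0.0, 721.0, 120.0)
masses_g = [0.0, 0.03, 0.7]

datasets = hd.generate_mass_sweep(config, masses_g, schedule, hd.NoiseModel("none"))

header = "t [min]  " + "  ".join("MP=%4.0f mg" % (1e3 * m) for m in masses_g)
print(header)
for i, t in enumerate(schedule):
    row = "  ".join("%9.3f" % d.outlet_conc[i] for d in datasets)
    print("%7.0f  %s" % (t, row))

# Each column is the outlet bilirubin concentration (µmol/L): at every
# post-fill time the heavier adsorbent loading gives the lower outlet.
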