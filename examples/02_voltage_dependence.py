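"""Voltage dependence of substrate uptake for all three transporters.

Runs the current-voltage/uptake protocol on DAT, NET, and SERT and prints
the uptake slope at each voltage normalized to -90 mV. DAT and NET slow
down steeply with depolarization (their rate-limiting return step carries
charge); SERT is nearly voltage-independent because the K+-loaded return
is electroneutral.
"""

import numpy as np

import monokin as mk

voltages = np.array([-90, -60, -30, 0, 30]) * 1e-3

for builder in (mk.build_dat_model, mk.build_net_model, mk.build_sert_model):
    model = builder()
    result = mk.run_iv(model, voltages=voltages, concentration=30e-6, duration=15.0)
    normalized = result.normalized["uptake_slope"]
    print(f"\n{model.transporter_id}: normalized uptake (reference -90 mV)")
    for v, u in zip(voltages, normalized):
        print(f"  {v * 1e3:+5.0f} mV : {u:5.2f}")
    ratio = normalized[np.isclose(voltages, 0.03)][0]
    print(f"  uptake at +30 mV is {100 * ratio:.0f}% of that at -90 mV")
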