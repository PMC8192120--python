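"""Two-pulse recovery: measuring the catalytic (turnover) rate.

Applies a reference substrate pulse, waits a variable wash time, and
applies a test pulse; the test-pulse peak current recovers as transporters
complete the cycle and become available again. A mono-exponential fit of
the normalized recovery gives the catalytic rate. Compares physiological
intracellular K+ against its replacement by inert NMDG+ for DAT and SERT:
K+ removal halves SERT's rate (it antiports K+) but leaves DAT's
essentially unchanged (its K+ binding is transient).
"""

import monokin as mk

for transporter in ("DAT", "SERT"):
    model = mk.build_model(transporter, cognate=True)
    print(f"\n{transporter}:")
    rates = {}
    for preset in ("physiological", "NMDG_in"):
        result, fit = mk.run_two_pulse(model, preset=preset)
        rates[preset] = fit.rate
        print(f"  {preset:14s} catalytic rate = {fit.rate:5.2f} s^-1 "
              f"(tau = {fit.tau * 1e3:.0f} ms)")
    print(f"  K+ / NMDG+ rate ratio = {rates['physiological'] / rates['NMDG_in']:.2f}")
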