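"""Simulate a substrate application and inspect the evoked currents.

Clamps a DAT-expressing cell at -60 mV, superfuses 30 uM of the fluorescent
substrate for 15 s, and prints the peak and steady-state current amplitudes
and the uptake rate. The peak reflects the initial electrogenic
binding/translocation wave; the steady current reflects continuous cycling
plus the uncoupled conductance; the uptake slope is what the fluorescence
channel of a patch-fluorometry experiment measures.
"""

import monokin as mk

model = mk.build_dat_model()
conditions = mk.get_condition_preset("physiological")

traj, current, fluorescence, window = mk.simulate_application(
    model, conditions, V=-0.060, concentration=30e-6, duration=15.0
)

peak = mk.extract_peak(current, window)
steady = mk.extract_steady(current, window)
slope = mk.extract_uptake_slope(fluorescence, window)

print(f"peak current:    {peak * 1e12:8.2f} pA  (transient, first 200 ms)")
print(f"steady current:  {steady * 1e12:8.2f} pA  (cycling + uncoupled)")
print(f"uptake rate:     {slope:8.3e} molecules/s  (~{slope / 6.022e23:.2e} mol/s)")
print(f"turnover/cell:   {slope / 4e6:8.3f} substrate molecules per transporter per s")
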