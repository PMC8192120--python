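"""Free-energy profile of the DAT transport cycle.

Maps the Gibbs free energy along the outer loop of the DAT scheme (the
conformational trajectory taken in the presence of intracellular K+) at
0 mV and -60 mV under physiological gradients with 30 uM external
substrate. Individual steps may be steeply uphill (notably the conversion
of the K+ site to low affinity), but the cycle total is negative at both
potentials: forward transport is spontaneous.
"""

import monokin as mk

model = mk.build_dat_model()
conditions = mk.get_condition_preset("physiological").with_updates(
    {("S", "out"): 30e-6, ("S", "in"): 30e-9}
)

for V in (0.0, -0.060):
    profile = mk.loop_profile(model.scheme, conditions, V, mk.DAT_OUTER_LOOP)
    print(f"\nouter loop at {V * 1e3:+.0f} mV (kJ/mol):")
    for state, g in zip(profile.path, profile.cumulative):
        print(f"  {state:10s} {g / 1e3:+7.2f}")
    print(f"  total: {profile.total / 1e3:+.2f} kJ/mol "
          f"({'spontaneous' if profile.total < 0 else 'non-spontaneous'})")
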