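"""Balloon release kinetics: how much sirolimus leaves the coating.

The coating releases M_b(t) = a1 (1 - exp(-k1 t)) per unit balloon area
during inflation.  Prints the released areal mass over the 30 s
inflation and the instantaneous molar flux driving the tissue uptake.
"""

import numpy as np

import dcbsim as d

params = d.ModelParameters()
print(f"release capacity a1 = {params.a1} ug/mm^2, "
      f"rate k1 = {params.k1} 1/s, inflation t0 = {params.t0} s\n")
for t in (0.0, 5.0, 10.0, 20.0, 30.0):
    m = d.released_mass(t, params)
    q = d.release_flux(t, params)
    print(f"t = {t:5.1f} s   released {m:7.4f} ug/mm^2   "
          f"flux {q:.3e} mol/(mm^2 s)")
print("\nBy 30 s the balloon has delivered "
      f"{100 * d.released_mass(30, params) / params.a1:.1f}% of its "
      "capacity; the flux is the time derivative of the released mass "
      "converted to moles, so it is largest at inflation and has almost "
      "vanished at deflation.")
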