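"""How plaque composition and interstitial convection shape uptake.

Compares matched annular phantoms — soft (fibrous/fibrofatty), healthy,
and hard (calcium/necrotic core) — at the end of inflation, then shows
the convection amplification of tissue content under the no-flux
interface on the reference composition.
"""

import numpy as np

import dcbsim as d

params = d.ModelParameters()
scen30 = d.ScenarioSpec(interface_mode="no_flux", t0=30.0, t_end=40.0,
                        output_every=10.0)
grids = {
    "soft": d.make_heterogeneous_phantom(d.scenarios.soft_phantom_spec()),
    "healthy": d.make_circular_phantom(1.5, 0.5, 0.04),
    "hard": d.make_heterogeneous_phantom(d.scenarios.hard_phantom_spec()),
}
print("averaged free sirolimus at deflation (t = 30 s):")
for name, grid in grids.items():
    res = d.run_simulation(grid, params, scen30)
    c30 = np.interp(30.0, res.times, res.mean_ct)
    print(f"  {name:>8s}: {c30 * 1e9:6.3f} x 1e-9 mol/mm^3")
print("Uptake follows diffusivity: the fast FI/FF regions drain the "
      "balloon film fastest, the calcified interface leaves drug "
      "stranded on the balloon.\n")

ref = d.make_heterogeneous_phantom(d.scenarios.ref_phantom_spec())
for conv in (True, False):
    scen = d.ScenarioSpec(interface_mode="no_flux", convection=conv,
                          t0=30.0, t_end=1830.0, output_every=60.0)
    res = d.run_simulation(ref, params, scen)
    tc = np.interp(1800.0, res.times, res.tissue_content)
    print(f"tissue content at 30 min, convection {'on ' if conv else 'off'}:"
          f" {tc * 1e6:7.1f} ug/g")
print("Filtration both carries extra drug in through the interface and "
      "keeps near-wall drug moving inward, so convection amplifies the "
      "retained dose under the no-flux interface.")
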