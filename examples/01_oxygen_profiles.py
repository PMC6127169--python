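"""Oxygen profiles through eccentric spheroids.

Builds prolate and oblate spheroids (outer semi-major axis 500 um,
consumption 20 mmHg/s, external oxygen 100 mmHg), solves their anoxic
boundaries and prints the oxygen partial pressure along both principal
axes.  At low eccentricity the two solids are nearly indistinguishable;
at e = 0.9 their profiles — and the anoxic extents — visibly separate.
"""

from spheroidox import OxygenModelParams, profile, solve_anoxic_geometry

UM = 1e-6
params = OxygenModelParams(p_o=100.0, D=2e-9, a=20.0)

for e in (0.25, 0.9):
    print(f"\n=== anoxic-shell eccentricity e = {e} ===")
    for shape in ("prolate", "oblate"):
        g = solve_anoxic_geometry(shape, 500 * UM, e, params)
        print(f"{shape}: anoxic semi-major {g.r_n * 1e6:7.2f} um, "
              f"semi-minor {g.b_n * 1e6:7.2f} um")
        for axis in ("major", "minor"):
            samples = profile(g, params, axis=axis, n=6)
            vals = ", ".join(f"{s.P:6.1f}" for s in samples)
            print(f"  {axis} axis P [mmHg] from core to surface: {vals}")

print("\nEach row runs from the anoxic boundary (P = 0) outward; the last"
      "\nvalue on the minor axis is the external pressure because the model"
      "\npins the surface value at the semi-minor vertex.")
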