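"""Build a backbone, recover its helix parameters from coordinates alone.

Three independent routes to the same physics: the closed-form equations
(dihedrals in, helix parameters out), the screw decomposition of a built
chain (coordinates in), and the coordinate-based chirality indices.
"""

import math

from peptwist import (BackboneGeometry, DihedralState, build_regular,
                      helical_params_exact, screw_decomposition,
                      chi1, chi2, chi3, measure_dihedrals)

geom = BackboneGeometry()
state = DihedralState(phi=-57, psi=-47, omega=180)

chain = build_regular(12, state, geom)
measured = measure_dihedrals(chain)[5]
print(f"built 12-residue chain; residue 5 measures back "
      f"(phi, psi, omega) = ({measured[0]:.3f}, {measured[1]:.3f}, "
      f"{measured[2]:.3f})")

d, theta = helical_params_exact(state, geom)
sp = screw_decomposition(chain)
print(f"closed form : |d| = {abs(d):.4f} A  cos(theta) = "
      f"{math.cos(math.radians(theta)):+.4f}  h = "
      f"{math.copysign(1, d) * math.sin(math.radians(theta)):+.4f}")
print(f"screw oracle: |d| = {sp.abs_d:.4f} A  cos(theta) = "
      f"{sp.cos_theta:+.4f}  h = {sp.h:+.4f}  rho_a = {sp.rho_alpha:.4f} A")

ca = chain.ca_positions
print(f"chirality indices: chi1 = {chi1(ca):+.4f}  chi2 = {chi2(ca):+.4f} "
      f"rad  chi3 = {chi3(ca):+.5f}")
# All three indices share h's sign: the built helix twists right.
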