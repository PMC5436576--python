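"""Helical parameters and handedness of single backbone states.

Answers the motivating question: is the regular peptide at
phi = psi = -100 deg left- or right-handed?  (Naively it sits on the
"right-handed" side of the Ramachandran diagonal.)
"""

from peptwist import (BackboneGeometry, DihedralState, handedness_of,
                      helical_params_exact, helix_radii)

geom = BackboneGeometry()  # equilibrium bond lengths and angles

for label, (phi, psi, omega) in {
    "alpha helix      ": (-57, -47, 180),
    "phi=psi=-100     ": (-100, -100, 180),
    "extended (beta)  ": (-120, 140, 180),
    "cis, near-flat   ": (35, -35, 0),
}.items():
    state = DihedralState(phi, psi, omega)
    d, theta = helical_params_exact(state, geom)
    res = handedness_of(state, geom)
    rho_a = helix_radii(state, geom, d, theta)[1]
    h = "undefined" if res.h is None else f"{res.h:+.3f}"
    print(f"{label} (phi={phi:6.1f}, psi={psi:6.1f}, omega={omega:5.1f}): "
          f"d={d:+.3f} A/res  theta={theta:7.2f} deg  rho_a={rho_a:.2f} A  "
          f"h={h}  [{res.region}]")

# d is the rise per residue along the helix axis, theta the twist per
# residue (360/theta = residues per turn), rho_a the CA cylinder radius,
# and h = sgn(d) sin(theta) the twist handedness: + right, - left.
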