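# peptwist

Helical parameters and twist handedness of regular peptide backbones.

Any peptide backbone that repeats the same dihedral state (φ, ψ, ω) at every
residue traces a helix. `peptwist` computes, in closed form, the two numbers
that characterize that helix — the axial displacement per residue *d* (Å) and
the angular displacement per residue θ (degrees) — directly from the dihedral
angles and the covalent geometry (three bond lengths, three bond angles). From
them it derives the twist handedness

```
h = sgn(d) · sin θ,
```

which is positive for right-twisting and negative for left-twisting backbones,
together with the cylinder radii of the N, Cα and C′ atoms.

This answers questions the familiar Ramachandran picture cannot. The naive
reading — "below the φ = −ψ diagonal is right-handed" — is wrong over most of
the plane. For example, the regular backbone at φ = ψ = −100° sits on the
"right-handed" side of the diagonal but is actually a left-handed helix:

```console
$ peptwist compute --phi -100 --psi -100
phi_deg      -100.0000
psi_deg      -100.0000
omega_deg    180.0000
d_angstrom   -2.0137
theta_deg    71.6164
sin_theta    0.9490
h            -0.9490
region       left
rho_n_angstrom      2.2354
rho_alpha_angstrom  2.7733
rho_c_angstrom      2.2862
```

The true handedness boundaries are the two curves where the backbone is flat:
*d* = 0 (the chain closes into a ring) and θ = 180° (a planar zig-zag). These
split the Ramachandran plane into at least four regions of alternating sign
for every value of ω.

## What's in the box

| module | contents |
| --- | --- |
| `peptwist.geometry` | exact closed forms for (d, θ) from (φ, ψ, ω); two-term simplified trans/cis forms and re-derivation of their coefficients; same-atom-type distances; helix radii; ω wrapping |
| `peptwist.handedness` | h = sgn(d)·sin θ, region classification (right / left / flat_extended / flat_circular) |
| `peptwist.chirality` | coordinate-based chirality indices χ1, χ2, χ3 of a Cα trace |
| `peptwist.structure` | internal-coordinate backbone builder, dihedral measurement, PDB read/write, and a screw-decomposition oracle that recovers (|d|, cos θ, h, radii) from coordinates alone |
| `peptwist.survey` | Ramachandran-plane grids of (d, θ, h), boundary-curve extraction, sign-region counting, axis-frame conversion, attainable (θ, d) envelopes |
| `peptwist.cli` | the `peptwist` command (`compute`, `map`, `boundaries`, `envelope`, `build`, `analyze`) |

## Worked example

Build an ideal α-helix (φ = −57°, ψ = −47°, ω = 180°), then recover its helix
parameters three independent ways — closed form, screw decomposition of the
built coordinates, and coordinate-based chirality indices
(`examples/build_and_validate.py`):

```text
built 12-residue chain; residue 5 measures back (phi, psi, omega) = (-57.000, -47.000, 180.000)
closed form : |d| = 1.5622 A  cos(theta) = -0.1628  h = +0.9867
screw oracle: |d| = 1.5622 A  cos(theta) = -0.1628  h = +0.9867  rho_a = 2.2853 A
chirality indices: chi1 = +0.5862  chi2 = +0.6738 rad  chi3 = +0.01300
```

θ ≈ 99.4° gives 360/99.4 ≈ 3.62 residues per turn and a rise of 1.56 Å per
residue — the textbook α-helix. All three routes agree on the right-handed
sign.

Surveying the whole plane (`examples/handedness_map.py`):

```text
omega = 180.0 deg: 4 sign regions (cell counts [11515, 11337, 4861, 4683]),
   right-twisting cells: 50.0%, left-twisting: 50.0%
   boundary curves: 2 x d=0 (flat rings), 1 x theta=pi (flat zig-zags)
omega =   0.0 deg: 4 sign regions (cell counts [12691, 12602, 3596, 3507]),
   right-twisting cells: 50.0%, left-twisting: 50.0%
   boundary curves: 1 x d=0 (flat rings), 2 x theta=pi (flat zig-zags)
```

The same surveys are available from the shell:

```console
$ peptwist map --omega 180 --step 2 --out rama_trans.csv
$ peptwist boundaries --omega 180 --out boundaries.csv
$ peptwist envelope --omega 180 --halfwidth 5 --out envelope.csv
$ peptwist build --n 12 --phi -57 --psi -47 --out helix.pdb
$ peptwist analyze helix.pdb
```

## Conventions

- Angles in degrees at the API surface; distances in Å.
- d is signed; the representation is fixed by wrapping ω into
  [Δ, Δ+360) with Δ = −90° by default. Shifting ω by 360° maps
  (d, θ) → (d, 360° − θ), an equivalent screw; h is invariant.
- Grids are indexed `[psi, phi]` with inclusive endpoint axes.
- See `docs/methods.md` for the equations, parameter defaults and numerical
  choices.
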