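# Methods

## Model

A *regular* peptide backbone repeats the same internal coordinates at every
residue: the dihedrals (φ, ψ, ω) and six stereochemical constants — bond
lengths v_NCα, v_CαC′, v_C′N and bond angles σ_N (C′⁻¹–N–Cα), σ_α (N–Cα–C′),
σ_C (Cα–C′–N⁺¹). By symmetry such a chain traces a helix: the map from one
residue's frame to the next is a fixed screw motion with

- **axial displacement** d — the signed rise per residue along the screw axis
  (Å); its sign distinguishes the two axis orientations of one conformation,
- **angular displacement** θ ∈ [0, 360°) — the twist per residue about the
  axis,
- per-atom-type **cylinder radii** ρ_N, ρ_α, ρ_C′ — each atom type lies on
  its own coaxial cylinder.

### Exact identities

Both helix parameters are exact trigonometric sums over the four half-angle
combinations (±φ ± ψ ± ω)/2, weighted by products of sin/cos of the half
bond angles σ/2 (`geometry._half_angle_terms`):

```
cos(θ/2)   =  Σ ±  k_i               cos[(±φ ± ψ ± ω)/2]
d·sin(θ/2) =  Σ ± (±v₁ ± v₂ ± v₃) k_i sin[(±φ ± ψ ± ω)/2]
```

with k_i the corresponding products of sin(σ_N/2), sin(σ_α/2), sin(σ_C/2)
and their cosines, and matching ± patterns on bond lengths in the second
identity. θ is recovered as 2·arccos of the first expression (clamped to
[−1, 1] with a 10⁻¹² overflow tolerance), d by dividing the second by
sin(θ/2). θ = 0 would leave d undefined (`DegenerateGeometryError`), but is
unattainable for physical geometry: with equilibrium constants
max cos(θ/2) ≈ 0.8457, so θ ≥ ~64°.

**Mirror rule.** (φ, ψ, ω) → (−φ, −ψ, −ω) gives the enantiomer: same θ,
negated d. Consequently h (below) is antisymmetric under point reflection of
the Ramachandran plane.

### Amide-dihedral wrapping

The half-angle arguments flip sign under ω → ω + 360°, which maps
(d, θ) → (d, 360° − θ): the same screw, described with the opposite axis
convention. One representative per period is therefore fixed by wrapping ω
into [Δ, Δ+360°), default Δ = −90°, which keeps the cis (0 ± ε) and trans
(180 ± ε) populations each inside a contiguous window. `wrap_omega` is
idempotent and guards the floating-point seam at both window edges.
h = sgn(d)·sin θ is invariant under the ±360° shift, so handedness never
depends on the wrapping choice.

### Two-term simplified forms

At fixed ω ∈ {0°, 180°} each identity collapses, in the rotated coordinates
s = (φ+ψ)/2 and t = (φ−ψ)/2, to a two-term linear form. With equilibrium
geometry:

| | cos(θ/2) | d·sin(θ/2) |
|---|---|---|
| trans (ω = 180°) | −0.8235 sin s + 0.0222 sin t | 2.9986 cos s − 0.6575 cos t |
| cis (ω = 0°) | 0.4052 cos s − 0.4932 cos t | 2.3093 sin s + 0.0028 sin t |

`derive_simplified_coefficients` re-derives these from any geometry by
evaluating the exact right-hand sides at basis points where exactly one basis
function equals 1 and the other 0 — (s, t) = (90°, 0°) and (0°, 90°). For a
form that *is* a linear combination of the two basis functions, single-point
evaluation is exact; no fitting or symbolic algebra is involved. (A 2×2
collocation at (0, 0)/(90, 90) is singular for the sine-basis identities,
whose both basis functions vanish at the first point.) The printed
coefficients agree with this reduction to all four decimals; evaluating the
rounded forms agrees with the exact equations to ≲ 2×10⁻³ in cos(θ/2) and
d·sin(θ/2) over the whole plane.

### Same-type distances and radii

The distance between the same backbone atom in adjacent residues depends on
only one dihedral (the one spanned by the three-bond path between them): ω
for Cα, φ for C′, ψ for N. The law-of-cosines-type closed form lives in
`same_type_distance`; for equilibrium geometry the adjacent Cα–Cα distance is
3.80 Å (trans) and 2.83 Å (cis), independent of φ and ψ. Radii follow from
the chord relation ρ_X² = (d_X² − d²)/(2 − 2 cos θ); radicands below −10⁻⁹
raise (inconsistent inputs), smaller negative excursions clamp to zero.

## Handedness

```
h = sgn(d) · sin θ       (h ∈ [−1, 1])
```

h > 0 is a right-twisting helix, h < 0 left-twisting. Two flat boundaries:

- **θ = 180°** (`flat_extended`): a planar zig-zag, h = 0 but d ≠ 0;
- **d = 0** (`flat_circular`): the chain closes into a planar ring; h is
  *undefined* (sgn 0), reported as `None`.

Tolerances: |d| ≤ 10⁻⁹ Å triggers `flat_circular`; |sin θ| ≤ 10⁻⁹ with d ≠ 0
triggers `flat_extended`. These ε's only decide the *labels*; numeric h is
never thresholded.

Quadrant rule: d > 0 with θ < 180° and d < 0 with θ > 180° are right-handed;
the other two quadrants left-handed.

## Chirality indices

Coordinate-only chirality measures of a Cα trace (N points, bond vectors
v_i = P_{i+1} − P_i):

- **χ₁** = (1/N) Σ v_{i−1} · (v_i × v_{i+1}) / (|v_{i−1}||v_i||v_{i+1}|) —
  normalized triple products;
- **χ₂** = (1/N) Σ atan2(|v_i| v_{i−1}·(v_i×v_{i+1}),
  (v_{i−1}×v_i)·(v_i×v_{i+1})) — mean Cα virtual torsion, radians;
- **χ₃** = (4!/(3N⁴)) Σ over distinct ordered quadruples (i, j, k, l) of
  [(r_ij × r_kl) · r_il] (r_ij·r_jk)(r_jk·r_kl) / (normalizing powers of the
  distances), with the **interatomic convention r_ij = P_i − P_j**. O(N⁴); a
  `max_n` cap (default 30) guards against accidental large inputs.

All three are zero for planar or collinear traces, negate under mirror
reflection, and are invariant under rigid motion. On regular backbones built
at every 2° Ramachandran cell with |h| > 0.05, the signs of χ₁ and χ₂ agree
with sgn(h) at 100% of cells for both ω = 180° and ω = 0° (verified in the
acceptance tests); χ₃ agrees on canonical helices.

## Structure module

- **Builder**: sequential internal-coordinate (NeRF) placement. The first
  residue is laid in a canonical frame (N at origin, Cα on +x, C′ in the
  xy-plane); residue r's ω is the peptide bond *following* it.
  `build_pattern` cycles an arbitrary list of states.
- **Dihedral measurement**: atan2-based torsion; φ of the first residue and
  ψ, ω of the last are NaN; near-collinear frames yield NaN rather than
  noise.
- **Screw oracle**: for each residue pair, the rigid transform is recovered
  with a least-squares rotation fit (Kabsch via
  `scipy.spatial.transform.Rotation.align_vectors`); regularity across pairs
  is enforced to rtol 10⁻⁶ (`NotRegularError` otherwise). The rotation angle
  gives θ up to axis orientation, the translation's axis component |d|, and
  an axis point follows from least squares on (I − R)p = t_⊥. Because the
  recovered axis orientation is arbitrary, the oracle reports
  orientation-invariant quantities only: h, |d|, cos θ, and the radii. It
  agrees with the closed forms to ~10⁻⁶ on randomized states.
- **PDB I/O** via gemmi: poly-glycine, chain A, 3-decimal coordinate
  precision (round-trip dihedral error ≲ 0.1°); optional carbonyl oxygens;
  strict mode raises on missing backbone atoms naming the residue, lenient
  mode masks them as NaN.

## Surveys

- **Grids**: inclusive-endpoint axes (e.g. 181 × 181 at 2°), arrays indexed
  `[psi, phi]`. Fields: d, θ, h, and the two smooth half-angle fields.
- **Boundary curves** are extracted by marching squares
  (`skimage.measure.find_contours`) on the *smooth* fields — d·sin(θ/2) for
  d = 0 and cos(θ/2) for θ = 180° — never on d or h themselves, whose
  quotient/sign structure would break sub-cell interpolation. Linear
  interpolation on a 2° grid leaves level-set residuals < 10⁻³.
- **Region counting** drops the duplicated seam row/column, then labels each
  sign of h (|h| > 10⁻¹² and finite) with 4-connectivity,
  *without* periodic wraparound: regions touching opposite edges are counted
  separately, matching how the square map is read.
- **Frame conversion** between [−180°, 180°) and [0°, 360°) is a shift–
  reindex with `np.pad(mode="wrap")` to rebuild the inclusive seam; it is an
  involution up to the seam's floating-point representative.
- **Envelope**: sweeping ω over a window around a central value maps every
  (φ, ψ) cell to the attainable (θ, d) cloud. The trans cloud stays clear of
  θ ≈ 180°, d ≈ 0 (no flat conformation exists near trans); the cis cloud
  reaches it at φ = −ψ ≈ ±35°, where the flat-extended and flat-circular
  boundary curves nearly meet.

### Geometry of the handedness map

For every sampled ω the two boundary curves split the square into **at least
four** sign regions. For trans, the θ = 180° curve hugs the φ = −ψ diagonal
(within ~8°, due to the small 0.0222 cross term) and two d = 0 ovals sit in
the quadrant interiors; along the main diagonal φ = ψ, d changes sign at
≈ ±77.3°. The naive diagonal rule ("below φ = −ψ is right-handed") therefore
fails inside the ovals — which is where φ = ψ = −100° lives — while holding
throughout the α_R, β and α_L basins where folded proteins concentrate
(checked with an |h| > 0.05 guard, since h → 0 continuously at the
boundaries).

## Parameters and defaults

| symbol | meaning | default |
|---|---|---|
| v_NCα, v_CαC′, v_C′N | bond lengths | 1.459, 1.525, 1.336 Å |
| σ_N, σ_α, σ_C | bond angles | 121.7°, 111.0°, 117.2° |
| Δ | ω wrapping origin | −90° |
| grid step | survey resolution | 2° (must divide 360) |
| ε_d, ε_θ | flat-label tolerances | 10⁻⁹ |
| screw rtol | regularity check | 10⁻⁶ |

All defaults are overridable through `BackboneGeometry` and the CLI's
`--sigma-*` / `--v-*` options.

## Limitations

- The closed forms describe *regular* chains only; `screw_decomposition`
  rejects irregular ones rather than averaging.
- χ₃ is O(N⁴) and capped at N = 30 by default.
- Region counting is resolution-dependent in principle; counts are stable
  from 2° grids down.
- The simplified two-term forms exist only at ω exactly 0° or 180°; other ω
  use the exact identities.
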