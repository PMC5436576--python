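"""Backbone construction, dihedral measurement, PDB I/O and the screw oracle.

Chains are poly-glycine backbones (N, CA, C per residue) built by
sequential internal-coordinate extension from a repeating dihedral state
(or a cyclic pattern of states) and a set of stereochemical constants.
The screw decomposition recovers the helix parameters of a regular chain
purely from coordinates — by superposing one residue onto the next and
splitting the rigid transform into a rotation about and translation
along a single axis — and so provides an independent geometric check on
the closed-form equations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import gemmi
from scipy.spatial.transform import Rotation

from .geometry import BackboneGeometry, DihedralState, wrap_omega

__all__ = ["Chain", "ScrewParams", "build_regular", "build_pattern",
           "measure_dihedrals", "screw_decomposition", "write_pdb",
           "read_pdb", "NotRegularError"]


class NotRegularError(ValueError):
    """Raised when a chain's residue-to-residue transform is not constant."""


@dataclass
class Chain:
    """Ordered backbone coordinates: rows of (N, CA, C), one per residue."""

    coords: np.ndarray  # shape (n_residues, 3, 3): [residue, atom(N/CA/C), xyz]
    states: list[DihedralState] | None = None  # generating dihedrals, if built

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[1:] != (3, 3):
            raise ValueError("coords must have shape (n_residues, 3, 3)")
        if len(self.coords) < 1:
            raise ValueError("chain needs at least one residue")

    def __len__(self) -> int:
        return len(self.coords)

    @property
    def n_positions(self) -> np.ndarray:
        return self.coords[:, 0]

    @property
    def ca_positions(self) -> np.ndarray:
        return self.coords[:, 1]

    @property
    def c_positions(self) -> np.ndarray:
        return self.coords[:, 2]


def _dihedral(p0, p1, p2, p3) -> float:
    """Signed torsion angle p0-p1-p2-p3 in degrees, IUPAC sign convention."""
    b0, b1, b2 = p1 - p0, p2 - p1, p3 - p2
    n1, n2 = np.cross(b0, b1), np.cross(b1, b2)
    nb1 = np.linalg.norm(b1)
    if np.linalg.norm(n1) < 1e-12 or np.linalg.norm(n2) < 1e-12:
        return math.nan
    return math.degrees(math.atan2(np.dot(np.cross(n1, n2), b1) / nb1,
                                   np.dot(n1, n2)))


def _extend(a, b, c, length: float, angle_deg: float, torsion_deg: float
            ) -> np.ndarray:
    """Place atom d from a-b-c with bond c-d, angle b-c-d, torsion a-b-c-d."""
    ang = math.radians(angle_deg)
    tor = math.radians(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array([-length * math.cos(ang),
                        length * math.sin(ang) * math.cos(tor),
                        length * math.sin(ang) * math.sin(tor)])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def build_pattern(states: Sequence[DihedralState], n: int,
                  geom: BackboneGeometry = BackboneGeometry()) -> Chain:
    """Build an n-residue backbone cycling through a list of dihedral states.

    Residue r takes its (phi, psi, omega) from ``states[r % len(states)]``;
    omega is the dihedral of the peptide bond *following* residue r.  The
    first residue sits in a canonical frame: N at the origin, CA on +x,
    C in the xy-plane (y > 0).  Measuring dihedrals on the result returns
    the inputs to well below 1e-6 degrees.
    """
    if n < 2:
        raise ValueError("need at least 2 residues")
    if not states:
        raise ValueError("states must be non-empty")
    g = geom
    sa = math.radians(g.sigma_alpha)
    n0 = np.zeros(3)
    ca0 = np.array([g.v_n_alpha, 0.0, 0.0])
    c0 = ca0 + g.v_alpha_c * np.array([-math.cos(sa), math.sin(sa), 0.0])
    residues = [np.stack([n0, ca0, c0])]
    per_residue: list[DihedralState] = [states[0]]
    for r in range(1, n):
        prev_state = states[(r - 1) % len(states)]
        cur_state = states[r % len(states)]
        per_residue.append(cur_state)
        pn, pca, pc = residues[-1]
        nn = _extend(pn, pca, pc, g.v_c_n, g.sigma_c, prev_state.psi)
        nca = _extend(pca, pc, nn, g.v_n_alpha, g.sigma_n, prev_state.omega)
        nc = _extend(pc, nn, nca, g.v_alpha_c, g.sigma_alpha, cur_state.phi)
        residues.append(np.stack([nn, nca, nc]))
    return Chain(coords=np.stack(residues), states=per_residue)


def build_regular(n: int, state: DihedralState,
                  geom: BackboneGeometry = BackboneGeometry()) -> Chain:
    """Build an n-residue backbone in which every residue repeats ``state``."""
    return build_pattern([state], n, geom)


def measure_dihedrals(chain: Chain, delta: float = -90.0
                      ) -> list[tuple[float, float, float]]:
    """Per-residue (phi, psi, omega) in degrees, NaN where not measurable.

    phi_i needs the preceding carbonyl carbon, psi_i the following
    nitrogen and omega_i — assigned to the peptide bond following residue
    i — the following alpha carbon, so the first residue lacks phi and
    the last lacks psi and omega.  Omegas are wrapped into
    [delta, delta + 360).
    """
    if len(chain) < 2:
        raise ValueError("need at least 2 residues to measure dihedrals")
    out = []
    co = chain.coords
    for i in range(len(chain)):
        ni, cai, ci = co[i]
        phi = _dihedral(co[i - 1][2], ni, cai, ci) if i > 0 else math.nan
        if i < len(chain) - 1:
            n_next, ca_next = co[i + 1][0], co[i + 1][1]
            psi = _dihedral(ni, cai, ci, n_next)
            omega = _dihedral(cai, ci, n_next, ca_next)
            if math.isfinite(omega):
                omega = wrap_omega(omega, delta)
        else:
            psi = omega = math.nan
        out.append((phi, psi, omega))
    return out


@dataclass(frozen=True)
class ScrewParams:
    """Helix parameters recovered from coordinates alone.

    Only orientation-invariant quantities are reported: the screw axis of
    a rigid transform has no preferred direction, so the sign of the
    axial translation flips with the axis while h = sgn(d) sin(theta)
    and |d| do not.
    """

    h: float
    abs_d: float
    cos_theta: float
    rotation_deg: float  # rotation magnitude in (0, 180]
    rho_n: float
    rho_alpha: float
    rho_c: float


def screw_decomposition(chain: Chain, rtol: float = 1e-6) -> ScrewParams:
    """Recover helix parameters of a regular chain by screw decomposition.

    Least-squares superposes each residue's (N, CA, C) triad onto the
    next to obtain the repeating rigid transform, verifies it is constant
    along the chain (else :class:`NotRegularError`), then splits it into
    a rotation angle about and a translation along the screw axis.  The
    per-type radii are the distances of the atoms from that axis.

    Raises ValueError when the rotation is too small to define an axis
    (|sin| of the rotation angle below 1e-3).
    """
    if len(chain) < 4:
        raise ValueError("need at least 4 residues")
    co = chain.coords
    rots, trans = [], []
    for i in range(len(chain) - 1):
        a, b = co[i], co[i + 1]
        ac, bc = a.mean(axis=0), b.mean(axis=0)
        rot, _ = Rotation.align_vectors(b - bc, a - ac)
        rots.append(rot)
        trans.append(bc - rot.apply(ac))
    r0, t0 = rots[0], trans[0]
    for r, t in zip(rots[1:], trans[1:]):
        if (np.abs(r.as_matrix() - r0.as_matrix()).max() > rtol
                or np.abs(t - t0).max() > rtol):
            raise NotRegularError("residue-to-residue transform is not constant")

    rotvec = r0.as_rotvec()
    alpha = float(np.linalg.norm(rotvec))  # in [0, pi]
    if abs(math.sin(alpha)) < 1e-3:
        raise ValueError("rotation too close to 0 or 180 deg to fix an axis")
    axis = rotvec / alpha
    d_along = float(np.dot(t0, axis))
    h = math.copysign(1.0, d_along) * math.sin(alpha) if d_along != 0 else 0.0

    # A point p on the axis satisfies (I - R) p = t_perp; fix the component
    # along the axis to zero and solve the remaining rank-2 system.
    t_perp = t0 - d_along * axis
    A = np.eye(3) - r0.as_matrix()
    p, *_ = np.linalg.lstsq(np.vstack([A, axis]), np.append(t_perp, 0.0),
                            rcond=None)

    def radius(point: np.ndarray) -> float:
        rel = point - p
        return float(np.linalg.norm(rel - np.dot(rel, axis) * axis))

    return ScrewParams(h=h, abs_d=abs(d_along), cos_theta=math.cos(alpha),
                       rotation_deg=math.degrees(alpha),
                       rho_n=radius(co[0][0]), rho_alpha=radius(co[0][1]),
                       rho_c=radius(co[0][2]))


_O_LENGTH, _O_ANGLE = 1.229, 120.5  # carbonyl oxygen placement (cosmetic only)


def write_pdb(chain: Chain, path: str | Path, with_oxygen: bool = False) -> None:
    """Write the chain as poly-glycine ATOM records (chain A)."""
    st = gemmi.Structure()
    st.name = "peptwist"
    model = gemmi.Model("1")
    ch = gemmi.Chain("A")
    for i, (npos, capos, cpos) in enumerate(chain.coords):
        res = gemmi.Residue()
        res.name = "GLY"
        res.seqid = gemmi.SeqId(i + 1, " ")
        atoms = [("N", "N", npos), ("CA", "C", capos), ("C", "C", cpos)]
        if with_oxygen and i < len(chain) - 1:
            o = _extend(chain.coords[i + 1][0], capos, cpos,
                        _O_LENGTH, _O_ANGLE, 180.0)
            atoms.append(("O", "O", o))
        for name, element, pos in atoms:
            at = gemmi.Atom()
            at.name = name
            at.element = gemmi.Element(element)
            at.pos = gemmi.Position(*pos)
            at.occ = 1.0
            at.b_iso = 0.0
            res.add_atom(at)
        ch.add_residue(res)
    model.add_chain(ch)
    st.add_model(model)
    st.setup_entities()
    st.write_pdb(str(path))


def read_pdb(path: str | Path, chain_id: str | None = None,
             strict: bool = True) -> Chain:
    """Read N/CA/C backbone coordinates from a PDB file.

    With ``strict`` (default) a residue missing any backbone atom raises;
    otherwise it is skipped.  ``chain_id`` selects a chain, defaulting to
    the first.
    """
    st = gemmi.read_structure(str(path))
    if len(st) == 0 or len(st[0]) == 0:
        raise ValueError(f"no chains found in {path}")
    model = st[0]
    ch = None
    if chain_id is None:
        ch = model[0]
    else:
        for c in model:
            if c.name == chain_id:
                ch = c
                break
        if ch is None:
            raise ValueError(f"chain {chain_id!r} not found in {path}")
    rows = []
    for res in ch:
        atoms = {}
        for at in res:
            if at.name in ("N", "CA", "C"):
                atoms[at.name] = [at.pos.x, at.pos.y, at.pos.z]
        missing = [a for a in ("N", "CA", "C") if a not in atoms]
        if missing:
            if strict:
                raise ValueError(
                    f"residue {res.seqid.num} ({res.name}) is missing "
                    f"backbone atom(s) {','.join(missing)}")
            continue
        rows.append([atoms["N"], atoms["CA"], atoms["C"]])
    if not rows:
        raise ValueError(f"no complete backbone residues in {path}")
    return Chain(coords=np.array(rows))
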