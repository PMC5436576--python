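"""Closed-form helical parameters of a regular peptide backbone.

A backbone in which every residue repeats the same internal coordinates
traces a helix.  Given the three backbone dihedrals (phi, psi, omega) and
the six stereochemical constants of the repeating unit (bond lengths
N-CA, CA-C, C-N and bond angles at N, CA, C), the axial displacement per
residue ``d`` (the signed rise, in angstrom) and the angular displacement
per residue ``theta`` (the twist about the helix axis, in degrees) follow
from exact trigonometric identities.  With equilibrium geometry and a
fixed amide dihedral (trans: omega = 180 deg; cis: omega = 0 deg) those
identities collapse to two-term linear forms in sin/cos of (phi+psi)/2
and (phi-psi)/2; this module both evaluates the published forms and
re-derives their coefficients from any geometry.

All public angles are degrees; all lengths are angstrom.  Radians are
used only internally.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal

import numpy as np

__all__ = [
    "BackboneGeometry",
    "DihedralState",
    "HelicalParams",
    "DegenerateGeometryError",
    "wrap_omega",
    "helical_params_exact",
    "helical_params_simplified",
    "derive_simplified_coefficients",
    "same_type_distance",
    "helix_radii",
    "helix_radius",
    "TRANS_COEFFICIENTS",
    "CIS_COEFFICIENTS",
]

_DEG = math.pi / 180.0

# Published two-term coefficients for the equilibrium geometry below.
# cos(theta/2) = a_cos*B1 + b_cos*B2 ; d*sin(theta/2) = a_d*B3 + b_d*B4
# trans basis: B1,B2 = sin(s), sin(t); B3,B4 = cos(s), cos(t)
# cis basis:   B1,B2 = cos(s), cos(t); B3,B4 = sin(s), sin(t)
# with s = (phi+psi)/2, t = (phi-psi)/2.
TRANS_COEFFICIENTS = (-0.8235, 0.0222, 2.9986, -0.6575)
CIS_COEFFICIENTS = (0.4052, -0.4932, 2.3093, 0.0028)


class DegenerateGeometryError(ValueError):
    """Raised where a helical parameter is undefined (theta -> 0)."""


@dataclass(frozen=True)
class BackboneGeometry:
    """The six stereochemical constants of one backbone repeat unit.

    Lengths (angstrom): ``v_n_alpha`` (N-CA), ``v_alpha_c`` (CA-C),
    ``v_c_n`` (C-N of the following residue).  Angles (degrees):
    ``sigma_n`` at the nitrogen (C(-1)-N-CA), ``sigma_alpha`` at the
    alpha carbon (N-CA-C), ``sigma_c`` at the carbonyl carbon
    (CA-C-N(+1)).  Defaults are standard equilibrium values.
    """

    v_n_alpha: float = 1.459
    v_alpha_c: float = 1.525
    v_c_n: float = 1.336
    sigma_n: float = 121.7
    sigma_alpha: float = 111.0
    sigma_c: float = 117.2

    def __post_init__(self) -> None:
        for name in ("v_n_alpha", "v_alpha_c", "v_c_n"):
            if not getattr(self, name) > 0:
                raise ValueError(f"bond length {name} must be positive")
        for name in ("sigma_n", "sigma_alpha", "sigma_c"):
            a = getattr(self, name)
            if not 0.0 < a < 180.0:
                raise ValueError(f"bond angle {name} must lie in (0, 180) deg")


def wrap_omega(omega_raw: float, delta: float = -90.0) -> float:
    """Wrap an amide dihedral into the half-open window [delta, delta+360).

    The half-angle arguments of the exact helix equations flip sign under
    a 360-degree shift of omega, so one representative per period must be
    fixed.  The default origin of -90 deg keeps both the cis (0 +/- 5 deg)
    and trans (180 +/- 5 deg) populations contiguous, and maps a raw -180
    to +180.  Idempotent.
    """
    if not (math.isfinite(omega_raw) and math.isfinite(delta)):
        raise ValueError("omega and delta must be finite")
    r = (omega_raw - delta) % 360.0
    if r >= 360.0:  # float rounding at the seam
        r = 0.0
    out = r + delta
    # guard against re-entry drift: adding delta back can round to the
    # upper boundary, which must map to the lower one
    return delta if out - delta >= 360.0 else out


@dataclass(frozen=True)
class DihedralState:
    """One residue's backbone dihedrals (phi, psi, omega), degrees.

    ``omega`` is wrapped on construction into [delta, delta+360);
    ``frame`` records which window phi and psi are declared in.
    """

    phi: float
    psi: float
    omega: float = 180.0
    delta: float = -90.0
    frame: Literal["[-180,180)", "[0,360)"] = "[-180,180)"

    def __post_init__(self) -> None:
        object.__setattr__(self, "omega", wrap_omega(self.omega, self.delta))


def _half_angle_terms(phi, psi, omega, geom: BackboneGeometry):
    """The four (cos, sin) half-angle summands shared by both identities."""
    p, q, w = np.asarray(phi) * _DEG, np.asarray(psi) * _DEG, np.asarray(omega) * _DEG
    sn, sa, sc = (geom.sigma_n * _DEG / 2, geom.sigma_alpha * _DEG / 2,
                  geom.sigma_c * _DEG / 2)
    args = ((p + q + w) / 2, (p - q + w) / 2, (p + q - w) / 2, (-p + q + w) / 2)
    trig = (math.sin(sn) * math.sin(sa) * math.sin(sc),
            math.sin(sn) * math.cos(sa) * math.cos(sc),
            math.cos(sn) * math.sin(sa) * math.cos(sc),
            math.cos(sn) * math.cos(sa) * math.sin(sc))
    return args, trig


def _cos_half_theta(phi, psi, omega, geom: BackboneGeometry):
    args, k = _half_angle_terms(phi, psi, omega, geom)
    return (np.cos(args[0]) * k[0] - np.cos(args[1]) * k[1]
            - np.cos(args[2]) * k[2] - np.cos(args[3]) * k[3])


def _d_sin_half_theta(phi, psi, omega, geom: BackboneGeometry):
    args, k = _half_angle_terms(phi, psi, omega, geom)
    va, vb, vc = geom.v_n_alpha, geom.v_alpha_c, geom.v_c_n
    return ((va + vb + vc) * np.sin(args[0]) * k[0]
            - (va - vb + vc) * np.sin(args[1]) * k[1]
            - (va + vb - vc) * np.sin(args[2]) * k[2]
            - (-va + vb + vc) * np.sin(args[3]) * k[3])


def _theta_from_cos_half(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    over = np.abs(x) - 1.0
    if np.any(over > 1e-12):
        raise ValueError("cos(theta/2) outside [-1, 1] beyond tolerance")
    return 2.0 * np.degrees(np.arccos(np.clip(x, -1.0, 1.0)))


def helical_params_exact(state: DihedralState,
                         geom: BackboneGeometry = BackboneGeometry()
                         ) -> tuple[float, float]:
    """Exact (d, theta) of the helix traced by a regular backbone.

    Returns the signed axial displacement per residue d (angstrom) and
    angular displacement theta in [0, 360) degrees.  Mirror rule: the
    enantiomeric state (-phi, -psi, -omega) gives the same theta and -d.

    Raises :class:`DegenerateGeometryError` when theta = 0, where d is
    undefined (a conformation unattainable for physical backbone
    geometry).
    """
    x = float(_cos_half_theta(state.phi, state.psi, state.omega, geom))
    theta = float(_theta_from_cos_half(x))
    s = math.sin(math.radians(theta) / 2.0)
    if s == 0.0:
        raise DegenerateGeometryError("theta = 0: axial displacement undefined")
    d = float(_d_sin_half_theta(state.phi, state.psi, state.omega, geom)) / s
    return d, theta % 360.0


def helical_params_simplified(phi: float, psi: float,
                              mode: Literal["trans", "cis"] = "trans"
                              ) -> tuple[float, float]:
    """(d, theta) from the published two-term closed forms.

    ``mode='trans'`` evaluates the omega = 180 deg form, ``'cis'`` the
    omega = 0 form, both with the printed four-decimal coefficients for
    equilibrium geometry.  Accurate to ~2e-3 against the exact equations
    (coefficient rounding).
    """
    s = math.radians(phi + psi) / 2.0
    t = math.radians(phi - psi) / 2.0
    if mode == "trans":
        a, b, c, e = TRANS_COEFFICIENTS
        x = a * math.sin(s) + b * math.sin(t)
        y = c * math.cos(s) + e * math.cos(t)
    elif mode == "cis":
        a, b, c, e = CIS_COEFFICIENTS
        x = a * math.cos(s) + b * math.cos(t)
        y = c * math.sin(s) + e * math.sin(t)
    else:
        raise ValueError(f"mode must be 'trans' or 'cis', got {mode!r}")
    theta = float(_theta_from_cos_half(x))
    sh = math.sin(math.radians(theta) / 2.0)
    if sh == 0.0:
        raise DegenerateGeometryError("theta = 0: axial displacement undefined")
    return y / sh, theta % 360.0


def derive_simplified_coefficients(omega: float,
                                   geom: BackboneGeometry = BackboneGeometry()
                                   ) -> tuple[float, float, float, float]:
    """Reduce the exact identities at fixed omega to their two-term forms.

    For omega = 180 (trans) the cos(theta/2) identity is a pure sine
    series in s = (phi+psi)/2 and t = (phi-psi)/2 and the d*sin(theta/2)
    identity a pure cosine series; for omega = 0 (cis) the roles swap.
    Coefficients are read off by evaluating the exact right-hand sides at
    basis points where exactly one basis function is 1 and the other 0 —
    exact for linear-combination forms, no symbolic algebra needed.

    Returns ``(a_cos, b_cos, a_d, b_d)``: the coefficients on the s-term
    and t-term of the cos(theta/2) form, then of the d*sin(theta/2) form.
    With default geometry, reproduces the published values to 4 decimals.

    Raises ValueError for omega values (after wrapping) other than 0 or
    180, where the reduction needs all four basis functions per identity
    and no two-term form exists.
    """
    w = wrap_omega(omega)
    if math.isclose(w, 180.0, abs_tol=1e-12):
        sine_eq, mode = _cos_half_theta, "trans"
    elif math.isclose(w, 0.0, abs_tol=1e-12):
        sine_eq, mode = _d_sin_half_theta, "cis"
    else:
        raise ValueError("two-term reduction exists only for omega 0 or 180 deg")

    def rhs(f, s, t):  # evaluate at (s, t) via phi = s + t, psi = s - t
        return float(f(s + t, s - t, w, geom))

    # sine-basis identity: sin(s) is 1 at (90, 0), sin(t) is 1 at (0, 90)
    sin_a, sin_b = rhs(sine_eq, 90.0, 0.0), rhs(sine_eq, 0.0, 90.0)
    # cosine-basis identity: cos(t) vanishes at t = 90 and vice versa
    cos_eq = _d_sin_half_theta if mode == "trans" else _cos_half_theta
    cos_a, cos_b = rhs(cos_eq, 0.0, 90.0), rhs(cos_eq, 90.0, 0.0)
    if mode == "trans":
        return sin_a, sin_b, cos_a, cos_b
    return cos_a, cos_b, sin_a, sin_b


_ATOM_CYCLES = {
    # (v1, v2, v3, s1, s2, dihedral) for the squared same-type distance:
    # d_X^2 = v1^2+v2^2+v3^2 - 2 v2 (v1 cos s1 + v3 cos s2)
    #         + 2 v1 v3 (cos s1 cos s2 - sin s1 sin s2 cos tau)
    "alpha": ("v_alpha_c", "v_c_n", "v_n_alpha", "sigma_c", "sigma_n", "omega"),
    "c": ("v_c_n", "v_n_alpha", "v_alpha_c", "sigma_n", "sigma_alpha", "phi"),
    "n": ("v_n_alpha", "v_alpha_c", "v_c_n", "sigma_alpha", "sigma_c", "psi"),
}


def same_type_distance(geom: BackboneGeometry, atom_type: str,
                       state: DihedralState) -> float:
    """Distance between the same backbone atom in adjacent residues.

    ``atom_type`` is one of ``'n'``, ``'alpha'``, ``'c'``.  The distance
    depends on only one dihedral: omega for alpha carbons, phi for
    carbonyl carbons, psi for nitrogens.  For equilibrium geometry the
    adjacent CA-CA distance is ~3.8 A (trans) and ~2.8 A (cis).
    """
    try:
        n1, n2, n3, a1, a2, dih = _ATOM_CYCLES[atom_type]
    except KeyError:
        raise ValueError(f"atom_type must be one of 'n', 'alpha', 'c', "
                         f"got {atom_type!r}") from None
    v1, v2, v3 = (getattr(geom, n) for n in (n1, n2, n3))
    s1, s2 = getattr(geom, a1) * _DEG, getattr(geom, a2) * _DEG
    tau = getattr(state, dih) * _DEG
    sq = (v1 * v1 + v2 * v2 + v3 * v3
          - 2.0 * v2 * (v1 * math.cos(s1) + v3 * math.cos(s2))
          + 2.0 * v1 * v3 * (math.cos(s1) * math.cos(s2)
                             - math.sin(s1) * math.sin(s2) * math.cos(tau)))
    return math.sqrt(sq)


def helix_radius(state: DihedralState, geom: BackboneGeometry,
                 d: float, theta: float, atom_type: str) -> float:
    """Cylinder radius of one backbone atom type on the equivalent helix.

    rho_X = sqrt((d_X^2 - d^2) / (2 - 2 cos theta)) with d_X the
    same-type distance.  Requires theta != 0 (mod 360); a radicand more
    negative than -1e-9 flags an inconsistent (d, theta) pair for the
    given geometry, smaller excursions clamp to zero.
    """
    ct = math.cos(math.radians(theta))
    denom = 2.0 - 2.0 * ct
    if denom <= 1e-15:
        raise DegenerateGeometryError("theta = 0 (mod 360): radius undefined")
    dx = same_type_distance(geom, atom_type, state)
    num = dx * dx - d * d
    if num < -1e-9:
        raise ValueError(
            f"inconsistent (d, theta) for {atom_type}: negative radicand")
    return math.sqrt(max(num, 0.0) / denom)


def helix_radii(state: DihedralState, geom: BackboneGeometry,
                d: float, theta: float) -> tuple[float, float, float]:
    """Cylinder radii (rho_n, rho_alpha, rho_c) of the three atom types.

    Each backbone atom type of a regular chain lies on its own coaxial
    cylinder about the common helix axis; see :func:`helix_radius`.
    """
    return tuple(helix_radius(state, geom, d, theta, t)
                 for t in ("n", "alpha", "c"))


@dataclass(frozen=True)
class HelicalParams:
    """Helical description of a regular backbone: rise, twist, radii."""

    d: float
    theta: float
    rho_n: float | None = None
    rho_alpha: float | None = None
    rho_c: float | None = None

    @classmethod
    def from_state(cls, state: DihedralState,
                   geom: BackboneGeometry = BackboneGeometry()
                   ) -> "HelicalParams":
        d, theta = helical_params_exact(state, geom)
        try:
            rn, ra, rc = helix_radii(state, geom, d, theta)
        except DegenerateGeometryError:
            rn = ra = rc = None
        return cls(d=d, theta=theta, rho_n=rn, rho_alpha=ra, rho_c=rc)
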