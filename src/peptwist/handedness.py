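"""Twist handedness of a regular backbone from its helical parameters.

The handedness metric is h = sgn(d) * sin(theta): negative for
left-handed twists, positive for right-handed, |h| proportional to the
extent of twist.  It is undefined at d = 0 (a flat, maximally curved,
ring-like backbone has no handedness) and exactly zero at theta = pi
(a flat, optimally extended zig-zag).  Handedness of twist is distinct
from molecular chirality: a planar conformation has no twist handedness
yet can still be chiral.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

from .geometry import (BackboneGeometry, DihedralState, helical_params_exact,
                       helical_params_simplified)

__all__ = ["HandednessResult", "handedness_value", "handedness_of",
           "EPS_D", "EPS_THETA"]

#: |d| below which h is reported undefined (flat-circular backbone).
EPS_D = 1e-9
#: |sin theta| below which the backbone is classified flat-extended.
EPS_THETA = 1e-9

Region = Literal["right", "left", "flat_extended", "flat_circular", "undefined"]


@dataclass(frozen=True)
class HandednessResult:
    """h in [-1, 1] (or None where undefined) plus a region label."""

    h: float | None
    region: Region

    @property
    def defined(self) -> bool:
        return self.h is not None


def handedness_value(d: float, theta: float) -> HandednessResult:
    """Classify a (d, theta) pair by twist handedness.

    ``theta`` must lie in [0, 360) degrees.  Quadrant rule: d > 0 with
    theta < 180 deg (or d < 0 with theta > 180 deg) is right-handed;
    the other two quadrants are left-handed.  |d| <= EPS_D yields the
    undefined marker (region ``flat_circular``); sin(theta) ~ 0 with
    d nonzero yields h = 0 (region ``flat_extended``).
    """
    if not 0.0 <= theta < 360.0:
        raise ValueError(f"theta must lie in [0, 360), got {theta}")
    if abs(d) <= EPS_D:
        return HandednessResult(h=None, region="flat_circular")
    st = math.sin(math.radians(theta))
    if abs(st) <= EPS_THETA:
        return HandednessResult(h=0.0, region="flat_extended")
    h = math.copysign(1.0, d) * st
    return HandednessResult(h=h, region="right" if h > 0 else "left")


def handedness_of(state: DihedralState,
                  geom: BackboneGeometry = BackboneGeometry(),
                  mode: Literal["exact", "simplified"] = "exact"
                  ) -> HandednessResult:
    """Handedness of the regular backbone defined by one dihedral state."""
    if mode == "exact":
        d, theta = helical_params_exact(state, geom)
    elif mode == "simplified":
        if math.isclose(state.omega, 180.0, abs_tol=1e-9):
            form = "trans"
        elif math.isclose(state.omega, 0.0, abs_tol=1e-9):
            form = "cis"
        else:
            raise ValueError("simplified mode requires omega of 0 or 180 deg")
        d, theta = helical_params_simplified(state.phi, state.psi, form)
    else:
        raise ValueError(f"mode must be 'exact' or 'simplified', got {mode!r}")
    return handedness_value(d, theta)
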