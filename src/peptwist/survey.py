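"""Ramachandran-space surveys of helix parameters and handedness.

Builds dense (phi, psi) grids of (d, theta, sin theta, h, region) for
any fixed amide dihedral omega, extracts the two flat-backbone boundary
curves (d = 0, maximally curved; theta = pi, optimally extended),
counts connected regions of constant twist sign, converts between the
[-180, 180] and [0, 360] angle frames, and sweeps (phi, psi, omega)
to chart the attainable region of the Cartesian (theta, d) map.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import measure as _skmeasure

from .geometry import (BackboneGeometry, _cos_half_theta, _d_sin_half_theta,
                       _theta_from_cos_half, wrap_omega)
from .handedness import EPS_D, EPS_THETA

__all__ = ["RamaGrid", "BoundaryCurve", "rama_grid", "boundary_curves",
           "count_sign_regions", "frame_convert", "thetad_envelope"]

Frame = Literal["[-180,180)", "[0,360)"]
_FRAME_LO = {"[-180,180)": -180.0, "[0,360)": 0.0}


@dataclass
class RamaGrid:
    """A (phi, psi) survey at fixed omega.

    ``phi_values``/``psi_values`` are the inclusive grid axes (both
    endpoints present, so the +360-shifted seam duplicates the first
    row/column).  2-D arrays are indexed [psi, phi].  ``h`` is NaN where
    undefined (|d| below the flat-circular tolerance).
    """

    frame: Frame
    step: float
    omega: float
    phi_values: np.ndarray
    psi_values: np.ndarray
    d: np.ndarray
    theta: np.ndarray
    h: np.ndarray
    cos_half_theta: np.ndarray
    d_sin_half_theta: np.ndarray

    @property
    def sin_theta(self) -> np.ndarray:
        return np.sin(np.radians(self.theta))

    def region_labels(self) -> np.ndarray:
        """String label per cell: right/left/flat_extended/flat_circular."""
        out = np.full(self.h.shape, "flat_extended", dtype=object)
        out[np.isnan(self.h)] = "flat_circular"
        out[self.h > EPS_THETA] = "right"
        out[self.h < -EPS_THETA] = "left"
        return out

    def to_frame(self) -> pd.DataFrame:
        """Long-format table, one row per grid cell."""
        pp, qq = np.meshgrid(self.phi_values, self.psi_values)
        return pd.DataFrame({
            "phi_deg": pp.ravel(), "psi_deg": qq.ravel(),
            "omega_deg": self.omega,
            "theta_deg": self.theta.ravel(),
            "d_angstrom": self.d.ravel(),
            "sin_theta": self.sin_theta.ravel(),
            "h": self.h.ravel(),
            "region": self.region_labels().ravel(),
        })


def _axis(frame: Frame, step: float) -> np.ndarray:
    lo = _FRAME_LO[frame]
    n = 360.0 / step
    if abs(n - round(n)) > 1e-9:
        raise ValueError(f"step {step} does not divide the 360-degree span")
    return lo + step * np.arange(int(round(n)) + 1)


def rama_grid(omega: float = 180.0, step: float = 2.0,
              frame: Frame = "[-180,180)",
              mode: Literal["exact", "simplified"] = "exact",
              geom: BackboneGeometry = BackboneGeometry()) -> RamaGrid:
    """Survey (d, theta, h) over the full (phi, psi) plane at fixed omega.

    The default 2-degree grid includes both endpoints (-180 ... 180).
    ``mode='simplified'`` uses the published two-term coefficient forms
    (omega must wrap to 0 or 180); ``'exact'`` the full identities.
    """
    omega = wrap_omega(omega)
    ax = _axis(frame, step)
    pp, qq = np.meshgrid(ax, ax)
    if mode == "exact":
        x = _cos_half_theta(pp, qq, omega, geom)
        y = _d_sin_half_theta(pp, qq, omega, geom)
    elif mode == "simplified":
        from .geometry import CIS_COEFFICIENTS, TRANS_COEFFICIENTS
        s, t = np.radians(pp + qq) / 2, np.radians(pp - qq) / 2
        if math.isclose(omega, 180.0, abs_tol=1e-9):
            a, b, c, e = TRANS_COEFFICIENTS
            x = a * np.sin(s) + b * np.sin(t)
            y = c * np.cos(s) + e * np.cos(t)
        elif math.isclose(omega, 0.0, abs_tol=1e-9):
            a, b, c, e = CIS_COEFFICIENTS
            x = a * np.cos(s) + b * np.cos(t)
            y = c * np.sin(s) + e * np.sin(t)
        else:
            raise ValueError("simplified mode needs omega of 0 or 180 deg")
    else:
        raise ValueError(f"mode must be 'exact' or 'simplified', got {mode!r}")

    theta = _theta_from_cos_half(x)
    sin_half = np.sin(np.radians(theta) / 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        d = np.where(sin_half > 0, y / np.where(sin_half > 0, sin_half, 1.0),
                     np.nan)
    sin_theta = np.sin(np.radians(theta))
    h = np.where(np.abs(d) > EPS_D, np.sign(d) * sin_theta, np.nan)
    return RamaGrid(frame=frame, step=step, omega=omega,
                    phi_values=ax, psi_values=ax, d=d, theta=theta, h=h,
                    cos_half_theta=np.asarray(x),
                    d_sin_half_theta=np.asarray(y))


@dataclass
class BoundaryCurve:
    """One contour segment of a flat-backbone boundary in (phi, psi)."""

    kind: Literal["d_zero", "theta_pi"]
    vertices: np.ndarray  # (m, 2) columns (phi, psi), degrees


def boundary_curves(grid: RamaGrid) -> list[BoundaryCurve]:
    """Extract the d = 0 and theta = pi curves from a survey grid.

    Contours are traced on the smooth scalar fields d*sin(theta/2)
    (whose zeros are d = 0, since sin(theta/2) > 0 away from theta = 0)
    and cos(theta/2) (whose zeros are theta = pi), avoiding branch
    artifacts of the wrapped theta itself.  Marching-squares vertices
    are linearly interpolated on the grid edges.
    """
    out: list[BoundaryCurve] = []
    for kind, fld in (("d_zero", grid.d_sin_half_theta),
                      ("theta_pi", grid.cos_half_theta)):
        for seg in _skmeasure.find_contours(fld, 0.0):
            phi = grid.phi_values[0] + seg[:, 1] * grid.step
            psi = grid.psi_values[0] + seg[:, 0] * grid.step
            out.append(BoundaryCurve(kind=kind,
                                     vertices=np.column_stack([phi, psi])))
    return out


def count_sign_regions(grid: RamaGrid) -> tuple[int, list[int]]:
    """Count connected components of constant sign(h) on the grid.

    Components are 4-connected on the square as plotted (non-periodic);
    the duplicated +360 seam row/column and cells with undefined or
    essentially-zero h are excluded.  Returns the component count and
    the per-component cell counts (descending).
    """
    h = grid.h[:-1, :-1]  # drop the duplicated seam
    sizes: list[int] = []
    n_total = 0
    four = ndimage.generate_binary_structure(2, 1)
    for mask in (np.nan_to_num(h) > 1e-12, np.nan_to_num(h) < -1e-12):
        labels, n = ndimage.label(mask, structure=four)
        n_total += n
        sizes += [int(c) for c in np.bincount(labels.ravel())[1:]]
    return n_total, sorted(sizes, reverse=True)


def frame_convert(grid: RamaGrid, target_frame: Frame) -> RamaGrid:
    """Re-index a survey into the other angle frame by +/-360 shifts.

    A pure relabeling: the multiset of (d, theta, h) values is unchanged,
    only which cells are adjacent in the plotted square differs.
    Involutive.
    """
    if target_frame == grid.frame:
        return grid
    ax = _axis(target_frame, grid.step)
    n = len(grid.phi_values) - 1  # interior size (seam dropped then rebuilt)
    lo_new, lo_old = ax[0], grid.phi_values[0]
    shift = int(round((lo_new - lo_old) / grid.step)) % n
    idx = (np.arange(n) + shift) % n

    def remap(a: np.ndarray) -> np.ndarray:
        core = a[:-1, :-1][np.ix_(idx, idx)]
        return np.pad(core, ((0, 1), (0, 1)), mode="wrap")

    return RamaGrid(frame=target_frame, step=grid.step, omega=grid.omega,
                    phi_values=ax, psi_values=ax,
                    d=remap(grid.d), theta=remap(grid.theta),
                    h=remap(grid.h),
                    cos_half_theta=remap(grid.cos_half_theta),
                    d_sin_half_theta=remap(grid.d_sin_half_theta))


def thetad_envelope(omega_center: float = 180.0, omega_halfwidth: float = 5.0,
                    step: float = 2.0, omega_step: float = 1.0,
                    geom: BackboneGeometry = BackboneGeometry()
                    ) -> pd.DataFrame:
    """Sweep (phi, psi, omega) and chart attainable points of the (theta, d) map.

    Returns a table of columns theta_deg, d_angstrom, h — the point cloud
    of conformations reachable with omega within ``omega_halfwidth`` of
    ``omega_center``.  The Cartesian (theta, d) plane is a universal
    backbone map: every conformation, cis, trans or strained, has one
    place in it.
    """
    if omega_halfwidth < 0:
        raise ValueError("omega_halfwidth must be >= 0")
    omegas = omega_center + np.arange(-omega_halfwidth, omega_halfwidth + 1e-9,
                                      omega_step) if omega_halfwidth > 0 \
        else np.array([omega_center])
    frames = []
    for om in omegas:
        g = rama_grid(omega=float(om), step=step)
        frames.append(pd.DataFrame({
            "theta_deg": g.theta.ravel(),
            "d_angstrom": g.d.ravel(),
            "h": g.h.ravel(),
            "omega_deg": g.omega,
        }))
    return pd.concat(frames, ignore_index=True)
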