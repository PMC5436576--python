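"""Coordinate-based chirality indices of an alpha-carbon trace.

Three pseudoscalar indices computed from CA positions alone, used to
cross-validate the analytic handedness metric h: a normalized
triple-product index chi1 in [-1, 1], the mean CA-trace torsion chi2 in
radians, and the computationally heavier all-quadruples G0S index chi3.
All three vanish for planar traces and negate exactly under reflection.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np

__all__ = ["ChiralityIndices", "chi1", "chi2", "chi3"]


def _steps(ca: np.ndarray) -> np.ndarray:
    ca = np.asarray(ca, dtype=float)
    if ca.ndim != 2 or ca.shape[1] != 3:
        raise ValueError("expected an (N, 3) array of CA positions")
    if ca.shape[0] < 4:
        raise ValueError("need at least 4 CA positions")
    v = np.diff(ca, axis=0)
    if np.any(np.linalg.norm(v, axis=1) < 1e-12):
        raise ValueError("coincident consecutive CA positions")
    return v


def chi1(ca_positions: np.ndarray) -> float:
    """Normalized triple-product chirality of the CA trace, in [-1, 1].

    Averages the scalar triple product of three consecutive unit step
    vectors over the chain interior, dividing by the chain length N.
    """
    v = _steps(ca_positions)
    n = np.linalg.norm(v, axis=1)
    # summand window: steps (k-1, k, k+1) for k = 1 .. len(v)-2 (0-based)
    triple = np.einsum("ij,ij->i", np.cross(v[:-2], v[1:-1]), v[2:])
    terms = triple / (n[:-2] * n[1:-1] * n[2:])
    return float(terms.sum() / (len(v) + 1))


def chi2(ca_positions: np.ndarray) -> float:
    """Mean signed torsion (radians) of four contiguous alpha carbons.

    Each summand is the dihedral angle of a sliding window of four CA
    atoms, evaluated with the four-quadrant arctangent so it lies in
    (-pi, pi]; the sum is divided by the chain length N.
    """
    v = _steps(ca_positions)
    v0, v1, v2 = v[:-2], v[1:-1], v[2:]
    y = np.linalg.norm(v1, axis=1) * np.einsum("ij,ij->i", v0, np.cross(v1, v2))
    x = np.einsum("ij,ij->i", np.cross(v0, v1), np.cross(v1, v2))
    return float(np.arctan2(y, x).sum() / (len(v) + 1))


def chi3(ca_positions: np.ndarray, max_n: int = 30) -> float:
    """The G0S chirality index over all distinct ordered CA quadruples.

    Cost grows as N^4; traces longer than ``max_n`` are refused.
    Arbitrary range; sign agrees with chi1/chi2 on helical traces.
    """
    ca = np.asarray(ca_positions, dtype=float)
    _steps(ca)  # validate shape / length / coincidence
    n = ca.shape[0]
    if n > max_n:
        raise ValueError(f"chi3 is O(N^4); trace length {n} exceeds cap {max_n}")
    idx = np.array(list(itertools.permutations(range(n), 4)))
    i, j, k, l = idx.T
    # interatomic vectors r_i - r_j (the G0S convention); the opposite
    # orientation negates the index and breaks sign concordance with
    # chi1/chi2 on right-handed helices
    vij = ca[i] - ca[j]
    vjk = ca[j] - ca[k]
    vkl = ca[k] - ca[l]
    vil = ca[i] - ca[l]
    nij = np.linalg.norm(vij, axis=1)
    njk = np.linalg.norm(vjk, axis=1)
    nkl = np.linalg.norm(vkl, axis=1)
    nil = np.linalg.norm(vil, axis=1)
    ok = nil > 1e-12  # i == l revisited positions would zero the denominator
    num = (np.einsum("ij,ij->i", np.cross(vij, vkl), vil)
           * np.einsum("ij,ij->i", vij, vjk)
           * np.einsum("ij,ij->i", vjk, vkl))
    den = (nij * njk * nkl) ** 2 * np.where(ok, nil, 1.0)
    terms = np.where(ok, num / den, 0.0)
    return float(math.factorial(4) / (3.0 * n ** 4) * terms.sum())


@dataclass(frozen=True)
class ChiralityIndices:
    """The three indices of one CA trace, computed together."""

    chi1: float
    chi2: float
    chi3: float | None
    n_residues: int

    @classmethod
    def from_trace(cls, ca_positions: np.ndarray,
                   include_chi3: bool = True) -> "ChiralityIndices":
        ca = np.asarray(ca_positions, dtype=float)
        c3 = chi3(ca) if include_chi3 and ca.shape[0] <= 30 else None
        return cls(chi1=chi1(ca), chi2=chi2(ca), chi3=c3,
                   n_residues=ca.shape[0])
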