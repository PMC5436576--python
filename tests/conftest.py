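"""Shared fixtures and vectorized helpers for the test suite."""

import math

import numpy as np
import pytest

from peptwist import BackboneGeometry, DihedralState


@pytest.fixture(scope="session")
def geom():
    return BackboneGeometry()


@pytest.fixture
def alpha_state():
    """Textbook right-handed alpha helix dihedrals."""
    return DihedralState(phi=-57.0, psi=-47.0, omega=180.0)


def extend_batch(a, b, c, length, angle_deg, torsion_deg):
    """Vectorized internal-coordinate atom placement over (M, 3) arrays."""
    ang = math.radians(angle_deg)
    tor = np.radians(np.asarray(torsion_deg, dtype=float))
    bc = c - b
    bc = bc / np.linalg.norm(bc, axis=1, keepdims=True)
    ab = b - a
    n = np.cross(ab, bc)
    n = n / np.linalg.norm(n, axis=1, keepdims=True)
    m = np.cross(n, bc)
    return (c - length * math.cos(ang) * bc
            + (length * math.sin(ang) * np.cos(tor))[:, None] * m
            + (length * math.sin(ang) * np.sin(tor))[:, None] * n)


def build_ca_batch(phi, psi, omega, n_residues, geom=BackboneGeometry()):
    """CA traces of regular chains for many (phi, psi, omega) states at once.

    Same sequential extension as the library builder, broadcast over M
    states; returns an (M, n_residues, 3) array.  Used to make dense-grid
    cross-validation against the coordinate-based chirality indices
    affordable.
    """
    phi = np.atleast_1d(np.asarray(phi, dtype=float))
    psi = np.atleast_1d(np.asarray(psi, dtype=float))
    omega = np.broadcast_to(np.asarray(omega, dtype=float), phi.shape)
    m = phi.size
    g = geom
    sa = math.radians(g.sigma_alpha)
    npos = np.zeros((m, 3))
    ca = np.tile([g.v_n_alpha, 0.0, 0.0], (m, 1))
    c = ca + g.v_alpha_c * np.array([-math.cos(sa), math.sin(sa), 0.0])
    cas = [ca]
    for _ in range(1, n_residues):
        nn = extend_batch(npos, ca, c, g.v_c_n, g.sigma_c, psi)
        can = extend_batch(ca, c, nn, g.v_n_alpha, g.sigma_n, omega)
        cn = extend_batch(c, nn, can, g.v_alpha_c, g.sigma_alpha, phi)
        npos, ca, c = nn, can, cn
        cas.append(ca)
    return np.stack(cas, axis=1)


def chi12_batch(ca):
    """chi1 and chi2 over a batch of CA traces, shape (M, N, 3)."""
    v = np.diff(ca, axis=1)
    norms = np.linalg.norm(v, axis=2)
    v0, v1, v2 = v[:, :-2], v[:, 1:-1], v[:, 2:]
    cr01, cr12 = np.cross(v0, v1), np.cross(v1, v2)
    n_res = ca.shape[1]
    triple = np.einsum("mij,mij->mi", cr01, v2)
    c1 = (triple / (norms[:, :-2] * norms[:, 1:-1] * norms[:, 2:])
          ).sum(axis=1) / n_res
    y = norms[:, 1:-1] * np.einsum("mij,mij->mi", v0, cr12)
    x = np.einsum("mij,mij->mi", cr01, cr12)
    c2 = np.arctan2(y, x).sum(axis=1) / n_res
    return c1, c2
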