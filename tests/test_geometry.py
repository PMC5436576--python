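"""Exact and simplified helical-parameter equations, radii and coefficients."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from peptwist import (BackboneGeometry, DihedralState, DegenerateGeometryError,
                      wrap_omega, helical_params_exact,
                      helical_params_simplified, derive_simplified_coefficients,
                      same_type_distance, helix_radii, helix_radius,
                      HelicalParams)


class TestWrapOmega:
    @pytest.mark.parametrize("raw, delta, expected", [
        (350.0, -90.0, -10.0),
        (-180.0, -90.0, 180.0),
        (180.0, -90.0, 180.0),
        (0.0, -90.0, 0.0),
        (365.0, 0.0, 5.0),
    ])
    def test_examples(self, raw, delta, expected):
        assert wrap_omega(raw, delta) == pytest.approx(expected, abs=1e-12)

    @given(st.floats(-7200, 7200), st.floats(-360, 360))
    @settings(max_examples=200, deadline=None)
    def test_range_and_idempotence(self, raw, delta):
        w = wrap_omega(raw, delta)
        assert delta <= w < delta + 360.0
        assert wrap_omega(w, delta) == pytest.approx(w, abs=1e-9)

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            wrap_omega(float("nan"), -90.0)


class TestExactParams:
    def test_alpha_helix(self, alpha_state, geom):
        # ~3.6 residues/turn, ~1.5 A rise, right-handed
        d, theta = helical_params_exact(alpha_state, geom)
        assert theta == pytest.approx(99.3712, abs=1e-3)
        assert d == pytest.approx(1.5622, abs=1e-3)

    def test_left_handed_example(self, geom):
        # phi = psi = -100 deg: negative rise -> left-handed twist
        d, theta = helical_params_exact(DihedralState(-100, -100, 180), geom)
        assert theta == pytest.approx(71.6164, abs=1e-3)
        assert d == pytest.approx(-2.0137, abs=1e-3)

    def test_mirror_rule_after_wrapping(self, geom):
        # the mirror state (57, 47, -180) wraps its omega to +180, which
        # shifts the result to the equivalent screw representation
        # (d, 360 - theta) of the literal mirror (-d, theta); the
        # handedness it encodes is still the exact opposite
        s1 = DihedralState(-57, -47, 180)
        s2 = DihedralState(57, 47, -180)
        d1, t1 = helical_params_exact(s1, geom)
        d2, t2 = helical_params_exact(s2, geom)
        assert t2 == pytest.approx(360.0 - t1, abs=1e-9)
        assert d2 == pytest.approx(d1, abs=1e-9)
        assert math.sin(math.radians(t2)) == pytest.approx(
            -math.sin(math.radians(t1)), abs=1e-12)

    @pytest.mark.parametrize("omega", [0.0, 60.0, -60.0, 120.0, -120.0, 180.0])
    def test_mirror_antisymmetry_grid(self, geom, omega):
        # literal mirror rule, with the wrap origin chosen per state so
        # both omega and -omega are representable as given
        grid = np.arange(-180.0, 180.0, 15.0)
        pp, qq = np.meshgrid(grid, grid)
        for phi, psi in zip(pp.ravel(), qq.ravel()):
            d1, t1 = helical_params_exact(
                DihedralState(phi, psi, omega, delta=omega - 180.0), geom)
            d2, t2 = helical_params_exact(
                DihedralState(-phi, -psi, -omega, delta=-omega - 180.0), geom)
            assert t2 == pytest.approx(t1, abs=1e-9)
            assert d2 == pytest.approx(-d1, abs=1e-9)


class TestSimplifiedParams:
    def test_trans_printed_coefficient_point(self):
        # phi = psi = 90: the (phi-psi) term vanishes, leaving -0.8235
        d, theta = helical_params_simplified(90, 90, "trans")
        assert math.cos(math.radians(theta) / 2) == pytest.approx(-0.8235,
                                                                  abs=1e-12)

    def test_trans_origin(self):
        d, theta = helical_params_simplified(0, 0, "trans")
        assert theta == pytest.approx(180.0, abs=1e-12)
        assert d == pytest.approx(2.3411, abs=1e-9)  # 2.9986 - 0.6575

    def test_cis_origin(self):
        d, theta = helical_params_simplified(0, 0, "cis")
        assert math.cos(math.radians(theta) / 2) == pytest.approx(
            -0.0880, abs=1e-12)  # 0.4052 - 0.4932

    def test_bad_mode(self):
        with pytest.raises(ValueError):
            helical_params_simplified(0, 0, "gauche")

    @pytest.mark.parametrize("mode, omega", [("trans", 180.0), ("cis", 0.0)])
    def test_agreement_with_exact(self, geom, mode, omega):
        # the printed 4-decimal coefficients track the exact identities
        # to ~2e-3 over the full 2-degree Ramachandran grid
        from peptwist.survey import rama_grid
        ge = rama_grid(omega=omega, step=2.0, mode="exact")
        gs = rama_grid(omega=omega, step=2.0, mode="simplified")
        assert np.abs(ge.cos_half_theta - gs.cos_half_theta).max() <= 2e-3
        assert np.abs(ge.d_sin_half_theta - gs.d_sin_half_theta).max() <= 2e-3

    def test_trans_twist_never_vanishes(self):
        # no trans (phi, psi) reaches theta = 0: cos(theta/2) stays
        # bounded near the coefficient-sum limit, well below 1
        from peptwist.survey import rama_grid
        g = rama_grid(omega=180.0, step=2.0, mode="exact")
        assert g.cos_half_theta.max() < 0.846
        gs = rama_grid(omega=180.0, step=2.0, mode="simplified")
        assert gs.cos_half_theta.max() == pytest.approx(0.8457, abs=1e-12)


class TestCoefficientDerivation:
    def test_trans_printed_values(self, geom):
        coeffs = derive_simplified_coefficients(180.0, geom)
        assert np.round(coeffs, 4).tolist() == [-0.8235, 0.0222,
                                                2.9986, -0.6575]

    def test_cis_printed_values(self, geom):
        coeffs = derive_simplified_coefficients(0.0, geom)
        assert np.round(coeffs, 4).tolist() == [0.4052, -0.4932,
                                                2.3093, 0.0028]

    def test_symmetric_bond_angles_kill_cross_term(self):
        g = BackboneGeometry(sigma_n=120.0, sigma_c=120.0)
        _, b_cos, _, _ = derive_simplified_coefficients(180.0, g)
        assert b_cos == pytest.approx(0.0, abs=1e-12)

    def test_unsupported_omega(self, geom):
        with pytest.raises(ValueError):
            derive_simplified_coefficients(90.0, geom)

    def test_wrapped_omega_accepted(self, geom):
        assert derive_simplified_coefficients(-180.0, geom) == \
            derive_simplified_coefficients(180.0, geom)


class TestSameTypeDistance:
    def test_trans_ca_ca(self, geom):
        st_ = DihedralState(-57, -47, 180)
        assert same_type_distance(geom, "alpha", st_) == pytest.approx(
            3.8192, abs=1e-3)

    def test_cis_ca_ca(self, geom):
        st_ = DihedralState(-80, 80, 0)
        assert same_type_distance(geom, "alpha", st_) == pytest.approx(
            2.8021, abs=1e-3)

    def test_omega_wrap_equivalence(self, geom):
        a = same_type_distance(geom, "alpha", DihedralState(0, 0, 180))
        b = same_type_distance(geom, "alpha", DihedralState(0, 0, -180))
        assert a == pytest.approx(b, abs=1e-12)

    def test_bad_atom_type(self, geom):
        with pytest.raises(ValueError):
            same_type_distance(geom, "cb", DihedralState(0, 0, 180))

    def test_dihedral_dependence(self, geom):
        # CA-CA depends on omega only; C-C on phi only; N-N on psi only
        base = DihedralState(-57, -47, 180)
        moved_phi = DihedralState(100, -47, 180)
        assert same_type_distance(geom, "alpha", base) == pytest.approx(
            same_type_distance(geom, "alpha", moved_phi), abs=1e-12)
        assert same_type_distance(geom, "c", base) != pytest.approx(
            same_type_distance(geom, "c", moved_phi), abs=1e-6)
        moved_psi = DihedralState(-57, 100, 180)
        assert same_type_distance(geom, "c", base) == pytest.approx(
            same_type_distance(geom, "c", moved_psi), abs=1e-12)
        assert same_type_distance(geom, "n", base) != pytest.approx(
            same_type_distance(geom, "n", moved_psi), abs=1e-6)


class TestHelixRadii:
    def test_alpha_helix_radius(self, alpha_state, geom):
        d, theta = helical_params_exact(alpha_state, geom)
        rho_n, rho_a, rho_c = helix_radii(alpha_state, geom, d, theta)
        assert rho_a == pytest.approx(2.2853, abs=1e-3)  # canonical ~2.3 A
        assert rho_n > 0 and rho_c > 0

    def test_zero_radius_at_limit(self, geom):
        # d equal to the same-type distance with theta = 180 leaves no
        # room for any in-plane offset for that atom type
        st_ = DihedralState(0, 0, 180)
        da = same_type_distance(geom, "alpha", st_)
        assert helix_radius(st_, geom, da, 180.0, "alpha") == 0.0
        with pytest.raises(ValueError):
            # the smaller same-type distances then have negative radicands
            helix_radii(st_, geom, da, 180.0)

    def test_inconsistent_pair_rejected(self, alpha_state, geom):
        with pytest.raises(ValueError):
            helix_radii(alpha_state, geom, 10.0, 99.0)

    def test_degenerate_theta(self, alpha_state, geom):
        with pytest.raises(DegenerateGeometryError):
            helix_radii(alpha_state, geom, 1.0, 0.0)

    def test_quadratic_identity_over_grid(self, geom):
        # 2 rho_a^2 (1 - cos theta) + d^2 reproduces the squared
        # adjacent-CA distance everywhere it is defined
        rng = np.arange(-180.0, 180.0, 10.0)
        for phi in rng:
            for psi in rng:
                st_ = DihedralState(phi, psi, 180.0)
                d, theta = helical_params_exact(st_, geom)
                try:
                    _, rho_a, _ = helix_radii(st_, geom, d, theta)
                except DegenerateGeometryError:
                    continue
                da = same_type_distance(geom, "alpha", st_)
                lhs = 2 * rho_a**2 * (1 - math.cos(math.radians(theta))) + d**2
                assert lhs == pytest.approx(da**2, rel=1e-9)


def test_geometry_validation():
    with pytest.raises(ValueError):
        BackboneGeometry(v_n_alpha=-1.0)
    with pytest.raises(ValueError):
        BackboneGeometry(sigma_n=180.0)


def test_helical_params_dataclass(alpha_state, geom):
    hp = HelicalParams.from_state(alpha_state, geom)
    assert 0 <= hp.theta < 360
    assert hp.rho_alpha == pytest.approx(2.2853, abs=1e-3)
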