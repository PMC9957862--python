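"""EM solver oracles: TEM coax analytics, port projection, power balance."""

import numpy as np
import pytest

from mwablate import _fem
from mwablate.geometry import BoundaryTag
from mwablate.em import (S11_FLOOR_DB, SourceSpec, incident_amplitude,
                         incident_field, reflection_coefficient, solve_em,
                         compute_loss_density)
from conftest import RI, RO, make_coax

# scalar evaluations of A0 = sqrt(P Z / (pi ln(ro/ri))) at the default setup
Z_PTFE = 264.41284442083145
A0_30W = 52.70835771165735


class TestIncidentAmplitude:
    def test_zero_power(self):
        assert incident_amplitude(0.0, 50.0, 1e-3, 2e-3) == 0.0

    def test_unit_combination(self):
        # ln(ro/ri) = 1 and Z = pi make A0 = sqrt(P)
        assert incident_amplitude(1.0, np.pi, 1e-3, np.e * 1e-3) == pytest.approx(1.0)

    def test_default_setup_matches_scalar_oracle(self):
        src = SourceSpec()  # 30 W, PTFE, default coax radii
        assert src.Z == pytest.approx(Z_PTFE, rel=1e-12)
        assert src.A0 == pytest.approx(A0_30W, rel=1e-12)

    def test_invalid_annulus(self):
        with pytest.raises(ValueError):
            incident_amplitude(1.0, 50.0, 2e-3, 1e-3)


class TestIncidentField:
    def test_inverse_radius_profile(self):
        src = SourceSpec()
        e_i = incident_field(src, src.r_i)
        assert abs(e_i) == pytest.approx(src.A0 / src.r_i)
        mid = 2 * src.r_i
        assert abs(incident_field(src, mid)) == pytest.approx(abs(e_i) / 2)

    def test_outside_annulus_rejected(self):
        src = SourceSpec()
        with pytest.raises(ValueError):
            incident_field(src, 2 * src.r_o)

    def test_poynting_integral_recovers_power(self):
        """2 pi int E x H* /2 r dr over the annulus equals the input power."""
        src = SourceSpec()
        r = np.linspace(src.r_i, src.r_o, 20001)
        E = np.abs(incident_field(src, r))
        H = E / src.Z
        P = 2 * np.pi * np.trapezoid(0.5 * E * H * r, r)
        assert P == pytest.approx(src.power, rel=1e-6)


class TestReflectionProjection:
    def setup_method(self):
        self.r = np.linspace(RI, RO, 21)
        self.w = np.full_like(self.r, (RO - RI) / 21)
        self.E_inc = 1.0 / self.r

    def test_no_reflection_floors_s11(self):
        gamma, s11 = reflection_coefficient(self.E_inc, self.E_inc, self.r, self.w)
        assert gamma == 0
        assert s11 == S11_FLOOR_DB

    def test_total_reflection(self):
        gamma, s11 = reflection_coefficient(np.zeros_like(self.r), self.E_inc,
                                            self.r, self.w)
        assert gamma == pytest.approx(-1.0)
        assert s11 == pytest.approx(0.0, abs=1e-9)

    def test_linearity(self):
        gamma, _ = reflection_coefficient(2 * self.E_inc, self.E_inc, self.r, self.w)
        assert gamma == pytest.approx(1.0)

    def test_zero_incident_rejected(self):
        with pytest.raises(ValueError):
            reflection_coefficient(self.E_inc, np.zeros_like(self.r), self.r, self.w)


def test_loss_density_formula():
    assert compute_loss_density(np.array([1.0]), np.array([2.0]))[0] == 1.0
    assert np.all(compute_loss_density(np.array([3.0, 1.0]), 0.0) == 0.0)


class TestCoaxOracles:
    """Analytic TEM line: the solver's fundamental verification fixture."""

    def test_matched_line(self):
        geo, mesh = make_coax(BoundaryTag.OUTER_ABSORBING)
        space = _fem.build_space(mesh)
        src = SourceSpec(power=1.0, r_i=RI, r_o=RO)
        props = (np.full(mesh.n_triangles, 2.03), np.zeros(mesh.n_triangles))
        sol = solve_em(mesh, props, src, space=space)
        assert abs(sol.Gamma) <= 0.05
        mids = mesh.vertices[mesh.triangles].mean(axis=1)
        interior = (mids[:, 1] > 4e-3) & (mids[:, 1] < 16e-3)
        Emag = np.sqrt(sol.E_sq[interior])
        expect = src.A0 / mids[interior, 0]
        assert np.max(np.abs(Emag - expect) / expect) <= 0.02

    def test_shorted_line_total_reflection(self):
        geo, mesh = make_coax(BoundaryTag.PEC)
        space = _fem.build_space(mesh)
        src = SourceSpec(power=1.0, r_i=RI, r_o=RO)
        props = (np.full(mesh.n_triangles, 2.03), np.zeros(mesh.n_triangles))
        sol = solve_em(mesh, props, src, space=space)
        assert abs(sol.Gamma) == pytest.approx(1.0, abs=0.01)

    def test_lossless_medium_absorbs_nothing(self):
        geo, mesh = make_coax(BoundaryTag.PEC)
        space = _fem.build_space(mesh)
        src = SourceSpec(power=1.0, r_i=RI, r_o=RO)
        props = (np.full(mesh.n_triangles, 2.03), np.zeros(mesh.n_triangles))
        sol = solve_em(mesh, props, src, space=space)
        assert sol.power_absorbed == pytest.approx(0.0, abs=1e-12)

    def test_power_balance_in_lossy_shorted_line(self):
        """(1 - |Gamma|^2) P equals the revolved volume integral of Qs."""
        geo, mesh = make_coax(BoundaryTag.PEC, length=40e-3)
        space = _fem.build_space(mesh)
        src = SourceSpec(power=1.0, r_i=RI, r_o=RO)
        # tissue-like lossy fill: every watt not reflected is absorbed
        props = (np.full(mesh.n_triangles, 2.03), np.full(mesh.n_triangles, 0.5))
        sol = solve_em(mesh, props, src, space=space)
        delivered = (1 - abs(sol.Gamma) ** 2) * src.power
        assert sol.power_absorbed == pytest.approx(delivered, rel=0.05)


class TestProbeSolve:
    def test_power_balance(self, ss_em):
        delivered = ss_em.delivered_power
        assert ss_em.power_absorbed == pytest.approx(delivered, rel=0.05)
        assert ss_em.power_absorbed <= delivered * 1.01

    def test_qs_nonnegative_and_gamma_passive(self, ss_em):
        assert np.all(ss_em.Qs >= 0)
        assert abs(ss_em.Gamma) <= 1.0 + 1e-3

    def test_power_scaling(self, ss_mesh, ss_em):
        """Scaling input power by c scales |E| by sqrt(c), Qs by c, Gamma fixed."""
        space = ss_em.space
        src4 = SourceSpec(power=4 * ss_em.source.power)
        sol4 = solve_em(ss_mesh, (ss_em.eps_c.real,
                                  ss_em.sigma), src4, space=space)
        assert sol4.Gamma == pytest.approx(ss_em.Gamma, rel=1e-6, abs=1e-9)
        np.testing.assert_allclose(sol4.Qs, 4 * ss_em.Qs, rtol=1e-6)
        np.testing.assert_allclose(np.sqrt(sol4.E_sq), 2 * np.sqrt(ss_em.E_sq),
                                   rtol=1e-6)

    def test_s11_stable_under_refinement(self, ss_geometry, coarse_controls, ss_em):
        """Successive refinement moves S11 by less than 0.5 dB."""
        from mwablate.mesh import MeshControls, generate_mesh
        from mwablate.materials import default_assignment, material_field

        fine = MeshControls(h_fine=coarse_controls.h_fine / 1.5,
                            h_far=coarse_controls.h_far / 1.5,
                            h_port=coarse_controls.h_port / 1.5)
        mesh2 = generate_mesh(ss_geometry, fine)
        space2 = _fem.build_space(mesh2)
        T = np.full(mesh2.n_vertices, 37.0)
        sol2 = solve_em(mesh2, material_field(mesh2, T, default_assignment()),
                        SourceSpec(), space=space2)
        assert abs(sol2.s11_db - ss_em.s11_db) < 0.5
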