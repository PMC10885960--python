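"""X-ray excitation, FEM assembly, and the sensitivity matrix."""

import numpy as np
import pytest

from xlct._errors import (
    ConfigurationError,
    DegenerateSignalError,
    InvalidGeometryError,
)
from xlct.forward import (
    Measurement,
    OpticalTissue,
    XRayConfig,
    assemble_F,
    assemble_K,
    boundary_mass_matrix,
    restrict_rows,
    sensitivity_columns,
    simulate_measurements,
    stiffness_matrix,
    system_matrix,
    visible_detector_nodes,
    xray_field,
)
from xlct.mesh import Mesh, build_cylinder_mesh


class TestXRayField:
    def test_no_attenuation_gives_source_intensity_in_cone(self, small_mesh):
        cfg = XRayConfig(source_position=(0, -10, 0.5), mu_t=0.0,
                         cone_half_angle=np.deg2rad(45))
        X = xray_field(small_mesh, cfg)
        assert np.allclose(X, 1.0)

    def test_beer_lambert_along_known_path(self, phantom_mesh):
        # source on the -y axis; the center node's in-medium path is the
        # phantom radius, so X = exp(-mu_t * R)
        cfg = XRayConfig(source_position=(0, -20, 1.3), mu_t=0.2,
                         cone_half_angle=np.deg2rad(20))
        X = xray_field(phantom_mesh, cfg)
        i0 = np.argmin(
            np.linalg.norm(phantom_mesh.node_coords - [0, 0, 1.3], axis=1)
        )
        assert np.isclose(X[i0], np.exp(-0.2 * 1.5), rtol=1e-10)

    def test_out_of_cone_nodes_are_dark(self, phantom_mesh):
        cfg = XRayConfig(source_position=(0, -20, 1.3), mu_t=0.2,
                         cone_half_angle=np.deg2rad(1.0))
        X = xray_field(phantom_mesh, cfg)
        assert (X == 0).any() and (X > 0).any()

    def test_source_inside_mesh_rejected(self, small_mesh):
        cfg = XRayConfig(source_position=(0, 0, 0.5))
        with pytest.raises(InvalidGeometryError):
            xray_field(small_mesh, cfg)

    def test_monotone_attenuation_with_path_length(self, phantom_mesh):
        cfg = XRayConfig(source_position=(0, -20, 1.3), mu_t=0.2,
                         cone_half_angle=np.deg2rad(20))
        X = xray_field(phantom_mesh, cfg)
        near = np.argmin(np.linalg.norm(
            phantom_mesh.node_coords - [0, -1.5, 1.3], axis=1))
        far = np.argmin(np.linalg.norm(
            phantom_mesh.node_coords - [0, 1.5, 1.3], axis=1))
        assert X[near] > X[far]


class TestAssembly:
    def test_stiffness_rows_sum_to_zero(self, unit_tet, phantom_mesh):
        for mesh in (unit_tet, phantom_mesh):
            S = stiffness_matrix(mesh)
            assert np.abs(np.asarray(S.sum(axis=1))).max() < 1e-12

    def test_unit_tet_mass_entries(self, unit_tet):
        # consistent P1 mass matrix of a volume-V tet: V/10 diagonal,
        # V/20 off-diagonal
        F = assemble_F(unit_tet).toarray()
        V = unit_tet.total_volume()
        assert np.isclose(V, 1.0)
        expect = np.full((4, 4), V / 20.0)
        np.fill_diagonal(expect, V / 10.0)
        assert np.allclose(F, expect, atol=1e-14)

    def test_mass_total_equals_mesh_volume(self, phantom_mesh):
        F = assemble_F(phantom_mesh)
        assert np.isclose(F.sum(), phantom_mesh.total_volume(), rtol=1e-12)

    def test_two_tet_shared_node_mass_row_sum(self):
        # two tets sharing a face: the mass row sum at a shared node is
        # V1/4 + V2/4 (per-element lumped contribution)
        coords = np.array(
            [[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1], [1, 1, 1]], float
        )
        mesh = Mesh(coords, np.array([[0, 1, 2, 3], [1, 2, 3, 4]]))
        F = assemble_F(mesh)
        v = mesh.tet_volumes()
        rowsum = np.asarray(F.sum(axis=1)).ravel()
        for shared in (1, 2, 3):
            assert np.isclose(rowsum[shared], v[0] / 4 + v[1] / 4, rtol=1e-12)

    def test_K_positive_definite_with_phantom_coefficients(
        self, small_mesh, tissue
    ):
        K = assemble_K(small_mesh, tissue).toarray()
        w = np.linalg.eigvalsh(K)
        assert w.min() > 0

    def test_K_symmetric(self, phantom_mesh, tissue):
        K = assemble_K(phantom_mesh, tissue)
        assert abs(K - K.T).max() < 1e-14

    def test_boundary_mass_total_equals_surface_area(self, phantom_mesh):
        Mb = boundary_mass_matrix(phantom_mesh)
        assert np.isclose(
            Mb.sum(), phantom_mesh.boundary_face_areas.sum(), rtol=1e-12
        )


@pytest.fixture(scope="module")
def system(tissue):
    mesh = build_cylinder_mesh(1.2, 1.6, 0.4)  # <=500 nodes
    sysm = system_matrix(mesh, tissue, np.ones(mesh.n_nodes))
    det = visible_detector_nodes(mesh, 0.0, 60.0, (0.3, 1.3))
    H = restrict_rows(sysm, det)
    return mesh, sysm, det, H


class TestSensitivity:
    def test_eta_linearity(self, tissue, system):
        mesh, sysm, det, H = system
        sys2 = system_matrix(mesh, tissue, np.ones(mesh.n_nodes), eta=2.0)
        H2 = restrict_rows(sys2, det)
        assert np.allclose(H2, 2.0 * H, rtol=1e-12)

    def test_H_rho_equals_direct_fem_solve(self, system, rng):
        mesh, sysm, det, H = system
        rho = rng.random(mesh.n_nodes)
        direct = sysm.solve_fluence(rho)[det]
        rel = np.abs(H @ rho - direct).max() / np.abs(direct).max()
        assert rel < 1e-10

    def test_adjoint_rows_match_columnwise_solves(self, system):
        mesh, sysm, det, H = system
        cols = [0, mesh.n_nodes // 2, mesh.n_nodes - 1]
        ref = sensitivity_columns(sysm, cols, det)
        rel = np.abs(H[:, cols] - ref).max() / np.abs(ref).max()
        assert rel < 1e-8

    def test_measurement_doubles_with_concentration(self, system, rng):
        mesh, sysm, det, H = system
        rho = rng.random(mesh.n_nodes)
        m1 = simulate_measurements(H, rho, None)
        m2 = simulate_measurements(H, 2 * rho, None)
        assert np.allclose(m2.values, 2 * m1.values, rtol=1e-12)

    def test_H_meas_nonnegative_up_to_fem_undershoot(self, system):
        # P1 adjoint solutions undershoot slightly near the detector node;
        # entries are non-negative up to a ~1 % numerical undershoot
        _, _, _, H = system
        assert H.min() >= -0.01 * H.max()


class TestDetectorSelection:
    def test_facing_side_included_far_side_excluded(self, phantom_mesh):
        ids = visible_detector_nodes(phantom_mesh, 0.0, 60.0, (0.2, 2.4))
        p = phantom_mesh.node_coords[ids]
        assert (p[:, 0] > 0).all()  # all on the +x half for a 0 deg view

    def test_opposite_view_selects_antipodal_set(self, phantom_mesh):
        a = visible_detector_nodes(phantom_mesh, 0.0, 60.0, (0.2, 2.4))
        b = visible_detector_nodes(phantom_mesh, 180.0, 60.0, (0.2, 2.4))
        pa = phantom_mesh.node_coords[a]
        mirrored = np.c_[-pa[:, 0], -pa[:, 1], pa[:, 2]]
        pb = set(map(tuple, np.round(phantom_mesh.node_coords[b], 9)))
        hits = sum(tuple(np.round(q, 9)) in pb for q in mirrored)
        assert hits / len(a) > 0.95

    def test_empty_selection_is_configuration_error(self, phantom_mesh):
        with pytest.raises(ConfigurationError):
            visible_detector_nodes(phantom_mesh, 0.0, 60.0, (10.0, 11.0))


class TestSimulateMeasurements:
    def test_noiseless_and_deterministic(self, rng):
        H = rng.random((7, 5))
        rho = rng.random(5)
        clean = simulate_measurements(H, rho, None)
        assert np.allclose(clean.values, H @ rho)
        a = simulate_measurements(H, rho, 20.0, rng_seed=42)
        b = simulate_measurements(H, rho, 20.0, rng_seed=42)
        assert np.array_equal(a.values, b.values)

    def test_zero_signal_with_finite_snr_rejected(self):
        with pytest.raises(DegenerateSignalError):
            simulate_measurements(np.ones((3, 2)), np.zeros(2), 20.0, 0)

    def test_empirical_snr_matches_requested_level(self, rng):
        H = rng.random((117, 40))
        rho = rng.random(40)
        signal = H @ rho
        p_s = np.mean(signal**2)
        noise_p = []
        for k in range(300):
            m = simulate_measurements(H, rho, 20.0, rng_seed=k)
            noise_p.append(np.mean((m.values - signal) ** 2))
        snr_db = 10 * np.log10(p_s / np.mean(noise_p))
        assert abs(snr_db - 20.0) < 0.2

    def test_negative_concentration_rejected(self):
        from xlct._errors import DataError

        with pytest.raises(DataError):
            simulate_measurements(np.ones((2, 2)), np.array([-1.0, 0.0]), None)


def test_fluence_decay_matches_diffusion_theory(tissue):
    """Fluence from a small interior source decays with the effective
    attenuation mu_eff = sqrt(3 mu_a (mu_a + mu_s')) ~ 0.775 cm^-1."""
    from xlct.mesh import interpolate_field

    mesh = build_cylinder_mesh(2.0, 3.4, 0.29)
    assert mesh.n_nodes <= 3000
    sysm = system_matrix(mesh, tissue, np.ones(mesh.n_nodes))
    rho = np.zeros(mesh.n_nodes)
    rho[np.argmin(np.linalg.norm(mesh.node_coords - [0, 0, 1.7], axis=1))] = 1.0
    phi = sysm.solve_fluence(rho)
    rs = np.linspace(0.3, 1.0, 15)
    ang = np.linspace(0, 2 * np.pi, 24, endpoint=False)
    prof = np.array(
        [
            np.nanmean(
                interpolate_field(
                    mesh,
                    phi,
                    np.c_[r * np.cos(ang), r * np.sin(ang), np.full(24, 1.7)],
                )
            )
            for r in rs
        ]
    )
    slope = -np.polyfit(rs, np.log(prof * rs), 1)[0]
    assert abs(slope - tissue.mu_eff) / tissue.mu_eff < 0.15
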