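"""Localization error, DICE overlap, and the spatial-resolution index."""

import numpy as np
import pytest

from xlct.mesh import TargetSpec, build_cylinder_mesh
from xlct.metrics import (
    dice,
    evaluate_reconstruction,
    evaluate_slice,
    location_error,
    profile_spi,
    spi,
)


@pytest.fixture(scope="module")
def mesh():
    return build_cylinder_mesh(1.5, 2.6, 0.25)


def _single_node_recon(mesh, point, value=1.0):
    rho = np.zeros(mesh.n_nodes)
    j = np.argmin(np.linalg.norm(mesh.node_coords - np.asarray(point), axis=1))
    rho[j] = value
    return rho, mesh.node_coords[j]


class TestLocationError:
    def test_zero_when_peak_at_center(self, mesh):
        rho, node = _single_node_recon(mesh, (0.25, 0, 1.3))
        target = TargetSpec(center=tuple(node), diameter=0.4, height=0.6,
                            concentration=0.1)
        assert location_error(rho, mesh, target) == 0.0

    def test_three_four_five_triangle(self, mesh):
        # p_r = origin-adjacent node, p_t offset by (0.3, 0.4, 0): 5 mm
        rho, node = _single_node_recon(mesh, (0.0, 0.0, 1.3))
        target = TargetSpec(
            center=(node[0] + 0.3, node[1] + 0.4, node[2]),
            diameter=0.4, height=0.6, concentration=0.1,
        )
        assert np.isclose(location_error(rho, mesh, target), 5.0)

    def test_fixture_distance_matches_hand_computation(self, mesh):
        rho, node = _single_node_recon(mesh, (0.5, 0, 1.3))
        target = TargetSpec(center=(0.25, 0, 1.04), diameter=0.4, height=0.6,
                            concentration=0.1)
        expect = 10 * np.linalg.norm(node - np.array(target.center))
        assert np.isclose(location_error(rho, mesh, target), expect)

    def test_missing_target_flagged_as_nan(self, mesh):
        target = TargetSpec(center=(0.3, 0, 1.3), diameter=0.4, height=0.6,
                            concentration=0.1)
        assert np.isnan(location_error(np.zeros(mesh.n_nodes), mesh, target))

    def test_scale_invariance(self, mesh):
        rho, _ = _single_node_recon(mesh, (0.4, 0.3, 1.0))
        target = TargetSpec(center=(0.3, 0, 1.3), diameter=0.4, height=0.6,
                            concentration=0.1)
        assert location_error(rho, mesh, target) == location_error(
            7.3 * rho, mesh, target
        )


class TestDice:
    def test_perfect_overlap(self, mesh):
        target = TargetSpec(center=(0.25, 0, 1.3), diameter=0.5, height=0.52,
                            concentration=0.1)
        # recon == indicator of the target region on nodes
        rho = target.contains(mesh.node_coords).astype(float)
        val = dice(rho, mesh, target, threshold_frac=0.5, grid_step=0.05)
        assert val > 0.55  # hat-function spill limits the overlap

    def test_disjoint_regions_give_zero(self, mesh):
        rho, _ = _single_node_recon(mesh, (-0.75, 0, 0.52))
        target = TargetSpec(center=(0.75, 0, 2.08), diameter=0.4, height=0.4,
                            concentration=0.1)
        assert dice(rho, mesh, target, grid_step=0.05) == 0.0

    def test_set_arithmetic_example(self):
        # |ROI_r| = 3, |ROI_t| = 3, overlap 2 -> 2*2/6
        roi_r = {(0, 0), (1, 0), (2, 0)}
        roi_t = {(1, 0), (2, 0), (3, 0)}
        val = 2 * len(roi_r & roi_t) / (len(roi_r) + len(roi_t))
        assert np.isclose(val, 2 / 3)

    def test_empty_reconstruction_gives_zero(self, mesh):
        target = TargetSpec(center=(0.3, 0, 1.3), diameter=0.4, height=0.6,
                            concentration=0.1)
        assert dice(np.zeros(mesh.n_nodes), mesh, target) == 0.0

    def test_scale_invariance(self, mesh):
        target = TargetSpec(center=(0.25, 0, 1.3), diameter=0.5, height=0.5,
                            concentration=0.1)
        rho = target.contains(mesh.node_coords).astype(float)
        a = dice(rho, mesh, target, grid_step=0.05)
        b = dice(100 * rho, mesh, target, grid_step=0.05)
        assert a == b


class TestProfileSpi:
    def test_worked_example(self):
        # max 1.0, valley 0.4, min 0.0 -> (1 - 0.4) / (1 - 0) = 0.6
        assert np.isclose(profile_spi([0.0, 1.0, 0.4, 0.9, 0.1]), 0.6)

    def test_fully_separated_blobs(self):
        prof = [0.0, 0.0, 1.0, 0.0, 0.0, 0.8, 0.0, 0.0]
        assert profile_spi(prof) == 1.0

    def test_merged_blob_gives_zero(self):
        assert profile_spi([0.0, 0.5, 1.0, 0.9, 0.5, 0.0]) == 0.0

    def test_flat_profile_gives_zero(self):
        assert profile_spi([1.0, 1.0, 1.0, 1.0]) == 0.0

    def test_monotone_under_blur(self):
        x = np.linspace(-1, 1, 101)
        base = np.exp(-((x + 0.4) ** 2) / 0.005) + np.exp(
            -((x - 0.4) ** 2) / 0.005
        )
        vals = []
        for sigma in (1, 5, 10, 15):
            k = np.exp(-0.5 * (np.arange(-30, 31) / sigma) ** 2)
            blurred = np.convolve(base, k / k.sum(), mode="same")
            vals.append(profile_spi(blurred))
        assert all(a >= b - 1e-12 for a, b in zip(vals, vals[1:]))


class TestSpiOnMesh:
    def test_two_sparse_blobs_fully_resolved(self, mesh):
        rho1, n1 = _single_node_recon(mesh, (-0.5, 0, 1.3))
        rho2, n2 = _single_node_recon(mesh, (0.5, 0, 1.3), 0.8)
        val, prof = spi(rho1 + rho2, mesh, n1, n2)
        assert val == 1.0

    def test_center_outside_mesh_rejected(self, mesh):
        from xlct._errors import InvalidGeometryError

        rho = np.ones(mesh.n_nodes)
        with pytest.raises(InvalidGeometryError):
            spi(rho, mesh, np.array([5.0, 5, 5]), np.array([0.0, 0, 1.3]))


class TestReports:
    def test_full_report_shape_two_targets(self, mesh):
        targets = [
            TargetSpec(center=(-0.5, 0, 1.3), diameter=0.4, height=0.6,
                       concentration=0.1, name="a"),
            TargetSpec(center=(0.5, 0, 1.3), diameter=0.4, height=0.6,
                       concentration=0.1, name="b"),
        ]
        rho1, _ = _single_node_recon(mesh, (-0.5, 0, 1.3))
        rho2, _ = _single_node_recon(mesh, (0.5, 0, 1.3), 0.9)
        rep = evaluate_reconstruction(rho1 + rho2, mesh, targets,
                                      grid_step=0.05)
        assert set(rep.le_mm) == {"a", "b"}
        assert set(rep.dice) == {"a", "b"}
        assert set(rep.spi) == {"a|b"}
        assert rep.mode == "volume"

    def test_slice_report_in_plane_le(self, mesh):
        targets = [
            TargetSpec(center=(-0.5, 0, 1.3), diameter=0.4, height=2.6,
                       concentration=0.1, name="a"),
            TargetSpec(center=(0.5, 0, 1.3), diameter=0.4, height=2.6,
                       concentration=0.1, name="b"),
        ]
        # peaks displaced only in z: in-plane LE must be 0
        rho1, _ = _single_node_recon(mesh, (-0.5, 0, 2.08))
        rho2, _ = _single_node_recon(mesh, (0.5, 0, 0.52), 0.9)
        rep = evaluate_slice(rho1 + rho2, mesh, targets)
        assert rep.mode == "slice"
        assert np.isclose(rep.le_mm["a"], 0.0)
        assert np.isclose(rep.le_mm["b"], 0.0)
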