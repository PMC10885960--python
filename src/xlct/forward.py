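"""Cone-beam X-ray excitation and the FEM diffusion forward model.

Physics
-------
X-rays from a point source attenuate along straight lines (Beer-Lambert),
X(r) = X(r0) exp(-int mu_t dtau).  Nanophosphors at concentration rho
convert X-ray flux to an isotropic light source S = eta * X * rho.  Light
transport in highly scattering tissue follows the diffusion equation

    -div(D grad Phi) + mu_a Phi = S        in Omega
    Phi + 2 kappa D (nu . grad Phi) = 0    on dOmega

with D = 1 / (3 (mu_a + mu_s')).  P1 finite elements turn this into
K Phi = F S with K the stiffness + absorption + Robin boundary matrix and
F the mass matrix.  The sensitivity matrix H = K^-1 F eta A (A = diag of
the nodal X-ray field) maps concentration to fluence; restricting its rows
to the camera-visible boundary nodes gives the measurement operator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from ._errors import (
    AssemblyError,
    ConfigurationError,
    DataError,
    DegenerateSignalError,
    FactorizationError,
    InvalidGeometryError,
)
from .mesh import Mesh, interpolate_field

__all__ = [
    "XRayConfig",
    "OpticalTissue",
    "SystemMatrices",
    "Measurement",
    "xray_field",
    "assemble_K",
    "assemble_F",
    "system_matrix",
    "restrict_rows",
    "visible_detector_nodes",
    "simulate_measurements",
]


@dataclass
class XRayConfig:
    """Cone-beam X-ray source.

    mu_t may be a scalar (homogeneous medium, analytic path integral) or a
    nodal vector (numerically integrated along the ray).  Tube settings are
    metadata only; the forward model is linear so absolute flux cancels in
    normalized reconstructions.
    """

    source_position: tuple[float, float, float]
    initial_intensity: float = 1.0
    mu_t: float | np.ndarray = 0.2
    cone_half_angle: float = np.deg2rad(15.0)
    cone_axis: tuple[float, float, float] | None = None  # default: at centroid
    inverse_square: bool = False
    tube_kv: float | None = 40.0
    tube_ma: float | None = 1.0

    def __post_init__(self) -> None:
        if self.initial_intensity <= 0:
            raise ConfigurationError("initial_intensity must be > 0")
        if np.any(np.asarray(self.mu_t) < 0):
            raise ConfigurationError("mu_t must be non-negative")


@dataclass
class OpticalTissue:
    """Homogeneous optical coefficients of the medium (cm^-1).

    kappa is the Robin boundary constant for the tissue/air refractive
    index mismatch; 2.52 is a typical soft-tissue value.
    """

    mu_a: float = 0.02
    mu_s_prime: float = 10.0
    kappa: float = 2.52

    def __post_init__(self) -> None:
        if self.mu_a <= 0 or self.mu_s_prime <= 0 or self.kappa <= 0:
            raise ConfigurationError(
                "mu_a, mu_s_prime and kappa must all be positive"
            )

    @property
    def D(self) -> float:
        return 1.0 / (3.0 * (self.mu_a + self.mu_s_prime))

    @property
    def mu_eff(self) -> float:
        """Effective attenuation sqrt(mu_a / D) = sqrt(3 mu_a (mu_a+mu_s'))."""
        return float(np.sqrt(3.0 * self.mu_a * (self.mu_a + self.mu_s_prime)))


@dataclass
class SystemMatrices:
    """FEM system: K Phi = F eta diag(X) rho, plus the detector-restricted
    sensitivity matrix when computed."""

    K: sp.csr_matrix
    F: sp.csr_matrix
    X: np.ndarray  # nodal X-ray excitation (diagonal of A)
    eta: float = 1.0
    H_meas: np.ndarray | None = None
    detector_node_ids: np.ndarray | None = None
    _factor: object = field(default=None, repr=False, compare=False)

    def factorize(self):
        if self._factor is None:
            try:
                self._factor = spla.splu(self.K.tocsc())
            except RuntimeError as exc:  # pragma: no cover - singular K
                raise FactorizationError(f"K factorization failed: {exc}")
        return self._factor

    def solve_fluence(self, rho: np.ndarray) -> np.ndarray:
        """Nodal fluence Phi for a concentration field: K Phi = F eta A rho."""
        load = self.F @ (self.eta * self.X * np.asarray(rho, dtype=float))
        return self.factorize().solve(load)


@dataclass
class Measurement:
    """Single-view surface measurement: fluence at detector boundary nodes."""

    detector_node_ids: np.ndarray
    values: np.ndarray
    view_angle_deg: float
    snr_db: float | None
    rng_seed: int | None
    mesh_checksum: str | None = None

    def __post_init__(self) -> None:
        self.detector_node_ids = np.asarray(self.detector_node_ids, dtype=np.int64)
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise DataError("measurement values must be finite")


# -- X-ray excitation ------------------------------------------------------


def _cylinder_entry_t(p0: np.ndarray, p1: np.ndarray, radius: float, height: float):
    """First parameter t in [0, 1] at which segment p0->p1 enters the
    cylinder x^2+y^2<=R^2, 0<=z<=h; None if it never does."""
    d = p1 - p0
    tmin, tmax = 0.0, 1.0
    # z slab
    if abs(d[2]) < 1e-15:
        if not (0.0 <= p0[2] <= height):
            return None
    else:
        t1, t2 = (0.0 - p0[2]) / d[2], (height - p0[2]) / d[2]
        tmin = max(tmin, min(t1, t2))
        tmax = min(tmax, max(t1, t2))
    # infinite cylinder
    a = d[0] ** 2 + d[1] ** 2
    if a < 1e-18:
        if p0[0] ** 2 + p0[1] ** 2 > radius**2:
            return None
    else:
        b = 2.0 * (p0[0] * d[0] + p0[1] * d[1])
        c = p0[0] ** 2 + p0[1] ** 2 - radius**2
        disc = b * b - 4 * a * c
        if disc < 0:
            return None
        sq = np.sqrt(disc)
        t1, t2 = (-b - sq) / (2 * a), (-b + sq) / (2 * a)
        tmin = max(tmin, t1)
        tmax = min(tmax, t2)
    if tmin > tmax + 1e-12:
        return None
    return max(tmin, 0.0)


def xray_field(mesh: Mesh, cfg: XRayConfig) -> np.ndarray:
    """Nodal X-ray intensity X(node) for a cone-beam point source.

    Attenuation only accrues along the in-medium part of the source-to-node
    segment; nodes outside the cone get 0.
    """
    src = np.asarray(cfg.source_position, dtype=float)
    pts = mesh.node_coords
    idx, _ = mesh.locate(src[None, :])
    if idx[0] >= 0:
        raise InvalidGeometryError("X-ray source lies inside the mesh")
    vec = pts - src
    dist = np.linalg.norm(vec, axis=1)
    axis = (
        np.asarray(cfg.cone_axis, dtype=float)
        if cfg.cone_axis is not None
        else pts.mean(axis=0) - src
    )
    axis = axis / np.linalg.norm(axis)
    cosang = (vec @ axis) / np.maximum(dist, 1e-300)
    in_cone = cosang >= np.cos(cfg.cone_half_angle)
    X = np.zeros(mesh.n_nodes)
    path = _in_medium_path(mesh, src, pts, dist)
    if np.isscalar(cfg.mu_t) or np.ndim(cfg.mu_t) == 0:
        tau = float(cfg.mu_t) * path
    else:
        tau = _integrate_nodal_mu(mesh, np.asarray(cfg.mu_t, float), src, pts, path)
    X[in_cone] = cfg.initial_intensity * np.exp(-tau[in_cone])
    if cfg.inverse_square:
        X[in_cone] /= np.maximum(dist[in_cone], 1e-12) ** 2
    return X


def _in_medium_path(mesh, src, pts, dist) -> np.ndarray:
    """Length of the in-medium segment between the source and each node."""
    path = np.zeros(len(pts))
    if mesh.cylinder is not None:
        radius, height = mesh.cylinder
        for i, p in enumerate(pts):
            t_in = _cylinder_entry_t(src, p, radius, height)
            if t_in is not None:
                path[i] = (1.0 - t_in) * dist[i]
        return path
    # generic mesh: march along the ray with point-in-mesh tests
    n_samp = 256
    for i, p in enumerate(pts):
        ts = np.linspace(0.0, 1.0, n_samp, endpoint=False)
        samples = src + ts[:, None] * (p - src)
        idx, _ = mesh.locate(samples)
        inside = idx >= 0
        path[i] = inside.mean() * dist[i]
    return path


def _integrate_nodal_mu(mesh, mu_t, src, pts, path) -> np.ndarray:
    """Trapezoid integral of a nodal mu_t field over the in-medium segment."""
    n_samp = 64
    tau = np.zeros(len(pts))
    for i, p in enumerate(pts):
        if path[i] <= 0:
            continue
        # sample the last `path` cm of the segment (the in-medium part)
        d = p - src
        L = np.linalg.norm(d)
        ts = np.linspace(1.0 - path[i] / L, 1.0, n_samp)
        samples = src + ts[:, None] * d
        mu = interpolate_field(mesh, mu_t, samples, fill=0.0)
        tau[i] = np.trapezoid(mu, ts * L)
    return tau


# -- FEM assembly ----------------------------------------------------------


def _tet_geometry(mesh: Mesh):
    p = mesh.node_coords[mesh.tet_conn]  # (m, 4, 3)
    e = p[:, 1:] - p[:, :1]  # (m, 3, 3)
    vol = np.einsum("ij,ij->i", e[:, 0], np.cross(e[:, 1], e[:, 2])) / 6.0
    if np.any(vol <= 0):
        bad = int(np.argmin(vol))
        raise AssemblyError(f"non-positive volume in element {bad}")
    # barycentric hats: lambda_(1..3)(x) = T^-1 (x - x0) with T = [e1 e2 e3]
    # as columns, so grad lambda_i is row i of T^-1; lambda_0 = -(sum)
    tinv = np.linalg.inv(e.transpose(0, 2, 1))  # T^-1, (m,3,3)
    g123 = tinv
    g0 = -g123.sum(axis=1, keepdims=True)
    grads = np.concatenate([g0, g123], axis=1)  # (m, 4, 3)
    return vol, grads


def _assemble_nodal(mesh: Mesh, local: np.ndarray) -> sp.csr_matrix:
    """Scatter (m, 4, 4) local matrices into a sparse global matrix."""
    m = mesh.n_tets
    conn = mesh.tet_conn
    rows = np.repeat(conn, 4, axis=1).ravel()
    cols = np.tile(conn, (1, 4)).ravel()
    A = sp.coo_matrix(
        (local.reshape(m, 16).ravel(), (rows, cols)),
        shape=(mesh.n_nodes, mesh.n_nodes),
    )
    return A.tocsr()


def stiffness_matrix(mesh: Mesh) -> sp.csr_matrix:
    """int grad(psi_i) . grad(psi_j) over Omega (unit coefficient)."""
    vol, grads = _tet_geometry(mesh)
    local = np.einsum("mid,mjd,m->mij", grads, grads, vol)
    return _assemble_nodal(mesh, local)


def assemble_F(mesh: Mesh) -> sp.csr_matrix:
    """P1 mass matrix int psi_i psi_j over Omega: per element V/10 on the
    diagonal and V/20 off it."""
    vol, _ = _tet_geometry(mesh)
    base = np.full((4, 4), 1.0 / 20.0)
    np.fill_diagonal(base, 1.0 / 10.0)
    local = vol[:, None, None] * base[None, :, :]
    return _assemble_nodal(mesh, local)


def boundary_mass_matrix(mesh: Mesh) -> sp.csr_matrix:
    """int psi_i psi_j over dOmega: per triangle A/6 diagonal, A/12 off."""
    faces = mesh.boundary_faces
    areas = mesh.boundary_face_areas
    base = np.full((3, 3), 1.0 / 12.0)
    np.fill_diagonal(base, 1.0 / 6.0)
    local = areas[:, None, None] * base[None, :, :]
    rows = np.repeat(faces, 3, axis=1).ravel()
    cols = np.tile(faces, (1, 3)).ravel()
    A = sp.coo_matrix(
        (local.reshape(len(faces), 9).ravel(), (rows, cols)),
        shape=(mesh.n_nodes, mesh.n_nodes),
    )
    return A.tocsr()


def assemble_K(mesh: Mesh, tissue: OpticalTissue) -> sp.csr_matrix:
    """Diffusion system matrix K = D*stiffness + mu_a*mass + Robin boundary
    term with coefficient 1/(2 kappa)."""
    K = (
        tissue.D * stiffness_matrix(mesh)
        + tissue.mu_a * assemble_F(mesh)
        + (1.0 / (2.0 * tissue.kappa)) * boundary_mass_matrix(mesh)
    )
    return K.tocsr()


# -- sensitivity matrix ----------------------------------------------------


def system_matrix(
    mesh: Mesh,
    tissue: OpticalTissue,
    X: np.ndarray,
    eta: float = 1.0,
) -> SystemMatrices:
    if eta <= 0:
        raise ConfigurationError("eta must be > 0")
    K = assemble_K(mesh, tissue)
    F = assemble_F(mesh)
    return SystemMatrices(K=K, F=F, X=np.asarray(X, dtype=float), eta=eta)


def restrict_rows(
    sysmat: SystemMatrices, detector_node_ids: Sequence[int]
) -> np.ndarray:
    """Detector-row-restricted sensitivity H_meas (detector x node).

    Uses the adjoint trick: row d of K^-1 F eta A is
    (K^-T e_d)^T F diag(eta X), so one sparse solve per detector instead of
    inverting K.
    """
    ids = np.asarray(detector_node_ids, dtype=np.int64)
    factor = sysmat.factorize()
    n = sysmat.K.shape[0]
    etaX = sysmat.eta * sysmat.X
    H = np.empty((len(ids), n))
    for k, d in enumerate(ids):
        e = np.zeros(n)
        e[d] = 1.0
        y = factor.solve(e, trans="T")
        H[k] = (sysmat.F @ y) * etaX
    if not np.all(np.isfinite(H)):
        raise FactorizationError("H_meas contains non-finite entries")
    sysmat.H_meas = H
    sysmat.detector_node_ids = ids
    return H


def sensitivity_columns(
    sysmat: SystemMatrices, cols: Sequence[int], detector_node_ids: Sequence[int]
) -> np.ndarray:
    """Reference column-wise construction of H_meas columns (one full FEM
    solve per column); used to cross-check the adjoint row construction."""
    ids = np.asarray(detector_node_ids, dtype=np.int64)
    out = np.empty((len(ids), len(cols)))
    for k, j in enumerate(cols):
        rho = np.zeros(sysmat.K.shape[0])
        rho[j] = 1.0
        out[:, k] = sysmat.solve_fluence(rho)[ids]
    return out


def visible_detector_nodes(
    mesh: Mesh,
    view_angle_deg: float,
    angular_cutoff_deg: float = 60.0,
    z_window: tuple[float, float] | None = None,
) -> np.ndarray:
    """Boundary nodes visible to a camera at azimuth theta.

    A node qualifies when at least one of its supporting boundary faces has
    an outward normal within ``angular_cutoff_deg`` of the camera direction
    d = (cos theta, sin theta, 0) and its z lies inside ``z_window``.
    """
    theta = np.deg2rad(view_angle_deg)
    d = np.array([np.cos(theta), np.sin(theta), 0.0])
    cos_cut = np.cos(np.deg2rad(angular_cutoff_deg))
    ok_faces = mesh.face_normals @ d >= cos_cut
    ids = np.unique(mesh.boundary_faces[ok_faces])
    if z_window is not None:
        z = mesh.node_coords[ids, 2]
        ids = ids[(z >= z_window[0]) & (z <= z_window[1])]
    if len(ids) == 0:
        raise ConfigurationError(
            "no boundary node is visible for this view/cutoff/z-window"
        )
    return ids


def simulate_measurements(
    H_meas: np.ndarray,
    rho: np.ndarray,
    snr_db: float | None,
    rng_seed: int | None = None,
    detector_node_ids: np.ndarray | None = None,
    view_angle_deg: float = 0.0,
    mesh_checksum: str | None = None,
) -> Measurement:
    """Noisy surface measurement Phi = H_meas rho + eps.

    eps is i.i.d. zero-mean Gaussian with variance mean(signal^2) /
    10^(snr_db/10), i.e. snr_db is the power SNR of the noiseless vector.
    ``snr_db=None`` means noiseless.
    """
    rho = np.asarray(rho, dtype=float)
    if np.any(rho < 0):
        raise DataError("rho must be non-negative")
    signal = H_meas @ rho
    values = signal
    if snr_db is not None and np.isfinite(snr_db):
        power = float(np.mean(signal**2))
        if power <= 0:
            raise DegenerateSignalError(
                "noiseless signal is identically zero; SNR undefined"
            )
        sigma = np.sqrt(power / 10.0 ** (snr_db / 10.0))
        rng = np.random.default_rng(rng_seed)
        values = signal + rng.normal(0.0, sigma, size=signal.shape)
    if detector_node_ids is None:
        detector_node_ids = np.arange(H_meas.shape[0])
    return Measurement(
        detector_node_ids=detector_node_ids,
        values=values,
        view_angle_deg=view_angle_deg,
        snr_db=snr_db,
        rng_seed=rng_seed,
        mesh_checksum=mesh_checksum,
    )
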