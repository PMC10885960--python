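"""Tetrahedral meshes of cylindrical phantoms.

The imaging domain Omega is discretized with piecewise-linear (P1)
tetrahedral elements; the boundary dOmega is the set of triangle faces
owned by exactly one tetrahedron, with outward unit normals nu.  The mesher
is a deterministic structured one: a triangulated disk ("spider-web" rings)
is extruded along z and each triangular prism is split into three
tetrahedra with index-consistent diagonals, so the same inputs always
produce the same mesh and shared quad faces never mismatch.

All coordinates are in cm; z is the cylinder axis with z = 0 the bottom
plane.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from ._errors import InvalidGeometryError, ResourceError, UnderResolutionError

__all__ = [
    "Mesh",
    "TargetSpec",
    "build_cylinder_mesh",
    "mark_target_nodes",
    "interpolate_field",
]

_MAX_NODES = 2_000_000  # sanity budget for the structured mesher


@dataclass(frozen=True)
class TargetSpec:
    """An axis-aligned cylindrical luminescent target (tube / tumour).

    Parameters
    ----------
    center : (3,) array-like
        Center position in cm.
    diameter : float
        Tube diameter in cm.
    height : float
        Tube height in cm (axis parallel to z).
    concentration : float
        Nanophosphor concentration in arbitrary linear units (the forward
        model is linear in concentration, so only ratios matter).
    name : str
        Label used in reports and error messages.
    """

    center: tuple[float, float, float]
    diameter: float
    height: float
    concentration: float
    name: str = "target"

    def __post_init__(self) -> None:
        if self.diameter <= 0 or self.height <= 0:
            raise InvalidGeometryError(
                f"{self.name}: diameter and height must be positive"
            )
        if self.concentration <= 0:
            raise InvalidGeometryError(f"{self.name}: concentration must be > 0")

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Vectorized point-in-cylinder test; points is (n, 3)."""
        p = np.atleast_2d(np.asarray(points, dtype=float))
        c = np.asarray(self.center, dtype=float)
        r2 = (p[:, 0] - c[0]) ** 2 + (p[:, 1] - c[1]) ** 2
        in_radial = r2 <= (self.diameter / 2.0) ** 2 + 1e-12
        in_axial = np.abs(p[:, 2] - c[2]) <= self.height / 2.0 + 1e-12
        return in_radial & in_axial

    def volume(self) -> float:
        return np.pi * (self.diameter / 2.0) ** 2 * self.height


class Mesh:
    """A tetrahedral mesh with boundary topology and point-location.

    Attributes
    ----------
    node_coords : (n_nodes, 3) float array, cm
    tet_conn : (n_tets, 4) int array
        Node indices per tetrahedron, oriented to positive signed volume.
    boundary_faces : (n_bfaces, 3) int array
        Surface triangles wound so the right-hand normal points outward.
    boundary_node_ids : (n_bnodes,) int array
    face_normals : (n_bfaces, 3) float array, outward unit normals
    cylinder : (radius, height) or None
        Set when the mesh was generated as a cylinder; used for analytic
        ray clipping.
    """

    def __init__(
        self,
        node_coords: np.ndarray,
        tet_conn: np.ndarray,
        cylinder: tuple[float, float] | None = None,
    ) -> None:
        self.node_coords = np.asarray(node_coords, dtype=float)
        tets = np.asarray(tet_conn, dtype=np.int64)
        if self.node_coords.ndim != 2 or self.node_coords.shape[1] != 3:
            raise InvalidGeometryError("node_coords must be (n, 3)")
        if tets.ndim != 2 or tets.shape[1] != 4:
            raise InvalidGeometryError("tet_conn must be (m, 4)")
        self.tet_conn = _orient_positive(self.node_coords, tets)
        self.cylinder = cylinder
        self._build_boundary()
        self._bins = None

    # -- basic quantities -------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return self.node_coords.shape[0]

    @property
    def n_tets(self) -> int:
        return self.tet_conn.shape[0]

    def tet_volumes(self) -> np.ndarray:
        return _signed_volumes(self.node_coords, self.tet_conn)

    def total_volume(self) -> float:
        return float(self.tet_volumes().sum())

    def checksum(self) -> str:
        h = hashlib.sha256()
        h.update(np.ascontiguousarray(self.node_coords).tobytes())
        h.update(np.ascontiguousarray(self.tet_conn).tobytes())
        return h.hexdigest()[:16]

    def bounding_box(self) -> tuple[np.ndarray, np.ndarray]:
        return self.node_coords.min(axis=0), self.node_coords.max(axis=0)

    # -- boundary topology ------------------------------------------------

    def _build_boundary(self) -> None:
        tets = self.tet_conn
        # local faces opposite each vertex; winding chosen so that for a
        # positively oriented tet the right-hand normal points out of it
        local = np.array([[1, 2, 3], [0, 3, 2], [0, 1, 3], [0, 2, 1]])
        faces = tets[:, local].reshape(-1, 3)  # (4m, 3) oriented
        owner = np.repeat(np.arange(self.n_tets), 4)
        key = np.sort(faces, axis=1)
        order = np.lexsort((key[:, 2], key[:, 1], key[:, 0]))
        key_sorted = key[order]
        dup = np.all(key_sorted[1:] == key_sorted[:-1], axis=1)
        is_first_of_pair = np.concatenate([dup, [False]])
        is_second_of_pair = np.concatenate([[False], dup])
        boundary_mask = ~(is_first_of_pair | is_second_of_pair)
        sel = order[boundary_mask]
        self.boundary_faces = faces[sel]
        self.boundary_face_owner = owner[sel]
        self.boundary_node_ids = np.unique(self.boundary_faces)
        p = self.node_coords
        a = p[self.boundary_faces[:, 0]]
        b = p[self.boundary_faces[:, 1]]
        c = p[self.boundary_faces[:, 2]]
        n = np.cross(b - a, c - a)
        norms = np.linalg.norm(n, axis=1, keepdims=True)
        n = n / norms
        # guarantee outward orientation w.r.t. the owning tet
        tet_centroids = p[tets[self.boundary_face_owner]].mean(axis=1)
        face_centroids = (a + b + c) / 3.0
        flip = np.einsum("ij,ij->i", n, face_centroids - tet_centroids) < 0
        n[flip] *= -1.0
        self.boundary_faces[flip] = self.boundary_faces[flip][:, [0, 2, 1]]
        self.face_normals = n
        self.boundary_face_areas = norms[:, 0] / 2.0

    def boundary_euler_characteristic(self) -> int:
        """V - E + F of the boundary surface (2 for a closed genus-0 shell)."""
        f = self.boundary_faces
        v = len(np.unique(f))
        edges = np.sort(
            np.concatenate([f[:, [0, 1]], f[:, [1, 2]], f[:, [0, 2]]]), axis=1
        )
        e = len(np.unique(edges, axis=0))
        return v - e + len(f)

    def node_normals(self) -> np.ndarray:
        """Area-weighted outward normals at boundary nodes (unit length);
        zero rows for interior nodes."""
        n = np.zeros_like(self.node_coords)
        w = self.face_normals * self.boundary_face_areas[:, None]
        for k in range(3):
            np.add.at(n, self.boundary_faces[:, k], w)
        lens = np.linalg.norm(n, axis=1)
        nz = lens > 0
        n[nz] /= lens[nz, None]
        return n

    def node_adjacency(self) -> list[set[int]]:
        """Node-to-node adjacency along tet edges (for graph-hop queries)."""
        adj: list[set[int]] = [set() for _ in range(self.n_nodes)]
        pairs = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]
        for i, j in pairs:
            for a, b in zip(self.tet_conn[:, i], self.tet_conn[:, j]):
                adj[a].add(int(b))
                adj[b].add(int(a))
        return adj

    # -- point location ---------------------------------------------------

    def _build_bins(self) -> None:
        p = self.node_coords
        tets = self.tet_conn
        lo = p.min(axis=0)
        hi = p.max(axis=0)
        tp = p[tets]  # (m, 4, 3)
        tlo = tp.min(axis=1)
        thi = tp.max(axis=1)
        h = max((thi - tlo).max(), 1e-12)
        nbin = np.maximum(1, np.floor((hi - lo) / h).astype(int))
        cell = (hi - lo) / nbin
        cell[cell == 0] = 1.0
        ilo = np.clip(((tlo - lo) / cell).astype(int), 0, nbin - 1)
        ihi = np.clip(((thi - lo) / cell).astype(int), 0, nbin - 1)
        bins: dict[tuple[int, int, int], list[int]] = {}
        for t in range(len(tets)):
            for ix in range(ilo[t, 0], ihi[t, 0] + 1):
                for iy in range(ilo[t, 1], ihi[t, 1] + 1):
                    for iz in range(ilo[t, 2], ihi[t, 2] + 1):
                        bins.setdefault((ix, iy, iz), []).append(t)
        for k in bins:
            bins[k] = np.array(sorted(bins[k]), dtype=np.int64)
        # precompute barycentric transforms: bary = Tinv @ (x - x0)
        x0 = tp[:, 0]
        edges = tp[:, 1:] - x0[:, None, :]  # (m, 3, 3) rows are edge vecs
        tinv = np.linalg.inv(edges.transpose(0, 2, 1))  # columns are edges
        self._bins = (lo, cell, nbin, bins, x0, tinv)

    def locate(self, points: np.ndarray, tol: float = 1e-9):
        """Find containing tetrahedra.

        Returns ``(tet_idx, bary)`` where ``tet_idx`` is -1 for points
        outside the mesh and ``bary`` the 4 barycentric coordinates.
        Points on shared faces resolve to the lowest tetrahedron index.
        """
        if self._bins is None:
            self._build_bins()
        lo, cell, nbin, bins, x0, tinv = self._bins
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        n = len(pts)
        tet_idx = np.full(n, -1, dtype=np.int64)
        bary = np.zeros((n, 4))
        idx = np.clip(((pts - lo) / cell).astype(int), 0, nbin - 1)
        keys = [tuple(row) for row in idx]
        from collections import defaultdict

        groups: dict[tuple[int, int, int], list[int]] = defaultdict(list)
        for i, k in enumerate(keys):
            groups[k].append(i)
        for k, members in groups.items():
            cand = bins.get(k)
            if cand is None:
                continue
            members = np.array(members)
            unresolved = members.copy()
            for t in cand:  # ascending: ties resolve to lowest index
                if len(unresolved) == 0:
                    break
                d = pts[unresolved] - x0[t]
                lam = d @ tinv[t].T  # (q, 3) lambdas 1..3
                lam0 = 1.0 - lam.sum(axis=1)
                ok = (
                    (lam0 >= -tol)
                    & (lam[:, 0] >= -tol)
                    & (lam[:, 1] >= -tol)
                    & (lam[:, 2] >= -tol)
                )
                hit = unresolved[ok]
                tet_idx[hit] = t
                bary[hit, 0] = lam0[ok]
                bary[hit, 1:] = lam[ok]
                unresolved = unresolved[~ok]
        return tet_idx, bary


def _signed_volumes(coords: np.ndarray, tets: np.ndarray) -> np.ndarray:
    p = coords[tets]
    e = p[:, 1:] - p[:, :1]
    return np.einsum("ij,ij->i", e[:, 0], np.cross(e[:, 1], e[:, 2])) / 6.0


def _orient_positive(coords: np.ndarray, tets: np.ndarray) -> np.ndarray:
    vol = _signed_volumes(coords, tets)
    if np.any(np.abs(vol) < 1e-14):
        bad = int(np.argmin(np.abs(vol)))
        raise InvalidGeometryError(f"degenerate tetrahedron at index {bad}")
    tets = tets.copy()
    neg = vol < 0
    tets[neg] = tets[neg][:, [0, 1, 3, 2]]
    return tets


# -- structured cylinder mesher -------------------------------------------


def _disk_points(radius: float, n_rings: int) -> np.ndarray:
    pts = [(0.0, 0.0)]
    for k in range(1, n_rings + 1):
        r = radius * k / n_rings
        m = 6 * k
        ang = 2.0 * np.pi * np.arange(m) / m
        pts.extend(zip(r * np.cos(ang), r * np.sin(ang)))
    return np.array(pts)


def _ring_offsets(n_rings: int) -> list[int]:
    off = [0, 1]
    for k in range(1, n_rings + 1):
        off.append(off[-1] + 6 * k)
    return off  # off[k] .. off[k+1] are ring-k node ids (ring 0 = center)


def _disk_triangles(n_rings: int) -> np.ndarray:
    off = _ring_offsets(n_rings)
    tris: list[tuple[int, int, int]] = []
    # ring 1 fan around the center
    for j in range(6):
        tris.append((0, off[1] + j, off[1] + (j + 1) % 6))
    # annuli: merge inner ring (6(k-1) pts) with outer ring (6k pts) by angle
    for k in range(2, n_rings + 1):
        n_in, n_out = 6 * (k - 1), 6 * k
        base_in, base_out = off[k - 1], off[k]
        i = o = 0
        while i < n_in or o < n_out:
            a_in_next = 2 * np.pi * (i + 1) / n_in
            a_out_next = 2 * np.pi * (o + 1) / n_out
            ii = base_in + i % n_in
            oo = base_out + o % n_out
            if o < n_out and (i >= n_in or a_out_next <= a_in_next + 1e-12):
                tris.append((ii, oo, base_out + (o + 1) % n_out))
                o += 1
            else:
                tris.append((ii, oo, base_in + (i + 1) % n_in))
                i += 1
    return np.array(tris, dtype=np.int64)


def _split_prism(b: Sequence[int], t: Sequence[int], col: Sequence[int]):
    """Split prism (bottom b, top t, global column keys col) into 3 tets.

    Diagonal of each vertical quad runs from the bottom vertex of the
    lower-keyed column to the top vertex of the higher-keyed column; this
    depends only on the shared columns, so neighbouring prisms agree.
    """
    order = int(np.argmin(col))
    idx = [(order + i) % 3 for i in range(3)]  # rotate, keep cyclic order
    b0, b1, b2 = (b[i] for i in idx)
    t0, t1, t2 = (t[i] for i in idx)
    c1, c2 = col[idx[1]], col[idx[2]]
    if c1 < c2:
        return [(b0, b1, b2, t2), (b0, b1, t2, t1), (b0, t1, t2, t0)]
    return [(b0, b1, b2, t1), (b0, b2, t1, t2), (b0, t1, t2, t0)]


def build_cylinder_mesh(
    radius: float, height: float, target_edge_length: float
) -> Mesh:
    """Deterministic structured tet mesh of a cylinder (axis = z, base at
    z = 0).

    ``target_edge_length`` sets both the radial ring spacing and the axial
    layer height; the node count grows as the edge length shrinks.
    """
    if radius <= 0 or height <= 0:
        raise InvalidGeometryError("radius and height must be positive")
    if not (0 < target_edge_length < radius):
        raise InvalidGeometryError(
            "target_edge_length must lie in (0, radius)"
        )
    n_rings = max(1, int(np.ceil(radius / target_edge_length)))
    n_layers = max(1, int(np.ceil(height / target_edge_length)))
    n_disk = 1 + 3 * n_rings * (n_rings + 1)
    if n_disk * (n_layers + 1) > _MAX_NODES:
        raise ResourceError(
            f"edge length {target_edge_length} would require "
            f"{n_disk * (n_layers + 1)} nodes"
        )
    disk = _disk_points(radius, n_rings)
    tris = _disk_triangles(n_rings)
    zs = np.linspace(0.0, height, n_layers + 1)
    coords = np.empty((n_disk * (n_layers + 1), 3))
    for l, z in enumerate(zs):
        coords[l * n_disk : (l + 1) * n_disk, :2] = disk
        coords[l * n_disk : (l + 1) * n_disk, 2] = z
    tets: list[tuple[int, int, int, int]] = []
    for l in range(n_layers):
        lo = l * n_disk
        hi = (l + 1) * n_disk
        for tri in tris:
            b = [lo + int(v) for v in tri]
            t = [hi + int(v) for v in tri]
            tets.extend(_split_prism(b, t, [int(v) for v in tri]))
    return Mesh(coords, np.array(tets, dtype=np.int64), cylinder=(radius, height))


# -- nodal fields ----------------------------------------------------------


def mark_target_nodes(mesh: Mesh, targets: Iterable[TargetSpec]) -> np.ndarray:
    """Nodal concentration vector rho: each node takes the concentration of
    the unique target containing it, 0 elsewhere."""
    rho = np.zeros(mesh.n_nodes)
    claimed = np.zeros(mesh.n_nodes, dtype=bool)
    for tg in targets:
        inside = tg.contains(mesh.node_coords)
        if not inside.any():
            raise UnderResolutionError(
                f"target '{tg.name}' contains no mesh node at this resolution"
            )
        if (claimed & inside).any():
            raise InvalidGeometryError(
                f"target '{tg.name}' overlaps a previously marked target"
            )
        rho[inside] = tg.concentration
        claimed |= inside
    return rho


def interpolate_field(
    mesh: Mesh,
    nodal_values: np.ndarray,
    query_points: np.ndarray,
    fill: float = np.nan,
) -> np.ndarray:
    """Barycentric-linear interpolation of a nodal field.

    Points outside the mesh get the ``fill`` sentinel (NaN by default);
    they are flagged, never fatal.
    """
    vals = np.asarray(nodal_values, dtype=float)
    if vals.shape[0] != mesh.n_nodes:
        raise ValueError("nodal_values length must equal the node count")
    pts = np.atleast_2d(np.asarray(query_points, dtype=float))
    tet_idx, bary = mesh.locate(pts)
    out = np.full(len(pts), fill, dtype=float)
    inside = tet_idx >= 0
    if inside.any():
        conn = mesh.tet_conn[tet_idx[inside]]
        out[inside] = np.einsum("ij,ij->i", bary[inside], vals[conn])
    return out
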