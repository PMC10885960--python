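"""Text-format I/O: Gmsh MSH v2 ASCII and legacy VTK meshes with nodal
fields, measurement CSV files, solver traces, and run manifests.

Both mesh formats are simple line-oriented ASCII containers; fields are
attached as point-data arrays.  Measurement CSVs carry their acquisition
metadata (view angle, SNR, seed, mesh checksum) in ``#``-prefixed header
lines so a file is self-describing.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from ._errors import DataError
from .forward import Measurement
from .mesh import Mesh

__all__ = [
    "write_msh",
    "read_msh",
    "write_vtk",
    "read_vtk",
    "write_measurement_csv",
    "read_measurement_csv",
    "write_trace_csv",
    "RunManifest",
]


# -- Gmsh MSH v2 ASCII -----------------------------------------------------


def write_msh(path, mesh: Mesh, fields: dict[str, np.ndarray] | None = None):
    """Write a tetrahedral mesh (and optional nodal fields) as MSH 2.2.

    Boundary triangles are written as element type 2, tetrahedra as type
    4; nodal fields go into ``$NodeData`` blocks.
    """
    path = Path(path)
    lines = ["$MeshFormat", "2.2 0 8", "$EndMeshFormat", "$Nodes",
             str(mesh.n_nodes)]
    for i, (x, y, z) in enumerate(mesh.node_coords, start=1):
        lines.append(f"{i} {x:.17g} {y:.17g} {z:.17g}")
    lines.append("$EndNodes")
    n_elem = mesh.n_tets + len(mesh.boundary_faces)
    lines += ["$Elements", str(n_elem)]
    eid = 1
    for tri in mesh.boundary_faces:
        lines.append(f"{eid} 2 2 0 0 " + " ".join(str(v + 1) for v in tri))
        eid += 1
    for tet in mesh.tet_conn:
        lines.append(f"{eid} 4 2 0 0 " + " ".join(str(v + 1) for v in tet))
        eid += 1
    lines.append("$EndElements")
    for name, vals in (fields or {}).items():
        vals = np.asarray(vals, dtype=float)
        lines += ["$NodeData", "1", f'"{name}"', "1", "0.0", "3", "0", "1",
                  str(mesh.n_nodes)]
        for i, v in enumerate(vals, start=1):
            lines.append(f"{i} {v:.17g}")
        lines.append("$EndNodeData")
    path.write_text("\n".join(lines) + "\n")


def read_msh(path) -> tuple[Mesh, dict[str, np.ndarray]]:
    """Read an MSH 2.2 ASCII file written by :func:`write_msh` (or any
    file restricted to type-2/type-4 elements)."""
    tokens = Path(path).read_text().splitlines()
    it = iter(tokens)
    coords = None
    tets = []
    fields: dict[str, np.ndarray] = {}
    for line in it:
        if line.strip() == "$Nodes":
            n = int(next(it))
            coords = np.empty((n, 3))
            for _ in range(n):
                parts = next(it).split()
                coords[int(parts[0]) - 1] = [float(p) for p in parts[1:4]]
        elif line.strip() == "$Elements":
            n = int(next(it))
            for _ in range(n):
                parts = next(it).split()
                etype = int(parts[1])
                ntags = int(parts[2])
                conn = [int(p) - 1 for p in parts[3 + ntags:]]
                if etype == 4:
                    tets.append(conn)
        elif line.strip() == "$NodeData":
            n_str_tags = int(next(it))
            name = next(it).strip().strip('"')
            for _ in range(n_str_tags - 1):
                next(it)
            n_real = int(next(it))
            for _ in range(n_real):
                next(it)
            n_int = int(next(it))
            int_tags = [int(next(it)) for _ in range(n_int)]
            n_vals = int_tags[-1]
            vals = np.empty(n_vals)
            for _ in range(n_vals):
                parts = next(it).split()
                vals[int(parts[0]) - 1] = float(parts[1])
            fields[name] = vals
    if coords is None or not tets:
        raise DataError(f"{path}: no nodes/tetrahedra found")
    return Mesh(coords, np.array(tets, dtype=np.int64)), fields


# -- legacy VTK ASCII ------------------------------------------------------


def write_vtk(path, mesh: Mesh, fields: dict[str, np.ndarray] | None = None):
    """Write the mesh as a legacy VTK ASCII unstructured grid with nodal
    scalar fields as POINT_DATA."""
    path = Path(path)
    out = [
        "# vtk DataFile Version 3.0",
        "xlct unstructured grid",
        "ASCII",
        "DATASET UNSTRUCTURED_GRID",
        f"POINTS {mesh.n_nodes} double",
    ]
    for x, y, z in mesh.node_coords:
        out.append(f"{x:.17g} {y:.17g} {z:.17g}")
    m = mesh.n_tets
    out.append(f"CELLS {m} {5 * m}")
    for tet in mesh.tet_conn:
        out.append("4 " + " ".join(str(v) for v in tet))
    out.append(f"CELL_TYPES {m}")
    out += ["10"] * m  # VTK_TETRA
    if fields:
        out.append(f"POINT_DATA {mesh.n_nodes}")
        for name, vals in fields.items():
            out.append(f"SCALARS {name} double 1")
            out.append("LOOKUP_TABLE default")
            out += [f"{v:.17g}" for v in np.asarray(vals, dtype=float)]
    path.write_text("\n".join(out) + "\n")


def read_vtk(path) -> tuple[Mesh, dict[str, np.ndarray]]:
    """Read a legacy VTK ASCII unstructured grid of tetrahedra."""
    words = Path(path).read_text().split()
    fields: dict[str, np.ndarray] = {}
    i = 0

    def seek(token):
        nonlocal i
        while i < len(words) and words[i].upper() != token:
            i += 1
        if i == len(words):
            raise DataError(f"{path}: missing {token} section")

    seek("POINTS")
    n = int(words[i + 1])
    i += 3
    coords = np.array(words[i : i + 3 * n], dtype=float).reshape(n, 3)
    i += 3 * n
    seek("CELLS")
    m = int(words[i + 1])
    i += 3
    tets = []
    for _ in range(m):
        k = int(words[i])
        if k != 4:
            raise DataError(f"{path}: only tetrahedral cells supported")
        tets.append([int(w) for w in words[i + 1 : i + 5]])
        i += 5
    mesh = Mesh(coords, np.array(tets, dtype=np.int64))
    while True:
        try:
            seek("SCALARS")
        except DataError:
            break
        name = words[i + 1]
        i += 4  # SCALARS name type 1
        if words[i].upper() == "LOOKUP_TABLE":
            i += 2
        fields[name] = np.array(words[i : i + n], dtype=float)
        i += n
    return mesh, fields


# -- measurements ----------------------------------------------------------


def write_measurement_csv(path, measurement: Measurement, mesh: Mesh):
    """Measurement CSV: metadata header lines plus one row per detector
    node (detector_node_id, x, y, z, phi)."""
    path = Path(path)
    p = mesh.node_coords[measurement.detector_node_ids]
    header = [
        f"# view_angle_deg={measurement.view_angle_deg}",
        f"# snr_db={measurement.snr_db}",
        f"# seed={measurement.rng_seed}",
        f"# mesh_checksum={measurement.mesh_checksum or mesh.checksum()}",
    ]
    df = pd.DataFrame(
        {
            "detector_node_id": measurement.detector_node_ids,
            "x": p[:, 0],
            "y": p[:, 1],
            "z": p[:, 2],
            "phi": measurement.values,
        }
    )
    with open(path, "w") as fh:
        fh.write("\n".join(header) + "\n")
        df.to_csv(fh, index=False)


def read_measurement_csv(path) -> Measurement:
    meta = {}
    lines = Path(path).read_text().splitlines()
    body_start = 0
    for k, line in enumerate(lines):
        if not line.startswith("#"):
            body_start = k
            break
        key, _, val = line[1:].strip().partition("=")
        meta[key.strip()] = val.strip()
    import io

    df = pd.read_csv(io.StringIO("\n".join(lines[body_start:])))

    def _num(key, cast):
        v = meta.get(key, "None")
        return None if v in ("None", "") else cast(float(v))

    return Measurement(
        detector_node_ids=df["detector_node_id"].to_numpy(np.int64),
        values=df["phi"].to_numpy(float),
        view_angle_deg=float(meta.get("view_angle_deg", 0.0)),
        snr_db=_num("snr_db", float),
        rng_seed=_num("seed", int),
        mesh_checksum=meta.get("mesh_checksum"),
    )


def write_trace_csv(path, trace):
    trace.to_frame().to_csv(path, index=False)


# -- run manifest ----------------------------------------------------------


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


@dataclass
class RunManifest:
    """Reproducibility record for a pipeline run: config snapshot, input
    hashes, seeds, timestamps, and the produced files."""

    config: dict
    seed: int | None
    inputs: dict[str, str] = field(default_factory=dict)
    outputs: dict[str, str] = field(default_factory=dict)
    started: str = field(
        default_factory=lambda: datetime.now(timezone.utc).isoformat()
    )
    finished: str | None = None

    def add_input(self, path):
        self.inputs[str(path)] = _sha256(Path(path))

    def add_output(self, path):
        self.outputs[str(path)] = _sha256(Path(path))

    def config_hash(self) -> str:
        blob = json.dumps(self.config, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]

    def finalize(self):
        self.finished = datetime.now(timezone.utc).isoformat()

    def write(self, path):
        Path(path).write_text(
            json.dumps(
                {
                    "config": self.config,
                    "config_hash": self.config_hash(),
                    "seed": self.seed,
                    "inputs": self.inputs,
                    "outputs": self.outputs,
                    "started": self.started,
                    "finished": self.finished,
                },
                indent=2,
                default=str,
            )
            + "\n"
        )
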