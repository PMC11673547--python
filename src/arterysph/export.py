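"""Plain-text exports: particle snapshots (CSV, legacy VTK), surfaces
(ASCII PLY, legacy VTK PolyData), growth logs and WSS series.

Legacy-VTK and PLY are written directly — both are simple line-oriented
ASCII formats — so snapshots open in ParaView or Blender without any
binary dependencies.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "snapshot_frame",
    "write_snapshot_csv",
    "write_points_vtk",
    "write_surface_ply",
    "write_surface_vtk",
    "write_series_csv",
]


def snapshot_frame(system, wss_field=None) -> pd.DataFrame:
    """Tabulate a particle system (one row per particle) for export."""
    n = len(system)
    wall_flag = np.zeros(n, dtype=int)
    wss = np.zeros(n)
    if wss_field is not None and len(wss_field.wall_particle_ids):
        wall_flag[wss_field.wall_particle_ids] = 1
        wss[wss_field.wall_particle_ids] = wss_field.wss_values
    return pd.DataFrame(
        {
            "id": np.arange(n),
            "x": system.positions[:, 0],
            "y": system.positions[:, 1],
            "z": system.positions[:, 2],
            "vx": system.velocities[:, 0],
            "vy": system.velocities[:, 1],
            "vz": system.velocities[:, 2],
            "density": system.densities,
            "pressure": system.pressures,
            "wall_flag": wall_flag,
            "wss": wss,
        }
    )


def write_snapshot_csv(path, system, wss_field=None) -> None:
    snapshot_frame(system, wss_field).to_csv(path, index=False, float_format="%.9g")


def write_points_vtk(path, positions, scalars=None, scalar_name="wss") -> None:
    """Legacy-VTK point cloud with an optional scalar array."""
    pos = np.asarray(positions, dtype=float).reshape(-1, 3)
    n = len(pos)
    lines = [
        "# vtk DataFile Version 3.0",
        "arterysph particles",
        "ASCII",
        "DATASET POLYDATA",
        f"POINTS {n} float",
    ]
    lines += [f"{p[0]:.9g} {p[1]:.9g} {p[2]:.9g}" for p in pos]
    lines += [f"VERTICES {n} {2 * n}"] + [f"1 {i}" for i in range(n)]
    if scalars is not None:
        scalars = np.asarray(scalars, dtype=float).reshape(-1)
        lines += [
            f"POINT_DATA {n}",
            f"SCALARS {scalar_name} float 1",
            "LOOKUP_TABLE default",
        ] + [f"{s:.9g}" for s in scalars]
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def write_surface_ply(path, vertices, faces) -> None:
    """ASCII PLY triangle mesh."""
    vertices = np.asarray(vertices, dtype=float)
    faces = np.asarray(faces, dtype=int)
    with open(path, "w") as fh:
        fh.write(
            "ply\nformat ascii 1.0\n"
            f"element vertex {len(vertices)}\n"
            "property float x\nproperty float y\nproperty float z\n"
            f"element face {len(faces)}\n"
            "property list uchar int vertex_indices\nend_header\n"
        )
        for v in vertices:
            fh.write(f"{v[0]:.9g} {v[1]:.9g} {v[2]:.9g}\n")
        for f in faces:
            fh.write(f"3 {f[0]} {f[1]} {f[2]}\n")


def write_surface_vtk(path, vertices, faces) -> None:
    """Legacy-VTK PolyData triangle mesh."""
    vertices = np.asarray(vertices, dtype=float)
    faces = np.asarray(faces, dtype=int)
    lines = [
        "# vtk DataFile Version 3.0",
        "arterysph surface",
        "ASCII",
        "DATASET POLYDATA",
        f"POINTS {len(vertices)} float",
    ]
    lines += [f"{v[0]:.9g} {v[1]:.9g} {v[2]:.9g}" for v in vertices]
    lines += [f"POLYGONS {len(faces)} {4 * len(faces)}"]
    lines += [f"3 {f[0]} {f[1]} {f[2]}" for f in faces]
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def write_series_csv(path, frame: pd.DataFrame) -> None:
    frame.to_csv(path, index=False, float_format="%.9g")
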