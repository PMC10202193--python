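"""Export helpers: PLY point clouds, OBJ/PLY meshes, JSON results."""

from __future__ import annotations

import numpy as np

from .volume import PointCloud, TriangleMesh


def write_ply_cloud(cloud: PointCloud, path, binary: bool = True) -> None:
    """Write a point cloud as PLY (x y z r g b per vertex).

    Binary little-endian by default; ``binary=False`` writes ASCII.
    """
    pts = np.asarray(cloud.points, dtype=np.float32)
    if cloud.colors is not None:
        cols = np.clip(cloud.colors, 0, 255).astype(np.uint8)
    else:
        cols = np.full((len(pts), 3), 200, dtype=np.uint8)
    fmt = "binary_little_endian" if binary else "ascii"
    header = (
        f"ply\nformat {fmt} 1.0\n"
        f"element vertex {len(pts)}\n"
        "property float x\nproperty float y\nproperty float z\n"
        "property uchar red\nproperty uchar green\nproperty uchar blue\n"
        "end_header\n")
    if binary:
        rec = np.zeros(len(pts), dtype=[("xyz", "<f4", 3), ("rgb", "u1", 3)])
        rec["xyz"] = pts
        rec["rgb"] = cols
        with open(path, "wb") as fh:
            fh.write(header.encode("ascii"))
            rec.tofile(fh)
    else:
        with open(path, "w") as fh:
            fh.write(header)
            for p, c in zip(pts, cols):
                fh.write(f"{p[0]} {p[1]} {p[2]} {c[0]} {c[1]} {c[2]}\n")


def write_obj_mesh(mesh: TriangleMesh, path) -> None:
    """Write a triangle mesh as Wavefront OBJ (1-based indices)."""
    with open(path, "w") as fh:
        for v in mesh.vertices:
            fh.write(f"v {v[0]:.6f} {v[1]:.6f} {v[2]:.6f}\n")
        for t in mesh.triangles:
            fh.write(f"f {t[0] + 1} {t[1] + 1} {t[2] + 1}\n")


def read_ply_cloud(path) -> PointCloud:
    """Read back a PLY written by :func:`write_ply_cloud` (round-trip)."""
    with open(path, "rb") as fh:
        header = []
        while True:
            line = fh.readline().decode("ascii").strip()
            header.append(line)
            if line == "end_header":
                break
        n = next(int(l.split()[-1]) for l in header
                 if l.startswith("element vertex"))
        binary = any("binary_little_endian" in l for l in header)
        if binary:
            rec = np.fromfile(fh, dtype=[("xyz", "<f4", 3),
                                         ("rgb", "u1", 3)], count=n)
            return PointCloud(rec["xyz"].astype(np.float64),
                              rec["rgb"].astype(np.float64))
        rows = [fh.readline().decode("ascii").split() for _ in range(n)]
        arr = np.asarray(rows, dtype=np.float64)
        return PointCloud(arr[:, :3], arr[:, 3:6])
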