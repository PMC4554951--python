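"""Volumetric image and network I/O with explicit physical metadata.

Grids are stored as multi-page TIFF (or a directory of equally sized 2D
TIFF slices) with a JSON sidecar ``<stem>.meta.json`` carrying the voxel
edge length in mm.  Arrays follow the ``(z, y, x)`` axis convention and a
physical coordinate is ``index * voxel_size_mm`` (index 0 maps to 0.0 mm).
Voxels are cubic; anisotropic voxel sizes are rejected at read time.

Vessel networks are exported as legacy ASCII VTK polydata with a per-point
``radius_mm`` scalar, which ParaView-class viewers read directly.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np
import tifffile

logger = logging.getLogger(__name__)


class VolumeFormatError(ValueError):
    """Raised for malformed image stacks (ragged slices, bad dtype ...)."""


class MetadataError(ValueError):
    """Raised when the physical voxel size cannot be determined."""


def _check_grid(voxels: np.ndarray, voxel_size_mm: float) -> None:
    if voxels.ndim != 3:
        raise VolumeFormatError(f"expected a 3D grid, got shape {voxels.shape}")
    if min(voxels.shape) < 1:
        raise VolumeFormatError(f"degenerate shape {voxels.shape}")
    if not (voxel_size_mm > 0):
        raise MetadataError(f"voxel_size_mm must be > 0, got {voxel_size_mm}")


@dataclass
class Volume:
    """A 3D scalar image on a cubic-voxel grid.

    Attributes
    ----------
    voxels
        ``(nz, ny, nx)`` array of intensities (stored 8- or 16-bit).
    voxel_size_mm
        Edge length of one (cubic) voxel in millimetres.
    """

    voxels: np.ndarray
    voxel_size_mm: float

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        _check_grid(self.voxels, self.voxel_size_mm)
        if np.issubdtype(self.voxels.dtype, np.floating) and not np.all(np.isfinite(self.voxels)):
            raise VolumeFormatError("intensities must be finite")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(self.voxel_size_mm) ** 3


@dataclass
class Mask:
    """A 3D boolean grid aligned with a :class:`Volume`."""

    voxels: np.ndarray
    voxel_size_mm: float

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        _check_grid(self.voxels, self.voxel_size_mm)
        if self.voxels.dtype != bool:
            self.voxels = self.voxels != 0

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(self.voxel_size_mm) ** 3


@dataclass
class LabelMap:
    """A 3D non-negative integer grid; 0 is background, labels are 1..K."""

    voxels: np.ndarray
    voxel_size_mm: float

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        _check_grid(self.voxels, self.voxel_size_mm)
        if not np.issubdtype(self.voxels.dtype, np.integer):
            raise VolumeFormatError("LabelMap requires an integer grid")
        if self.voxels.min() < 0:
            raise VolumeFormatError("labels must be non-negative")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def n_labels(self) -> int:
        return int(self.voxels.max())


GridLike = Union[Volume, Mask, LabelMap]


def _meta_path(path: Path) -> Path:
    if path.is_dir():
        return path / f"{path.name}.meta.json"
    stem = path.name
    for suf in (".tif", ".tiff"):
        if stem.lower().endswith(suf):
            stem = stem[: -len(suf)]
            break
    return path.parent / f"{stem}.meta.json"


def read_volume(
    path: Union[str, Path],
    voxel_size_mm: Optional[float] = None,
    as_mask: bool = False,
) -> GridLike:
    """Read a multi-page TIFF or a directory of 2D TIFF slices.

    Slices from a directory are stacked in sorted file-name order along z.
    The voxel size is taken from the ``<stem>.meta.json`` sidecar unless
    overridden.  Returns a :class:`Mask` when ``as_mask`` is set (any
    nonzero voxel reads as true), a :class:`LabelMap` for signed/unsigned
    integer data read through :func:`read_labels`, else a :class:`Volume`.
    """
    path = Path(path)
    if path.is_dir():
        slices = sorted(p for p in path.iterdir() if p.suffix.lower() in (".tif", ".tiff"))
        if not slices:
            raise VolumeFormatError(f"no TIFF slices in directory {path}")
        arrays = [tifffile.imread(p) for p in slices]
        shapes = {a.shape for a in arrays}
        if len(shapes) != 1 or any(a.ndim != 2 for a in arrays):
            raise VolumeFormatError(f"ragged or non-2D slices in {path}: shapes {sorted(shapes)}")
        voxels = np.stack(arrays, axis=0)
    elif path.exists():
        voxels = tifffile.imread(path)
        if voxels.ndim == 2:  # single-page TIFF -> degenerate 1-slice stack
            voxels = voxels[None, :, :]
        if voxels.ndim != 3:
            raise VolumeFormatError(f"{path}: expected 2D/3D TIFF, got ndim={voxels.ndim}")
    else:
        raise VolumeFormatError(f"no such file or directory: {path}")

    if voxel_size_mm is None:
        meta = _meta_path(path)
        if not meta.exists():
            raise MetadataError(
                f"voxel size not given and sidecar {meta} not found; "
                "pass voxel_size_mm explicitly or write the sidecar"
            )
        with open(meta) as fh:
            doc = json.load(fh)
        if "voxel_size_mm" not in doc:
            raise MetadataError(f"{meta} has no 'voxel_size_mm' key")
        voxel_size_mm = float(doc["voxel_size_mm"])

    if as_mask:
        return Mask(voxels != 0, voxel_size_mm)
    return Volume(voxels, voxel_size_mm)


def read_labels(path: Union[str, Path], voxel_size_mm: Optional[float] = None) -> LabelMap:
    """Read an integer-labelled grid (stored 8/16-bit TIFF)."""
    v = read_volume(path, voxel_size_mm)
    return LabelMap(v.voxels.astype(np.int32), v.voxel_size_mm)


def write_volume(grid: GridLike, path: Union[str, Path]) -> Path:
    """Write a grid as multi-page TIFF plus a JSON metadata sidecar.

    Masks serialize as 0/255 uint8; label maps as uint16 (uint8 if K < 256);
    volumes keep their stored dtype.  ``read_volume(write_volume(g))``
    reproduces voxels and voxel size bit-exactly.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if isinstance(grid, Mask):
        data = np.where(grid.voxels, np.uint8(255), np.uint8(0))
    elif isinstance(grid, LabelMap):
        k = grid.n_labels
        if k > 65535:
            raise VolumeFormatError(f"too many labels for 16-bit storage: {k}")
        data = grid.voxels.astype(np.uint8 if k < 256 else np.uint16)
    else:
        data = grid.voxels
    try:
        tifffile.imwrite(path, data)
    except OSError as exc:
        raise OSError(f"cannot write volume to {path}: {exc}") from exc
    with open(_meta_path(path), "w") as fh:
        json.dump({"voxel_size_mm": float(grid.voxel_size_mm)}, fh)
    return path


def export_network(net, path: Union[str, Path]) -> Path:
    """Export a :class:`~pomoct.vasculature.VesselNetwork` as legacy ASCII VTK polydata.

    One VTK point per skeleton polyline vertex, one polyline per edge, and a
    per-point scalar ``radius_mm``.  An empty network writes a header-only
    file with a warning.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    points: list[np.ndarray] = []
    radii: list[float] = []
    lines: list[list[int]] = []
    for a, b, data in net.graph.edges(data=True):
        poly = np.asarray(data["polyline_mm"], dtype=float)
        r = np.asarray(data.get("radii_mm", np.zeros(len(poly))), dtype=float)
        idx0 = len(points)
        points.extend(poly)
        radii.extend(r.tolist())
        lines.append(list(range(idx0, idx0 + len(poly))))
    if not points:
        warnings.warn("exporting empty network: writing header-only VTK file")
        logger.warning("empty network exported to %s", path)
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\n")
        fh.write("pomoct vessel network\nASCII\nDATASET POLYDATA\n")
        fh.write(f"POINTS {len(points)} float\n")
        for p in points:
            # VTK is (x, y, z); our arrays are (z, y, x)
            fh.write(f"{p[2]:.6g} {p[1]:.6g} {p[0]:.6g}\n")
        nconn = sum(len(l) + 1 for l in lines)
        fh.write(f"LINES {len(lines)} {nconn}\n")
        for l in lines:
            fh.write(" ".join([str(len(l))] + [str(i) for i in l]) + "\n")
        fh.write(f"POINT_DATA {len(points)}\n")
        fh.write("SCALARS radius_mm float 1\nLOOKUP_TABLE default\n")
        for r in radii:
            fh.write(f"{r:.6g}\n")
    return path


def export_network_json(net, path: Union[str, Path]) -> Path:
    """Write a vessel network as JSON (nodes with position/radius, edges
    with length; polylines included for full round-trips)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    doc = {
        "nodes": [
            {"id": int(n), "pos_mm": [float(x) for x in np.asarray(d["pos_mm"])],
             "radius_mm": float(d.get("radius_mm", 0.0))}
            for n, d in net.graph.nodes(data=True)
        ],
        "edges": [
            {"a": int(a), "b": int(b), "length_mm": float(d["length_mm"]),
             "polyline_mm": np.asarray(d["polyline_mm"]).tolist(),
             "radii_mm": np.asarray(d["radii_mm"]).tolist()}
            for a, b, d in net.graph.edges(data=True)
        ],
        "total_length_m": net.total_length_m,
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)
    return path


def read_network_json(path: Union[str, Path]):
    """Load a vessel network written by :func:`export_network_json`."""
    import networkx as nx

    from pomoct.vasculature import VesselNetwork

    with open(path) as fh:
        doc = json.load(fh)
    g = nx.MultiGraph()
    for nd in doc["nodes"]:
        g.add_node(nd["id"], pos_mm=np.array(nd["pos_mm"]), radius_mm=nd["radius_mm"])
    for ed in doc["edges"]:
        g.add_edge(ed["a"], ed["b"], length_mm=ed["length_mm"],
                   polyline_mm=np.array(ed["polyline_mm"]),
                   radii_mm=np.array(ed["radii_mm"]))
    return VesselNetwork(g)


def read_network_vtk(path: Union[str, Path]) -> tuple[np.ndarray, list[list[int]], np.ndarray]:
    """Parse a legacy-VTK polyline file written by :func:`export_network`.

    Returns ``(points_zyx_mm, polylines, radii_mm)``; used for round-trip
    checks and for re-loading exported networks.
    """
    with open(path) as fh:
        body = fh.read().splitlines()
    points = np.zeros((0, 3))
    lines: list[list[int]] = []
    radii = np.zeros(0)
    i = 0
    while i < len(body):
        parts = body[i].split()
        if parts[:1] == ["POINTS"]:
            n = int(parts[1])
            flat = []
            i += 1
            while len(flat) < 3 * n:
                flat.extend(float(t) for t in body[i].split())
                i += 1
            xyz = np.array(flat).reshape(n, 3)
            points = xyz[:, ::-1]  # back to (z, y, x)
            continue
        if parts[:1] == ["LINES"]:
            n = int(parts[1])
            i += 1
            for _ in range(n):
                ints = [int(t) for t in body[i].split()]
                lines.append(ints[1 : 1 + ints[0]])
                i += 1
            continue
        if parts[:1] == ["SCALARS"]:
            i += 2  # skip LOOKUP_TABLE line
            vals = []
            while i < len(body) and body[i].strip():
                vals.extend(float(t) for t in body[i].split())
                i += 1
            radii = np.array(vals)
            continue
        i += 1
    return points, lines, radii
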