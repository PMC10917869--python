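"""Per-vertex searchlight mapping: hybrid volume scoring and surface graphs.

The hybrid algorithm avoids volume-to-surface interpolation artefacts by
scoring in voxel space: each cortical surface vertex is mapped (through
the inverse volume affine, nearest-voxel) to its containing voxel, the
3x3x3 neighbourhood of masked voxels around that voxel supplies the time
series, and the resulting VB index or ReHo value is written back to the
originating vertex. Vertices that fall outside the volume, or whose
neighbourhood retains fewer than ``min_neighbors`` masked voxels, get NaN
— never a silent zero.

The purely surface-based searchlight instead builds each vertex's graph
from the vertex and its one-ring mesh neighbours' series.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import (DegenerateGraphError, InputError, OutOfVolumeError,
                     SpatialMismatchError)
from .graph_core import TimeSeriesMatrix, build_affinity, vb_index
from .reho import kendalls_w

#: below this many masked voxels/vertices a neighbourhood graph carries no
#: usable spectral or concordance information
DEFAULT_MIN_NEIGHBORS = 3


@dataclass(frozen=True)
class SurfaceMesh:
    """Triangulated cortical surface with per-vertex cortical mask.

    coordinates are in scanner millimetres (the space the volume affine
    maps voxel indices into); vertex_mask marks vertices to evaluate.
    """

    coordinates: np.ndarray   # V x 3 mm
    triangles: np.ndarray     # T x 3 vertex indices
    vertex_mask: np.ndarray   # V booleans

    def __post_init__(self):
        coords = np.asarray(self.coordinates, dtype=float)
        tris = np.asarray(self.triangles, dtype=int)
        mask = np.asarray(self.vertex_mask, dtype=bool)
        if coords.ndim != 2 or coords.shape[1] != 3:
            raise InputError("coordinates must be V x 3")
        V = coords.shape[0]
        if tris.ndim != 2 or tris.shape[1] != 3:
            raise InputError("triangles must be T x 3")
        if tris.size and (tris.min() < 0 or tris.max() >= V):
            raise InputError("triangle indices out of range")
        if mask.shape != (V,):
            raise InputError("vertex mask length must match vertex count")
        referenced = np.zeros(V, dtype=bool)
        referenced[tris.ravel()] = True
        orphan = np.flatnonzero(mask & ~referenced)
        if orphan.size:
            raise InputError(
                f"{orphan.size} unmasked vertices belong to no triangle "
                f"(first: {int(orphan[0])})"
            )
        object.__setattr__(self, "coordinates", coords)
        object.__setattr__(self, "triangles", tris)
        object.__setattr__(self, "vertex_mask", mask)

    @property
    def n_vertices(self) -> int:
        return self.coordinates.shape[0]

    def one_ring(self) -> list:
        """Adjacency lists: vertices sharing a triangle edge with each vertex."""
        neighbors = [set() for _ in range(self.n_vertices)]
        for a, b, c in self.triangles:
            neighbors[a].update((b, c))
            neighbors[b].update((a, c))
            neighbors[c].update((a, b))
        return [sorted(s) for s in neighbors]


@dataclass(frozen=True)
class VolumeData:
    """4-D functional volume (X x Y x Z x k) with affine and binary mask."""

    values: np.ndarray
    affine: np.ndarray
    mask: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        aff = np.asarray(self.affine, dtype=float)
        mask = np.asarray(self.mask, dtype=bool)
        if v.ndim != 4:
            raise InputError(f"functional volume must be 4-D, got shape {v.shape}")
        if aff.shape != (4, 4):
            raise InputError("affine must be 4 x 4")
        if abs(np.linalg.det(aff)) < 1e-12:
            raise InputError("affine is not invertible")
        if mask.shape != v.shape[:3]:
            raise SpatialMismatchError(
                f"mask shape {mask.shape} does not match volume grid {v.shape[:3]}"
            )
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "affine", aff)
        object.__setattr__(self, "mask", mask)

    @property
    def grid_shape(self) -> tuple:
        return self.values.shape[:3]

    @property
    def k(self) -> int:
        return self.values.shape[3]


@dataclass(frozen=True)
class VertexResultMap:
    """One scalar (or NaN) per surface vertex; NaN marks unevaluable vertices."""

    values: np.ndarray
    metric: str
    normalization: str = "n/a"

    @property
    def n_evaluated(self) -> int:
        return int(np.isfinite(self.values).sum())

    @property
    def n_nan(self) -> int:
        return int(np.isnan(self.values).sum())


def _round_half_away(x: np.ndarray) -> np.ndarray:
    # numpy's round() is half-to-even; the voxel assignment rule is
    # half-away-from-zero so e.g. 2.5 mm at 1 mm spacing -> index 3
    return np.sign(x) * np.floor(np.abs(x) + 0.5)


def vertex_to_voxel(mesh: SurfaceMesh, vol: VolumeData, vertex: int) -> tuple:
    """Nearest voxel index of one surface vertex via the inverse affine.

    Raises OutOfVolumeError when the rounded index leaves the array; the
    returned voxel may still be outside the mask — the caller decides.
    """
    mm = np.append(mesh.coordinates[vertex], 1.0)
    ijk = _round_half_away((np.linalg.inv(vol.affine) @ mm)[:3]).astype(int)
    if (ijk < 0).any() or (ijk >= vol.grid_shape).any():
        raise OutOfVolumeError(
            f"vertex {vertex} maps to voxel {tuple(ijk)} outside grid {vol.grid_shape}"
        )
    return tuple(int(i) for i in ijk)


def voxel_neighborhood(vol: VolumeData, center: tuple) -> np.ndarray:
    """Masked voxels of the 3x3x3 block around ``center``, raster order.

    The block is clipped at the array boundary and intersected with the
    volume mask; the center itself is included only if masked. An empty
    result is valid and yields NaN downstream.
    """
    c = np.asarray(center, dtype=int)
    if (c < 0).any() or (c >= vol.grid_shape).any():
        raise InputError(f"center {tuple(c)} outside grid {vol.grid_shape}")
    lo = np.maximum(c - 1, 0)
    hi = np.minimum(c + 1, np.asarray(vol.grid_shape) - 1)
    ii, jj, kk = np.meshgrid(*(np.arange(l, h + 1) for l, h in zip(lo, hi)),
                             indexing="ij")
    idx = np.column_stack([ii.ravel(), jj.ravel(), kk.ravel()])
    keep = vol.mask[idx[:, 0], idx[:, 1], idx[:, 2]]
    return idx[keep]


def _score_neighborhood(series: np.ndarray, metric: str, normalization: str) -> float:
    ts = TimeSeriesMatrix(series)
    if metric == "vb":
        try:
            return vb_index(build_affinity(ts), normalization).value
        except DegenerateGraphError:
            # geig on a vertex whose every clamped correlation is zero
            return np.nan
    return kendalls_w(ts).W


def _score_vertices(vertices, mesh, vol, metric, normalization, min_neighbors):
    out = np.full(len(vertices), np.nan)
    for j, v in enumerate(vertices):
        try:
            center = vertex_to_voxel(mesh, vol, v)
        except OutOfVolumeError:
            continue
        hood = voxel_neighborhood(vol, center)
        if hood.shape[0] < min_neighbors:
            continue
        series = vol.values[hood[:, 0], hood[:, 1], hood[:, 2], :]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # flat voxels already yield weight 0
            out[j] = _score_neighborhood(series, metric, normalization)
    return out


def hybrid_map(vol: VolumeData, mesh: SurfaceMesh, metric: str = "vb",
               normalization: str = "unnorm",
               min_neighbors: int = DEFAULT_MIN_NEIGHBORS,
               jobs: int = 1) -> VertexResultMap:
    """Score every unmasked surface vertex from its 27-voxel neighbourhood.

    ``jobs`` > 1 chunks the vertex list across processes (joblib); the
    result is identical to the serial map because each vertex is scored
    independently and deterministically.
    """
    if metric not in ("vb", "reho"):
        raise InputError(f"unknown metric {metric!r}")
    if metric == "vb" and normalization not in ("unnorm", "geig"):
        raise InputError(f"unknown normalization {normalization!r}")
    if min_neighbors < 2:
        raise InputError("min_neighbors must be at least 2")
    norm = normalization if metric == "vb" else "n/a"
    values = np.full(mesh.n_vertices, np.nan)
    todo = np.flatnonzero(mesh.vertex_mask)
    if jobs == 1 or todo.size == 0:
        values[todo] = _score_vertices(todo, mesh, vol, metric, norm, min_neighbors)
    else:
        from joblib import Parallel, delayed

        chunks = np.array_split(todo, max(jobs, 1) * 4)
        chunks = [c for c in chunks if c.size]
        results = Parallel(n_jobs=jobs)(
            delayed(_score_vertices)(c, mesh, vol, metric, norm, min_neighbors)
            for c in chunks
        )
        for c, r in zip(chunks, results):
            values[c] = r
    return VertexResultMap(values=values, metric=metric, normalization=norm)


def surface_searchlight_map(surface_series: TimeSeriesMatrix, mesh: SurfaceMesh,
                            normalization: str = "unnorm",
                            min_neighbors: int = DEFAULT_MIN_NEIGHBORS) -> VertexResultMap:
    """VB map from per-vertex series and one-ring mesh neighbourhoods.

    ``surface_series`` must carry one row per mesh vertex (rows of masked
    vertices are ignored). Each unmasked vertex is scored on the graph of
    itself plus its unmasked one-ring neighbours; neighbourhoods smaller
    than ``min_neighbors`` yield NaN, isolated vertices additionally warn.
    """
    if surface_series.m != mesh.n_vertices:
        raise SpatialMismatchError(
            f"{surface_series.m} series for {mesh.n_vertices} mesh vertices"
        )
    rings = mesh.one_ring()
    values = np.full(mesh.n_vertices, np.nan)
    for v in np.flatnonzero(mesh.vertex_mask):
        members = [v] + [u for u in rings[v] if mesh.vertex_mask[u]]
        if len(members) == 1:
            warnings.warn(f"vertex {int(v)} is isolated; yielding NaN", stacklevel=2)
            continue
        if len(members) < min_neighbors:
            continue
        ts = TimeSeriesMatrix(surface_series.values[members],
                              series_ids=[surface_series.series_ids[i] for i in members])
        values[v] = vb_index(build_affinity(ts), normalization).value
    return VertexResultMap(values=values, metric="vb", normalization=normalization)
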