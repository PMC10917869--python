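"""Seeded generators for the three kinds of validation input.

1. Toy graphs whose vertices carry time series engineered so that
   non-adjacent vertices are exactly orthogonal (zero Pearson
   correlation) while adjacent ones correlate at a chosen floor — the
   cleanest way to compare VB against ReHo on known topologies.
2. Dense random affinity matrices with Uniform[0, 1] weights, the
   "hard to disconnect" regime used to stress the ratio-cut relaxation.
3. Synthetic task fMRI volumes: hard-edged spherical activations driven
   by a boxcar, on a six-component noise mixture (white/Rician, AR(3)
   temporal, low-frequency drift, cardiac+respiratory sinusoids, task-
   locked, and a spatially smooth Gaussian random field).

Every generator is a pure function of (spec, seed).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.ndimage import gaussian_filter

from .errors import GraphConstructionError, InputError
from .graph_core import AffinityMatrix, TimeSeriesMatrix
from .searchlight import SurfaceMesh, VolumeData

_FWHM_TO_SIGMA = 1.0 / np.sqrt(8.0 * np.log(2.0))

#: noise-component weights (fractions of noise standard deviation)
DEFAULT_NOISE_WEIGHTS = {
    "white": 0.05,
    "temporal": 0.10,
    "drift": 0.01,
    "physiological": 0.09,
    "task": 0.05,
    "spatial": 0.70,
}


@dataclass(frozen=True)
class Activation:
    """A hard-edged spherical task activation (voxel units)."""

    center: tuple
    radius: float
    amplitude: float = 1.0


@dataclass(frozen=True)
class SimulationSpec:
    """Parameters of the synthetic fMRI generator.

    The defaults encode the simulated validation regime: SNR 3, five
    hard-edged activation spheres, and the noise mixture weighted
    white 5% / temporal 10% / drift 1% / physiological 9% / task 5% /
    spatial 70%. Grid size, repetition time, series length, sphere
    geometry and the AR/physiological constants are desk-scale defaults
    chosen here (a 40^3 grid at 1 mm, k = 100 volumes at TR 2 s); they
    are not canonical to any acquisition.
    """

    grid_shape: tuple = (40, 40, 40)
    k: int = 100
    snr: float = 3.0
    activations: tuple = (
        Activation((10, 10, 20), 4.0),
        Activation((30, 10, 20), 4.0),
        Activation((10, 30, 20), 4.0),
        Activation((30, 30, 20), 4.0),
        Activation((20, 20, 20), 4.0),
    )
    noise_weights: dict = field(default_factory=lambda: dict(DEFAULT_NOISE_WEIGHTS))
    ar_coefficients: tuple = (0.2, 0.1, 0.05)
    drift_period_s: float = 128.0
    tr_s: float = 2.0
    cardiac_hz: float = 1.17
    respiratory_hz: float = 0.2
    spatial_fwhm: float = 4.0   # voxels
    baseline: float = 100.0
    block_length_s: float = 20.0
    seed: int = 0

    def __post_init__(self):
        w = dict(self.noise_weights)
        if set(w) != set(DEFAULT_NOISE_WEIGHTS):
            raise InputError(f"noise_weights must name exactly {sorted(DEFAULT_NOISE_WEIGHTS)}")
        vals = np.array([w[k] for k in sorted(w)])
        if (vals < 0).any():
            raise InputError("noise weights must be non-negative")
        if abs(vals.sum() - 1.0) > 1e-12:
            raise InputError(f"noise weights must sum to 1, got {vals.sum()!r}")
        shape = np.asarray(self.grid_shape, dtype=int)
        if shape.shape != (3,) or (shape < 1).any():
            raise InputError("grid_shape must be three positive integers")
        for a in self.activations:
            c = np.asarray(a.center, dtype=float)
            if ((c - a.radius) < 0).any() or ((c + a.radius) >= shape).any():
                raise InputError(f"activation sphere at {a.center} leaves the grid")
        object.__setattr__(self, "grid_shape", tuple(int(s) for s in shape))
        object.__setattr__(self, "activations", tuple(self.activations))
        object.__setattr__(self, "noise_weights", w)
        object.__setattr__(self, "ar_coefficients", tuple(self.ar_coefficients))

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "SimulationSpec":
        d = json.loads(text)
        d["activations"] = tuple(Activation(tuple(a["center"]), a["radius"],
                                            a.get("amplitude", 1.0))
                                 for a in d.get("activations", ()))
        d["grid_shape"] = tuple(d["grid_shape"])
        d["ar_coefficients"] = tuple(d["ar_coefficients"])
        return cls(**d)


def default_spec(seed: int = 0) -> SimulationSpec:
    """The default simulation regime (see SimulationSpec)."""
    return SimulationSpec(seed=seed)


def activation_mask(spec: SimulationSpec) -> np.ndarray:
    """Boolean grid marking voxels inside any activation sphere (hard edges)."""
    idx = np.indices(spec.grid_shape, dtype=float)
    mask = np.zeros(spec.grid_shape, dtype=bool)
    for a in spec.activations:
        d2 = sum((idx[i] - a.center[i]) ** 2 for i in range(3))
        mask |= d2 <= a.radius**2
    return mask


def _unit_sd(x: np.ndarray) -> np.ndarray:
    return x / x.std()


def _noise_components(spec: SimulationSpec, rng: np.random.Generator) -> dict:
    shape4 = (*spec.grid_shape, spec.k)
    t = np.arange(spec.k) * spec.tr_s
    comps = {}

    # white: Rician magnitude noise with zero non-centrality == Rayleigh;
    # left uncentred so its distributional shape survives the mixing
    ray = rng.rayleigh(scale=1.0, size=shape4)
    comps["white"] = ray / (np.sqrt((4.0 - np.pi) / 2.0))

    # temporal: AR(3) innovations filtered along time
    ar = np.asarray(spec.ar_coefficients, dtype=float)
    e = rng.standard_normal(shape4)
    x = np.zeros_like(e)
    for i in range(spec.k):
        x[..., i] = e[..., i]
        for lag, a in enumerate(ar, start=1):
            if i - lag >= 0:
                x[..., i] += a * x[..., i - lag]
    comps["temporal"] = _unit_sd(x)

    # low-frequency drift: one cosine at the drift period, random phase per voxel
    phase = rng.uniform(0.0, 2.0 * np.pi, spec.grid_shape)[..., None]
    comps["drift"] = _unit_sd(np.cos(2.0 * np.pi * t / spec.drift_period_s + phase))

    # physiological: cardiac + respiratory sinusoids, random phases per voxel
    ph_c = rng.uniform(0.0, 2.0 * np.pi, spec.grid_shape)[..., None]
    ph_r = rng.uniform(0.0, 2.0 * np.pi, spec.grid_shape)[..., None]
    physio = (np.sin(2.0 * np.pi * spec.cardiac_hz * t + ph_c)
              + np.sin(2.0 * np.pi * spec.respiratory_hz * t + ph_r))
    comps["physiological"] = _unit_sd(physio)

    # task: spontaneous activity confined to the activation sites
    act = activation_mask(spec)
    task = np.zeros(shape4)
    n_act = int(act.sum())
    if n_act:
        task[act] = rng.standard_normal((n_act, spec.k))
        task /= task[act].std()
    comps["task"] = task

    # spatial: Gaussian random field per volume (white noise smoothed with a
    # kernel of the stated FWHM, reflect boundaries)
    sigma = spec.spatial_fwhm * _FWHM_TO_SIGMA
    g = rng.standard_normal(shape4)
    for i in range(spec.k):
        g[..., i] = gaussian_filter(g[..., i], sigma=sigma, mode="reflect")
    comps["spatial"] = _unit_sd(g)

    return comps


def _boxcar(spec: SimulationSpec) -> np.ndarray:
    """Alternating off/on blocks of block_length_s, starting off."""
    t = np.arange(spec.k) * spec.tr_s
    return ((t // spec.block_length_s) % 2 == 1).astype(float)


def simulate_fmri(spec: SimulationSpec, return_parts: bool = False):
    """Synthetic 4-D task fMRI volume (baseline + boxcar signal + noise).

    Component weights scale component standard deviations (each component
    is normalised to unit SD before weighting). The task signal is a
    boxcar inside the activation spheres, scaled so that its temporal SD
    in a unit-amplitude sphere equals ``snr`` times the pooled noise SD.

    Returns VolumeData with a full (all-true) mask and an identity affine
    at 1 mm; with ``return_parts`` also returns (signal, noise) arrays.
    """
    if min(spec.grid_shape) < 3:
        raise InputError("grid too small to host 3x3x3 neighbourhoods")
    if spec.k < 10:
        raise InputError("need at least 10 time points")
    rng = np.random.default_rng(spec.seed)
    comps = _noise_components(spec, rng)
    noise = np.zeros((*spec.grid_shape, spec.k))
    for name, w in spec.noise_weights.items():
        if w > 0.0:
            noise += w * comps[name]

    box = _boxcar(spec)
    box_sd = box.std()
    if box_sd == 0.0:
        raise InputError("series too short for one full task block")
    noise_sd = float((noise - noise.mean(axis=-1, keepdims=True)).std())
    amp = spec.snr * noise_sd / box_sd

    signal = np.zeros_like(noise)
    idx = np.indices(spec.grid_shape, dtype=float)
    for a in spec.activations:
        d2 = sum((idx[i] - a.center[i]) ** 2 for i in range(3))
        inside = d2 <= a.radius**2
        signal[inside] += a.amplitude * amp * box

    data = spec.baseline + signal + noise
    vol = VolumeData(values=data, affine=np.eye(4),
                     mask=np.ones(spec.grid_shape, dtype=bool))
    if return_parts:
        return vol, signal, noise
    return vol


def flat_grid_mesh(spec_or_shape, z: int | None = None) -> SurfaceMesh:
    """A triangulated x-y plane of vertices at voxel centres, height ``z``.

    Stands in for a cortical sheet when exercising the hybrid searchlight
    on simulated volumes (the volume affine is identity, so voxel indices
    are millimetres). All vertices are unmasked.
    """
    shape = spec_or_shape.grid_shape if isinstance(spec_or_shape, SimulationSpec) \
        else tuple(spec_or_shape)
    nx, ny, nz = shape
    if z is None:
        z = nz // 2
    xs, ys = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    coords = np.column_stack([xs.ravel(), ys.ravel(),
                              np.full(nx * ny, float(z))]).astype(float)
    tris = []
    for i in range(nx - 1):
        for j in range(ny - 1):
            a = i * ny + j
            b = a + 1
            c = a + ny
            d = c + 1
            tris.append((a, b, c))
            tris.append((b, d, c))
    return SurfaceMesh(coordinates=coords, triangles=np.asarray(tris, dtype=int),
                       vertex_mask=np.ones(nx * ny, dtype=bool))


def orthogonal_graph_series(adjacency: np.ndarray, k: int, seed: int,
                            floor: float = 0.5) -> TimeSeriesMatrix:
    """Series whose pairwise correlations realise a given graph topology.

    Non-adjacent vertices get exactly orthogonal (zero-correlation)
    series; adjacent vertices correlate at ``floor``. The construction
    factorises the target Gram matrix I + floor * adjacency and expresses
    each vertex in a seeded orthonormal basis of the zero-mean subspace
    of R^k, so the realised Pearson correlations match the target to
    machine precision.
    """
    adj = np.asarray(adjacency, dtype=bool)
    n = adj.shape[0]
    if adj.ndim != 2 or adj.shape != (n, n):
        raise InputError("adjacency must be square")
    if not np.array_equal(adj, adj.T) or np.diagonal(adj).any():
        raise InputError("adjacency must be symmetric with a zero diagonal")
    if n > k - 1:
        raise InputError(f"need k >= n + 1 time points to embed {n} vertices, got k = {k}")
    if not 0.0 < floor < 1.0:
        raise InputError("correlation floor must be in (0, 1)")

    gram = np.eye(n) + floor * adj
    vals, vecs = np.linalg.eigh(gram)
    if vals.min() < -1e-10:
        offending = np.argsort(-np.abs(vecs[:, 0]))[:2]
        i, j = sorted(int(v) for v in offending)
        raise GraphConstructionError(
            f"orthogonality demands are unsatisfiable at floor {floor} "
            f"(Gram matrix has eigenvalue {vals.min():.3g} < 0; most "
            f"conflicted vertex pair: {i} and {j})"
        )
    coeffs = vecs @ np.diag(np.sqrt(np.clip(vals, 0.0, None)))

    rng = np.random.default_rng(seed)
    basis = rng.standard_normal((k, n))
    basis -= basis.mean(axis=0)  # zero-mean columns stay zero-mean under QR
    q, _ = np.linalg.qr(basis)
    series = coeffs @ q.T
    return TimeSeriesMatrix(series)


def toy_adjacency(kind: str, n: int = 6) -> np.ndarray:
    """Three ways of joining n=6 vertices: sparse (path), complete, disconnected."""
    if n != 6:
        raise InputError("the toy patterns are defined for 6 vertices")
    adj = np.zeros((n, n), dtype=bool)
    if kind == "sparse":
        for i in range(n - 1):
            adj[i, i + 1] = adj[i + 1, i] = True
    elif kind == "complete":
        adj[:] = True
        np.fill_diagonal(adj, False)
    elif kind == "disconnected":
        for a, b in [(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5)]:
            adj[a, b] = adj[b, a] = True
    else:
        raise InputError(f"unknown toy pattern {kind!r}")
    return adj


def uniform_affinity(n: int, seed: int) -> AffinityMatrix:
    """Dense affinity with i.i.d. Uniform[0, 1] upper-triangle weights."""
    if n < 2:
        raise InputError("need at least 2 vertices")
    rng = np.random.default_rng(seed)
    u = np.triu(rng.uniform(0.0, 1.0, (n, n)), k=1)
    return AffinityMatrix(weights=u + u.T)


def banded_affinity(n: int, seed: int, bandwidth: int = 1) -> AffinityMatrix:
    """Sparse comparator: Uniform[0, 1] weights only within a diagonal band."""
    if n < 2:
        raise InputError("need at least 2 vertices")
    rng = np.random.default_rng(seed)
    u = np.triu(rng.uniform(0.0, 1.0, (n, n)), k=1)
    i, j = np.indices((n, n))
    u[np.abs(i - j) > bandwidth] = 0.0
    return AffinityMatrix(weights=u + u.T)
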