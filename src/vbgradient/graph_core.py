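"""Core spectral-graph machinery behind the Vogt-Bailey (VB) index.

A searchlight neighbourhood of fMRI time series is turned into a small
weighted graph: each series is a vertex, and the edge weight between two
vertices is an angular rescaling of their Pearson correlation so that
identical signals score 1, uncorrelated signals score 0, and the mapping
from angle to weight is linear (a correlation of cos 45° scores 0.5).

The algebraic connectivity of the resulting graph Laplacian — its second
smallest eigenvalue, lambda_2 — measures how hard the neighbourhood is to
disconnect. The VB index is lambda_2 scaled into [0, 1] by the graph
order n (a complete unit-weight graph has lambda_2 = n, so it scores 1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import linalg

from .errors import DegenerateGraphError, InputError

#: eigenvalues with magnitude below this are treated as zero when deciding
#: connectivity; double-precision eigensolver noise on <=27x27 matrices
#: stays well under this.
ZERO_TOL = 1e-8


def _as_labels(ids, n: int, prefix: str) -> tuple:
    if ids is None:
        return tuple(f"{prefix}{i}" for i in range(n))
    ids = tuple(str(x) for x in ids)
    if len(ids) != n:
        raise InputError(f"expected {n} labels, got {len(ids)}")
    if len(set(ids)) != n:
        raise InputError("labels must be unique")
    return ids


@dataclass(frozen=True)
class TimeSeriesMatrix:
    """m signals observed at k common time points.

    Rows are series (voxels/vertices), columns are time points. Missing
    values are rejected at construction: a searchlight neighbourhood with
    unusable voxels should simply not include them.
    """

    values: np.ndarray
    series_ids: tuple = None

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2:
            raise InputError("time series matrix must be 2-D (m series x k time points)")
        m, k = v.shape
        if m < 2 or k < 2:
            raise InputError(f"need at least 2 series and 2 time points, got {m}x{k}")
        if not np.isfinite(v).all():
            raise InputError("time series contain missing or non-finite values")
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "series_ids", _as_labels(self.series_ids, m, "s"))

    @property
    def m(self) -> int:
        return self.values.shape[0]

    @property
    def k(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class AffinityMatrix:
    """Symmetric n x n matrix of edge weights in [0, 1] with zero diagonal.

    Absent edges are represented by zero weights, i.e. every graph is
    treated as a complete graph some of whose edges weigh nothing.
    """

    weights: np.ndarray
    vertex_ids: tuple = None

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise InputError("affinity matrix must be square")
        n = w.shape[0]
        if n < 2:
            raise InputError("affinity matrix needs at least 2 vertices")
        if not np.array_equal(w, w.T):
            raise InputError("affinity matrix must be exactly symmetric")
        if np.diagonal(w).any():
            raise InputError("affinity matrix must have a zero diagonal")
        if not np.isfinite(w).all() or w.min() < 0.0 or w.max() > 1.0:
            raise InputError("affinity weights must lie in [0, 1]")
        object.__setattr__(self, "weights", w)
        object.__setattr__(self, "vertex_ids", _as_labels(self.vertex_ids, n, "v"))

    @property
    def n(self) -> int:
        return self.weights.shape[0]

    # -- plain-text round trip -------------------------------------------------

    def to_tsv(self, path) -> None:
        """Write vertex labels (header row) and the n x n weight matrix as TSV."""
        import pandas as pd

        pd.DataFrame(self.weights, columns=list(self.vertex_ids)).to_csv(
            path, sep="\t", index=False, float_format="%.17g"
        )

    @classmethod
    def from_tsv(cls, path) -> "AffinityMatrix":
        import pandas as pd

        df = pd.read_csv(path, sep="\t", float_precision="round_trip")
        w = df.to_numpy(dtype=float)
        w = 0.5 * (w + w.T)  # undo asymmetric decimal-text rounding
        return cls(weights=w, vertex_ids=tuple(df.columns))

    def to_npy(self, path) -> None:
        np.save(path, self.weights)

    @classmethod
    def from_npy(cls, path, vertex_ids=None) -> "AffinityMatrix":
        return cls(weights=np.load(path), vertex_ids=vertex_ids)


@dataclass(frozen=True)
class LaplacianPair:
    """Graph Laplacian L = D - A together with the vertex degrees diag(D)."""

    laplacian: np.ndarray
    degrees: np.ndarray

    def __post_init__(self):
        L = np.asarray(self.laplacian, dtype=float)
        d = np.asarray(self.degrees, dtype=float)
        if L.ndim != 2 or L.shape[0] != L.shape[1] or d.shape != (L.shape[0],):
            raise InputError("Laplacian/degree shapes inconsistent")
        if not np.allclose(L, L.T, atol=1e-12):
            raise InputError("Laplacian must be symmetric")
        if np.abs(L.sum(axis=1)).max() > 1e-10:
            raise InputError("Laplacian rows must sum to zero")
        if d.min() < -1e-12:
            raise InputError("degrees must be non-negative")
        object.__setattr__(self, "laplacian", L)
        object.__setattr__(self, "degrees", d)

    @property
    def n(self) -> int:
        return self.laplacian.shape[0]


@dataclass(frozen=True)
class SpectralResult:
    """Eigenvalues (ascending) and eigenvectors of a Laplacian.

    mode "standard" solves L u = lambda u; mode "geig" solves the
    generalised problem L u = lambda D u, equivalently the standard
    problem for the random-walk normalised Laplacian D^-1 L.

    When lambda_2 is degenerate (multiplicity > 1) the returned Fiedler
    vector is an arbitrary unit vector in the eigenspace; lambda_2 itself
    is still well defined and is all the VB index uses.
    """

    eigenvalues: np.ndarray
    eigenvectors: np.ndarray  # column i pairs with eigenvalues[i]
    mode: str

    @property
    def lambda2(self) -> float:
        return float(self.eigenvalues[1])

    @property
    def fiedler_vector(self) -> np.ndarray:
        return self.eigenvectors[:, 1]


@dataclass(frozen=True)
class VBIndexValue:
    """The VB index of one neighbourhood graph: lambda_2 rescaled into [0, 1]."""

    value: float
    lambda2: float
    n: int
    normalization: str


def build_affinity(ts: TimeSeriesMatrix) -> AffinityMatrix:
    """Edge weights from the arccos-linearised Pearson correlation.

    w_ij = 1 - arccos(corr(s_i, s_j)) * (180/pi) / 90, i.e. the angle
    between the mean-centred series mapped linearly from [0°, 90°] onto
    [1, 0]. Negative correlations (angles beyond 90°) would give negative
    weights; they are clamped to 0 so weights stay in [0, 1].

    A zero-variance series has no defined correlation; all its weights are
    set to 0 and a warning is emitted so flat (e.g. masked) voxels degrade
    gracefully instead of aborting a whole map.
    """
    v = ts.values
    sd = v.std(axis=1)
    flat = sd == 0.0
    if flat.any():
        warnings.warn(
            f"{int(flat.sum())} zero-variance series treated as uncorrelated "
            f"(weights 0): {[ts.series_ids[i] for i in np.flatnonzero(flat)][:5]}",
            stacklevel=2,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(v)
    corr = np.clip(corr, -1.0, 1.0)  # guard arccos against fp overshoot
    corr[flat, :] = 0.0
    corr[:, flat] = 0.0
    w = 1.0 - np.arccos(corr) * (2.0 / np.pi)
    w = np.clip(w, 0.0, 1.0)
    w = 0.5 * (w + w.T)
    np.fill_diagonal(w, 0.0)
    return AffinityMatrix(weights=w, vertex_ids=ts.series_ids)


def graph_laplacian(A: AffinityMatrix) -> LaplacianPair:
    """L = D - A with D the diagonal matrix of vertex degrees (row sums of A)."""
    degrees = A.weights.sum(axis=1)
    L = np.diag(degrees) - A.weights
    return LaplacianPair(laplacian=L, degrees=degrees)


def spectrum(pair: LaplacianPair, mode: str = "standard") -> SpectralResult:
    """Full symmetric eigendecomposition of L (standard) or (L, D) (geig).

    A full decomposition (not an iterative solver) is used throughout:
    searchlight graphs have at most 27 vertices, where completeness and
    determinism matter more than asymptotic speed. Tiny negative
    eigenvalues from round-off are snapped to 0.
    """
    if mode not in ("standard", "geig"):
        raise InputError(f"unknown spectrum mode {mode!r}")
    L = pair.laplacian
    if mode == "standard":
        vals, vecs = linalg.eigh(L)
    else:
        zero = np.flatnonzero(pair.degrees <= 0.0)
        if zero.size:
            raise DegenerateGraphError(
                f"geig mode requires strictly positive degrees; "
                f"vertex {int(zero[0])} has degree 0"
            )
        vals, vecs = linalg.eigh(L, np.diag(pair.degrees))
    vals = np.where(np.abs(vals) < ZERO_TOL, 0.0, vals)
    vals = np.maximum(vals, 0.0)
    order = np.argsort(vals, kind="stable")
    return SpectralResult(eigenvalues=vals[order], eigenvectors=vecs[:, order], mode=mode)


def rayleigh_quotient(pair: LaplacianPair, x: np.ndarray) -> float:
    """x^T L x / x^T x for a non-zero vector x.

    The quadratic form is computed both directly and as the weighted sum
    of squared coordinate differences over edges, (1/2) sum_ij w_ij
    (x_i - x_j)^2; the two must agree, which guards the Laplacian
    construction at every call site.
    """
    x = np.asarray(x, dtype=float)
    if x.shape != (pair.n,):
        raise InputError(f"vector length {x.shape} does not match graph order {pair.n}")
    xtx = float(x @ x)
    if xtx == 0.0:
        raise InputError("Rayleigh quotient undefined for the zero vector")
    quad = float(x @ pair.laplacian @ x)
    # reconstruct the affinity from L to evaluate the edge-sum identity
    w = np.diag(pair.degrees) - pair.laplacian
    diff = x[:, None] - x[None, :]
    edge_sum = 0.5 * float((w * diff**2).sum())
    scale = max(abs(quad), abs(edge_sum), 1.0)
    if abs(quad - edge_sum) > 1e-8 * scale:
        raise AssertionError(
            f"quadratic-form identity violated: {quad} vs {edge_sum}"
        )
    return quad / xtx


def vb_index(A: AffinityMatrix, normalization: str = "unnorm") -> VBIndexValue:
    """The VB index of the graph encoded by ``A``.

    unnorm: lambda_2 of L, divided by the graph order n (a complete
    unit-weight graph attains lambda_2 = n and scores exactly 1).

    geig: lambda_2 of the generalised problem L x = lambda D x, divided
    by n/(n-1) — the value that same complete graph attains there (the
    mean of its non-smallest eigenvalues) — so both modes share the
    calibration point VB = 1.
    """
    if normalization not in ("unnorm", "geig"):
        raise InputError(f"unknown normalization {normalization!r}")
    pair = graph_laplacian(A)
    n = A.n
    if normalization == "unnorm":
        lam2 = spectrum(pair, "standard").lambda2
        value = lam2 / n
    else:
        lam2 = spectrum(pair, "geig").lambda2
        value = lam2 / (n / (n - 1))
    if value > 1.0:
        if value > 1.0 + ZERO_TOL:
            raise AssertionError(f"VB index {value} exceeds 1 beyond tolerance")
        value = 1.0
    return VBIndexValue(value=float(value), lambda2=float(lam2), n=n,
                        normalization=normalization)
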