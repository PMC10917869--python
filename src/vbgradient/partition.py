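"""Exhaustive minimum-ratio-cut oracle.

The VB index is the spectral relaxation of a combinatorial quantity: the
ratio cut, i.e. the cut-set weight of a 2-cluster split scaled by
(1/n_B + 1/n_C) to penalise unbalanced clusters. The minimum ratio cut
over all bipartitions is bounded below by the algebraic connectivity
lambda_2, and in practice tracks it closely; the cut-set weight of the
minimising split (the "VB cut") divided by n_B0 * n_C0 approximates the
VB index itself.

This module enumerates every bipartition exactly. It exists to be an
oracle on small graphs, so correctness and determinism trump speed:
bipartitions are encoded as (n-1)-bit integers with vertex 0 pinned to
cluster B, ties broken by the first partition encountered in that
canonical order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import InputError
from .graph_core import AffinityMatrix

#: hard cap on graph order for exhaustive search (2^26 bipartitions at n=27,
#: the neighbourhood size of the hybrid searchlight)
MAX_EXHAUSTIVE_N = 27
#: above this order the search is still exact but takes minutes, so it must
#: be requested explicitly
WARN_N = 20


@dataclass(frozen=True)
class Bipartition:
    """A split of the vertex set {0..n-1} into disjoint non-empty B and C."""

    members_B: frozenset
    members_C: frozenset

    def __post_init__(self):
        B = frozenset(int(i) for i in self.members_B)
        C = frozenset(int(i) for i in self.members_C)
        if not B or not C:
            raise InputError("both clusters must be non-empty")
        if B & C:
            raise InputError(f"clusters overlap: {sorted(B & C)}")
        n = len(B) + len(C)
        if B | C != set(range(n)):
            raise InputError("clusters must partition {0..n-1} with no stray indices")
        object.__setattr__(self, "members_B", B)
        object.__setattr__(self, "members_C", C)

    @property
    def n_B(self) -> int:
        return len(self.members_B)

    @property
    def n_C(self) -> int:
        return len(self.members_C)

    @property
    def n(self) -> int:
        return self.n_B + self.n_C

    def swapped(self) -> "Bipartition":
        return Bipartition(self.members_C, self.members_B)


@dataclass(frozen=True)
class RatioCutResult:
    ratio_cut: float
    cut_set_weight: float
    partition: Bipartition
    n_evaluated: int


def indicator_vector(p: Bipartition) -> np.ndarray:
    """The balanced cluster indicator: 1/n_B on B, -1/n_C on C.

    Analytically x . 1 = 1 - 1 = 0 and x^T x = 1/n_B + 1/n_C; plugging
    this vector into the Laplacian quadratic form recovers the ratio cut,
    which is what links the combinatorial cut to the spectral relaxation.
    """
    x = np.empty(p.n, dtype=float)
    x[sorted(p.members_B)] = 1.0 / p.n_B
    x[sorted(p.members_C)] = -1.0 / p.n_C
    return x


def ratio_cut(A: AffinityMatrix, p: Bipartition) -> RatioCutResult:
    """Cut-set weight and ratio cut of one bipartition of A's graph.

    Absent edges carry weight 0, so the sum runs over the full cross
    block of the affinity matrix.
    """
    if p.n != A.n:
        raise InputError(f"partition covers {p.n} vertices but graph has {A.n}")
    B = sorted(p.members_B)
    C = sorted(p.members_C)
    w = float(A.weights[np.ix_(B, C)].sum())
    rc = (1.0 / p.n_B + 1.0 / p.n_C) * w
    return RatioCutResult(ratio_cut=rc, cut_set_weight=w, partition=p, n_evaluated=1)


def _bitmask_partition(mask: int, n: int) -> Bipartition:
    """Decode an (n-1)-bit integer: bit i set puts vertex i+1 in C; vertex 0 in B."""
    C = frozenset(i + 1 for i in range(n - 1) if (mask >> i) & 1)
    B = frozenset(range(n)) - C
    return Bipartition(B, C)


def min_ratio_cut_exhaustive(A: AffinityMatrix, allow_large: bool = False) -> RatioCutResult:
    """Scan all 2^(n-1) - 1 bipartitions and return the minimum ratio cut.

    Vertex 0 is pinned to cluster B, which halves the search space without
    losing any split (B and C are interchangeable). Ties are broken by the
    first partition encountered in ascending bitmask order, making the
    returned partition reproducible.
    """
    n = A.n
    if n < 2 or n > MAX_EXHAUSTIVE_N:
        raise InputError(f"exhaustive search supports 2 <= n <= {MAX_EXHAUSTIVE_N}, got {n}")
    if n > WARN_N and not allow_large:
        raise InputError(
            f"n = {n} means {2 ** (n - 1) - 1} bipartitions; pass allow_large=True "
            f"to spend the minutes this costs"
        )
    if n > WARN_N:
        warnings.warn(f"exhaustive ratio-cut search over {2 ** (n - 1) - 1} "
                      f"bipartitions (n = {n}); this is slow", stacklevel=2)
    W = A.weights
    row_tot = W.sum(axis=1)
    best_rc = np.inf
    best_w = np.nan
    best_mask = -1
    n_eval = 0
    # incremental cross-weight bookkeeping is possible but the plain loop is
    # already milliseconds for the n <= 10 validation sizes
    members = np.arange(1, n)
    for mask in range(1, 2 ** (n - 1)):
        in_C = (mask >> (members - 1)) & 1 == 1
        C_idx = members[in_C]
        n_C = C_idx.size
        n_B = n - n_C
        # cut weight = total degree of C minus twice the internal C weight
        w_cut = row_tot[C_idx].sum() - W[np.ix_(C_idx, C_idx)].sum()
        rc = (1.0 / n_B + 1.0 / n_C) * w_cut
        n_eval += 1
        if rc < best_rc - 1e-15:
            best_rc, best_w, best_mask = rc, w_cut, mask
    p = _bitmask_partition(best_mask, n)
    return RatioCutResult(ratio_cut=float(best_rc), cut_set_weight=float(best_w),
                          partition=p, n_evaluated=n_eval)


def vb_cut_decomposition(A: AffinityMatrix, allow_large: bool = False) -> tuple[float, float]:
    """(VB cut, combinatorial VB index) of the minimising bipartition.

    The VB cut is the cut-set weight of the split that minimises the ratio
    cut; dividing it by n_B0 * n_C0 — the number of (possibly zero-weight)
    edges removed — gives the cut-based reading of the VB index, which the
    spectral value approximates.
    """
    res = min_ratio_cut_exhaustive(A, allow_large=allow_large)
    p = res.partition
    vb_cut = res.cut_set_weight
    return float(vb_cut), float(vb_cut / (p.n_B * p.n_C))
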