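"""Regional Homogeneity (ReHo): Kendall's coefficient of concordance.

ReHo scores a neighbourhood of m time series of length k by how well
their within-series rank orderings agree:

    W = 12 R / (m^2 (k^3 - k)),   R = sum_i (R_i - Rbar)^2,

where R_i is the sum over series of the rank of time point i and Rbar the
mean sum rank. W = 1 means every series ranks the time points
identically; W near 0 means the orderings are unrelated. Unlike the VB
index, W depends only on rankings, not on the signal values.

No tie-correction term is applied — the formula above is used exactly.
Continuous fMRI-like data make ties measure-zero; when they do occur,
tied values receive average (mid) ranks, which can only lower W. This is
a deliberate divergence from tie-corrected W variants.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

from .errors import InputError
from .graph_core import TimeSeriesMatrix


@dataclass(frozen=True)
class ReHoValue:
    W: float
    m: int
    k: int
    sum_ranks: np.ndarray      # R_i, one per time point
    mean_sum_rank: float       # Rbar
    R: float                   # sum of squared deviations of R_i


def kendalls_w(ts: TimeSeriesMatrix) -> ReHoValue:
    """Kendall's W over the rows of ``ts`` (series ranked along time)."""
    m, k = ts.m, ts.k
    if k < 3:
        raise InputError(f"Kendall's W needs k >= 3 time points, got {k}")
    flat = ts.values.std(axis=1) == 0.0
    if flat.any():
        warnings.warn(
            f"{int(flat.sum())} constant series enter ReHo as all-tied midranks",
            stacklevel=2,
        )
    ranks = rankdata(ts.values, axis=1, method="average")
    R_i = ranks.sum(axis=0)
    R_bar = float(R_i.mean())
    # with complete (mid)ranks each row sums to k(k+1)/2, so Rbar = m(k+1)/2
    expected_bar = m * (k + 1) / 2.0
    if abs(R_bar - expected_bar) > 1e-8 * expected_bar:
        raise AssertionError(f"mean sum rank {R_bar} != m(k+1)/2 = {expected_bar}")
    R = float(((R_i - R_bar) ** 2).sum())
    W = 12.0 * R / (m**2 * (k**3 - k))
    if not 0.0 <= W <= 1.0 + 1e-12:
        raise AssertionError(f"W = {W} outside [0, 1]")
    return ReHoValue(W=float(min(W, 1.0)), m=m, k=k, sum_ranks=R_i,
                     mean_sum_rank=R_bar, R=R)
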