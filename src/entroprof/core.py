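"""Classical Kolmogorov–Sinai entropy estimators for univariate time series.

This module implements the template-matching family of irregularity
statistics used in heart-rate-variability (HRV) analysis:

* approximate entropy (ApEn) — self-matches included, so it is always
  finite but biased toward regularity;
* sample entropy (SampEn) — self-matches excluded; may be *undefined*
  (no matches at dimension ``m + 1``), which is reported as ``nan``
  rather than raised;
* fuzzy entropy (FuzzyEn) — the hard tolerance threshold is replaced by
  an exponential similarity degree ``exp(-(d/r)^2)``, so it is always
  finite;
* the traditional tolerance grid search for ``rmax`` / ``MaxApEn``.

Conventions fixed once, package-wide
------------------------------------
* Standard deviation is the *population* SD (``ddof=0``); every place a
  tolerance is written ``r = k * SD`` uses it.
* A template pair "matches" when their Chebyshev distance satisfies
  ``d <= r`` (inclusive), so the profile module's cumulative-histogram
  construction agrees with these estimators exactly.
* ApEn embeds ``N - m + 1`` vectors at dimension ``m`` and ``N - m`` at
  ``m + 1`` and keeps self-matches; SampEn/FuzzyEn embed ``N - m``
  vectors at *both* dimensions and drop self-matches.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence, Union

import numpy as np

__all__ = [
    "UNDEFINED",
    "TimeSeries",
    "EntropyParams",
    "DistanceMatrices",
    "MaxApEnResult",
    "as_series",
    "is_defined",
    "embed_vectors",
    "chebyshev_distances",
    "apen",
    "sampen",
    "fuzzyen",
    "max_apen_search",
]

#: Sentinel for an indefinite SampEn value (no matches at dimension m+1).
#: It is a value, never an exception, so profile code can mask it.
UNDEFINED: float = float("nan")

Units = Literal["seconds", "milliseconds", "arbitrary"]
Convention = Literal["apen", "sampen"]


def is_defined(value: float) -> bool:
    """True if an entropy value is defined (finite), False for UNDEFINED."""
    return bool(np.isfinite(value))


@dataclass(frozen=True)
class TimeSeries:
    """An ordered, finite, real-valued signal (RR intervals or synthetic).

    Parameters
    ----------
    values : array-like of float
        The samples, in temporal order. Length >= 1, all finite.
    units : {"seconds", "milliseconds", "arbitrary"}
        Physical unit of the samples.
    label : str
        Free-text identifier (subject id, generator name, ...).
    """

    values: np.ndarray
    units: Units = "arbitrary"
    label: str = ""

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=float)
        if arr.ndim != 1:
            raise ValueError(f"time series must be 1-D, got shape {arr.shape}")
        if arr.size < 1:
            raise ValueError("time series must contain at least one sample")
        if not np.all(np.isfinite(arr)):
            raise ValueError("time series contains non-finite samples")
        arr.setflags(write=False)
        object.__setattr__(self, "values", arr)
        # population SD, cached once; the convention behind every r = k*SD
        object.__setattr__(self, "_sd", float(np.std(arr)))

    def __len__(self) -> int:
        return int(self.values.size)

    @property
    def n(self) -> int:
        return int(self.values.size)

    @property
    def sd(self) -> float:
        """Population standard deviation (ddof=0) of the samples."""
        return self._sd  # type: ignore[attr-defined]


SeriesLike = Union[TimeSeries, Sequence[float], np.ndarray]


def as_series(x: SeriesLike, units: Units = "arbitrary", label: str = "") -> TimeSeries:
    """Coerce an array-like to a :class:`TimeSeries` (no copy if already one)."""
    if isinstance(x, TimeSeries):
        return x
    return TimeSeries(np.asarray(x, dtype=float), units=units, label=label)


@dataclass(frozen=True)
class EntropyParams:
    """Embedding dimension plus tolerance, given absolutely or as ``k * SD``.

    Exactly one of ``r`` (absolute) and ``k`` (SD multiple) is given; the
    other is derived when the params are resolved against a series.
    """

    m: int = 2
    r: float | None = None
    k: float | None = None

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValueError(f"embedding dimension m must be >= 1, got {self.m}")
        if (self.r is None) == (self.k is None):
            raise ValueError("exactly one of {r, k} must be given")
        if self.r is not None and self.r < 0:
            raise ValueError(f"tolerance r must be non-negative, got {self.r}")
        if self.k is not None and self.k < 0:
            raise ValueError(f"tolerance coefficient k must be non-negative, got {self.k}")

    def resolve_r(self, x: SeriesLike) -> float:
        """Absolute tolerance for a given series (``r`` or ``k * SD``)."""
        if self.r is not None:
            return float(self.r)
        return float(self.k) * as_series(x).sd


@dataclass(frozen=True)
class DistanceMatrices:
    """Per-template Chebyshev distance sets at dimensions m and m+1.

    ``d_m[i]`` holds template i's distances to every other template at
    dimension m (row length ``n_templates - 1`` when self-matches are
    excluded, the SampEn/CHM convention).
    """

    d_m: np.ndarray
    d_m1: np.ndarray
    n_templates: int
    self_matches_included: bool = False


@dataclass(frozen=True)
class MaxApEnResult:
    """Outcome of a tolerance grid search: the full ApEn-vs-r curve plus
    its maximum and the tolerance attaining it (smallest grid value on ties)."""

    r_grid: np.ndarray
    apen_curve: np.ndarray
    rmax: float
    max_apen: float


# ---------------------------------------------------------------------------
# embedding and distances
# ---------------------------------------------------------------------------

def _require_length(x: TimeSeries, m: int) -> None:
    if m < 1:
        raise ValueError(f"embedding dimension m must be >= 1, got {m}")
    if x.n <= m + 1:
        raise ValueError(
            f"series of length {x.n} too short for m={m}; need N >= {m + 2}"
        )


def embed_vectors(
    x: SeriesLike, m: int, convention: Convention = "sampen"
) -> tuple[np.ndarray, np.ndarray]:
    """Build overlapping template vectors at dimensions m and m+1.

    The ``sampen`` convention forms ``N - m`` vectors at *both*
    dimensions (same template count, as the CHM profile requires); the
    ``apen`` convention forms ``N - m + 1`` vectors at dimension m and
    ``N - m`` at m+1.

    Returns
    -------
    (X_m, X_m1) : pair of 2-D arrays
        Rows are templates ``X_i = (x(i), ..., x(i + len - 1))``.
    """
    ts = as_series(x)
    _require_length(ts, m)
    v = ts.values
    windows_m = np.lib.stride_tricks.sliding_window_view(v, m)
    windows_m1 = np.lib.stride_tricks.sliding_window_view(v, m + 1)
    if convention == "sampen":
        return windows_m[: ts.n - m].copy(), windows_m1.copy()
    if convention == "apen":
        return windows_m.copy(), windows_m1.copy()
    raise ValueError(f"unknown embedding convention: {convention!r}")


def chebyshev_distances(vectors: np.ndarray, exclude_self: bool = False) -> np.ndarray:
    """All pairwise Chebyshev (max-norm) distances between template vectors.

    Returns an ``(n, n)`` symmetric matrix, or ``(n, n - 1)`` with the
    ``j = i`` entries dropped from each row when ``exclude_self`` is set.
    """
    vecs = np.asarray(vectors, dtype=float)
    if vecs.ndim != 2 or vecs.shape[0] < 1:
        raise ValueError("need a non-empty 2-D set of template vectors")
    n = vecs.shape[0]
    d = np.abs(vecs[:, None, :] - vecs[None, :, :]).max(axis=2)
    if not exclude_self:
        return d
    return _drop_diagonal(d)


def _drop_diagonal(d: np.ndarray) -> np.ndarray:
    n = d.shape[0]
    if n == 1:
        return np.empty((1, 0))
    mask = ~np.eye(n, dtype=bool)
    return d[mask].reshape(n, n - 1)


def _abs_diff_matrix(v: np.ndarray) -> np.ndarray:
    return np.abs(v[:, None] - v[None, :])


def _window_max(diff: np.ndarray, m: int, n: int) -> np.ndarray:
    """Chebyshev distances between length-m windows, from the sample-wise
    |x_i - x_j| matrix: d_ij = max_{0<=k<m} |x(i+k) - x(j+k)|."""
    d = diff[:n, :n].copy()
    for k in range(1, m):
        np.maximum(d, diff[k : k + n, k : k + n], out=d)
    return d


def _distance_squares(x: TimeSeries, m: int, convention: Convention) -> tuple[np.ndarray, np.ndarray]:
    """Full square distance matrices at dimensions m and m+1 (diagonal kept)."""
    diff = _abs_diff_matrix(x.values)
    n_m1 = x.n - m
    n_m = n_m1 + 1 if convention == "apen" else n_m1
    return _window_max(diff, m, n_m), _window_max(diff, m + 1, n_m1)


def build_distance_matrices(x: SeriesLike, m: int) -> DistanceMatrices:
    """Self-match-free distance sets at m and m+1 (SampEn/CHM convention):
    ``N - m`` templates at both dimensions, rows of ``N - m - 1`` distances."""
    ts = as_series(x)
    _require_length(ts, m)
    d_m, d_m1 = _distance_squares(ts, m, "sampen")
    return DistanceMatrices(
        d_m=_drop_diagonal(d_m),
        d_m1=_drop_diagonal(d_m1),
        n_templates=ts.n - m,
        self_matches_included=False,
    )


# ---------------------------------------------------------------------------
# estimators
# ---------------------------------------------------------------------------

def apen(x: SeriesLike, m: int = 2, r: float | None = None, k: float | None = None) -> float:
    """Approximate entropy with self-matches included.

    ``C_i^m = B_i / (N - m + 1)`` where ``B_i`` counts templates within
    ``d <= r`` of template i *including itself* (so every ``C_i > 0``
    and the log-mean ``Phi`` is always defined); the result is
    ``Phi^m - Phi^{m+1}``.

    Tolerance is ``r`` (absolute) or ``k * SD``; it must be positive.
    """
    ts = as_series(x)
    _require_length(ts, m)
    r_abs = _resolve_tolerance(ts, r, k)
    if r_abs <= 0:
        raise ValueError(f"ApEn requires a positive tolerance, got r={r_abs}")
    d_m, d_m1 = _distance_squares(ts, m, "apen")
    phi_m = float(np.mean(np.log((d_m <= r_abs).sum(axis=1) / d_m.shape[0])))
    phi_m1 = float(np.mean(np.log((d_m1 <= r_abs).sum(axis=1) / d_m1.shape[0])))
    return phi_m - phi_m1


def sampen(x: SeriesLike, m: int = 2, r: float | None = None, k: float | None = None) -> float:
    """Sample entropy; returns ``UNDEFINED`` (nan) when indefinite.

    Self-matches are excluded and ``N - m`` templates are formed at both
    dimensions. ``Phi`` is the plain mean of the per-template match
    fractions, and the result is ``ln(Phi^m / Phi^{m+1})``. With no
    matches at dimension m+1 the ratio is indeterminate and the sentinel
    ``UNDEFINED`` is returned — never an exception.
    """
    ts = as_series(x)
    _require_length(ts, m)
    r_abs = _resolve_tolerance(ts, r, k)
    if r_abs < 0:
        raise ValueError(f"tolerance must be non-negative, got r={r_abs}")
    d_m, d_m1 = _distance_squares(ts, m, "sampen")
    n = d_m.shape[0]
    # diagonal distance is 0 <= r, so subtract the self-match from each count
    counts_m = (d_m <= r_abs).sum(axis=1) - 1
    counts_m1 = (d_m1 <= r_abs).sum(axis=1) - 1
    phi_m = float(np.mean(counts_m / (n - 1)))
    phi_m1 = float(np.mean(counts_m1 / (n - 1)))
    if phi_m1 == 0.0 or phi_m == 0.0:
        return UNDEFINED
    return math.log(phi_m / phi_m1)


def fuzzyen(x: SeriesLike, m: int = 2, r: float | None = None, k: float | None = None) -> float:
    """Fuzzy entropy: graded matching by the similarity degree
    ``D_ij = exp(-(d_ij / r)^2)``.

    Defaults to ``m=2``, ``r = 0.15 * SD`` when no tolerance is given.
    Template counts follow the self-match-free convention (``N - m`` at
    both dimensions); each ``C_i`` averages the ``N - m - 1`` similarity
    degrees to the other templates. Always finite since ``D_ij > 0``.
    Vectors are compared as-is (no per-vector baseline removal).
    """
    ts = as_series(x)
    _require_length(ts, m)
    if r is None and k is None:
        k = 0.15
    r_abs = _resolve_tolerance(ts, r, k)
    if r_abs <= 0:
        raise ValueError(f"FuzzyEn requires a positive tolerance, got r={r_abs}")
    d_m, d_m1 = _distance_squares(ts, m, "sampen")
    n = d_m.shape[0]
    # subtract the diagonal's exp(0) = 1 from each row sum
    sim_m = (np.exp(-((d_m / r_abs) ** 2)).sum(axis=1) - 1.0) / (n - 1)
    sim_m1 = (np.exp(-((d_m1 / r_abs) ** 2)).sum(axis=1) - 1.0) / (n - 1)
    return math.log(float(np.mean(sim_m)) / float(np.mean(sim_m1)))


def _resolve_tolerance(ts: TimeSeries, r: float | None, k: float | None) -> float:
    if (r is None) == (k is None):
        raise ValueError("exactly one of {r, k} must be given")
    return float(r) if r is not None else float(k) * ts.sd


def max_apen_search(
    x: SeriesLike, m: int = 2, grid: Sequence[float] | np.ndarray | None = None
) -> MaxApEnResult:
    """Traditional grid search for the entropy-maximising tolerance.

    The default grid is ``r = i * SD / 100`` for ``i = 1..100``. ApEn is
    evaluated at every grid point; ``rmax`` is the smallest tolerance
    attaining the curve maximum (deterministic tie-break).
    """
    ts = as_series(x)
    _require_length(ts, m)
    if grid is None:
        grid_arr = ts.sd * np.arange(1, 101) / 100.0
    else:
        grid_arr = np.asarray(grid, dtype=float)
    if grid_arr.size == 0:
        raise ValueError("tolerance grid must be non-empty")
    if np.any(grid_arr <= 0):
        raise ValueError("all grid tolerances must be positive")
    # distances are shared across grid points; only the counting repeats
    d_m, d_m1 = _distance_squares(ts, m, "apen")
    n_m, n_m1 = d_m.shape[0], d_m1.shape[0]
    curve = np.empty(grid_arr.size)
    for idx, r_abs in enumerate(grid_arr):
        phi_m = np.mean(np.log((d_m <= r_abs).sum(axis=1) / n_m))
        phi_m1 = np.mean(np.log((d_m1 <= r_abs).sum(axis=1) / n_m1))
        curve[idx] = phi_m - phi_m1
    max_apen = float(curve.max())
    tied = np.flatnonzero(curve == max_apen)
    rmax = float(grid_arr[tied].min())
    return MaxApEnResult(r_grid=grid_arr, apen_curve=curve, rmax=rmax, max_apen=max_apen)
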