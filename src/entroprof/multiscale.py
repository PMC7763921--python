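"""Coarse-graining and multiscale application of entropy estimators.

Multiscale entropy (MSE) replaces a series by non-overlapping block
means at increasing scale factors and re-estimates entropy at each
scale; irregularity that survives coarse-graining reflects structure
(complexity) rather than noise. Any of the package's single-series
measures can be multiscaled, including the r-free profile summaries
TotalSampEn / AvgSampEn.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Literal, Sequence

import numpy as np

from .core import UNDEFINED, SeriesLike, TimeSeries, as_series, fuzzyen, sampen
from .profile import avg_sampen, sampen_profile, total_sampen

__all__ = ["MultiscaleCurve", "coarse_grain", "multiscale_curve", "DEFAULT_SCALES"]

#: Scales 1..20, the conventional span for short-term HRV multiscale analysis.
DEFAULT_SCALES: tuple[int, ...] = tuple(range(1, 21))

Estimator = Literal["sampen_fixed_r", "fuzzyen_fixed_r", "total_sampen", "avg_sampen"]


@dataclass(frozen=True)
class MultiscaleCurve:
    """Entropy (or UNDEFINED) per scale factor, with length bookkeeping."""

    scales: tuple[int, ...]
    values: np.ndarray
    estimator_tag: str
    coarse_lengths: tuple[int, ...]
    reasons: tuple[str, ...] = ()  # per-scale note, "" when defined

    @property
    def defined(self) -> np.ndarray:
        return np.isfinite(self.values)


def coarse_grain(x: SeriesLike, scale: int) -> TimeSeries:
    """Block-average a series by ``scale``: consecutive non-overlapping
    blocks of ``scale`` samples are replaced by their mean; the trailing
    remainder (< scale samples) is dropped, so the output has
    ``floor(N / scale)`` samples. Scale 1 is the identity."""
    ts = as_series(x)
    if scale < 1:
        raise ValueError(f"scale must be a positive integer, got {scale}")
    if scale > ts.n:
        raise ValueError(f"scale {scale} exceeds series length {ts.n}")
    n_blocks = ts.n // scale
    coarse = ts.values[: n_blocks * scale].reshape(n_blocks, scale).mean(axis=1)
    return TimeSeries(coarse, units=ts.units, label=ts.label)


def multiscale_curve(
    x: SeriesLike,
    scales: Sequence[int] | None = None,
    estimator: Estimator = "sampen_fixed_r",
    m: int = 2,
    k: float = 0.15,
    r_mode: Literal["per_scale_sd", "scale1_sd"] = "scale1_sd",
) -> MultiscaleCurve:
    """Apply an estimator independently to every coarse-grained scale.

    For the fixed-r estimators the tolerance is ``k * SD``; ``r_mode``
    selects whose SD: the original series' (``scale1_sd``, the classical
    multiscale-entropy convention, default) or each coarse-grained
    series' own (``per_scale_sd``, which re-normalises every scale).
    TotalSampEn / AvgSampEn are tolerance-free and ignore ``k``/``r_mode``.

    A scale whose coarse series is too short for the embedding (or whose
    estimate is indefinite) is reported UNDEFINED with a reason — never
    a hard failure.
    """
    ts = as_series(x)
    scale_list = tuple(int(s) for s in (scales if scales is not None else DEFAULT_SCALES))
    if any(s < 1 for s in scale_list):
        raise ValueError("scales must be positive integers")
    if any(b <= a for a, b in zip(scale_list, scale_list[1:])):
        raise ValueError("scales must be strictly increasing")
    r_fixed = k * ts.sd
    values = np.full(len(scale_list), UNDEFINED)
    lengths: list[int] = []
    reasons: list[str] = []
    for idx, scale in enumerate(scale_list):
        if scale > ts.n:
            lengths.append(0)
            reasons.append(f"scale {scale} exceeds series length {ts.n}")
            continue
        coarse = coarse_grain(ts, scale)
        lengths.append(coarse.n)
        if coarse.n <= m + 1:
            reasons.append(
                f"coarse length {coarse.n} too short for m={m} (need > {m + 1})"
            )
            continue
        try:
            values[idx] = _apply(estimator, coarse, m, k, r_fixed, r_mode)
        except ValueError as exc:  # e.g. degenerate profile, zero-SD coarse series
            reasons.append(str(exc))
            continue
        reasons.append("" if np.isfinite(values[idx]) else "indefinite estimate")
    return MultiscaleCurve(
        scales=scale_list,
        values=values,
        estimator_tag=estimator,
        coarse_lengths=tuple(lengths),
        reasons=tuple(reasons),
    )


def _apply(
    estimator: str,
    coarse: TimeSeries,
    m: int,
    k: float,
    r_fixed: float,
    r_mode: str,
) -> float:
    if coarse.sd == 0.0:
        return 0.0  # constant series: perfectly regular at any tolerance
    r = r_fixed if r_mode == "scale1_sd" else k * coarse.sd
    if estimator == "sampen_fixed_r":
        return sampen(coarse, m, r=r)
    if estimator == "fuzzyen_fixed_r":
        return fuzzyen(coarse, m, r=r)
    if estimator == "total_sampen":
        return total_sampen(sampen_profile(coarse, m))
    if estimator == "avg_sampen":
        return avg_sampen(sampen_profile(coarse, m))
    raise ValueError(f"unknown estimator: {estimator!r}")
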