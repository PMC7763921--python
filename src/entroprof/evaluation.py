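"""Group-comparison statistics for entropy features.

Two-group discrimination is reported the way HRV classification studies
report it: a two-sided Mann–Whitney U p-value and the AUC (probability
that a random member of one group ranks above a random member of the
other, ties credited 1/2). Feature vectors may contain UNDEFINED (nan)
entries — indefinite SampEn cases — which are excluded pairwise with
counts reported, and a group left empty by exclusion yields NA rather
than an error.

:func:`truncation_report` evaluates a set of measures over several
series truncation lengths and emits the long-format table of p / AUC
values that mirrors the usual benchmark layout.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import SeriesLike, as_series, fuzzyen, sampen
from .profile import avg_sampen, sampen_profile, total_sampen

__all__ = [
    "GroupComparison",
    "mann_whitney_p",
    "auc",
    "compare_groups",
    "truncation_report",
    "MEASURES",
    "SIGNIFICANCE_LEVEL",
]

#: Two-sided significance threshold used to flag "NS" cells in reports.
SIGNIFICANCE_LEVEL: float = 0.05

#: Group size at or below which the exact (enumeration) null is used
#: when the pooled sample is tie-free.
_EXACT_MAX_N: int = 8


@dataclass(frozen=True)
class GroupComparison:
    """Mann–Whitney / AUC comparison of one feature across two groups."""

    n_a: int
    n_b: int
    u_statistic: float
    p_value: float
    auc: float
    n_undefined_a: int = 0
    n_undefined_b: int = 0

    @property
    def auc_folded(self) -> float:
        """Orientation-free AUC, max(AUC, 1 - AUC)."""
        return max(self.auc, 1.0 - self.auc)

    @property
    def significant(self) -> bool:
        return bool(self.p_value < SIGNIFICANCE_LEVEL)


def _clean(values: Sequence[float]) -> tuple[np.ndarray, int]:
    arr = np.asarray(values, dtype=float).ravel()
    finite = arr[np.isfinite(arr)]
    return finite, int(arr.size - finite.size)


def mann_whitney_p(a: Sequence[float], b: Sequence[float]) -> float:
    """Two-sided Mann–Whitney U p-value.

    Exact enumeration null when both groups have <= 8 observations and
    the pooled sample is tie-free; tie-corrected normal approximation
    otherwise. UNDEFINED (nan) entries are dropped first; a group left
    empty yields nan (the "NA" cell).
    """
    aa, _ = _clean(a)
    bb, _ = _clean(b)
    if aa.size == 0 or bb.size == 0:
        return float("nan")
    pooled = np.concatenate([aa, bb])
    tie_free = np.unique(pooled).size == pooled.size
    method = "exact" if (tie_free and min(aa.size, bb.size) <= _EXACT_MAX_N) else "asymptotic"
    return float(stats.mannwhitneyu(aa, bb, alternative="two-sided", method=method).pvalue)


def auc(a: Sequence[float], b: Sequence[float]) -> float:
    """Probability that a random element of ``a`` exceeds a random
    element of ``b``, counting ties as 1/2 (the rank-sum U divided by
    ``n_a * n_b``)."""
    aa, _ = _clean(a)
    bb, _ = _clean(b)
    if aa.size == 0 or bb.size == 0:
        return float("nan")
    ranks = stats.rankdata(np.concatenate([aa, bb]))
    u_a = ranks[: aa.size].sum() - aa.size * (aa.size + 1) / 2.0
    return float(u_a / (aa.size * bb.size))


def compare_groups(a: Sequence[float], b: Sequence[float]) -> GroupComparison:
    """Full two-group comparison with UNDEFINED bookkeeping."""
    aa, bad_a = _clean(a)
    bb, bad_b = _clean(b)
    auc_val = auc(aa, bb) if aa.size and bb.size else float("nan")
    u_stat = auc_val * aa.size * bb.size if np.isfinite(auc_val) else float("nan")
    return GroupComparison(
        n_a=int(aa.size),
        n_b=int(bb.size),
        u_statistic=float(u_stat),
        p_value=mann_whitney_p(aa, bb) if aa.size and bb.size else float("nan"),
        auc=float(auc_val),
        n_undefined_a=bad_a,
        n_undefined_b=bad_b,
    )


def _measure_sampen(x: SeriesLike) -> float:
    return sampen(x, m=2, k=0.2)


def _measure_fuzzyen(x: SeriesLike) -> float:
    return fuzzyen(x, m=2, k=0.15)


def _measure_total(x: SeriesLike) -> float:
    return total_sampen(sampen_profile(x, m=2))


def _measure_avg(x: SeriesLike) -> float:
    return avg_sampen(sampen_profile(x, m=2))


#: Built-in per-series feature extractors for reports. Tolerances follow
#: the conventional choices: SampEn at r = 0.2*SD, FuzzyEn at r = 0.15*SD,
#: both at m = 2; the profile summaries are tolerance-free.
MEASURES: dict[str, Callable[[SeriesLike], float]] = {
    "sampen": _measure_sampen,
    "fuzzyen": _measure_fuzzyen,
    "total_sampen": _measure_total,
    "avg_sampen": _measure_avg,
}


def truncation_report(
    groups: Mapping[str, Sequence[SeriesLike]],
    lengths: Sequence[int],
    measures: Sequence[str] | Mapping[str, Callable[[SeriesLike], float]] = (
        "sampen",
        "fuzzyen",
        "total_sampen",
        "avg_sampen",
    ),
) -> pd.DataFrame:
    """p / AUC table over truncation lengths, for every group pair.

    Each series is truncated *from its start* to each requested length
    and every measure is evaluated per subject. Subjects shorter than a
    requested length are flagged (counted in ``n_short``) and excluded
    from that cell, as are subjects whose measure is UNDEFINED
    (``n_excluded``); nothing is dropped silently.

    Returns a long-format frame with one row per
    (length, measure, group pair).
    """
    if len(groups) < 2:
        raise ValueError("need at least two labeled groups")
    if isinstance(measures, Mapping):
        measure_fns = dict(measures)
    else:
        unknown = [name for name in measures if name not in MEASURES]
        if unknown:
            raise ValueError(f"unknown measures {unknown}; choose from {sorted(MEASURES)}")
        measure_fns = {name: MEASURES[name] for name in measures}
    labels = list(groups)
    series_by_group = {
        lab: [as_series(s) for s in group] for lab, group in groups.items()
    }
    rows = []
    for length in lengths:
        features: dict[str, dict[str, list[float]]] = {}
        n_short: dict[str, int] = {}
        for lab in labels:
            per_measure: dict[str, list[float]] = {name: [] for name in measure_fns}
            short = 0
            for ts in series_by_group[lab]:
                if ts.n < length:
                    short += 1
                    continue
                head = as_series(ts.values[:length], units=ts.units, label=ts.label)
                for name, fn in measure_fns.items():
                    try:
                        per_measure[name].append(fn(head))
                    except ValueError:
                        per_measure[name].append(float("nan"))
            features[lab] = per_measure
            n_short[lab] = short
        for name in measure_fns:
            for i, lab_a in enumerate(labels):
                for lab_b in labels[i + 1 :]:
                    cmp = compare_groups(features[lab_a][name], features[lab_b][name])
                    rows.append(
                        {
                            "length": int(length),
                            "measure": name,
                            "group_pair": f"{lab_a} vs {lab_b}",
                            "p": cmp.p_value,
                            "auc": cmp.auc,
                            "auc_folded": cmp.auc_folded,
                            "n_a": cmp.n_a,
                            "n_b": cmp.n_b,
                            "n_excluded": cmp.n_undefined_a + cmp.n_undefined_b,
                            "n_short": n_short[lab_a] + n_short[lab_b],
                            "significant": bool(
                                np.isfinite(cmp.p_value)
                                and cmp.p_value < SIGNIFICANCE_LEVEL
                            ),
                        }
                    )
    return pd.DataFrame(rows)
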