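"""Readers and writers: RR-interval files, profile/curve/report CSVs.

Input is plain-text or CSV lists of RR intervals (one positive duration
per line or per cell of a named column; '#' comments allowed in plain
files). Milliseconds are converted to seconds on read (exact / 1000).

Every writer emits RFC-4180 CSV with floats formatted at 17 significant
digits — enough for a read-back to reproduce the values bit-for-bit —
plus a JSON sidecar (``<path>.json``) carrying the parameters needed to
re-run the computation. UNDEFINED values are serialized as an *empty
cell* alongside an explicit boolean ``defined`` column, never as a NaN
a spreadsheet could silently coerce.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd

from .core import TimeSeries
from .multiscale import MultiscaleCurve
from .profile import EntropyProfile, ProfileSummary

__all__ = [
    "RRRecord",
    "read_rr",
    "write_series",
    "write_profile",
    "write_curve",
    "write_report",
    "read_profile",
]

FLOAT_FMT = "%.17g"


@dataclass(frozen=True)
class RRRecord:
    """An RR/NN interval series with its provenance."""

    intervals: TimeSeries
    source_path: str
    units: Literal["seconds", "milliseconds"]
    subject_id: str = ""
    group_label: str | None = None


def _fmt(x: float) -> str:
    return FLOAT_FMT % x


def read_rr(
    path: str | Path,
    units: Literal["seconds", "milliseconds"] = "seconds",
    dialect: Literal["plain", "csv"] = "plain",
    column: str = "rr",
    subject_id: str = "",
    group_label: str | None = None,
) -> RRRecord:
    """Read an RR-interval file; intervals are validated positive and
    stored in seconds (milliseconds divided by 1000 exactly).

    Plain dialect: one value per line, blank lines and '#' comments
    skipped. CSV dialect: values taken from the named ``column``.
    Errors cite the offending line and value.
    """
    path = Path(path)
    raw: list[float] = []
    if dialect == "plain":
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                text = line.split("#", 1)[0].strip()
                if not text:
                    continue
                try:
                    raw.append(float(text))
                except ValueError:
                    raise ValueError(
                        f"{path}: non-numeric value {text!r} on line {lineno}"
                    ) from None
    elif dialect == "csv":
        frame = pd.read_csv(path)
        if column not in frame.columns:
            raise ValueError(f"{path}: no column named {column!r}")
        for lineno, value in enumerate(frame[column], start=2):
            try:
                raw.append(float(value))
            except (TypeError, ValueError):
                raise ValueError(
                    f"{path}: non-numeric value {value!r} on line {lineno}"
                ) from None
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    if not raw:
        raise ValueError(f"{path}: file contains no samples")
    values = np.asarray(raw, dtype=float)
    bad = np.flatnonzero(values <= 0)
    if bad.size:
        raise ValueError(
            f"{path}: RR interval must be a positive duration, got {values[bad[0]]}"
        )
    if units == "milliseconds":
        values = values / 1000.0
    elif units != "seconds":
        raise ValueError(f"unknown units {units!r}")
    ts = TimeSeries(values, units="seconds", label=subject_id or path.stem)
    return RRRecord(
        intervals=ts,
        source_path=str(path),
        units=units,
        subject_id=subject_id or path.stem,
        group_label=group_label,
    )


def _write_sidecar(path: Path, payload: dict) -> None:
    from . import __version__

    payload = {"entroprof_version": __version__, **payload}
    with open(path.with_suffix(path.suffix + ".json"), "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")


def write_series(values: np.ndarray, path: str | Path, meta: dict | None = None) -> None:
    """Plain-text series, one value per line (17 significant digits)."""
    path = Path(path)
    with open(path, "w") as fh:
        for v in np.asarray(values, dtype=float):
            fh.write(_fmt(v) + "\n")
    if meta is not None:
        _write_sidecar(path, meta)


def write_profile(
    profile: EntropyProfile,
    summary: ProfileSummary,
    path: str | Path,
    extra_meta: dict | None = None,
) -> None:
    """Profile CSV: (q, r_value, theta_m, theta_m1, sampen, defined) rows,
    with an empty sampen cell for undefined bins, plus a JSON sidecar
    carrying N, m, nbin and the summary measures."""
    path = Path(path)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["q", "r_value", "theta_m", "theta_m1", "sampen", "defined"])
        for q in range(profile.nbin):
            defined = bool(profile.defined[q])
            writer.writerow(
                [
                    q + 1,
                    _fmt(profile.range.values[q]),
                    _fmt(profile.theta_m[q]),
                    _fmt(profile.theta_m1[q]),
                    _fmt(profile.sampen[q]) if defined else "",
                    str(defined).lower(),
                ]
            )
    meta = {
        "N": profile.n,
        "m": profile.m,
        "nbin": profile.nbin,
        "total_sampen": summary.total_sampen,
        "avg_sampen": summary.avg_sampen,
        "n_defined_bins": summary.n_defined_bins,
        "n_undefined_bins": summary.n_undefined_bins,
    }
    if extra_meta:
        meta.update(extra_meta)
    _write_sidecar(path, meta)


def read_profile(path: str | Path) -> pd.DataFrame:
    """Read back a profile CSV (empty sampen cells become NaN with
    ``defined`` False)."""
    frame = pd.read_csv(path, float_precision="round_trip")
    frame["defined"] = frame["defined"].astype(bool)
    return frame


def write_curve(curve: MultiscaleCurve, path: str | Path, extra_meta: dict | None = None) -> None:
    """Multiscale curve CSV: (scale, coarse_length, value, defined)."""
    path = Path(path)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["scale", "coarse_length", "value", "defined"])
        for i, scale in enumerate(curve.scales):
            defined = bool(np.isfinite(curve.values[i]))
            writer.writerow(
                [
                    scale,
                    curve.coarse_lengths[i],
                    _fmt(curve.values[i]) if defined else "",
                    str(defined).lower(),
                ]
            )
    meta = {"estimator": curve.estimator_tag, "scales": list(curve.scales)}
    if extra_meta:
        meta.update(extra_meta)
    _write_sidecar(path, meta)


def write_report(report: pd.DataFrame, path: str | Path, extra_meta: dict | None = None) -> None:
    """Long-format comparison report CSV plus sidecar."""
    path = Path(path)
    report.to_csv(path, index=False, float_format=FLOAT_FMT)
    _write_sidecar(path, extra_meta or {})
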