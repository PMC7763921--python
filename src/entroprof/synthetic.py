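"""Seeded generators for the synthetic signals used throughout the package.

Three families cover the usual test conditions for tolerance-selection
and profiling experiments:

* noisy logistic maps at three irregularity levels (periodic a=3.5,
  intermediate a=3.75, chaotic a=4.0) with additive Gaussian white
  noise — the standard benchmark for the rmax / MaxApEn grid search;
* Gaussian white noise and 1/f-type power-law noise (the canonical
  uncorrelated vs long-range-correlated pair for multiscale analysis);
* shuffled surrogates, which preserve a series' value distribution
  exactly while destroying its temporal structure.

Every generator is a pure function of its configuration including the
seed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Literal

import numpy as np

from .core import TimeSeries, SeriesLike, as_series

__all__ = [
    "LogisticMapConfig",
    "PRESETS",
    "preset_config",
    "logistic_map",
    "gaussian_noise",
    "powerlaw_noise",
    "shuffle_surrogate",
]


@dataclass(frozen=True)
class LogisticMapConfig:
    """Configuration of a noisy logistic-map signal.

    The map ``x_{n+1} = a * x_n * (1 - x_n)`` is iterated from ``x0``
    (after a seeded micro-jitter, see below), ``transient`` iterations
    are discarded, ``n`` samples are recorded, and Gaussian white noise
    of standard deviation ``noise_sd`` is added sample-wise.

    ``x0 = 0.5`` with ``a = 4.0`` lands exactly on the degenerate orbit
    0.5 -> 1 -> 0 -> 0..., so a tiny seeded jitter (magnitude between
    0.5x and 1x ``jitter``) is added to ``x0`` to put the chaotic preset
    on a generic orbit; set ``jitter = 0`` to reproduce the degenerate
    trajectory. The default 1e-7 is the smallest scale that reliably
    survives IEEE-double rounding: for a perturbation e the first
    iterate is ``1 - 4 e**2``, which rounds back to exactly 1.0 (and
    thus re-enters the absorbing orbit) whenever ``4 e**2`` falls below
    the spacing of doubles near 1 (~2.2e-16), i.e. for e below ~1e-8.

    ``noise_mode`` selects whether ``noise_sd`` scales the clean
    signal's SD (``relative``, default — the noise-"level" convention of
    the classic MATLAB chaotic-signal generators) or is an absolute
    standard deviation.
    """

    a: float = 4.0
    x0: float = 0.5
    n: int = 1000
    transient: int = 1000
    noise_sd: float = 0.1
    seed: int = 0
    jitter: float = 1e-7
    noise_mode: Literal["absolute", "relative"] = "relative"

    def __post_init__(self) -> None:
        if not 0.0 < self.x0 < 1.0:
            raise ValueError(f"x0 must lie in (0, 1), got {self.x0}")
        if not 0.0 < self.a <= 4.0:
            raise ValueError(f"map parameter a must lie in (0, 4], got {self.a}")
        if self.n < 1:
            raise ValueError("output length n must be >= 1")
        if self.transient < 0:
            raise ValueError("transient must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.jitter < 0:
            raise ValueError("jitter must be >= 0")


#: Irregularity presets: map parameter per regime.
PRESETS: dict[str, float] = {"periodic": 3.5, "intermediate": 3.75, "chaotic": 4.0}


def preset_config(name: str, n: int = 1000, seed: int = 0, **overrides) -> LogisticMapConfig:
    """Named noisy-logistic preset (periodic / intermediate / chaotic)."""
    if name not in PRESETS:
        raise ValueError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
    return replace(LogisticMapConfig(a=PRESETS[name], n=n, seed=seed), **overrides)


def logistic_map(cfg: LogisticMapConfig) -> TimeSeries:
    """Generate a noisy logistic-map series from its configuration.

    The clean (pre-noise) trajectory lies in [0, 1]; noise is applied
    after map generation, never fed back into the iteration.
    """
    rng = np.random.default_rng(cfg.seed)
    x = cfg.x0
    if cfg.jitter > 0:
        u = rng.uniform(-1.0, 1.0)
        # keep the magnitude in [jitter/2, jitter] so it cannot round away
        x = x + cfg.jitter * np.sign(u) * (0.5 + 0.5 * abs(u))
        if not 0.0 < x < 1.0:
            raise ValueError(f"jittered x0 = {x} left the open interval (0, 1)")
    total = cfg.transient + cfg.n
    out = np.empty(total)
    for i in range(total):
        x = cfg.a * x * (1.0 - x)
        out[i] = x
    clean = out[cfg.transient :]
    sd = cfg.noise_sd if cfg.noise_mode == "absolute" else cfg.noise_sd * float(np.std(clean))
    noisy = clean + rng.normal(0.0, sd, cfg.n) if sd > 0 else clean
    return TimeSeries(noisy, units="arbitrary", label=f"logistic(a={cfg.a})")


def gaussian_noise(n: int, sd: float = 1.0, seed: int = 0) -> TimeSeries:
    """I.i.d. Gaussian white noise, mean 0, standard deviation ``sd``."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if sd < 0:
        raise ValueError("sd must be >= 0")
    rng = np.random.default_rng(seed)
    values = rng.normal(0.0, sd, n) if sd > 0 else np.zeros(n)
    return TimeSeries(values, units="arbitrary", label="white noise")


def powerlaw_noise(n: int, exponent: float = 1.0, sd: float = 1.0, seed: int = 0) -> TimeSeries:
    """Long-range-correlated noise with a ~1/f^exponent power spectrum.

    Spectral synthesis: Gaussian white noise is filtered in the Fourier
    domain by ``f^(-exponent / 2)`` (DC untouched) and standardised to
    mean 0, SD ``sd``. ``exponent = 1`` gives classic pink noise, the
    conventional stand-in for a complex physiological signal.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    rng = np.random.default_rng(seed)
    spectrum = np.fft.rfft(rng.normal(0.0, 1.0, n))
    freqs = np.fft.rfftfreq(n)
    scale = np.ones_like(freqs)
    nonzero = freqs > 0
    scale[nonzero] = freqs[nonzero] ** (-exponent / 2.0)
    scale[0] = 0.0
    values = np.fft.irfft(spectrum * scale, n)
    values = (values - values.mean())
    current = float(np.std(values))
    if current > 0 and sd > 0:
        values *= sd / current
    return TimeSeries(values, units="arbitrary", label=f"1/f^{exponent} noise")


def shuffle_surrogate(x: SeriesLike, seed: int = 0) -> TimeSeries:
    """Uniformly random permutation of the samples (value multiset
    preserved exactly; temporal structure destroyed)."""
    ts = as_series(x)
    if ts.n < 2:
        raise ValueError("need at least 2 samples to shuffle")
    rng = np.random.default_rng(seed)
    return TimeSeries(
        rng.permutation(ts.values), units=ts.units, label=f"{ts.label} [surrogate]"
    )
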