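"""First-order detrended fluctuation analysis (DFA).

DFA quantifies scaling of fluctuations in a (possibly nonstationary)
series: the mean-centred series is integrated into a profile, the profile
is cut into non-overlapping boxes of size s, a least-squares line is
removed from each box, and F(s) is the RMS of the residuals.  The log-log
slope of F(s) versus s estimates the scaling exponent alpha, which for
fractional-Gaussian-noise-like input approximates the Hurst exponent
(white noise: alpha = 0.5; integrated white noise / Brownian increments of
the profile: alpha = 1.5).

R-R interval series typically show a crossover: different exponents at
short scales (boxes of <= 15 points) and long scales, so the default fit
reports a slope pair split at box size 15.
"""

from __future__ import annotations

from dataclasses import dataclass
import json

import numpy as np

from .core import as_series

__all__ = ["DFAResult", "default_box_sizes", "dfa_fluctuations", "fit_scaling_exponents", "dfa"]


@dataclass(frozen=True)
class DFAResult:
    """Fluctuation function and fitted two-regime scaling exponents."""

    box_sizes: np.ndarray
    fluctuations: np.ndarray
    alpha_short: float
    alpha_long: float
    crossover: int

    def to_json(self) -> str:
        return json.dumps(
            {
                "box_sizes": self.box_sizes.tolist(),
                "fluctuations": self.fluctuations.tolist(),
                "alpha_short": self.alpha_short,
                "alpha_long": self.alpha_long,
                "crossover": self.crossover,
            }
        )


def default_box_sizes(n: int, n_sizes: int = 20, min_size: int = 4) -> np.ndarray:
    """Approximately log-spaced box sizes from ``min_size`` to ``n // 4``."""
    max_size = n // 4
    if max_size < min_size:
        raise ValueError(f"series too short for DFA: n={n}")
    sizes = np.geomspace(min_size, max_size, n_sizes)
    return np.unique(np.round(sizes).astype(int))


def dfa_fluctuations(
    series,
    box_sizes: np.ndarray | None = None,
    detrend_order: int = 1,
    reversed_pass: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Fluctuation function F(s) of a series over the given box sizes.

    The profile is the cumulative sum of the mean-centred samples.  For
    each box size s the profile is split into floor(N/s) non-overlapping
    boxes starting from the beginning; the remainder tail is discarded
    unless ``reversed_pass`` is set, in which case boxes taken from the
    end are averaged in as well so no samples are dropped.

    Raises on constant input (F would be identically 0, undefined on a log
    scale) and on box sizes outside [detrend_order + 2, N // 2].
    """
    ts = as_series(series)
    x = ts.values
    n = x.size
    if np.all(x == x[0]):
        raise ValueError("DFA is undefined for a constant series (zero fluctuation)")
    if box_sizes is None:
        box_sizes = default_box_sizes(n)
    sizes = np.asarray(box_sizes, dtype=int)
    if sizes.size == 0:
        raise ValueError("need at least one box size")
    if np.any(np.diff(sizes) <= 0):
        raise ValueError("box sizes must be strictly increasing")
    if sizes[0] < detrend_order + 2 or sizes[0] < 4:
        raise ValueError("box sizes must be >= 4 and allow detrending")
    if sizes[-1] > n // 2:
        raise ValueError(f"largest box size {sizes[-1]} exceeds N/2 = {n // 2}")

    profile = np.cumsum(x - x.mean())

    def rms_residuals(y: np.ndarray, s: int) -> float:
        nbox = y.size // s
        Y = y[: nbox * s].reshape(nbox, s).T  # (s, nbox)
        t = np.arange(s, dtype=float)
        A = np.vander(t, detrend_order + 1)
        coef, *_ = np.linalg.lstsq(A, Y, rcond=None)
        res = Y - A @ coef
        return float(np.mean(res**2))

    F = np.empty(sizes.size)
    for k, s in enumerate(sizes):
        ms = rms_residuals(profile, int(s))
        if reversed_pass:
            ms = 0.5 * (ms + rms_residuals(profile[::-1], int(s)))
        F[k] = np.sqrt(ms)
    return sizes, F


def fit_scaling_exponents(
    box_sizes: np.ndarray, fluctuations: np.ndarray, crossover: int = 15
) -> DFAResult:
    """Least-squares slope of log F vs log s on each side of the crossover.

    ``alpha_short`` fits box sizes <= crossover, ``alpha_long`` the rest;
    each regime needs at least two box sizes.
    """
    s = np.asarray(box_sizes, dtype=float)
    F = np.asarray(fluctuations, dtype=float)
    if s.shape != F.shape:
        raise ValueError("box_sizes and fluctuations must have equal length")
    if np.any(F <= 0):
        raise ValueError("fluctuations must be positive for a log-log fit")
    short = s <= crossover
    if short.sum() < 2 or (~short).sum() < 2:
        raise ValueError(
            f"need >= 2 box sizes on each side of the crossover {crossover}; "
            f"got {int(short.sum())} short and {int((~short).sum())} long"
        )
    a_short = np.polyfit(np.log(s[short]), np.log(F[short]), 1)[0]
    a_long = np.polyfit(np.log(s[~short]), np.log(F[~short]), 1)[0]
    return DFAResult(s.astype(int), F, float(a_short), float(a_long), int(crossover))


def fit_scaling_exponent(box_sizes: np.ndarray, fluctuations: np.ndarray) -> float:
    """Single overall log-log slope of F(s), ignoring any crossover."""
    s = np.asarray(box_sizes, dtype=float)
    F = np.asarray(fluctuations, dtype=float)
    if np.any(F <= 0):
        raise ValueError("fluctuations must be positive for a log-log fit")
    return float(np.polyfit(np.log(s), np.log(F), 1)[0])


def dfa(series, box_sizes=None, crossover: int = 15, detrend_order: int = 1) -> DFAResult:
    """Convenience wrapper: fluctuations plus the two-regime fit."""
    sizes, F = dfa_fluctuations(series, box_sizes, detrend_order)
    return fit_scaling_exponents(sizes, F, crossover)
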