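"""Circular-statistics primitives: wrapping, circular mean/SD, bootstrap CIs.

All public functions take and return degrees. The wrapping convention is
(-180, 180] everywhere: positive differences are clockwise of the reference.
The circular standard deviation is ``sqrt(-2 ln R)`` (R the mean resultant
length), the convention of the MATLAB Circular Statistics Toolbox — not the
angular deviation ``sqrt(2(1 - R))``; the two diverge for dispersed data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "wrap_deg",
    "wrap360",
    "circular_sd",
    "circular_mean",
    "bootstrap_ci",
    "BootstrapCI",
]

_RESULTANT_EPS = 1e-12


def wrap_deg(angle):
    """Wrap angle(s) in degrees into (-180, 180].

    Idempotent and congruent mod 360: ``wrap_deg(a) == a (mod 360)``.
    The boundary maps -180 -> 180 (a half-turn is reported as +180).

    Parameters
    ----------
    angle : float or array_like
        Angle(s) in degrees; must be finite.
    """
    a = np.asarray(angle, dtype=float)
    if not np.all(np.isfinite(a)):
        raise ValueError("wrap_deg requires finite angles")
    w = np.mod(a, 360.0)
    w = np.where(w > 180.0, w - 360.0, w)
    if np.ndim(angle) == 0:
        return float(w)
    return w


def wrap360(angle):
    """Wrap angle(s) in degrees into [0, 360)."""
    a = np.asarray(angle, dtype=float)
    if not np.all(np.isfinite(a)):
        raise ValueError("wrap360 requires finite angles")
    w = np.mod(a, 360.0)
    if np.ndim(angle) == 0:
        return float(w)
    return w


def _resultant(angles_deg: np.ndarray) -> tuple[float, float, float]:
    """Mean resultant (C, S, R) of unit vectors at the given angles."""
    rad = np.deg2rad(angles_deg)
    c = float(np.mean(np.cos(rad)))
    s = float(np.mean(np.sin(rad)))
    return c, s, float(np.hypot(c, s))


def circular_sd(angles_deg: Sequence[float]) -> float:
    """Circular standard deviation, in degrees: ``sqrt(-2 ln R)``.

    This is the dispersion measure used as "perceptual error" for report
    distributions: it approaches the linear SD for concentrated samples and
    is unbounded as the sample approaches uniformity (R -> 0), in which case
    ``inf`` is returned with a warning.
    """
    a = np.asarray(angles_deg, dtype=float)
    if a.size == 0:
        raise ValueError("circular_sd requires a non-empty sample")
    if not np.all(np.isfinite(a)):
        raise ValueError("circular_sd requires finite angles")
    _, _, r = _resultant(a)
    if r < _RESULTANT_EPS:
        warnings.warn("zero resultant length: circular SD is undefined (uniform-like sample)")
        return float("inf")
    return float(np.degrees(np.sqrt(-2.0 * np.log(r))))


def circular_mean(angles_deg: Sequence[float]) -> float:
    """Circular mean direction in degrees, wrapped to (-180, 180].

    Raises
    ------
    ValueError
        On an empty sample or when the mean resultant vanishes (the mean
        direction is undefined, e.g. two diametrically opposed angles).
    """
    a = np.asarray(angles_deg, dtype=float)
    if a.size == 0:
        raise ValueError("circular_mean requires a non-empty sample")
    if not np.all(np.isfinite(a)):
        raise ValueError("circular_mean requires finite angles")
    c, s, r = _resultant(a)
    if r < _RESULTANT_EPS:
        raise ValueError("zero resultant length: circular mean is undefined")
    return wrap_deg(np.degrees(np.arctan2(s, c)))


@dataclass(frozen=True)
class BootstrapCI:
    """A percentile bootstrap confidence interval for a scalar statistic.

    ``lower <= point <= upper`` holds in the typical case but is not
    guaranteed by the percentile method for pathological resamples.
    """

    point: float
    lower: float
    upper: float
    level: float = 0.95
    n_boot: int = 1000
    seed: int | None = None


def bootstrap_ci(
    data: Sequence[float],
    statistic: Callable[[np.ndarray], float],
    n_boot: int = 1000,
    level: float = 0.95,
    seed: int | None = None,
) -> BootstrapCI:
    """Percentile bootstrap CI of ``statistic(data)``, resampling observations.

    Reproducible from ``seed``; the resampling unit is the individual
    observation (trial).
    """
    arr = np.asarray(data)
    if arr.size == 0:
        raise ValueError("bootstrap_ci requires non-empty data")
    if not 0.0 < level < 1.0:
        raise ValueError("confidence level must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    point = float(statistic(arr))
    stats = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.integers(0, arr.size, size=arr.size)
        try:
            stats[b] = statistic(arr[idx])
        except Exception as exc:  # statistic must be total on resamples
            raise RuntimeError(f"statistic failed on bootstrap resample {b}") from exc
    alpha = (1.0 - level) / 2.0
    lower, upper = np.quantile(stats, [alpha, 1.0 - alpha])
    return BootstrapCI(point=point, lower=float(lower), upper=float(upper),
                       level=level, n_boot=n_boot, seed=seed)
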