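"""Center-of-pressure posturography: excursion, velocity, approximate entropy.

The seat mat records the planar center of pressure (COP) at a nominal
56 Hz.  Three measures summarize how far, how fast, and how regularly the
COP moved during the eight-direction reach test:

* total excursion -- cumulative Euclidean path length (m);
* mean velocity   -- total excursion over recording duration (reported in
  cm/s, the customary posturography unit);
* approximate entropy (ApEn) -- the Pincus regularity statistic; values
  near 0 indicate predictable, repetitive sway, larger values more complex
  postural dynamics, typically in the range 0-2 at the conventional
  parameters m=2, r=0.2*SD.

ApEn here is the classic formulation with self-matches included (not sample
entropy)::

    ApEn(m, r) = Phi_m(r) - Phi_{m+1}(r)
    Phi_m(r)   = (N-m+1)^-1 * sum_i ln C_i^m(r)

where ``C_i^m(r)`` is the fraction of length-m templates within Chebyshev
distance ``r`` of template i.  Self-matches guarantee ``C_i > 0``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .exceptions import ConfigurationError, DataQualityError
from .preprocess import TimeSeriesPlanar

__all__ = [
    "COPSeries",
    "ApEnParams",
    "total_excursion",
    "mean_velocity",
    "approximate_entropy",
    "cop_apen",
]

COP_NOMINAL_RATE_HZ = 56.0

#: COP series type: a planar TimeSeriesPlanar at nominal 56 Hz.
COPSeries = TimeSeriesPlanar


@dataclass(frozen=True)
class ApEnParams:
    """Approximate-entropy parameters.

    ``m`` is the template (embedding) length in samples; ``r`` the match
    tolerance in signal units, or ``None`` to use ``r_factor`` times the
    signal SD (the Pincus convention, default 0.2*SD).  ``axis_mode``
    selects the scalar series derived from planar COP: ``"resultant"``
    (default) uses the centered resultant displacement sqrt(x~^2 + y~^2);
    ``"per-axis-mean"`` averages ApEn of the x and y series.  ``clip``
    confines the reported value to the conventional [0, 2] range with a
    warning (set False to obtain the raw statistic, which can exceed 2
    when template matches are sparse).
    """

    m: int = 2
    r: float | None = None
    r_factor: float = 0.2
    axis_mode: str = "resultant"
    clip: bool = True

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ConfigurationError("embedding length m must be >= 1")
        if self.r is not None and not self.r > 0:
            raise ConfigurationError("tolerance r must be positive")
        if self.r is None and not self.r_factor > 0:
            raise ConfigurationError("r_factor must be positive")
        if self.axis_mode not in ("resultant", "per-axis-mean"):
            raise ConfigurationError(
                f"axis_mode must be 'resultant' or 'per-axis-mean', got {self.axis_mode!r}"
            )


def total_excursion(cop: COPSeries) -> float:
    """Total COP path length (m): sum of consecutive Euclidean step lengths."""
    if cop.n_samples < 2:
        raise DataQualityError("total excursion needs at least 2 samples")
    steps = np.linalg.norm(np.diff(cop.values[:, :2], axis=0), axis=1)
    return float(steps.sum())


def mean_velocity(cop: COPSeries) -> float:
    """Mean COP velocity in cm/s: total excursion over recording duration."""
    duration = cop.duration
    if duration <= 0:
        raise DataQualityError("zero-duration COP series")
    return total_excursion(cop) / duration * 100.0


def _phi(x: np.ndarray, m: int, r: float) -> float:
    """Phi_m(r): mean log fraction of templates within Chebyshev distance r."""
    n_templates = x.size - m + 1
    # Chebyshev distance between length-m templates as a running max over
    # the scalar distance matrix's shifted diagonals: O(m) passes, O(N^2) memory.
    abs_diff = np.abs(x[:, None] - x[None, :])
    d = abs_diff[:n_templates, :n_templates].copy()
    for k in range(1, m):
        np.maximum(d, abs_diff[k : k + n_templates, k : k + n_templates], out=d)
    counts = (d <= r).sum(axis=1)
    return float(np.mean(np.log(counts / n_templates)))


def approximate_entropy(signal: np.ndarray, params: ApEnParams = ApEnParams()) -> float:
    """Approximate entropy of a scalar series (self-matches included).

    The tolerance is ``params.r`` if given, else ``params.r_factor`` times
    the series SD.  The result is clipped to the conventional [0, 2] range
    with a warning if it falls outside.

    Raises
    ------
    DataQualityError
        If the series is shorter than ``m + 2`` samples, or the tolerance
        resolves to zero (constant signal with relative ``r``).
    """
    x = np.asarray(signal, dtype=float).ravel()
    n = x.size
    m = params.m
    if n <= m + 1:
        raise DataQualityError(f"need more than m+1={m + 1} samples, got {n}")
    if not np.all(np.isfinite(x)):
        raise DataQualityError("non-finite samples in ApEn input")
    r = params.r if params.r is not None else params.r_factor * float(np.std(x))
    if not r > 0:
        raise DataQualityError(
            "ApEn tolerance resolved to zero (constant signal with relative r)"
        )
    value = _phi(x, m, r) - _phi(x, m + 1, r)
    if not params.clip:
        return float(value)
    if value < -1e-12 or value > 2.0:
        warnings.warn(
            f"ApEn value {value:.4f} outside the conventional [0, 2] range; clipping",
            stacklevel=2,
        )
    return float(np.clip(value, 0.0, 2.0))


def cop_apen(cop: COPSeries, params: ApEnParams = ApEnParams()) -> float:
    """Approximate entropy of a planar COP series.

    ``axis_mode="resultant"`` computes ApEn of the centered resultant
    displacement series; ``"per-axis-mean"`` averages the per-axis values.
    A constant COP series yields 0 when an absolute tolerance is supplied.
    """
    xy = cop.values[:, :2]
    centered = xy - xy.mean(axis=0)
    if params.axis_mode == "resultant":
        series = np.linalg.norm(centered, axis=1)
        return approximate_entropy(series, params)
    return float(
        np.mean(
            [approximate_entropy(centered[:, 0], params),
             approximate_entropy(centered[:, 1], params)]
        )
    )
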