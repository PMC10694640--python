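"""The 12 step-based fall-risk parameters over a participant's walking bouts.

Four gait domains:

* quantity — number of kept bouts, total retained steps, average steps/bout;
* intensity — cadence (steps/min), mean step time, mean stride time;
* variability — coefficient of variation (CoV = SD/mean) of step and stride
  intervals;
* complexity — detrended fluctuation analysis (DFA) scaling exponent and
  sample entropy (SampEn) of the step- and stride-interval series, computed
  on the middle 200 retained steps only, because both estimators are
  length-dependent and a constant window keeps bouts and participants
  comparable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .streams import WalkingBout, extract_middle200

__all__ = [
    "PARAMETER_NAMES",
    "BoutParameterRecord",
    "QuantityRecord",
    "UndefinedParameterError",
    "dfa_exponent",
    "sample_entropy",
    "intensity_params",
    "variability_params",
    "complexity_params",
    "quantity_params",
    "compute_bout_parameters",
]

#: Canonical order of the 12 parameters as used in cohort tables and models.
PARAMETER_NAMES = (
    "n_bouts",
    "total_steps",
    "avg_steps_per_bout",
    "cadence",
    "mean_step_time",
    "mean_stride_time",
    "cov_step_time",
    "cov_stride_time",
    "dfa_step",
    "dfa_stride",
    "sampen_step",
    "sampen_stride",
)

BOUT_PARAMETER_NAMES = PARAMETER_NAMES[3:]
QUANTITY_PARAMETER_NAMES = PARAMETER_NAMES[:3]


class UndefinedParameterError(ValueError):
    """A parameter is undefined for the given series (too short/degenerate)."""


def dfa_box_sizes(n: int, min_box: int = 4, n_boxes: int = 10) -> np.ndarray:
    """Log-spaced integer box sizes from ``min_box`` to ``n // 4``."""
    max_box = n // 4
    if max_box < min_box:
        raise UndefinedParameterError(
            f"series of length {n} too short for DFA (max box {max_box} < {min_box})"
        )
    sizes = np.unique(
        np.round(np.logspace(np.log10(min_box), np.log10(max_box), n_boxes)).astype(int)
    )
    return sizes


def dfa_exponent(
    series: np.ndarray,
    box_sizes: np.ndarray | None = None,
    min_box: int = 4,
    n_boxes: int = 10,
) -> float:
    """First-order detrended fluctuation analysis scaling exponent.

    The series is mean-centered and cumulatively summed; for each box size
    ``n`` the profile is cut into non-overlapping boxes of ``n`` points
    (trailing remainder dropped), each box is linearly detrended, and the
    RMS fluctuation F(n) is pooled over all boxes. The exponent is the
    least-squares slope of log10 F(n) against log10 n. White noise gives
    alpha ~ 0.5, persistent fGn with Hurst H gives alpha ~ H, and an
    integrated random walk gives alpha ~ 1.5.
    """
    x = np.asarray(series, dtype=float)
    if x.size < 50:
        raise UndefinedParameterError(f"DFA needs >= 50 points, got {x.size}")
    if box_sizes is None:
        sizes = dfa_box_sizes(x.size, min_box=min_box, n_boxes=n_boxes)
    else:
        sizes = np.unique(np.asarray(box_sizes, dtype=int))
        if sizes.min() < 4 or sizes.max() > x.size // 4:
            raise UndefinedParameterError("box sizes must lie in [4, len/4]")
    if sizes.size < 6:
        raise UndefinedParameterError(
            f"DFA needs >= 6 distinct box sizes, got {sizes.size}"
        )
    profile = np.cumsum(x - x.mean())
    fluct = np.empty(sizes.size)
    for k, n in enumerate(sizes):
        nb = profile.size // n
        boxes = profile[: nb * n].reshape(nb, n)
        t = np.arange(n, dtype=float)
        # closed-form per-box linear fit (shared abscissa)
        t_mean = t.mean()
        t_var = ((t - t_mean) ** 2).sum()
        b_mean = boxes.mean(axis=1)
        slope = ((t - t_mean) * (boxes - b_mean[:, None])).sum(axis=1) / t_var
        resid = boxes - (b_mean[:, None] + slope[:, None] * (t - t_mean))
        fluct[k] = np.sqrt(np.mean(resid**2))
    if np.any(fluct == 0):
        raise UndefinedParameterError("zero fluctuation (constant series)")
    alpha, _ = np.polyfit(np.log10(sizes), np.log10(fluct), 1)
    return float(alpha)


def sample_entropy(
    series: np.ndarray,
    m: int = 2,
    r: float | None = None,
    r_factor: float = 0.2,
) -> float:
    """Sample entropy SampEn(m, r) in nats.

    ``-ln(A/B)`` where B counts pairs of length-m templates within Chebyshev
    distance r (self-matches excluded) and A does the same at length m+1.
    By default r = ``r_factor`` times the series' sample SD. Lower values
    mean a more regular (less complex) series; a constant series gives 0.
    Returns NaN when no template pair matches (A or B zero) — the value is
    then undefined and propagates as missing.
    """
    x = np.asarray(series, dtype=float)
    n = x.size
    if n < m + 2:
        raise UndefinedParameterError(f"SampEn needs >= {m + 2} points, got {n}")
    if r is None:
        r = r_factor * (x.std(ddof=1) if n > 1 else 0.0)
    if r < 0:
        raise UndefinedParameterError("tolerance r must be non-negative")

    def _pairs(width: int) -> int:
        templ = sliding_window_view(x, width)[: n - m]
        d = np.abs(templ[:, None, :] - templ[None, :, :]).max(axis=-1)
        return int(np.count_nonzero(np.triu(d <= r, k=1)))

    b = _pairs(m)
    a = _pairs(m + 1)
    if a == 0 or b == 0:
        return math.nan
    return float(-math.log(a / b))


@dataclass(frozen=True)
class BoutParameterRecord:
    """Per-bout values of the nine bout-level parameters.

    Complexity fields are NaN when the bout has fewer than 200 retained
    steps (``complexity_defined`` False) or when SampEn is undefined.
    """

    bout_id: int
    cadence: float
    mean_step_time: float
    mean_stride_time: float
    cov_step_time: float
    cov_stride_time: float
    dfa_step: float
    dfa_stride: float
    sampen_step: float
    sampen_stride: float
    complexity_defined: bool

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in BOUT_PARAMETER_NAMES}


@dataclass(frozen=True)
class QuantityRecord:
    """Gait-quantity totals over one participant's kept bouts."""

    n_bouts: int
    total_steps: int
    avg_steps_per_bout: float

    def as_dict(self) -> dict[str, float]:
        return {
            "n_bouts": float(self.n_bouts),
            "total_steps": float(self.total_steps),
            "avg_steps_per_bout": self.avg_steps_per_bout,
        }


def intensity_params(bout: WalkingBout) -> tuple[float, float, float]:
    """(cadence steps/min, mean step time s, mean stride time s)."""
    if bout.n_retained < 2:
        raise UndefinedParameterError("intensity needs >= 2 retained steps")
    mean_step = float(bout.step_intervals.mean())
    strides = bout.stride_intervals()
    mean_stride = float(strides.mean()) if strides.size else math.nan
    return 60.0 / mean_step, mean_step, mean_stride


def variability_params(bout: WalkingBout) -> tuple[float, float]:
    """(CoV of step time, CoV of stride time), as fractions (SD/mean)."""
    steps = bout.step_intervals
    strides = bout.stride_intervals()
    if steps.size < 3 or strides.size < 3:
        raise UndefinedParameterError("variability needs >= 3 intervals per series")
    cov_step = float(steps.std(ddof=1) / steps.mean())
    cov_stride = float(strides.std(ddof=1) / strides.mean())
    return cov_step, cov_stride


def complexity_params(
    bout: WalkingBout,
    dfa_min_box: int = 4,
    dfa_n_boxes: int = 10,
    sampen_m: int = 2,
    sampen_r: float = 0.2,
) -> tuple[float, float, float, float]:
    """(dfa_step, dfa_stride, sampen_step, sampen_stride) on the middle 200 steps.

    Interval series are rebuilt from the central 200-step window (199 step
    intervals, 99 non-overlapping stride intervals) so every bout
    contributes equally sized series to the length-sensitive estimators.
    """
    if not bout.complexity_defined:
        raise UndefinedParameterError(
            f"complexity needs >= 200 retained steps, got {bout.n_retained}"
        )
    mid = extract_middle200(bout)
    step_iv = np.diff(mid)
    idx = 2 * np.arange((mid.size - 1) // 2)
    stride_iv = mid[idx + 2] - mid[idx]
    dfa_s = dfa_exponent(step_iv, min_box=dfa_min_box, n_boxes=dfa_n_boxes)
    dfa_t = dfa_exponent(stride_iv, min_box=dfa_min_box, n_boxes=dfa_n_boxes)
    se_s = sample_entropy(step_iv, m=sampen_m, r_factor=sampen_r)
    se_t = sample_entropy(stride_iv, m=sampen_m, r_factor=sampen_r)
    return dfa_s, dfa_t, se_s, se_t


def quantity_params(bouts) -> QuantityRecord:
    """Totals over kept bouts; step counts use retained (trimmed) steps."""
    n = len(bouts)
    total = int(sum(b.n_retained for b in bouts))
    avg = total / n if n else math.nan
    return QuantityRecord(n_bouts=n, total_steps=total, avg_steps_per_bout=avg)


def compute_bout_parameters(
    bout: WalkingBout,
    bout_id: int = 0,
    dfa_min_box: int = 4,
    dfa_n_boxes: int = 10,
    sampen_m: int = 2,
    sampen_r: float = 0.2,
) -> BoutParameterRecord:
    """All bout-level parameters for one bout; complexity NaN when ineligible."""
    cadence, mean_step, mean_stride = intensity_params(bout)
    cov_step, cov_stride = variability_params(bout)
    if bout.complexity_defined:
        try:
            dfa_s, dfa_t, se_s, se_t = complexity_params(
                bout,
                dfa_min_box=dfa_min_box,
                dfa_n_boxes=dfa_n_boxes,
                sampen_m=sampen_m,
                sampen_r=sampen_r,
            )
        except UndefinedParameterError:
            dfa_s = dfa_t = se_s = se_t = math.nan
    else:
        dfa_s = dfa_t = se_s = se_t = math.nan
    return BoutParameterRecord(
        bout_id=bout_id,
        cadence=cadence,
        mean_step_time=mean_step,
        mean_stride_time=mean_stride,
        cov_step_time=cov_step,
        cov_stride_time=cov_stride,
        dfa_step=dfa_s,
        dfa_stride=dfa_t,
        sampen_step=se_s,
        sampen_stride=se_t,
        complexity_defined=bout.complexity_defined,
    )
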