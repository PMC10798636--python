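"""Phenotype quantification on numeric tables.

Four families of measurements, all operating on plain numeric series —
no image or plate-reader file handling:

* exponential growth-rate fitting: ordinary least squares of ln(OD600)
  against time over a chosen (or automatically selected) window, the
  standard semi-log procedure;
* diauxic-shift analysis: detect the slowdown marking depletion of the
  first substrate, fit the post-shift exponential, and quantify the lag
  as the time lost relative to instantaneous resumption
  (back-extrapolation of the second exponential to the OD at shift onset);
* starvation survival from CFU plating: colony counts, dilution factors
  and plated volumes give densities, and survival is the final/initial
  density ratio in percent;
* soft-agar motility metrics: per-colony area fold changes and the
  fraction of colonies scored as swarming.

OD background subtraction is the caller's responsibility; the module
validates positivity only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import (
    DataError,
    DomainError,
    InsufficientDataError,
    NoRegrowthError,
    NoShiftError,
    SelectionError,
)

__all__ = [
    "ODSeries",
    "ExponentialFit",
    "DiauxicResult",
    "CFUObservation",
    "fit_growth_rate",
    "auto_window",
    "detect_shift",
    "smoothed_log_derivative",
    "diauxic_lag",
    "analyze_diauxie",
    "survival_percent",
    "cfu_density",
    "colony_area_foldchange",
    "swarming_fraction",
]


@dataclass(frozen=True)
class ODSeries:
    """An optical-density (OD600) time series.

    ``times`` in hours, strictly ascending; ``od600`` positive, same
    length (>= 2); ``label`` a free-text condition tag.
    """

    times: np.ndarray
    od600: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "times", np.asarray(self.times, dtype=float))
        object.__setattr__(self, "od600", np.asarray(self.od600, dtype=float))
        if self.times.ndim != 1 or self.times.shape != self.od600.shape:
            raise DataError("times and od600 must be 1-D arrays of equal length")
        if self.times.size < 2:
            raise DataError("an OD series needs at least 2 points")
        if not np.all(np.diff(self.times) > 0):
            raise DataError("times must be strictly ascending")
        if not np.all(self.od600 > 0):
            raise DataError("all od600 values must be > 0")

    def __len__(self) -> int:
        return self.times.size

    @property
    def log_od(self) -> np.ndarray:
        return np.log(self.od600)


@dataclass(frozen=True)
class ExponentialFit:
    """Result of a semi-log exponential fit.

    ``window`` is the half-open index range (start, stop) the fit used.
    ``intercept_log`` is the fitted ln(OD) at t = 0. ``doubling_time`` is
    ln2/growth_rate (inf when the rate is <= 0).
    """

    growth_rate: float
    doubling_time: float
    window: tuple[int, int]
    r_squared: float
    n_points: int
    intercept_log: float


@dataclass(frozen=True)
class DiauxicResult:
    """Quantification of a diauxic shift.

    ``t_shift`` is the onset of first-substrate depletion (h); ``lambda1``
    and ``lambda2`` the pre-/post-shift growth rates (1/h); ``lag`` the
    time lost (h, >= 0) relative to an instantaneous switch.
    """

    t_shift: float
    lambda1: float
    lambda2: float
    lag: float

    def __post_init__(self) -> None:
        if self.lag < 0:
            raise DomainError(f"lag must be >= 0, got {self.lag}")
        if self.lambda1 <= 0 or self.lambda2 <= 0:
            raise DomainError("lambda1 and lambda2 must be > 0")


@dataclass(frozen=True)
class CFUObservation:
    """One plate count: colonies, the dilution plated, and plated volume."""

    colonies: int
    dilution_factor: float
    plated_volume_mL: float

    def __post_init__(self) -> None:
        if self.colonies < 0:
            raise DomainError(f"colonies must be >= 0, got {self.colonies}")
        if self.dilution_factor < 1:
            raise DomainError(
                f"dilution_factor must be >= 1, got {self.dilution_factor}"
            )
        if not self.plated_volume_mL > 0:
            raise DomainError(
                f"plated_volume_mL must be > 0, got {self.plated_volume_mL}"
            )


# ---------------------------------------------------------------------------
# Exponential growth-rate fitting
# ---------------------------------------------------------------------------

def _ols_loglinear(t: np.ndarray, log_y: np.ndarray) -> tuple[float, float, float]:
    """Slope, intercept and R² of log_y ~ t (R² = 1 for a constant series)."""
    t_mean = t.mean()
    y_mean = log_y.mean()
    dt = t - t_mean
    dy = log_y - y_mean
    sxx = float(dt @ dt)
    slope = float(dt @ dy) / sxx
    intercept = y_mean - slope * t_mean
    ss_tot = float(dy @ dy)
    if ss_tot == 0.0:
        return slope, intercept, 1.0
    resid = dy - slope * dt
    r2 = 1.0 - float(resid @ resid) / ss_tot
    return slope, intercept, max(0.0, min(1.0, r2))


def fit_growth_rate(
    series: ODSeries, window: tuple[int, int] | None = None
) -> ExponentialFit:
    """Fit ln(OD600) ~ time by ordinary least squares over ``window``.

    ``window`` is a half-open index range (start, stop); ``None`` fits the
    whole series. At least 4 points are required (steady-state fits in
    this pipeline always use >= 4 time points).
    """
    start, stop = (0, len(series)) if window is None else window
    if not (0 <= start < stop <= len(series)):
        raise DomainError(f"window {(start, stop)} out of range for n={len(series)}")
    n = stop - start
    if n < 4:
        raise InsufficientDataError(f"growth-rate fit needs >= 4 points, got {n}")
    t = series.times[start:stop]
    log_y = series.log_od[start:stop]
    slope, intercept, r2 = _ols_loglinear(t, log_y)
    doubling = math.log(2) / slope if slope > 0 else math.inf
    return ExponentialFit(
        growth_rate=slope,
        doubling_time=doubling,
        window=(start, stop),
        r_squared=r2,
        n_points=n,
        intercept_log=intercept,
    )


def auto_window(
    series: ODSeries, min_points: int = 4, r2_min: float = 0.99
) -> tuple[int, int]:
    """Select the steady-state exponential window automatically.

    Among all contiguous windows of >= ``min_points`` whose semi-log fit
    reaches R² >= ``r2_min``, returns the one with the largest fitted
    growth rate; rate ties (within 1e-9 relative) are broken in favour of
    the longer window, then the earlier start. This automates the manual
    "pick the steady-state points" step.
    """
    if min_points < 4:
        raise DomainError(f"min_points must be >= 4, got {min_points}")
    if not 0 < r2_min <= 1:
        raise DomainError(f"r2_min must lie in (0, 1], got {r2_min}")
    n = len(series)
    best: tuple[int, int] | None = None
    best_rate = -math.inf
    for start in range(0, n - min_points + 1):
        for stop in range(start + min_points, n + 1):
            fit = fit_growth_rate(series, (start, stop))
            if fit.r_squared < r2_min:
                continue
            if best is None:
                best, best_rate = (start, stop), fit.growth_rate
                continue
            tol = 1e-9 * max(1.0, abs(best_rate))
            if fit.growth_rate > best_rate + tol:
                best, best_rate = (start, stop), fit.growth_rate
            elif abs(fit.growth_rate - best_rate) <= tol:
                cur_len = best[1] - best[0]
                new_len = stop - start
                if new_len > cur_len or (new_len == cur_len and start < best[0]):
                    best, best_rate = (start, stop), fit.growth_rate
    if best is None:
        raise SelectionError(
            f"no window of >= {min_points} points reaches r^2 >= {r2_min}"
        )
    return best


# ---------------------------------------------------------------------------
# Diauxic-shift analysis
# ---------------------------------------------------------------------------

def smoothed_log_derivative(series: ODSeries, smooth_points: int = 3) -> np.ndarray:
    """Instantaneous growth rate d ln(OD)/dt, smoothed.

    Centered finite differences (one-sided at the ends) followed by a
    centered moving average over ``smooth_points`` values, normalized at
    the edges so shorter effective windows are averaged correctly.
    """
    if smooth_points < 1 or smooth_points % 2 == 0:
        raise DomainError(f"smooth_points must be odd and >= 1, got {smooth_points}")
    rate = np.gradient(series.log_od, series.times)
    if smooth_points == 1:
        return rate
    kernel = np.ones(smooth_points)
    smoothed = np.convolve(rate, kernel, mode="same")
    counts = np.convolve(np.ones_like(rate), kernel, mode="same")
    return smoothed / counts


def detect_shift(
    series: ODSeries,
    lambda1: float,
    theta: float = 0.5,
    smooth_points: int = 3,
) -> float:
    """First time the instantaneous growth rate drops below θ·λ1.

    ``lambda1`` is the first-phase exponential rate; the shift onset is
    the first time point where the smoothed log-derivative falls below
    ``theta * lambda1``. Raises :class:`NoShiftError` if the rate never
    drops.
    """
    if not 0 < theta < 1:
        raise DomainError(f"theta must lie in (0, 1), got {theta}")
    if not lambda1 > 0:
        raise DomainError(f"lambda1 must be > 0, got {lambda1}")
    rate = smoothed_log_derivative(series, smooth_points)
    below = np.flatnonzero(rate < theta * lambda1)
    if below.size == 0:
        raise NoShiftError(
            f"growth rate never fell below {theta:g} x lambda1 = {theta * lambda1:g}/h"
        )
    return float(series.times[below[0]])


def diauxic_lag(
    series: ODSeries,
    t_shift: float,
    second_window: tuple[int, int],
    lambda1: float | None = None,
    log_od_shift: float | None = None,
) -> DiauxicResult:
    """Quantify the diauxic lag by back-extrapolating the second exponential.

    The post-shift growth phase is fit over ``second_window`` (half-open
    index range, entirely after ``t_shift``, >= 4 points). The lag is the
    horizontal offset between that fitted exponential and the OD reached
    at shift onset:

        lag = t_ref − t_shift − (ln OD_fit(t_ref) − ln OD(t_shift)) / λ2,

    which is independent of the reference point t_ref on the fitted line
    (the fitted values are used, so the identity is exact). A lag of zero
    means regrowth resumed instantly; small negative values arising from
    noise are clamped to 0. ``lambda1`` (pre-shift rate) defaults to a
    fit over all points strictly before ``t_shift``. ``log_od_shift``
    overrides the default single-point interpolation of ln OD at
    ``t_shift`` with a caller-supplied estimate (e.g. a plateau average).
    """
    start, stop = second_window
    if not (0 <= start < stop <= len(series)):
        raise DomainError(f"second_window {(start, stop)} out of range")
    if series.times[start] <= t_shift:
        raise DomainError("second_window must lie entirely after t_shift")
    if stop - start < 4:
        raise InsufficientDataError("second_window needs >= 4 points")

    if lambda1 is None:
        n_pre = int(np.searchsorted(series.times, t_shift, side="left"))
        if n_pre < 4:
            raise InsufficientDataError(
                "need >= 4 points before t_shift to fit lambda1 (or pass lambda1)"
            )
        lambda1 = fit_growth_rate(series, (0, n_pre)).growth_rate
    if lambda1 <= 0:
        raise DomainError(f"lambda1 must be > 0, got {lambda1}")

    fit2 = fit_growth_rate(series, (start, stop))
    if fit2.growth_rate <= 1e-12:
        raise NoRegrowthError(
            f"post-shift rate {fit2.growth_rate:.3g}/h is not positive regrowth"
        )
    lambda2 = fit2.growth_rate
    if log_od_shift is None:
        log_od_shift = float(np.interp(t_shift, series.times, series.log_od))
    t_ref = float(series.times[start])
    log_od_ref = fit2.intercept_log + lambda2 * t_ref
    lag = t_ref - t_shift - (log_od_ref - log_od_shift) / lambda2
    return DiauxicResult(
        t_shift=t_shift, lambda1=lambda1, lambda2=lambda2, lag=max(lag, 0.0)
    )


def analyze_diauxie(
    series: ODSeries,
    theta: float = 0.5,
    smooth_points: int = 3,
    first_window: tuple[int, int] | None = None,
) -> DiauxicResult:
    """End-to-end diauxic-shift pipeline on a single OD series.

    Steps: (1) fit the first-phase rate λ1 (default window: the first
    quarter of the series, assumed to lie within the first exponential);
    (2) detect the shift onset where the smoothed rate drops below θ·λ1;
    (3) detect regrowth — the first time after the shift where the
    smoothed rate recovers to half the terminal rate, sustained for
    ``smooth_points`` consecutive samples; (4) fit λ2 from just after
    regrowth to the end of the series and back-extrapolate to get the lag.

    ``smooth_points`` (odd) is the moving-average width for the rate
    estimate; widen it for noisy plate-reader data.
    """
    n = len(series)
    if first_window is None:
        first_window = (0, max(4, n // 4))
    lambda1 = fit_growth_rate(series, first_window).growth_rate
    if lambda1 <= 0:
        raise NoShiftError("no positive first-phase growth rate")
    t_shift = detect_shift(series, lambda1, theta=theta, smooth_points=smooth_points)

    rate = smoothed_log_derivative(series, smooth_points)
    shift_idx = int(np.searchsorted(series.times, t_shift, side="left"))
    # terminal rate from fully-smoothed interior points (the trailing
    # half-window is edge-dominated and far noisier)
    half = smooth_points // 2
    k = max(5, smooth_points)
    tail = rate[max(n - half - k, 0): max(n - half, 1)]
    rate_end = float(np.median(tail))
    if rate_end <= 0:
        raise NoRegrowthError("terminal growth rate is not positive")
    above = rate >= 0.5 * rate_end
    run = 0
    regrow_idx = None
    for i in range(shift_idx + 1, n):
        run = run + 1 if above[i] else 0
        if run >= smooth_points:
            regrow_idx = i - smooth_points + 1
            break
    if regrow_idx is None:
        raise NoRegrowthError("growth rate never recovered after the shift")
    start = regrow_idx + smooth_points // 2 + 1  # clear the smoothed transition
    if n - start < 4:
        raise NoRegrowthError("fewer than 4 points available after regrowth")
    # Estimate ln OD at the shift from the observed plateau when one exists:
    # averaging the flat stretch between shift and regrowth beats reading a
    # single noisy point. Trim half a smoothing window at both edges so the
    # transition regions do not leak in.
    lo = shift_idx + 1 + half
    hi = regrow_idx - half
    log_od_shift = float(np.mean(series.log_od[lo:hi])) if hi - lo >= 3 else None
    return diauxic_lag(
        series, t_shift, (start, n), lambda1=lambda1, log_od_shift=log_od_shift
    )


# ---------------------------------------------------------------------------
# Starvation survival (CFU plating)
# ---------------------------------------------------------------------------

def cfu_density(obs: CFUObservation) -> float:
    """Viable-cell density in CFU/mL implied by one plate count."""
    return obs.colonies * obs.dilution_factor / obs.plated_volume_mL


def _mean_density(observations) -> float:
    if isinstance(observations, CFUObservation):
        observations = [observations]
    observations = list(observations)
    if not observations:
        raise DomainError("need at least one CFU observation")
    return float(np.mean([cfu_density(o) for o in observations]))


def survival_percent(
    initial: CFUObservation | Sequence[CFUObservation],
    final: CFUObservation | Sequence[CFUObservation],
) -> float:
    """Survival after starvation as a percentage of initial viable cells.

    Densities (colonies × dilution / plated volume) are averaged over
    replicates at each timepoint before taking the ratio; the result is
    100 × final/initial. The statistic is invariant to the dilution used,
    provided counts and dilution change consistently.
    """
    d0 = _mean_density(initial)
    d1 = _mean_density(final)
    if d0 <= 0:
        raise DomainError("initial viable-cell density must be > 0")
    return 100.0 * d1 / d0


# ---------------------------------------------------------------------------
# Motility metrics
# ---------------------------------------------------------------------------

def colony_area_foldchange(areas_t0, areas_t1) -> tuple[float, float]:
    """Mean and sample SD of per-colony area fold changes between timepoints.

    ``areas_t0`` and ``areas_t1`` are paired areas of the same colonies
    at two imaging days; fold = area_t1/area_t0 per colony.
    """
    a0 = np.asarray(areas_t0, dtype=float)
    a1 = np.asarray(areas_t1, dtype=float)
    if a0.shape != a1.shape or a0.ndim != 1 or a0.size == 0:
        raise DataError("colony areas must be non-empty paired 1-D vectors")
    if np.any(a0 <= 0) or np.any(a1 <= 0):
        raise DataError("colony areas must be > 0")
    folds = a1 / a0
    sd = float(np.std(folds, ddof=1)) if folds.size > 1 else 0.0
    return float(np.mean(folds)), sd


def swarming_fraction(colonies, area_threshold: float | None = None) -> float:
    """Fraction of colonies scored as swarming.

    With ``area_threshold`` given, a colony swarms when its area exceeds
    the threshold; otherwise ``colonies`` is interpreted as boolean
    swarming flags.
    """
    values = np.asarray(colonies)
    if values.ndim != 1 or values.size == 0:
        raise DomainError("need at least one colony")
    if area_threshold is None:
        flags = values.astype(bool)
    else:
        flags = values.astype(float) > area_threshold
    return float(np.count_nonzero(flags)) / values.size
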