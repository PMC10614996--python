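"""Growth statistics of well time courses.

Turns an observed area series (or a simulated trajectory) into
per-capita growth rates, threshold-crossing times, a growth-pattern
class, and the least-squares comparison of candidate functional forms
for the density-dependent birth probability.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .branching import WellTrajectory
from .params import CELLS_PER_AREA_UNIT, ModelParams

__all__ = [
    "ObservedWell",
    "RatePoint",
    "FormFit",
    "GROWTH_PATTERNS",
    "area_to_cells",
    "cells_to_area",
    "per_capita_rates",
    "time_between_thresholds",
    "classify_growth_pattern",
    "exponential_phase_rate",
    "fit_birth_probability_form",
]

GROWTH_PATTERNS = (
    "extinct",
    "slow_no_exponential",
    "delayed_exponential",
    "normal_exponential",
)

#: per-day rate above which an interval counts as exponential growth
EXPONENTIAL_RATE_THRESHOLD = 0.3

#: intervals starting before this day are ignored by the pattern
#: detector (small-population observations are unreliable)
PATTERN_DETECTOR_FROM_DAY = 8.0


@dataclass
class ObservedWell:
    """Daily area-unit observations for one well.

    ``days`` are strictly increasing observation days; ``areas`` are in
    area units (1 unit ~ 500 cells).
    """

    well_id: str
    group_N0: int
    days: np.ndarray
    areas: np.ndarray

    def __post_init__(self) -> None:
        self.days = np.asarray(self.days, dtype=float)
        self.areas = np.asarray(self.areas, dtype=float)
        if self.days.shape != self.areas.shape:
            raise ValueError("days and areas must have equal length")
        if np.any(np.diff(self.days) <= 0):
            raise ValueError("days must be strictly increasing")
        if np.any(self.areas < 0):
            raise ValueError("areas must be non-negative")

    @property
    def cells(self) -> np.ndarray:
        return area_to_cells(self.areas)

    @classmethod
    def from_trajectory(
        cls, traj: WellTrajectory, observe_from_day: float = 0.0, well_id: str | None = None
    ) -> "ObservedWell":
        days, totals = traj.daily_totals()
        mask = days >= observe_from_day
        return cls(
            well_id=well_id if well_id is not None else traj.well_id,
            group_N0=traj.N0,
            days=days[mask],
            areas=cells_to_area(totals[mask]),
        )


@dataclass(frozen=True)
class RatePoint:
    """Per-capita growth rate attached to the interval-start population."""

    N: float
    rate: float
    well_id: str
    day: float


@dataclass(frozen=True)
class FormFit:
    chosen_form: str
    a: float
    b: float
    mse_by_form: dict[str, float]
    coeffs_by_form: dict[str, tuple[float, float]]


def area_to_cells(area):
    """500 cells per area unit; real-valued, no rounding."""
    area = np.asarray(area, dtype=float)
    if np.any(area < 0):
        raise ValueError("area must be non-negative")
    out = area * CELLS_PER_AREA_UNIT
    return float(out) if out.ndim == 0 else out


def cells_to_area(cells):
    cells = np.asarray(cells, dtype=float)
    out = cells / CELLS_PER_AREA_UNIT
    return float(out) if out.ndim == 0 else out


def _days_cells(well: ObservedWell | WellTrajectory) -> tuple[np.ndarray, np.ndarray, str]:
    if isinstance(well, WellTrajectory):
        days, totals = well.daily_totals()
        return days, totals.astype(float), well.well_id
    return well.days, well.cells, well.well_id


def per_capita_rates(well: ObservedWell | WellTrajectory) -> list[RatePoint]:
    """Daily log-ratio growth rates, one per observation interval.

    rate = ln(N(t2)/N(t1)) / (t2 - t1), attached to the interval-start
    population.  Intervals with a zero endpoint are skipped.
    """
    days, cells, well_id = _days_cells(well)
    points = []
    for i in range(len(days) - 1):
        n1, n2 = cells[i], cells[i + 1]
        if n1 <= 0 or n2 <= 0:
            continue
        dt = days[i + 1] - days[i]
        points.append(
            RatePoint(N=float(n1), rate=float(math.log(n2 / n1) / dt), well_id=well_id, day=float(days[i]))
        )
    return points


def _crossing_time(days: np.ndarray, cells: np.ndarray, threshold: float) -> float | None:
    """Day at which the series crosses ``threshold`` cells, by log-linear
    interpolation; extrapolates backwards from the first two positive
    observations if the series starts above the threshold."""
    pos = cells > 0
    days, cells = days[pos], cells[pos]
    if len(days) == 0 or np.max(cells) < threshold:
        return None
    log_thr = math.log(threshold)
    log_cells = np.log(cells)
    if cells[0] >= threshold:
        if len(days) < 2 or log_cells[1] == log_cells[0]:
            return float(days[0])
        slope = (log_cells[1] - log_cells[0]) / (days[1] - days[0])
        if slope <= 0:
            return float(days[0])
        return float(days[0] - (log_cells[0] - log_thr) / slope)
    idx = int(np.argmax(cells >= threshold))
    d1, d2 = days[idx - 1], days[idx]
    l1, l2 = log_cells[idx - 1], log_cells[idx]
    return float(d1 + (log_thr - l1) / (l2 - l1) * (d2 - d1))


def time_between_thresholds(
    well: ObservedWell | WellTrajectory, lo_cells: float, hi_cells: float
) -> float | None:
    """Days taken to grow from ``lo_cells`` to ``hi_cells``.

    Crossing times come from log-linear interpolation between bracketing
    observations.  Returns None if the series never reaches
    ``hi_cells``.  Invariant under uniform rescaling of the series, so
    areas and cells give the same answer for rescaled thresholds.
    """
    if lo_cells == hi_cells:
        return 0.0
    days, cells, _ = _days_cells(well)
    t_hi = _crossing_time(days, cells, hi_cells)
    if t_hi is None:
        return None
    t_lo = _crossing_time(days, cells, lo_cells)
    if t_lo is None:  # series never as low as lo; extrapolation failed
        return None
    return t_hi - t_lo


def classify_growth_pattern(
    well: ObservedWell | WellTrajectory, params: ModelParams | None = None
) -> str:
    """Assign one of the four growth-pattern classes.

    * extinct: final population below one cell.
    * normal_exponential: final population at least C/2.
    * delayed_exponential: final at least 1000 cells, or some reliable
      interval starting on/after Day 8 has a per-day rate >= 0.3.
    * slow_no_exponential: everything else (grew, but never
      exponentially, staying under 1000 cells).

    Requires the series to extend through Day 23.  The rate-based
    detector only trusts intervals starting at >= 5 area units (2500
    cells) and on/after Day 8: below that floor observed rates are
    dominated by small-count noise, so a single noisy daily interval
    would otherwise masquerade as exponential growth.
    """
    params = params or ModelParams()
    days, cells, _ = _days_cells(well)
    if len(days) == 0 or days[-1] < 23.0:
        raise ValueError("classification needs observations through Day 23")
    final = cells[-1]
    if final < 1.0:
        return "extinct"
    if final >= params.C / 2.0:
        return "normal_exponential"
    if final >= 1000.0:
        return "delayed_exponential"
    floor = area_to_cells(5.0)
    for pt in per_capita_rates(well):
        if (
            pt.day >= PATTERN_DETECTOR_FROM_DAY
            and pt.N >= floor
            and pt.rate >= EXPONENTIAL_RATE_THRESHOLD
        ):
            return "delayed_exponential"
    return "slow_no_exponential"


def exponential_phase_rate(
    well: ObservedWell | WellTrajectory,
    window_lo: float = 5.0,
    window_hi: float = 20.0,
) -> float | None:
    """Mean daily rate while the population is mid-exponential phase.

    The window is in area units (default 5-20, i.e. 2500-10000 cells):
    below it the data are unreliable, above it crowding slows growth.
    Unweighted mean over intervals whose start population lies in the
    window; None if no interval qualifies.
    """
    lo, hi = area_to_cells(window_lo), area_to_cells(window_hi)
    rates = [pt.rate for pt in per_capita_rates(well) if lo <= pt.N <= hi]
    if not rates:
        return None
    return float(np.mean(rates))


_FORMS = {
    "linear": lambda N: N,
    "quadratic": lambda N: N ** 2,
    "logarithmic": lambda N: np.log(N),
}


def fit_birth_probability_form(
    rate_points: Iterable[RatePoint],
    C: float,
    n_bins: int = 20,
) -> FormFit:
    """Compare linear, quadratic and logarithmic forms for g(N).

    Rates are binned by population over (0, C] in ``n_bins`` equal-width
    bins, bin-averaged, and halved (the per-day per-capita rate is
    approximately twice the per-half-day birth probability).  Each form
    g = a + b*f(N) is then fitted to the binned curve by least squares;
    the form with the smallest mean squared error wins.
    """
    points = list(rate_points)
    if not points:
        raise ValueError("no rate points supplied")
    N = np.array([p.N for p in points])
    rate = np.array([p.rate for p in points])
    edges = np.linspace(0.0, C, n_bins + 1)
    idx = np.clip(np.digitize(N, edges) - 1, 0, n_bins - 1)
    bin_N, bin_g = [], []
    for b in range(n_bins):
        mask = idx == b
        if not np.any(mask):
            continue
        bin_N.append(N[mask].mean())
        bin_g.append(rate[mask].mean() / 2.0)
    if len(bin_N) < 3:
        raise ValueError("need at least 3 populated population bins")
    bin_N, bin_g = np.array(bin_N), np.array(bin_g)
    mse_by_form: dict[str, float] = {}
    coeffs: dict[str, tuple[float, float]] = {}
    for name, transform in _FORMS.items():
        x = transform(bin_N)
        b, a = np.polyfit(x, bin_g, 1)
        resid = bin_g - (a + b * x)
        mse_by_form[name] = float(np.mean(resid ** 2))
        coeffs[name] = (float(a), float(b))
    chosen = min(mse_by_form, key=mse_by_form.get)
    a, b = coeffs[chosen]
    return FormFit(chosen_form=chosen, a=a, b=b, mse_by_form=mse_by_form, coeffs_by_form=coeffs)
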