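"""Radiocarbon calibration and climate-event time binning.

Single-date calibration against a tabulated calibration curve (IntCal-style
layout: calendar age, 14C age, curve error), highest-posterior-density
interval construction, and assignment of samples to one of seven
climate-event time bins spanning the early Holocene back to early Oxygen
Isotope Stage 3 (8,190–50,000 cal BP).

No reservoir offsets or Bayesian sequence modelling — only the single-date
posterior on a regular calendar grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "TimeBin",
    "DEFAULT_TIME_BINS",
    "CalibrationCurve",
    "CalibratedAge",
    "calibrate_radiocarbon",
    "assign_time_bin",
    "validate_bins",
]

EXCLUDED = "EXCLUDED"

#: Study window in calendar years BP: samples older/younger are excluded.
STUDY_WINDOW_CAL_BP = (8_190.0, 50_000.0)


@dataclass(frozen=True)
class TimeBin:
    """One climate-event time bin.

    ``upper_cal_bp`` is the older limit (larger cal BP number) and
    ``lower_cal_bp`` the younger limit, following the usual convention of
    bin tables printed oldest-limit-first.  A median age m belongs to the
    bin with ``lower_cal_bp <= m < upper_cal_bp``, so a boundary-valued
    median belongs to the bin in which it is the younger limit, exactly
    once.  ``climate_time_step`` is the palaeoclimate-simulation time step
    (years BP) used for covariate extraction in this bin.
    """

    name: str
    upper_cal_bp: float
    lower_cal_bp: float
    climate_time_step: int

    def __post_init__(self) -> None:
        if not self.upper_cal_bp > self.lower_cal_bp:
            raise ValueError(
                f"bin {self.name}: upper (older) limit {self.upper_cal_bp} "
                f"must exceed lower (younger) limit {self.lower_cal_bp}"
            )

    def contains(self, median_cal_bp: float) -> bool:
        if self.lower_cal_bp <= median_cal_bp < self.upper_cal_bp:
            return True
        # the oldest bin closes the study window at exactly 50,000 cal BP
        return (
            median_cal_bp == STUDY_WINDOW_CAL_BP[1]
            and self.upper_cal_bp == STUDY_WINDOW_CAL_BP[1]
        )


#: The seven climate-event bins with their climate-model time steps.
DEFAULT_TIME_BINS: tuple[TimeBin, ...] = (
    TimeBin("EH", 11_650, 8_190, 11_000),
    TimeBin("YD", 12_850, 11_650, 12_000),
    TimeBin("LGI", 14_650, 12_850, 14_000),
    TimeBin("LGT", 19_500, 14_650, 15_000),
    TimeBin("LGM", 27_500, 19_500, 24_000),
    TimeBin("LOIS3", 39_850, 27_500, 36_000),
    TimeBin("EOIS3", 50_000, 39_850, 42_000),
)


def validate_bins(bins: tuple[TimeBin, ...] | list[TimeBin]) -> None:
    """Check bins are non-overlapping and contiguous over the study window."""
    ordered = sorted(bins, key=lambda b: b.lower_cal_bp)
    for a, b in zip(ordered, ordered[1:]):
        if a.upper_cal_bp > b.lower_cal_bp:
            raise ValueError(f"bins {a.name} and {b.name} overlap")
        if a.upper_cal_bp < b.lower_cal_bp:
            raise ValueError(f"gap between bins {a.name} and {b.name}")
    if ordered[0].lower_cal_bp != STUDY_WINDOW_CAL_BP[0] or ordered[-1].upper_cal_bp != STUDY_WINDOW_CAL_BP[1]:
        raise ValueError(
            f"bins must span {STUDY_WINDOW_CAL_BP[0]}-{STUDY_WINDOW_CAL_BP[1]} cal BP"
        )


@dataclass
class CalibrationCurve:
    """Tabulated calibration curve: calendar grid, 14C age, curve error."""

    cal_age_grid: np.ndarray
    c14_age: np.ndarray
    curve_error: np.ndarray

    def __post_init__(self) -> None:
        self.cal_age_grid = np.asarray(self.cal_age_grid, dtype=float)
        self.c14_age = np.asarray(self.c14_age, dtype=float)
        self.curve_error = np.asarray(self.curve_error, dtype=float)
        if not (len(self.cal_age_grid) == len(self.c14_age) == len(self.curve_error)):
            raise ValueError("curve columns must have equal length")
        if np.any(np.diff(self.cal_age_grid) <= 0):
            raise ValueError("cal_age_grid must be strictly increasing")
        if np.any(self.curve_error <= 0):
            raise ValueError("curve_error must be positive everywhere")

    @classmethod
    def from_file(cls, path: str | Path) -> "CalibrationCurve":
        """Read a 3-column whitespace- or comma-separated curve table.

        Lines starting with ``#`` are treated as comments; a non-numeric
        first row is treated as a header.  Rows are sorted by calendar age.
        """
        df = pd.read_csv(path, sep=None, engine="python", comment="#")
        try:
            float(df.columns[0])
            df = pd.read_csv(path, sep=None, engine="python", comment="#", header=None)
        except (TypeError, ValueError):
            pass
        if df.shape[1] < 3:
            raise ValueError(f"calibration curve {path} must have >= 3 columns")
        arr = df.iloc[:, :3].to_numpy(dtype=float)
        arr = arr[np.argsort(arr[:, 0])]
        return cls(arr[:, 0], arr[:, 1], arr[:, 2])


@dataclass
class CalibratedAge:
    """Calibrated-age posterior on a calendar grid.

    ``median_cal_bp`` is the median of the posterior restricted to the
    95.4% HPD region (renormalized); ``median_full_cal_bp`` is the median
    of the full posterior.  Both are reported so the binning convention is
    auditable.
    """

    posterior_grid: np.ndarray
    posterior_mass: np.ndarray
    hpd_954: list[tuple[float, float]]
    median_cal_bp: float
    median_full_cal_bp: float = field(default=np.nan)


def _mass_median(grid: np.ndarray, mass: np.ndarray) -> float:
    cum = np.cumsum(mass) / mass.sum()
    return float(grid[int(np.searchsorted(cum, 0.5))])


def calibrate_radiocarbon(
    c14_age: float,
    c14_error: float,
    curve: CalibrationCurve,
    grid_step: float = 5.0,
    hpd_level: float = 0.954,
) -> CalibratedAge:
    """Calibrate a single radiocarbon date against a curve.

    The posterior over calendar age t on a regular grid is

        p(t) ∝ exp(-(y - mu(t))^2 / (2 (sigma^2 + sigma_c(t)^2)))
               / sqrt(sigma^2 + sigma_c(t)^2)

    with y the lab 14C age, sigma its error, and (mu, sigma_c) the curve
    interpolated to the grid.  The HPD region is built by greedy
    highest-density cell selection and merged into intervals.
    """
    if c14_error <= 0:
        raise ValueError("c14_error must be > 0")
    lo14 = curve.c14_age.min() - 5 * c14_error
    hi14 = curve.c14_age.max() + 5 * c14_error
    if not (lo14 <= c14_age <= hi14):
        raise ValueError(
            f"14C age {c14_age} outside curve support [{curve.c14_age.min()}, "
            f"{curve.c14_age.max()}] +/- 5 sigma"
        )
    grid = np.arange(curve.cal_age_grid[0], curve.cal_age_grid[-1] + grid_step / 2, grid_step)
    mu = np.interp(grid, curve.cal_age_grid, curve.c14_age)
    sc = np.interp(grid, curve.cal_age_grid, curve.curve_error)
    s2 = c14_error**2 + sc**2
    logd = -((c14_age - mu) ** 2) / (2 * s2) - 0.5 * np.log(s2)
    dens = np.exp(logd - logd.max())
    total = dens.sum()
    if total <= 0 or not np.isfinite(total):
        raise ValueError("zero posterior mass: date incompatible with curve")
    mass = dens / total

    order = np.argsort(mass)[::-1]
    cum = np.cumsum(mass[order])
    k = int(np.searchsorted(cum, hpd_level)) + 1
    in_hpd = np.zeros(len(grid), dtype=bool)
    in_hpd[order[:k]] = True
    # merge selected cells into contiguous intervals
    intervals: list[tuple[float, float]] = []
    idx = np.flatnonzero(in_hpd)
    start = idx[0]
    prev = idx[0]
    for i in idx[1:]:
        if i != prev + 1:
            intervals.append((float(grid[start]), float(grid[prev])))
            start = i
        prev = i
    intervals.append((float(grid[start]), float(grid[prev])))

    hpd_mass = np.where(in_hpd, mass, 0.0)
    return CalibratedAge(
        posterior_grid=grid,
        posterior_mass=mass,
        hpd_954=intervals,
        median_cal_bp=_mass_median(grid, hpd_mass),
        median_full_cal_bp=_mass_median(grid, mass),
    )


def assign_time_bin(
    median_cal_bp: float | None = None,
    bins: tuple[TimeBin, ...] = DEFAULT_TIME_BINS,
    *,
    dating_basis: str = "direct",
    context_age_bin: str | None = None,
    context_secure: bool = True,
) -> str:
    """Assign a sample to a time bin, or ``EXCLUDED``.

    Directly dated samples are binned by the median of their calibrated
    age; context-dated samples take their declared bin if it names a valid
    bin and the assignment is secure.  Samples whose median falls outside
    the study window, or whose context assignment is absent or insecure,
    are excluded.
    """
    validate_bins(bins)
    if dating_basis == "context":
        if not context_secure or context_age_bin is None:
            return EXCLUDED
        names = {b.name for b in bins}
        return context_age_bin if context_age_bin in names else EXCLUDED
    if median_cal_bp is None or not np.isfinite(median_cal_bp):
        return EXCLUDED
    for b in bins:
        if b.contains(median_cal_bp):
            return b.name
    return EXCLUDED
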