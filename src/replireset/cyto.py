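"""Flow-cytometry and plate-reader quantifications.

Covers the replication run-out readouts: DNA-content (DAPI) peak detection
on per-event intensities, a linear DAPI-signal to chromosome-number
calibration from control peaks, per-cell chromosome-fraction summaries, and
the simpler bulk quantifications (fluorescent-reporter normalisation,
plating viability, exponential-phase OD increment).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal, stats

__all__ = [
    "PeakSet",
    "ChromosomeCalibration",
    "detect_peaks",
    "fit_chromosome_calibration",
    "chromosome_fractions",
    "reporter_bulk_normalize",
    "plating_viability",
    "exponential_increment",
]

MIN_EVENTS = 100
DEFAULT_MIN_PROMINENCE = 0.05  # fraction of the maximum density
DEFAULT_TOLERANCE = 0.45  # chromosome units for fraction assignment
GRID_POINTS = 1024


@dataclass(frozen=True)
class PeakSet:
    """Detected intensity peaks: ascending positions (AU) and prominences."""

    positions: np.ndarray
    prominences: np.ndarray
    grid: np.ndarray
    density: np.ndarray

    def __len__(self) -> int:
        return len(self.positions)


@dataclass(frozen=True)
class ChromosomeCalibration:
    """Linear DAPI-signal -> chromosome-number map: signal = slope*n + intercept."""

    slope: float
    intercept: float
    r2: float

    def __post_init__(self):
        if self.slope <= 0:
            raise ValueError("calibration slope must be positive")

    def signal(self, n_chromosomes) -> np.ndarray:
        return self.slope * np.asarray(n_chromosomes, dtype=float) + self.intercept

    def chromosomes(self, signal_au) -> np.ndarray:
        return (np.asarray(signal_au, dtype=float) - self.intercept) / self.slope


def detect_peaks(
    values,
    bandwidth: float | str = "silverman",
    min_prominence: float = DEFAULT_MIN_PROMINENCE,
    grid_points: int = GRID_POINTS,
) -> PeakSet:
    """Find modes of a per-event intensity distribution.

    A Gaussian-kernel density estimate is evaluated on a fixed grid and
    peaks are the grid points where the first derivative of the density
    crosses from positive to negative (second derivative negative), kept if
    their prominence exceeds ``min_prominence`` times the maximum density.

    ``bandwidth`` is either an absolute kernel width in AU or
    ``"silverman"``/``"scott"`` for the usual reference rules.
    """
    values = np.asarray(values, dtype=float)
    if values.size < MIN_EVENTS:
        raise ValueError(f"need at least {MIN_EVENTS} events, got {values.size}")
    if not np.all(np.isfinite(values)) or np.any(values < 0):
        raise ValueError("intensities must be finite and non-negative")
    if isinstance(bandwidth, str):
        kde = stats.gaussian_kde(values, bw_method=bandwidth)
    else:
        if bandwidth <= 0:
            raise ValueError("bandwidth must be positive")
        kde = stats.gaussian_kde(values, bw_method=bandwidth / values.std(ddof=1))
    lo = max(0.0, values.min() - 3 * np.sqrt(kde.covariance[0, 0]))
    hi = values.max() + 3 * np.sqrt(kde.covariance[0, 0])
    grid = np.linspace(lo, hi, grid_points)
    density = kde(grid)
    idx, props = signal.find_peaks(density, prominence=min_prominence * density.max())
    return PeakSet(
        positions=grid[idx],
        prominences=props["prominences"],
        grid=grid,
        density=density,
    )


def fit_chromosome_calibration(
    peak_positions, assigned_counts
) -> ChromosomeCalibration:
    """Least-squares line through (chromosome count, peak signal) pairs.

    Signal is regressed on the assigned integer chromosome number (the way
    control peaks are plotted) and the fit is inverted for conversion.
    """
    x = np.asarray(assigned_counts, dtype=float)
    y = np.asarray(peak_positions, dtype=float)
    if x.size != y.size or x.size < 2:
        raise ValueError("need at least two (peak, count) pairs")
    if len(np.unique(x)) < 2:
        raise ValueError("assigned chromosome counts must be distinct")
    res = stats.linregress(x, y)
    return ChromosomeCalibration(
        slope=float(res.slope), intercept=float(res.intercept), r2=float(res.rvalue**2)
    )


def chromosome_fractions(
    values,
    calibration: ChromosomeCalibration,
    targets,
    tolerance: float = DEFAULT_TOLERANCE,
) -> pd.Series:
    """Fraction of events near each integer chromosome number.

    Each event's chromosome estimate is the inverted calibration; the
    fraction at target n counts events with ``|estimate - n| <= tolerance``
    over all events.  ``tolerance`` must stay below 0.5 so assignments to
    adjacent integers cannot overlap.
    """
    if not (0 < tolerance < 0.5):
        raise ValueError("tolerance must be in (0, 0.5) chromosomes")
    values = np.asarray(values, dtype=float)
    est = calibration.chromosomes(values)
    fractions = {
        int(n): float(np.mean(np.abs(est - n) <= tolerance)) for n in targets
    }
    return pd.Series(fractions, name="fraction")


def reporter_bulk_normalize(
    measurements: pd.DataFrame, untreated_ids
) -> pd.DataFrame:
    """Blank-subtracted, OD-normalised reporter signal scaled to untreated.

    ``measurements`` needs columns sample_id, od600, od_blank, fluor,
    fluor_blank.  Each sample's value is (fluor - fluor_blank) /
    (od600 - od_blank); all values are then divided by the mean value of
    the untreated samples.
    """
    df = measurements.copy()
    od = df["od600"] - df["od_blank"]
    if np.any(od <= 0):
        bad = df.loc[od <= 0, "sample_id"].tolist()
        raise ValueError(f"samples with OD600 at or below blank: {bad}")
    raw = (df["fluor"] - df["fluor_blank"]) / od
    untreated = df["sample_id"].isin(list(untreated_ids))
    if not untreated.any():
        raise ValueError("no untreated samples found")
    df["normalized_value"] = raw / raw[untreated].mean()
    return df


def plating_viability(
    selective_count: float,
    titer_count: float,
    selective_dilution: float = 1.0,
    titer_dilution: float = 1.0,
    selective_volume: float = 1.0,
    titer_volume: float = 1.0,
) -> float:
    """Percent survival from selective vs titer plate colony counts.

    survival% = 100 * (selective CFU/ml) / (titer CFU/ml) with
    CFU/ml = colonies * dilution / plated volume.
    """
    if titer_count <= 0:
        raise ValueError("titer plate has no colonies; survival undefined")
    if selective_count < 0:
        raise ValueError("colony counts must be non-negative")
    if selective_dilution < 1 or titer_dilution < 1:
        raise ValueError("dilution factors must be >= 1")
    selective_cfu = selective_count * selective_dilution / selective_volume
    titer_cfu = titer_count * titer_dilution / titer_volume
    return 100.0 * selective_cfu / titer_cfu


def viability_summary(percents) -> dict:
    """Mean percent survival with a 95% t-interval across replicates."""
    vals = np.asarray(percents, dtype=float)
    n = vals.size
    mean = float(vals.mean())
    if n < 2:
        return {"mean": mean, "ci95_lo": np.nan, "ci95_hi": np.nan, "n": n}
    sem = vals.std(ddof=1) / np.sqrt(n)
    half = float(stats.t.ppf(0.975, n - 1) * sem)
    return {"mean": mean, "ci95_lo": mean - half, "ci95_hi": mean + half, "n": n}


def exponential_increment(
    times_h, od600, t_start: float = 5.5, t_end: float = 6.5, max_gap_h: float = 0.125
) -> float:
    """OD600 increment between two growth-curve timepoints.

    Returns OD(t_end) - OD(t_start) using the nearest sampled points; each
    must lie within ``max_gap_h`` hours (half the 15-min sampling cadence)
    of the requested time.
    """
    times = np.asarray(times_h, dtype=float)
    od = np.asarray(od600, dtype=float)
    if times.size != od.size or times.size == 0:
        raise ValueError("times and OD series must be non-empty and aligned")
    vals = []
    for t in (t_start, t_end):
        i = int(np.argmin(np.abs(times - t)))
        if abs(times[i] - t) > max_gap_h:
            raise ValueError(f"no OD sample within {max_gap_h} h of t={t} h")
        vals.append(od[i])
    return float(vals[1] - vals[0])
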