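"""In-vivo extrusion-speed and spiraling-rate estimators.

These are deliberately simple arithmetic estimators applied to time series
of loop sizes (from P(s) analysis of synchronized time courses) and of
helix-turn genomic periods (from second-diagonal positions). Times are in
minutes since release from the G2 arrest unless a function says otherwise;
speeds are reported in kb/s. Rounding to two significant figures is applied
only in reports; raw values are retained.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "TimeSeries",
    "SpeedEstimate",
    "speed_endpoint",
    "speed_increment",
    "speed_gap_closure",
    "spiral_growth_rate",
    "volume_fold_from_area_fold",
    "gyre_size_check",
    "SECONDS_PER_MINUTE",
]

SECONDS_PER_MINUTE = 60.0


def minutes_to_seconds(t_min: float) -> float:
    return t_min * SECONDS_PER_MINUTE


@dataclass
class TimeSeries:
    """Measurement series: times in minutes, values in the unit of ``kind``.

    kind is one of 'loop_kb', 'period_mb', 'area_fold'.
    """

    times_min: np.ndarray
    values: np.ndarray
    kind: str = "loop_kb"

    def __post_init__(self) -> None:
        self.times_min = np.asarray(self.times_min, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if len(self.times_min) != len(self.values):
            raise ValueError("times and values must have equal length")
        if np.any(np.diff(self.times_min) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.values < 0):
            raise ValueError("values must be non-negative")


@dataclass
class SpeedEstimate:
    value_kb_s: float
    method: str
    inputs: dict = field(default_factory=dict)
    lower_bound: bool = False

    def __post_init__(self) -> None:
        if self.value_kb_s < 0:
            raise ValueError("speed must be >= 0")

    @property
    def rounded(self) -> float:
        """Two significant figures, the reporting convention."""
        v = self.value_kb_s
        if v == 0:
            return 0.0
        from math import floor, log10
        return round(v, -int(floor(log10(abs(v)))) + 1)


def speed_endpoint(loop_kb: float, elapsed_s: float) -> SpeedEstimate:
    """Loop size divided by the time taken to extrude it.

    E.g. a 400 kb loop present 5 min after condensin activation gives
    ~1.3 kb/s. An unknown activation delay makes this an upper bound on
    elapsed time, hence a conservative speed.
    """
    if elapsed_s <= 0:
        raise ValueError("elapsed time must be positive")
    if loop_kb < 0:
        raise ValueError("loop size must be >= 0")
    return SpeedEstimate(loop_kb / elapsed_s, "endpoint",
                         {"loop_kb": loop_kb, "elapsed_s": elapsed_s})


def speed_increment(series: TimeSeries, t0_min: float | None = None,
                    t1_min: float | None = None) -> SpeedEstimate:
    """Loop-size change between two time points.

    A lower bound when loops saturate within the interval (flagged).
    """
    if len(series.times_min) < 2:
        raise ValueError("need at least two points")
    t = series.times_min
    v = series.values
    i0 = 0 if t0_min is None else int(np.argmin(np.abs(t - t0_min)))
    i1 = len(t) - 1 if t1_min is None else int(np.argmin(np.abs(t - t1_min)))
    if i1 <= i0:
        raise ValueError("second time point must follow the first")
    dv = v[i1] - v[i0]
    if dv < 0:
        warnings.warn("loop size decreased over the interval")
        dv = 0.0
    dt_s = minutes_to_seconds(t[i1] - t[i0])
    saturating = _is_concave(t[i0:i1 + 1], v[i0:i1 + 1])
    return SpeedEstimate(dv / dt_s, "increment",
                         {"from": (t[i0], v[i0]), "to": (t[i1], v[i1])},
                         lower_bound=saturating)


def _is_concave(t: np.ndarray, v: np.ndarray) -> bool:
    if len(t) < 3:
        return False
    slopes = np.diff(v) / np.diff(t)
    return bool(np.all(np.diff(slopes) <= 1e-12))


def speed_gap_closure(mean_loop_kb: float, time_to_rod_s: float,
                      multiple: float = 4.5) -> SpeedEstimate:
    """Speed from the time to close most inter-loop gaps.

    Theory: to close most gaps, each condensin must extrude several times
    (default 4.5, range ~4-5) the average loop size; the rod-shaped
    morphology marks that point.
    """
    if not 1 <= multiple <= 10:
        raise ValueError("multiple must be in [1, 10]")
    if time_to_rod_s <= 0:
        raise ValueError("time must be positive")
    return SpeedEstimate(mean_loop_kb * multiple / time_to_rod_s, "gap_closure",
                         {"mean_loop_kb": mean_loop_kb,
                          "time_to_rod_s": time_to_rod_s, "multiple": multiple})


def spiral_growth_rate(series: TimeSeries, t0_min: float | None = None,
                       t1_min: float | None = None) -> SpeedEstimate:
    """Growth rate of the helix-turn genomic period, in kb/s.

    Input values are periods in Mb (second-diagonal positions).
    """
    if series.kind != "period_mb":
        warnings.warn("spiral_growth_rate expects a period series in Mb")
    if len(series.times_min) < 2:
        raise ValueError("need at least two points")
    t = series.times_min
    v = series.values * 1000.0  # Mb -> kb
    i0 = 0 if t0_min is None else int(np.argmin(np.abs(t - t0_min)))
    i1 = len(t) - 1 if t1_min is None else int(np.argmin(np.abs(t - t1_min)))
    dv = max(v[i1] - v[i0], 0.0)
    dt_s = minutes_to_seconds(t[i1] - t[i0])
    return SpeedEstimate(dv / dt_s, "spiral",
                         {"from_mb": v[i0] / 1000, "to_mb": v[i1] / 1000,
                          "dt_min": t[i1] - t[i0]})


def volume_fold_from_area_fold(area_fold: float) -> float:
    """Convert a projected-area compaction fold to a volume fold.

    Isotropic assumption: linear fold = sqrt(area fold), volume fold =
    area_fold^(3/2). A 2-fold area decrease is a 2.83-fold (~3-fold)
    volume decrease.
    """
    if area_fold < 1:
        raise ValueError("area fold must be >= 1")
    return float(area_fold ** 1.5)


def gyre_size_check(edu_height_mb: float | None = None,
                    model_turn_mb: float | None = None,
                    hic_period_mb: float | None = None,
                    tolerance: float = 0.2) -> dict:
    """Consistency report between independent gyre-size measurements.

    Compares pairwise ratios of the gyre (helix turn) size from EdU
    sister-chromatid-exchange heights, the model turn length, and the Hi-C
    second-diagonal period; a pair passes when |ratio - 1| < tolerance.
    """
    inputs = {"edu_height_mb": edu_height_mb, "model_turn_mb": model_turn_mb,
              "hic_period_mb": hic_period_mb}
    given = {k: v for k, v in inputs.items() if v is not None}
    if len(given) < 2:
        raise ValueError("need at least two of the three gyre-size estimates")
    report: dict = {"inputs": inputs, "pairs": {}, "all_pass": True}
    names = list(given)
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            a, b = names[i], names[j]
            ratio = given[a] / given[b]
            ok = abs(ratio - 1.0) < tolerance
            report["pairs"][f"{a}/{b}"] = {"ratio": ratio, "pass": ok}
            report["all_pass"] &= ok
    return report
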