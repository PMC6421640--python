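"""Temperature-maintenance phenotype: hourly averaging, trapezoid AUC, NAWAC filter.

The phenotype is the area under the body-temperature curve (degC * h) over a
five-day cold window, computed from hourly means of nominal 15-minute
ear-canal sensor readings.  Animals whose hourly means leave the allowable
core-temperature band for cattle (NAWAC, 36.5-40.5 degC) are excluded as
sensor/physiology abnormalities before genotyping-stage analyses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

#: Allowable core temperature band (degC) for cattle.
NAWAC_LOWER = 36.5
NAWAC_UPPER = 40.5

#: Default analysis window length.
DEFAULT_SPAN = pd.Timedelta(days=5)


class DataQualityError(ValueError):
    """A series too broken to produce a trustworthy phenotype."""


@dataclass
class TemperatureSeries:
    """One animal's timestamped temperature readings (degC)."""

    animal_id: str
    series: pd.Series  # DatetimeIndex -> temp_c

    def __post_init__(self) -> None:
        if not isinstance(self.series.index, pd.DatetimeIndex):
            raise TypeError("series must be indexed by timestamps")
        if not self.series.index.is_monotonic_increasing or self.series.index.has_duplicates:
            raise ValueError(f"{self.animal_id}: timestamps must be strictly increasing")


@dataclass
class HourlyMeans:
    """Hourly mean temperatures over a window; interpolated hours flagged."""

    temps: pd.Series  # hourly DatetimeIndex -> mean temp_c
    interpolated: np.ndarray  # bool per hour


def hourly_average(
    series: pd.Series,
    window: tuple[pd.Timestamp, pd.Timestamp],
    max_empty_fraction: float = 0.2,
) -> HourlyMeans:
    """Average readings within each clock hour of ``[start, end)``.

    Hours without readings are linearly interpolated from neighbouring hours
    (nearest-filled at the window edges) and flagged.  More than
    ``max_empty_fraction`` empty hours rejects the series.
    """
    start, end = pd.Timestamp(window[0]), pd.Timestamp(window[1])
    if start >= end:
        raise ValueError("window start must precede end")
    hours = pd.date_range(start, end, freq="1h", inclusive="left")
    sub = series[(series.index >= start) & (series.index < end)]
    means = sub.groupby(sub.index.floor("1h")).mean().reindex(hours)
    empty = means.isna().to_numpy()
    if empty.mean() > max_empty_fraction:
        raise DataQualityError(
            f"{empty.sum()} of {len(hours)} hours empty "
            f"(> {max_empty_fraction:.0%} allowed)"
        )
    if empty.any():
        means = means.interpolate(method="linear", limit_direction="both")
    if not np.isfinite(means.to_numpy()).all():
        raise DataQualityError("non-finite hourly means after interpolation")
    return HourlyMeans(means, empty)


def trapezoid_auc(values, spacing: float = 1.0) -> float:
    """Trapezoid-rule area under an hourly temperature vector (degC * h)."""
    v = np.asarray(values, dtype=float)
    if v.ndim != 1 or len(v) < 2:
        raise ValueError("need a 1-d vector of at least 2 values")
    if not np.isfinite(v).all():
        raise ValueError("non-finite values in AUC input")
    return float(np.trapezoid(v, dx=spacing))


def select_coldest_window(
    ambient: pd.Series,
    span: pd.Timedelta = DEFAULT_SPAN,
) -> tuple[pd.Timestamp, pd.Timestamp]:
    """Find the contiguous window of length ``span`` minimising mean ambient
    temperature; ties resolve to the earliest start (whole clock hours)."""
    span = pd.Timedelta(span)
    first = ambient.index.min().ceil("1h")
    last = ambient.index.max()
    if last - first < span:
        raise ValueError(f"ambient coverage {last - first} shorter than span {span}")
    n_hours = int(span / pd.Timedelta(hours=1))
    hourly = ambient.groupby(ambient.index.floor("1h")).mean()
    hourly = hourly.reindex(pd.date_range(hourly.index.min(), hourly.index.max(), freq="1h"))
    hourly = hourly.interpolate(method="linear", limit_direction="both")
    means = hourly.rolling(n_hours).mean().to_numpy()[n_hours - 1 :]
    starts = hourly.index[: len(means)]
    keep = starts + span <= last + pd.Timedelta(hours=1)
    means, starts = means[keep], starts[keep]
    best = int(np.argmin(means))  # first occurrence -> earliest tie
    return starts[best], starts[best] + span


def nawac_filter(
    hourly: dict[str, HourlyMeans],
    lower: float = NAWAC_LOWER,
    upper: float = NAWAC_UPPER,
) -> pd.DataFrame:
    """Partition animals by the NAWAC core-temperature band.

    An animal is excluded when any hourly mean in the window falls strictly
    below ``lower`` or strictly above ``upper`` (boundary values keep).
    Returns a frame (animal_id, excluded, reason) with reason in
    {"", "low", "high"}; "low" wins if both occur.
    """
    rows = []
    for animal_id, hm in hourly.items():
        t = hm.temps.to_numpy()
        low, high = bool((t < lower).any()), bool((t > upper).any())
        reason = "low" if low else ("high" if high else "")
        rows.append((animal_id, low or high, reason))
    return pd.DataFrame(rows, columns=["animal_id", "excluded", "reason"])


def auc_phenotypes(
    series_list: list[TemperatureSeries],
    window: tuple[pd.Timestamp, pd.Timestamp],
    lower: float = NAWAC_LOWER,
    upper: float = NAWAC_UPPER,
) -> pd.DataFrame:
    """Full phenotype construction over a chosen cold window.

    Returns one row per animal: (animal_id, auc, excluded, reason).  AUC is
    computed for every animal whose series passes hourly-coverage QC;
    NAWAC-excluded animals keep their AUC but are flagged for removal.
    """
    hourly: dict[str, HourlyMeans] = {}
    rows = []
    for ts in series_list:
        try:
            hourly[ts.animal_id] = hourly_average(ts.series, window)
        except DataQualityError:
            rows.append((ts.animal_id, np.nan, True, "coverage"))
    flags = nawac_filter(hourly, lower, upper).set_index("animal_id")
    for animal_id, hm in hourly.items():
        auc = trapezoid_auc(hm.temps.to_numpy())
        rows.append(
            (animal_id, auc, bool(flags.loc[animal_id, "excluded"]), flags.loc[animal_id, "reason"])
        )
    return (
        pd.DataFrame(rows, columns=["animal_id", "auc", "excluded", "reason"])
        .sort_values("animal_id", kind="stable")
        .reset_index(drop=True)
    )
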