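"""Gravimetric water-balance analytics for load-cell (lysimeter) series.

A potted plant on a weighing platform loses system weight through
transpiration and gains it at irrigation events.  The analytics here
recover, from the raw weight trace sampled every few minutes:

* per-interval transpiration rate, -1 times the first derivative of the
  weight series, normalized to plant fresh weight
  (g water / g plant / min);
* daily transpiration over the daylight window (ml, with water density
  taken as 1 g/ml);
* feedback drought irrigation volumes (a fixed fraction of the previous
  day's transpiration);
* water-use efficiency, dry biomass per ml of water transpired.

Intervals containing an irrigation event (plus one interval of guard on
each side) are masked out of rate computations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from palemapper.simulate import LoadCellSeries

DEFAULT_DAY_WINDOW = (6.0, 18.0)  # clock hours, end exclusive


def detect_irrigation_events(
    series: LoadCellSeries, jump_threshold: float = 2.0
) -> np.ndarray:
    """Boolean mask over intervals: True where weight jumps up by more
    than ``jump_threshold`` grams (an irrigation event), with one guard
    interval masked on each side.
    """
    w = series.data["weight_g"].to_numpy()
    if w.size < 2:
        raise ValueError("need at least two samples")
    jumps = np.diff(w) > jump_threshold
    masked = jumps.copy()
    masked[:-1] |= jumps[1:]
    masked[1:] |= jumps[:-1]
    return masked


def _fresh_weight(series: LoadCellSeries) -> np.ndarray:
    if "fw_g" in series.data and series.data["fw_g"].notna().all():
        fw = series.data["fw_g"].to_numpy(dtype=float)
    else:
        raise ValueError(
            "plant fresh weight not available; supply fw_g or run "
            "estimate_fresh_weight first"
        )
    if (fw <= 0).any():
        raise ValueError("fresh weight must be positive")
    return fw


def estimate_fresh_weight(
    series: LoadCellSeries,
    tare: float,
    soil_water_baseline: float,
    predawn_window: tuple[float, float] = (4.0, 5.0),
) -> LoadCellSeries:
    """Fill ``fw_g`` from daily pre-dawn system weights.

    Estimator: for each day, mean system weight in the pre-dawn window
    minus ``tare`` minus ``soil_water_baseline`` (the assumed soil water
    content at that hour, e.g. pot capacity under nightly refill);
    anchors are linearly interpolated across samples.  This is a stated,
    testable replacement for proprietary platform internals: it assumes
    the soil store is at a repeatable level each pre-dawn, so it is only
    meaningful under well-watered (refill) irrigation.
    """
    df = series.data.copy()
    hours = df["timestamp"].dt.hour + df["timestamp"].dt.minute / 60
    dates = df["timestamp"].dt.normalize()
    lo, hi = predawn_window
    anchor_idx: list[int] = []
    anchor_fw: list[float] = []
    for _, day in df.groupby(dates, sort=True):
        sel = day[(hours.loc[day.index] >= lo) & (hours.loc[day.index] < hi)]
        if sel.empty:
            continue
        fw = sel["weight_g"].mean() - tare - soil_water_baseline
        anchor_idx.append(int(sel.index[len(sel) // 2]))
        anchor_fw.append(fw)
    if not anchor_idx:
        raise ValueError("no samples inside the pre-dawn window")
    fw_interp = np.interp(
        np.arange(len(df)), np.array(anchor_idx), np.array(anchor_fw)
    )
    if (fw_interp <= 0).any():
        raise ValueError("estimated fresh weight non-positive; check tare/baseline")
    df["fw_g"] = fw_interp
    return LoadCellSeries(data=df, ground_truth=series.ground_truth, seed=series.seed)


def transpiration_rate(
    series: LoadCellSeries,
    jump_threshold: float = 2.0,
    smooth_window: int | None = None,
) -> pd.DataFrame:
    """Per-interval transpiration rates, g water / g plant / min.

    rate_i = -(W_{i+1} - W_i) / dt_i / FW_i.  Intervals masked by
    irrigation detection are NaN.  ``smooth_window`` applies a centered
    moving average over that many intervals (off by default).

    Returns a frame indexed like the intervals with columns
    ``timestamp`` (interval start), ``rate`` (normalized),
    ``water_loss_g`` (unnormalized -dW, NaN when masked) and ``masked``.
    """
    w = series.data["weight_g"].to_numpy(dtype=float)
    t = series.data["timestamp"]
    fw = _fresh_weight(series)
    dt_min = t.diff().dt.total_seconds().to_numpy()[1:] / 60.0
    masked = detect_irrigation_events(series, jump_threshold)
    loss = -np.diff(w)
    rate = loss / dt_min / fw[:-1]
    rate = np.where(masked, np.nan, rate)
    loss = np.where(masked, np.nan, loss)
    if smooth_window:
        rate = (
            pd.Series(rate)
            .rolling(smooth_window, center=True, min_periods=1)
            .mean()
            .to_numpy()
        )
    return pd.DataFrame(
        {
            "timestamp": t.iloc[:-1].to_numpy(),
            "rate": rate,
            "water_loss_g": loss,
            "masked": masked,
        }
    )


def daily_transpiration(
    rates: pd.DataFrame,
    window: tuple[float, float] = DEFAULT_DAY_WINDOW,
    clip_negative: bool = False,
    low_confidence_masked_frac: float = 0.2,
) -> pd.DataFrame:
    """Per-day transpired water (ml) over the daylight window.

    Sums unnormalized water loss over non-masked intervals whose *start*
    time falls in ``[window_start, window_end)``; the day boundary is
    local midnight.  Days where more than ``low_confidence_masked_frac``
    of daylight intervals are masked are flagged.  ``clip_negative``
    zeroes negative interval losses (noise) before summing — a
    documented bias trade-off, off by default.
    """
    ts = pd.to_datetime(rates["timestamp"])
    hours = ts.dt.hour + ts.dt.minute / 60 + ts.dt.second / 3600
    lo, hi = window
    in_window = (hours >= lo) & (hours < hi)
    loss = rates["water_loss_g"].copy()
    if clip_negative:
        loss = loss.clip(lower=0)
    day = ts.dt.normalize()
    sub = pd.DataFrame(
        {
            "day": day[in_window],
            "loss": loss[in_window],
            "masked": rates["masked"][in_window],
        }
    )
    grouped = sub.groupby("day")
    out = pd.DataFrame(
        {
            "daily_transpiration_ml": grouped["loss"].sum(min_count=1),
            "masked_frac": grouped["masked"].mean(),
        }
    )
    out["low_confidence"] = out["masked_frac"] > low_confidence_masked_frac
    return out


def cumulative_transpiration(
    rates: pd.DataFrame, clip_negative: bool = False
) -> float:
    """Total water loss (ml) over all non-masked intervals, day and night."""
    loss = rates["water_loss_g"]
    if clip_negative:
        loss = loss.clip(lower=0)
    return float(loss.sum(skipna=True))


def feedback_irrigation_volume(
    prev_day_transpiration: float, fraction: float = 0.8
) -> float:
    """Irrigation volume (ml) under the feedback drought protocol:
    a fixed fraction of the plant's own previous-day transpiration."""
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    if prev_day_transpiration < 0:
        raise ValueError("previous-day transpiration must be >= 0")
    return fraction * prev_day_transpiration


def wue(dry_weight: float, cumulative_transpiration_ml: float) -> float:
    """Water-use efficiency: harvest dry weight (g) per ml transpired."""
    if cumulative_transpiration_ml <= 0:
        raise ValueError("cumulative transpiration must be positive")
    return dry_weight / cumulative_transpiration_ml


@dataclass
class WaterBalanceSummary:
    """End-to-end summary of one load-cell series."""

    daily: pd.DataFrame
    cumulative_ml: float
    wue: float | None
    n_irrigation_events: int

    def to_dict(self) -> dict:
        return {
            "cumulative_transpiration_ml": self.cumulative_ml,
            "wue_g_per_ml": self.wue,
            "n_irrigation_events": self.n_irrigation_events,
            "daily_transpiration_ml": {
                str(day.date()): float(v)
                for day, v in self.daily["daily_transpiration_ml"].items()
            },
        }


def summarize(
    series: LoadCellSeries,
    dry_weight: float | None = None,
    window: tuple[float, float] = DEFAULT_DAY_WINDOW,
    jump_threshold: float = 2.0,
    clip_negative: bool = False,
) -> WaterBalanceSummary:
    """Run event detection -> rates -> daily and cumulative totals -> WUE."""
    rates = transpiration_rate(series, jump_threshold=jump_threshold)
    daily = daily_transpiration(rates, window=window, clip_negative=clip_negative)
    total = cumulative_transpiration(rates, clip_negative=clip_negative)
    n_events = int(
        (np.diff(series.data["weight_g"].to_numpy()) > jump_threshold).sum()
    )
    return WaterBalanceSummary(
        daily=daily,
        cumulative_ml=total,
        wue=wue(dry_weight, total) if dry_weight is not None else None,
        n_irrigation_events=n_events,
    )
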