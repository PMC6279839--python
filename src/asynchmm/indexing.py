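"""Window-indexing of breath-level records into count time series.

Breaths carry 0/1 flags for each asynchrony type (ineffective inspiratory
effort, double cycling, short cycling, prolonged cycling). Indexing groups
them into contiguous half-open windows of T minutes and counts either the
flagged events or the breaths with at least one flag; the trailing partial
window is dropped so every window has a homogeneous exposure length.
"""
from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .simulate import ASYNC_TYPES
from .types import CountSeries

__all__ = ["index_events", "resample_cardio"]

logger = logging.getLogger(__name__)


def _window_layout(times: pd.Series, T: float, origin, end):
    """Origin (first timestamp floored to the minute), number of complete
    windows, and the per-row window index."""
    if origin is None:
        origin = times.iloc[0].floor("min")
    else:
        origin = pd.Timestamp(origin)
    if end is None:
        end = times.iloc[-1]
    else:
        end = pd.Timestamp(end)
    n_win = int(np.floor((end - origin).total_seconds() / 60.0 / T))
    idx = np.floor((times - origin).dt.total_seconds().to_numpy() / 60.0 / T)
    return origin, n_win, idx.astype(np.int64)


def index_events(breaths: pd.DataFrame, T: float = 15.0,
                 counting_mode: str = "events", origin=None, end=None,
                 patient_id: str | None = None) -> CountSeries:
    """Count asynchrony events per half-open T-minute window.

    Parameters
    ----------
    breaths : DataFrame with a ``timestamp`` column plus one 0/1 column per
        asynchrony type (any subset of {iee, double_cycling, short_cycling,
        prolonged_cycling}).
    T : window length in minutes (> 0).
    counting_mode : ``"events"`` sums the set flags over breaths (a breath
        with two types contributes 2); ``"breaths"`` counts breaths with at
        least one flag.
    origin : window origin; default: first breath's timestamp truncated to
        the whole minute. A breath exactly on a boundary belongs to the
        later window.
    end : end of the recording; default: the last breath's timestamp.
        Windows whose right edge falls after ``end`` are dropped (trailing
        partial window).

    Returns an empty series for empty input rather than raising.
    """
    if T <= 0:
        raise ValueError("window length T must be positive")
    if counting_mode not in ("events", "breaths"):
        raise ValueError("counting_mode must be 'events' or 'breaths'")
    flag_cols = [c for c in ASYNC_TYPES if c in breaths.columns]
    if len(breaths) == 0:
        return CountSeries(x=np.zeros(0, dtype=np.int64),
                           n=np.zeros(0, dtype=np.int64), T=T,
                           patient_id=patient_id)
    times = pd.to_datetime(breaths["timestamp"])
    if not times.is_monotonic_increasing:
        logger.warning("breath timestamps not sorted; sorting internally")
        order = np.argsort(times.to_numpy(), kind="stable")
        breaths = breaths.iloc[order].reset_index(drop=True)
        times = pd.to_datetime(breaths["timestamp"])

    origin, n_win, widx = _window_layout(times, T, origin, end)
    if n_win <= 0:
        return CountSeries(x=np.zeros(0, dtype=np.int64),
                           n=np.zeros(0, dtype=np.int64), T=T, start=origin,
                           patient_id=patient_id)
    keep = (widx >= 0) & (widx < n_win)
    widx = widx[keep]
    flags = breaths.loc[keep, flag_cols].to_numpy(dtype=np.int64) \
        if flag_cols else np.zeros((int(keep.sum()), 0), dtype=np.int64)
    if counting_mode == "events":
        per_breath = flags.sum(axis=1)
    else:
        per_breath = (flags.sum(axis=1) > 0).astype(np.int64)
    x = np.bincount(widx, weights=per_breath, minlength=n_win).astype(np.int64)
    n = np.bincount(widx, minlength=n_win).astype(np.int64)
    return CountSeries(x=x, n=n, T=T, start=origin, patient_id=patient_id)


def resample_cardio(raw: pd.DataFrame, T: float = 15.0, origin=None,
                    end=None) -> pd.DataFrame:
    """Align raw (time, hr, spo2) samples to the indexing windows.

    Returns one row per complete window with the within-window sample means
    and the sample count; windows without samples carry NaN means (missing,
    never zero).
    """
    if T <= 0:
        raise ValueError("window length T must be positive")
    if len(raw) == 0:
        return pd.DataFrame(columns=["window_start", "hr", "spo2", "n_samples"])
    times = pd.to_datetime(raw["time"])
    origin, n_win, widx = _window_layout(times, T, origin, end)
    keep = (widx >= 0) & (widx < n_win)
    sub = raw.loc[keep].copy()
    sub["window"] = widx[keep]
    grouped = sub.groupby("window")[["hr", "spo2"]].mean()
    counts = sub.groupby("window").size()
    out = pd.DataFrame(index=pd.RangeIndex(n_win, name="window"))
    out["hr"] = grouped["hr"]
    out["spo2"] = grouped["spo2"]
    out["n_samples"] = counts.reindex(out.index, fill_value=0)
    out.insert(0, "window_start",
               origin + pd.to_timedelta(out.index * T, unit="m"))
    return out.reset_index(drop=True)
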