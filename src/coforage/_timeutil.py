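"""Conversions between datetime64 arrays and float seconds since the epoch."""

from __future__ import annotations

import numpy as np
import pandas as pd


def to_seconds(times) -> np.ndarray:
    """datetime64-like array/Series -> float seconds since 1970-01-01 UTC."""
    arr = np.asarray(pd.DatetimeIndex(np.asarray(times)).asi8, dtype="int64")
    return arr / 1e9


def from_seconds(seconds) -> np.ndarray:
    """Float seconds since the epoch -> datetime64[ns] array (tz-naive UTC)."""
    return (np.asarray(seconds, dtype=float) * 1e9).round().astype("int64").view("datetime64[ns]")


def ts(value) -> pd.Timestamp:
    return pd.Timestamp(value)
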