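"""Growth-rate kinetics: length-vs-time traces to rate-vs-length curves.

The instantaneous growth rate over a measurement interval dT is
``(L(T + dT) - L(T)) / dT`` in nm/min, assigned to the midpoint length
``L + dL/2`` (and midpoint time), exactly as in the time-lapse measurement
protocol.  Curves built from simulated traces are smoothed with a running
median over 100 points before being compared with data.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .simulator import GrowthTrace

__all__ = [
    "RateCurve",
    "instantaneous_rates",
    "median_filter_curve",
    "read_trace_csv",
    "write_trace_csv",
    "read_rate_csv",
    "write_rate_csv",
]

log = logging.getLogger(__name__)

TRACE_COLUMNS = ["time_s", "length_nm", "n_monomers", "occupancy"]
RATE_COLUMNS = ["length_nm", "rate_nm_per_min", "interval_min"]


@dataclass
class RateCurve:
    """Growth rate (nm/min) indexed by flagellar length (nm)."""

    lengths_nm: np.ndarray
    rates_nm_per_min: np.ndarray
    interval_min: float
    provenance: str = "simulated"  # "simulated" | "measured"

    def __post_init__(self) -> None:
        self.lengths_nm = np.asarray(self.lengths_nm, dtype=float)
        self.rates_nm_per_min = np.asarray(self.rates_nm_per_min, dtype=float)
        if len(self.lengths_nm) != len(self.rates_nm_per_min):
            raise ValueError("lengths and rates must have equal length")
        if len(self.lengths_nm) and np.any(np.diff(self.lengths_nm) < 0):
            raise ValueError("curve abscissa must be sorted ascending")
        if not np.all(np.isfinite(self.rates_nm_per_min)):
            raise ValueError("rates must be finite")

    def __len__(self) -> int:
        return len(self.lengths_nm)


def instantaneous_rates(
    trace: GrowthTrace, interval_min: float = 5.0, *, sample_period_s: Optional[float] = None
) -> RateCurve:
    """Differencing of a trace into instantaneous rates on the measurement grid.

    For every recorded time T with T + dT inside the trace, the rate
    (L(T+dT) - L(T)) / dT (nm/min) is assigned to the midpoint length
    (L(T) + L(T+dT)) / 2.  The sample nearest to T + dT is used, provided it
    falls within half a sampling period; otherwise the window is dropped.
    """
    if interval_min <= 0:
        raise ValueError("interval_min must be > 0")
    t = trace.times_s
    L = trace.lengths_nm
    dT_s = interval_min * 60.0
    if len(t) < 2 or t[-1] - t[0] < dT_s:
        warnings.warn("trace shorter than one measurement interval; empty rate curve")
        return RateCurve(np.empty(0), np.empty(0), interval_min)
    if sample_period_s is None:
        sample_period_s = float(np.median(np.diff(t)))
    targets = t + dT_s
    j = np.searchsorted(t, targets)
    # nearest of the two bracketing samples
    j = np.clip(j, 1, len(t) - 1)
    left_closer = (targets - t[j - 1]) < (t[j] - targets)
    j = np.where(left_closer, j - 1, j)
    valid = (targets <= t[-1] + sample_period_s / 2.0) & (
        np.abs(t[j] - targets) <= sample_period_s / 2.0 + 1e-9
    )
    i = np.nonzero(valid)[0]
    j = j[valid]
    rates = (L[j] - L[i]) / interval_min
    mids = (L[i] + L[j]) / 2.0
    return RateCurve(mids, rates, interval_min)


def median_filter_curve(curve: RateCurve, window: int = 100) -> RateCurve:
    """Centered running median over ``window`` points (rounded up to odd).

    Endpoint windows shrink rather than pad, so no data are invented; the
    output has the same abscissa and length as the input.  A window larger
    than the curve degrades gracefully to per-point medians of the available
    neighbourhood.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    if len(curve) == 0:
        return RateCurve(np.empty(0), np.empty(0), curve.interval_min, curve.provenance)
    w = int(window)
    if w % 2 == 0:
        w += 1
    if w > len(curve):
        warnings.warn(
            f"median window {window} exceeds curve length {len(curve)}; "
            "windows shrink to the available points"
        )
    filtered = (
        pd.Series(curve.rates_nm_per_min)
        .rolling(window=w, center=True, min_periods=1)
        .median()
        .to_numpy()
    )
    return RateCurve(curve.lengths_nm.copy(), filtered, curve.interval_min, curve.provenance)


# ---------------------------------------------------------------------------
# CSV plumbing
# ---------------------------------------------------------------------------

def write_trace_csv(trace: GrowthTrace, path) -> None:
    trace.to_frame().to_csv(path, index=False)


def read_trace_csv(path) -> GrowthTrace:
    """Read a trace CSV (time_s, length_nm[, n_monomers, occupancy])."""
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        warnings.warn(f"{path}: empty trace file")
        e = np.empty(0)
        return GrowthTrace(e, e, e.astype(int), e)
    missing = [c for c in ("time_s", "length_nm") if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    bad = df.index[df[["time_s", "length_nm"]].isna().any(axis=1)]
    if len(bad):
        # +2: header line plus 1-based numbering
        raise ValueError(f"{path}: malformed row at line {bad[0] + 2}")
    n = len(df)
    return GrowthTrace(
        df["time_s"].to_numpy(float),
        df["length_nm"].to_numpy(float),
        df["n_monomers"].to_numpy(int) if "n_monomers" in df else np.zeros(n, int),
        df["occupancy"].to_numpy(float) if "occupancy" in df else np.zeros(n),
    )


def write_rate_csv(curve: RateCurve, path) -> None:
    pd.DataFrame(
        {
            "length_nm": curve.lengths_nm,
            "rate_nm_per_min": curve.rates_nm_per_min,
            "interval_min": np.full(len(curve), curve.interval_min),
        }
    ).to_csv(path, index=False)


def read_rate_csv(path, provenance: str = "measured") -> RateCurve:
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        warnings.warn(f"{path}: empty rate file")
        return RateCurve(np.empty(0), np.empty(0), 5.0, provenance)
    missing = [c for c in RATE_COLUMNS[:2] if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    bad = df.index[df[RATE_COLUMNS[:2]].isna().any(axis=1)]
    if len(bad):
        raise ValueError(f"{path}: malformed row at line {bad[0] + 2}")
    interval = float(df["interval_min"].iloc[0]) if "interval_min" in df and len(df) else 5.0
    order = np.argsort(df["length_nm"].to_numpy(float), kind="stable")
    return RateCurve(
        df["length_nm"].to_numpy(float)[order],
        df["rate_nm_per_min"].to_numpy(float)[order],
        interval,
        provenance,
    )
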