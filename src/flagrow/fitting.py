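"""Grid-search fitting of (D, LS) to growth-rate-vs-length data.

For each candidate (D, LS) on the grid, replicate traces are simulated at
the fixed loading rate, pooled into a median-filtered model rate curve, and
scored against the dataset with the cost function

    E(D, LS) = sum_i (V_i^model - V_i^exp)**2 / (N - 1)

where V_i^model is the model curve linearly interpolated at the i-th
measured length.  The best fit is the arg-min of the cost surface; the full
surface is retained for contour inspection.  Lengths outside the simulated
span use nearest-endpoint extrapolation (experimental lengths can slightly
exceed the simulated stop length).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import simulator as sim
from .kinetics import RateCurve, instantaneous_rates, median_filter_curve

__all__ = [
    "ExperimentalDataset",
    "FitResult",
    "model_rate_at_length",
    "cost",
    "build_model_curve",
    "grid_search",
    "default_D_grid",
    "default_LS_grid",
    "write_contour_csv",
    "read_dataset_csv",
    "write_dataset_csv",
]

log = logging.getLogger(__name__)


@dataclass
class ExperimentalDataset:
    """(length, rate, interval) measurement points; one per cell."""

    lengths_nm: np.ndarray
    rates_nm_per_min: np.ndarray
    intervals_min: np.ndarray

    def __post_init__(self) -> None:
        self.lengths_nm = np.atleast_1d(np.asarray(self.lengths_nm, dtype=float))
        self.rates_nm_per_min = np.atleast_1d(np.asarray(self.rates_nm_per_min, dtype=float))
        iv = np.asarray(self.intervals_min, dtype=float)
        if iv.ndim == 0:
            iv = np.full(len(self.lengths_nm), float(iv))
        self.intervals_min = iv
        n = len(self.lengths_nm)
        if len(self.rates_nm_per_min) != n or len(self.intervals_min) != n:
            raise ValueError("dataset columns must have equal length")
        if n < 2:
            raise ValueError("a dataset needs at least 2 points")
        if np.any(self.lengths_nm <= 0):
            raise ValueError("lengths must be > 0")
        if np.any(self.rates_nm_per_min < 0):
            raise ValueError("rates must be >= 0")

    @property
    def N(self) -> int:
        return len(self.lengths_nm)


@dataclass
class FitResult:
    """Cost surface over the (D, LS) grid and its arg-min."""

    D_grid: np.ndarray
    LS_grid: np.ndarray
    cost_surface: np.ndarray          # shape (len(D_grid), len(LS_grid))
    truncated: np.ndarray             # bool mask of flagged (excluded) cells
    best_D: float
    best_LS: int
    replicates: int
    seed: int
    model_curves: dict = field(default_factory=dict, repr=False)

    @property
    def best(self) -> tuple[float, int]:
        return (self.best_D, self.best_LS)


def model_rate_at_length(curve: RateCurve, L: float | np.ndarray) -> float | np.ndarray:
    """Model growth rate at length L by linear interpolation on the curve.

    Outside the curve's span the nearest endpoint value is used and a
    warning is logged.
    """
    if len(curve) == 0:
        raise ValueError("cannot interpolate an empty rate curve")
    L_arr = np.atleast_1d(np.asarray(L, dtype=float))
    lo, hi = curve.lengths_nm[0], curve.lengths_nm[-1]
    n_out = int(np.sum((L_arr < lo) | (L_arr > hi)))
    if n_out:
        log.warning(
            "%d of %d lengths outside the model curve span [%.0f, %.0f] nm; "
            "using nearest-endpoint extrapolation", n_out, L_arr.size, lo, hi,
        )
    out = np.interp(L_arr, curve.lengths_nm, curve.rates_nm_per_min)
    return float(out[0]) if np.isscalar(L) or np.ndim(L) == 0 else out


def cost(model_curve: RateCurve, data: ExperimentalDataset) -> float:
    """E(D,LS) = sum_i (V_i^model - V_i^exp)^2 / (N - 1) over all N points."""
    v_model = model_rate_at_length(model_curve, data.lengths_nm)
    resid = v_model - data.rates_nm_per_min
    return float(np.sum(resid**2) / (data.N - 1))


def build_model_curve(
    D: float,
    LS: int,
    *,
    S_load: float = sim.S_LOAD_HZ,
    L_stop: float = 8000.0,
    t_max: float = 1e5,
    replicates: int = 3,
    seed: int = 0,
    interval_min: float = 5.0,
    filter_window: int = 100,
    sample_every: float = 1.0,
    ell: float = sim.ELL_NM,
    dL: float = sim.DL_NM,
) -> tuple[RateCurve, bool]:
    """Simulate replicates at (D, LS), pool their 5-min rates, median-filter.

    Returns (curve, any_truncated).  Replicate rate points are pooled and
    sorted by length before filtering, which averages replicate-to-replicate
    scatter the same way a denser single trace would.
    """
    seeds = sim.replicate_seeds(seed, replicates)
    mids, rates = [], []
    any_truncated = False
    for s in seeds:
        params = sim.SimParams(
            D=D, LS=LS, S_load=S_load, ell=ell, dL=dL, L_stop=L_stop,
            t_max=t_max, t_after_stop=interval_min * 60.0,
            sample_every=sample_every, seed=s,
        )
        trace = sim.simulate(params)
        any_truncated = any_truncated or trace.truncated
        rc = instantaneous_rates(trace, interval_min)
        mids.append(rc.lengths_nm)
        rates.append(rc.rates_nm_per_min)
    mids = np.concatenate(mids)
    rates = np.concatenate(rates)
    order = np.argsort(mids, kind="stable")
    pooled = RateCurve(mids[order], rates[order], interval_min)
    return median_filter_curve(pooled, filter_window), any_truncated


def default_D_grid(n: int = 20) -> np.ndarray:
    """Logarithmic D grid over the searched range 1500 to 2e5 nm^2/s."""
    return np.geomspace(1500.0, 2.0e5, n)


def default_LS_grid() -> np.ndarray:
    """Integer loading strengths 0..25."""
    return np.arange(0, 26)


def grid_search(
    data: ExperimentalDataset,
    D_grid: Sequence[float],
    LS_grid: Sequence[int],
    *,
    S_load: float = sim.S_LOAD_HZ,
    L_stop: Optional[float] = None,
    t_max: float = 1e5,
    replicates: int = 3,
    seed: int = 0,
    interval_min: float = 5.0,
    filter_window: int = 100,
    sample_every: float = 1.0,
    keep_curves: bool = False,
) -> FitResult:
    """Evaluate the cost surface over the (D, LS) grid and find its arg-min.

    Every cell simulates ``replicates`` traces with seeds derived from
    ``seed`` (re-running with the same seed reproduces the surface exactly).
    Cells whose simulation hits t_max before L_stop are flagged and excluded
    from the arg-min.  Ties break toward smaller D, then smaller LS.
    """
    D_grid = np.asarray(list(D_grid), dtype=float)
    LS_grid = np.asarray(list(LS_grid), dtype=int)
    if len(D_grid) == 0 or len(LS_grid) == 0:
        raise ValueError("grids must be non-empty")
    if L_stop is None:
        L_stop = float(np.max(data.lengths_nm)) + 100.0
    surface = np.full((len(D_grid), len(LS_grid)), np.nan)
    truncated = np.zeros_like(surface, dtype=bool)
    cell_seeds = sim.replicate_seeds(seed, len(D_grid) * len(LS_grid))
    curves: dict = {}
    best = (np.inf, None, None)
    for i, D in enumerate(D_grid):
        for j, LS in enumerate(LS_grid):
            cell_seed = cell_seeds[i * len(LS_grid) + j]
            curve, trunc = build_model_curve(
                D, int(LS), S_load=S_load, L_stop=L_stop, t_max=t_max,
                replicates=replicates, seed=cell_seed, interval_min=interval_min,
                filter_window=filter_window, sample_every=sample_every,
            )
            if len(curve) == 0:
                trunc = True
            truncated[i, j] = trunc
            if len(curve):
                surface[i, j] = cost(curve, data)
            if keep_curves:
                curves[(float(D), int(LS))] = curve
            if trunc:
                warnings.warn(
                    f"grid cell (D={D:.6g}, LS={LS}) truncated at t_max; "
                    "excluded from the arg-min"
                )
                continue
            # strict < with row-major (ascending D, then LS) scan order
            # implements the smaller-D-then-smaller-LS tie break
            if surface[i, j] < best[0]:
                best = (surface[i, j], float(D), int(LS))
    if best[1] is None:
        raise RuntimeError("all grid cells truncated; no best fit available")
    log.info("best fit: D=%.6g nm^2/s, LS=%d (cost %.4g)", best[1], best[2], best[0])
    return FitResult(
        D_grid=D_grid, LS_grid=LS_grid, cost_surface=surface, truncated=truncated,
        best_D=best[1], best_LS=best[2], replicates=replicates, seed=seed,
        model_curves=curves,
    )


# ---------------------------------------------------------------------------
# CSV plumbing
# ---------------------------------------------------------------------------

def write_contour_csv(result: FitResult, path) -> None:
    """Long-format contour table (D_nm2_s, LS, cost); flagged cells as NaN."""
    rows = []
    for i, D in enumerate(result.D_grid):
        for j, LS in enumerate(result.LS_grid):
            c = np.nan if result.truncated[i, j] else result.cost_surface[i, j]
            rows.append((D, int(LS), c))
    pd.DataFrame(rows, columns=["D_nm2_s", "LS", "cost"]).to_csv(path, index=False)


def read_dataset_csv(path) -> ExperimentalDataset:
    """Read a dataset in the rate-CSV dialect (length_nm, rate_nm_per_min, interval_min)."""
    df = pd.read_csv(path)
    missing = [c for c in ("length_nm", "rate_nm_per_min") if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    intervals = (df["interval_min"].to_numpy(float)
                 if "interval_min" in df else np.full(len(df), 5.0))
    return ExperimentalDataset(
        df["length_nm"].to_numpy(float),
        df["rate_nm_per_min"].to_numpy(float),
        intervals,
    )


def write_dataset_csv(data: ExperimentalDataset, path) -> None:
    pd.DataFrame(
        {
            "length_nm": data.lengths_nm,
            "rate_nm_per_min": data.rates_nm_per_min,
            "interval_min": data.intervals_min,
        }
    ).to_csv(path, index=False)
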