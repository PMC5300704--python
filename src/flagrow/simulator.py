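"""Monte Carlo engine for the injection-diffusion model of flagellar growth.

Unfolded flagellin monomers (rigid rods of length ``ell`` = 56 nm) are
injected at the base of the flagellar channel at a fixed loading rate
``S_load`` and perform overdamped single-file Brownian motion along the
channel.  At low Reynolds number the Langevin equation reduces to pure
diffusion, integrated with the Wiener update

    x(t + dt) = x(t) + sqrt(2 * D * dt) * Z,   Z ~ N(0, 1)

subject to hard-core exclusion (a move pauses where neighbours meet), a
reflecting base (no return through the secretion apparatus), and an
absorbing tip: a monomer whose front edge reaches the tip crystallizes
immediately, elongating the filament by ``dL`` = 0.47 nm and leaving the
simulation.

The secretion apparatus can push resident monomers to make room for a new
one.  The loading strength ``LS`` is the maximum number of residents the
injection event may displace: insertion places the new monomer at [0, ell]
and shifts each resident k (1-indexed from the base) to
``x'_k = max(x_k, k * ell)``.  The attempt succeeds iff at most ``LS``
residents move and no pushed monomer's front edge passes the tip.

A flagellin that arrives (on the fixed 1/S_load clock) while the channel
cannot accept it waits at the base and enters the moment the entry rule is
satisfiable again; only one flagellin can wait, and further arrivals while
the slot is occupied diffuse away.  Setting ``blocked_monomer="discard"``
drops a blocked arrival immediately instead (sensitivity option).

Two engines are provided: a pure-Python reference (`attempt_load`,
`diffuse_step`) used for unit-level scrutiny, and a numba-compiled kernel
used by `simulate` for production runs (a trace to a few microns takes
10^7-10^9 steps at the default dt = dL**2 / D).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from numba import njit

__all__ = [
    "ELL_NM",
    "DL_NM",
    "S_LOAD_HZ",
    "SimParams",
    "ChannelState",
    "GrowthTrace",
    "attempt_load",
    "diffuse_step",
    "channel_occupancy",
    "simulate",
    "replicate_seeds",
]

#: unfolded FlaE flagellin length in the channel (nm)
ELL_NM = 56.0
#: filament elongation per crystallized monomer: 5.2 nm per 11-monomer turn (nm)
DL_NM = 0.47
#: loading rate of the V. alginolyticus T3FSS (monomers/s), from the 50 nm/min plateau
S_LOAD_HZ = 1.7


@dataclass(frozen=True)
class SimParams:
    """Parameters of one injection-diffusion simulation.

    Attributes
    ----------
    D : float
        Apparent diffusion coefficient of flagellin in the channel (nm^2/s).
    LS : int
        Loading strength: max residents the injection push may displace.
    S_load : float
        Loading attempt rate at the base (attempts/s).
    ell : float
        Unfolded monomer length (nm).
    dL : float
        Filament increment per crystallized monomer (nm).
    dt : float or None
        Time step (s). None selects the default (dL)**2 / D, which makes the
        rms single-step displacement sqrt(2)*dL.
    L_stop : float
        Target filament length (nm); the run ends t_after_stop seconds after
        first reaching it.
    L0 : float or None
        Initial filament/channel length (nm). None selects ell (the channel
        must hold one monomer before the first crystallization).
    t_max : float
        Wall time cap (s); a run that ends here without reaching L_stop is
        flagged truncated.
    t_after_stop : float
        Extra simulated seconds after L_stop is reached (so rate windows
        ending past L_stop are observable).
    sample_every : float
        Recording period for the output trace (s).
    seed : int
        RNG seed (< 2**31).
    poisson_loading : bool
        If True, loading attempts arrive as a Poisson process of rate S_load
        instead of the default fixed 1/S_load clock (sensitivity option).
    blocked_monomer : str
        "wait" (default): a blocked arrival occupies a single waiting slot
        and enters as soon as the entry rule allows; later arrivals while
        the slot is full diffuse away.  "discard": a blocked arrival is
        dropped immediately.
    """

    D: float
    LS: int
    S_load: float = S_LOAD_HZ
    ell: float = ELL_NM
    dL: float = DL_NM
    dt: Optional[float] = None
    L_stop: float = 8000.0
    L0: Optional[float] = None
    t_max: float = 1e5
    t_after_stop: float = 0.0
    sample_every: float = 1.0
    seed: int = 0
    poisson_loading: bool = False
    blocked_monomer: str = "wait"

    def __post_init__(self) -> None:
        if self.D <= 0:
            raise ValueError(f"D must be > 0, got {self.D}")
        if self.LS < 0 or int(self.LS) != self.LS:
            raise ValueError(f"LS must be a non-negative integer, got {self.LS}")
        if self.S_load <= 0:
            raise ValueError(f"S_load must be > 0, got {self.S_load}")
        if self.ell <= 0:
            raise ValueError(f"ell must be > 0, got {self.ell}")
        if not (0 < self.dL < self.ell):
            raise ValueError(f"dL must be in (0, ell), got {self.dL}")
        if self.dt is not None and self.dt <= 0:
            raise ValueError(f"dt must be > 0, got {self.dt}")
        if self.L_stop <= self.resolved_L0:
            raise ValueError("L_stop must exceed L0")
        if self.resolved_L0 < self.ell:
            raise ValueError("L0 must be >= ell")
        if self.t_max <= 0 or self.sample_every <= 0 or self.t_after_stop < 0:
            raise ValueError("t_max/sample_every must be > 0 and t_after_stop >= 0")
        if not (0 <= self.seed < 2**31):
            raise ValueError("seed must be in [0, 2**31)")
        if self.blocked_monomer not in ("wait", "discard"):
            raise ValueError(
                f"blocked_monomer must be 'wait' or 'discard', got {self.blocked_monomer!r}"
            )

    @property
    def resolved_dt(self) -> float:
        return self.dt if self.dt is not None else self.dL**2 / self.D

    @property
    def resolved_L0(self) -> float:
        return self.L0 if self.L0 is not None else self.ell


@dataclass
class ChannelState:
    """Evolving state of the channel: filament length, monomer positions, clock.

    ``positions`` holds the rear-edge coordinate of each monomer, strictly
    increasing with gaps >= ell; monomer k occupies [x_k, x_k + ell].
    """

    L: float
    positions: np.ndarray = field(default_factory=lambda: np.empty(0))
    t: float = 0.0
    n_crystallized: int = 0

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)

    @property
    def n_monomers(self) -> int:
        return len(self.positions)

    def check_invariants(self, ell: float) -> None:
        """Raise AssertionError if ordering/exclusion/bounds are violated."""
        x = self.positions
        assert self.L > 0
        if len(x):
            assert x[0] >= -1e-9, "monomer behind the base"
            assert np.all(np.diff(x) >= ell - 1e-9), "hard-core overlap"
            assert x[-1] + ell <= self.L + 1e-9, "monomer beyond the tip"


@dataclass
class GrowthTrace:
    """Sampled output of one simulation: filament length vs time."""

    times_s: np.ndarray
    lengths_nm: np.ndarray
    n_monomers: np.ndarray
    occupancy: np.ndarray
    truncated: bool = False
    params: Optional[SimParams] = None

    def __len__(self) -> int:
        return len(self.times_s)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "time_s": self.times_s,
                "length_nm": self.lengths_nm,
                "n_monomers": self.n_monomers,
                "occupancy": self.occupancy,
            }
        )


# ---------------------------------------------------------------------------
# pure-Python reference engine
# ---------------------------------------------------------------------------

def attempt_load(state: ChannelState, params: SimParams) -> tuple[bool, ChannelState]:
    """Try to insert one monomer at the base; returns (success, new state).

    Success requires displacing at most params.LS residents (to
    x'_k = max(x_k, k*ell)) and no pushed front edge beyond the tip. On
    failure the state is returned unchanged (the monomer diffuses away).
    """
    ell, L = params.ell, state.L
    x = state.positions
    if ell > L + 1e-12:
        return False, state
    k = np.arange(1, len(x) + 1, dtype=float)
    pushed = np.maximum(x, k * ell)
    n_displaced = int(np.sum(pushed > x + 1e-12))
    if n_displaced > params.LS or np.any(pushed + ell > L + 1e-12):
        return False, state
    new_positions = np.concatenate(([0.0], pushed))
    new = ChannelState(L=L, positions=new_positions, t=state.t,
                       n_crystallized=state.n_crystallized)
    # a resident pushed exactly to the tip crystallizes immediately
    if new.positions[-1] + ell >= new.L:
        new.positions = new.positions[:-1]
        new.L += params.dL
        new.n_crystallized += 1
    return True, new


def diffuse_step(
    state: ChannelState, params: SimParams, rng: np.random.Generator
) -> ChannelState:
    """One Wiener step for every monomer, visited in a random permutation.

    Each proposed move sqrt(2*D*dt)*Z is clipped at the base (x >= 0) and at
    the neighbours' current edges (single-file exclusion). A monomer whose
    front edge reaches the tip after its move crystallizes immediately:
    it is removed and L grows by dL.
    """
    ell = params.ell
    dt = params.resolved_dt
    sigma = math.sqrt(2.0 * params.D * dt)
    pos = state.positions.copy()
    L = state.L
    n_cryst = state.n_crystallized
    M = len(pos)
    order = rng.permutation(M)
    for idx in order:
        if idx >= M:  # the tip monomer crystallized earlier in this sweep
            continue
        x = pos[idx] + sigma * rng.standard_normal()
        lo = 0.0 if idx == 0 else pos[idx - 1] + ell
        hi = pos[idx + 1] - ell if idx < M - 1 else math.inf
        x = min(max(x, lo), hi)
        pos[idx] = x
        if idx == M - 1 and x + ell >= L:
            M -= 1
            L += params.dL
            n_cryst += 1
    return ChannelState(L=L, positions=pos[:M], t=state.t + dt, n_crystallized=n_cryst)


def channel_occupancy(state: ChannelState, params: SimParams) -> float:
    """Total monomer length in the channel divided by filament length, in [0, 1]."""
    if state.L <= 0:
        raise ValueError("channel length must be > 0")
    return state.n_monomers * params.ell / state.L


# ---------------------------------------------------------------------------
# numba production kernel
# ---------------------------------------------------------------------------

@njit(cache=True)
def _grow_kernel(D, LS, s_load, ell, dL, dt, L0, L_stop, t_max, t_after_stop,
                 sample_every, poisson, wait_mode, seed):  # pragma: no cover - jitted
    np.random.seed(seed)
    growth_after = t_after_stop * s_load * dL + ell
    max_m = int((L_stop + growth_after) / ell) + 3
    pos = np.empty(max_m)
    order = np.empty(max_m, dtype=np.int64)
    # normals are drawn in bulk (3-4x cheaper than scalar draws) and consumed
    # in order, so the stream is still fully determined by the seed
    nbuf = np.random.standard_normal(8192)
    nb_i = 0
    n_samples_cap = int(min(t_max, 4.0e9) / sample_every) + 4
    ts = np.empty(n_samples_cap)
    ls = np.empty(n_samples_cap)
    ms = np.empty(n_samples_cap, dtype=np.int64)
    occ = np.empty(n_samples_cap)

    L = L0
    M = 0
    t = 0.0
    if poisson:
        next_load = np.random.exponential(1.0 / s_load)
    else:
        next_load = 1.0 / s_load
    next_samp = sample_every
    sigma = math.sqrt(2.0 * D * dt)
    t_hit = -1.0
    truncated = False
    pending = False
    waiting = False

    w = 0
    ts[w] = 0.0
    ls[w] = L
    ms[w] = 0
    occ[w] = 0.0
    w += 1

    step = 0
    while True:
        step += 1
        t = step * dt

        # single-file diffusion sweep in a fresh random order
        for i in range(M):
            order[i] = i
        for i in range(M - 1, 0, -1):
            j = np.random.randint(0, i + 1)
            tmp = order[i]
            order[i] = order[j]
            order[j] = tmp
        M_start = M
        for oi in range(M_start):
            idx = order[oi]
            if idx >= M:
                continue
            if nb_i == 8192:
                nbuf = np.random.standard_normal(8192)
                nb_i = 0
            x = pos[idx] + sigma * nbuf[nb_i]
            nb_i += 1
            lo = 0.0 if idx == 0 else pos[idx - 1] + ell
            if x < lo:
                x = lo
            if idx < M - 1:
                hi = pos[idx + 1] - ell
                if x > hi:
                    x = hi
            pos[idx] = x
            if idx == M - 1 and x + ell >= L:
                M -= 1
                L += dL
        # arrivals on the base clock; at most one flagellin can wait
        while t >= next_load - 1e-12:
            pending = True  # a flagellin arrives and tries to enter now
            if poisson:
                next_load += np.random.exponential(1.0 / s_load)
            else:
                next_load += 1.0 / s_load
        # the pending/waiting flagellin tries the entry rule this step.
        # residents needing displacement form a prefix of the file, and
        # undisplaced residents already satisfy the tip bound, so the scan
        # stops at the first resident in place or the (LS+1)-th displaced one
        if pending or waiting:
            ok = ell <= L + 1e-12
            displaced = 0
            if ok:
                for k in range(1, M + 1):
                    xk = pos[k - 1]
                    target = k * ell
                    if xk >= target - 1e-12:
                        break
                    displaced += 1
                    if displaced > LS or target + ell > L + 1e-12:
                        ok = False
                        break
            if ok and displaced <= LS:
                for k in range(M, 0, -1):
                    target = k * ell
                    xk = pos[k - 1]
                    pos[k] = xk if xk >= target else target
                pos[0] = 0.0
                M += 1
                waiting = False
                if pos[M - 1] + ell >= L:
                    M -= 1
                    L += dL
            elif pending and wait_mode and not waiting:
                waiting = True  # blocked arrival occupies the waiting slot
            pending = False
        # trace sampling
        while t >= next_samp - 1e-12 and w < n_samples_cap - 1:
            ts[w] = t
            ls[w] = L
            ms[w] = M
            occ[w] = M * ell / L
            w += 1
            next_samp += sample_every
        if t_hit < 0.0 and L >= L_stop:
            t_hit = t
        if t_hit >= 0.0 and t >= t_hit + t_after_stop:
            break
        if t >= t_max:
            truncated = t_hit < 0.0
            break

    # final state sample
    ts[w] = t
    ls[w] = L
    ms[w] = M
    occ[w] = M * ell / L if L > 0 else 0.0
    w += 1
    return ts[:w], ls[:w], ms[:w], occ[:w], truncated


def simulate(params: SimParams, engine: str = "numba") -> GrowthTrace:
    """Run the injection-diffusion model to L_stop (or t_max) and return the trace.

    ``engine="numba"`` uses the compiled kernel; ``engine="python"`` runs the
    reference implementation (orders of magnitude slower, for cross-checks).
    The two engines draw from different RNG streams, so they agree
    statistically, not sample-by-sample.
    """
    dt = params.resolved_dt
    L0 = params.resolved_L0
    if engine == "numba":
        ts, ls, ms, occ, truncated = _grow_kernel(
            float(params.D), int(params.LS), float(params.S_load),
            float(params.ell), float(params.dL), float(dt), float(L0),
            float(params.L_stop), float(params.t_max), float(params.t_after_stop),
            float(params.sample_every), params.poisson_loading,
            params.blocked_monomer == "wait", int(params.seed),
        )
        return GrowthTrace(np.asarray(ts), np.asarray(ls), np.asarray(ms),
                           np.asarray(occ), bool(truncated), params)
    if engine != "python":
        raise ValueError(f"unknown engine {engine!r}")

    rng = np.random.default_rng(params.seed)
    state = ChannelState(L=L0)
    next_load = (rng.exponential(1.0 / params.S_load) if params.poisson_loading
                 else 1.0 / params.S_load)
    next_samp = params.sample_every
    ts = [0.0]
    ls = [L0]
    ms = [0]
    occ = [0.0]
    t_hit = -1.0
    truncated = False
    pending = False
    waiting = False
    while True:
        state = diffuse_step(state, params, rng)
        t = state.t
        while t >= next_load - 1e-12:
            pending = True
            next_load += (rng.exponential(1.0 / params.S_load)
                          if params.poisson_loading else 1.0 / params.S_load)
        if pending or waiting:
            entered, state = attempt_load(state, params)
            if entered:
                waiting = False
            elif pending and params.blocked_monomer == "wait" and not waiting:
                waiting = True
            pending = False
        while t >= next_samp - 1e-12:
            ts.append(t)
            ls.append(state.L)
            ms.append(state.n_monomers)
            occ.append(channel_occupancy(state, params))
            next_samp += params.sample_every
        if t_hit < 0.0 and state.L >= params.L_stop:
            t_hit = t
        if t_hit >= 0.0 and t >= t_hit + params.t_after_stop:
            break
        if t >= params.t_max:
            truncated = t_hit < 0.0
            break
    ts.append(state.t)
    ls.append(state.L)
    ms.append(state.n_monomers)
    occ.append(channel_occupancy(state, params))
    return GrowthTrace(np.array(ts), np.array(ls), np.array(ms, dtype=np.int64),
                       np.array(occ), truncated, params)


def replicate_seeds(seed: int, n: int) -> list[int]:
    """Derive n independent sub-seeds (< 2**31) from a master seed."""
    ss = np.random.SeedSequence(seed)
    return [int(s) % 2**31 for s in ss.generate_state(n, dtype=np.uint64)]
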