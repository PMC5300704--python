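"""Synthetic growth-rate datasets emulating the time-lapse measurements.

The measured dataset this generator stands in for is a table of
(flagellar length, instantaneous growth rate, interval) points, one per
cell: 72 points at 5-min intervals spanning 400-2800 nm and 103 points at
20-min intervals spanning 1000-7500 nm, with a ~50 nm/min plateau below
1500 nm decaying to ~9 nm/min at 7500 nm.

Each synthetic cell is drawn from a seeded injection-diffusion trace at the
chosen true (D, LS): a target length is sampled uniformly in the group's
range, the two window endpoint lengths are read off the trace one
measurement interval apart, passed through the measurement emulation
(divide by the helix projection factor, quantize to the 65 nm pixel,
multiply back), differenced into a rate, and given additive Gaussian noise.

The flagellin length constants also live here: the unfolded FlaE length
scaled from the 74 nm / 494-residue FliC reference, and the 0.47 nm
filament increment per crystallized monomer (5.2 nm per 11-monomer turn).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import simulator as sim
from .fitting import ExperimentalDataset
from .kinetics import instantaneous_rates

__all__ = [
    "SynthConfig",
    "FlagellinSpec",
    "FLAE_SPEC",
    "simulate_truth_traces",
    "generate_dataset",
    "unfolded_length",
    "increment_per_monomer",
]


@dataclass(frozen=True)
class SynthConfig:
    """Study conditions of the emulated measurement campaign."""

    true_D: float = 5000.0
    true_LS: int = 12
    S_load: float = sim.S_LOAD_HZ
    n_short: int = 72
    short_range: tuple[float, float] = (400.0, 2800.0)
    short_interval_min: float = 5.0
    n_long: int = 103
    long_range: tuple[float, float] = (1000.0, 7500.0)
    long_interval_min: float = 20.0
    noise_sd: float = 5.0           # nm/min; the measurement scatter stand-in
    pixel_nm: float = 65.0          # camera pixel; 0 disables quantization
    projection_factor: float = 1.09
    replicates: int = 3             # independent traces cells are drawn from
    seed: int = 0

    def __post_init__(self) -> None:
        for rng_ in (self.short_range, self.long_range):
            if not (0 < rng_[0] < rng_[1]):
                raise ValueError(f"length range must be positive and ordered, got {rng_}")
        if self.noise_sd < 0 or self.pixel_nm < 0:
            raise ValueError("noise_sd and pixel_nm must be >= 0")
        if self.projection_factor < 1:
            raise ValueError("projection_factor must be >= 1")
        if self.n_short < 0 or self.n_long < 0 or self.n_short + self.n_long < 2:
            raise ValueError("need at least 2 synthetic points in total")


@dataclass(frozen=True)
class FlagellinSpec:
    """Residue count of a flagellin plus the unfolded-length reference."""

    n_aa: int
    ref_len_nm: float = 74.0   # unfolded S. enterica FliC
    ref_aa: int = 494

    def __post_init__(self) -> None:
        if self.n_aa < 0 or self.ref_len_nm <= 0 or self.ref_aa <= 0:
            raise ValueError("flagellin spec fields must be positive (n_aa >= 0)")


#: V. alginolyticus FlaE: 379 residues
FLAE_SPEC = FlagellinSpec(n_aa=379)


def unfolded_length(spec: FlagellinSpec) -> float:
    """Unfolded peptide length in nm, linear in residue count: ref_len * n_aa / ref_aa.

    For FlaE this is 74*379/494 = 56.77 nm; the simulator uses the truncated
    canonical constant ELL_NM = 56 nm.
    """
    return spec.ref_len_nm * spec.n_aa / spec.ref_aa


def increment_per_monomer(turn_len: float = 5.2, monomers_per_turn: int = 11,
                          units: str = "nm") -> float:
    """Filament elongation per crystallized monomer, rounded to the canonical 2 d.p.

    One helical turn of 11 monomers elongates the filament by 5.2 nm (52 A),
    so each monomer adds 5.2/11 = 0.47 nm.
    """
    if turn_len <= 0 or monomers_per_turn <= 0:
        raise ValueError("turn_len and monomers_per_turn must be > 0")
    if units == "angstrom":
        turn_len /= 10.0
    elif units != "nm":
        raise ValueError(f"units must be 'nm' or 'angstrom', got {units!r}")
    return round(turn_len / monomers_per_turn, 2)


def _quantize(length_nm: np.ndarray, factor: float, pixel_nm: float) -> np.ndarray:
    """Measurement emulation: project to 2D, snap to the pixel grid, correct back."""
    if pixel_nm == 0:
        return length_nm
    l2d = length_nm / factor
    return np.round(l2d / pixel_nm) * pixel_nm * factor


def simulate_truth_traces(cfg: SynthConfig) -> list[sim.GrowthTrace]:
    """Simulate the cfg.replicates seeded traces synthetic cells are drawn from."""
    groups = [
        (cfg.n_short, cfg.short_range, cfg.short_interval_min),
        (cfg.n_long, cfg.long_range, cfg.long_interval_min),
    ]
    groups = [g for g in groups if g[0] > 0]
    max_len = max(g[1][1] for g in groups)
    max_interval = max(g[2] for g in groups)
    traces = []
    for s in sim.replicate_seeds(cfg.seed, cfg.replicates):
        params = sim.SimParams(
            D=cfg.true_D, LS=cfg.true_LS, S_load=cfg.S_load,
            L_stop=max_len, t_max=5e5, t_after_stop=max_interval * 60.0, seed=s,
        )
        traces.append(sim.simulate(params))
    return traces


def generate_dataset(
    cfg: SynthConfig, *, traces: list[sim.GrowthTrace] | None = None,
    return_traces: bool = False,
) -> ExperimentalDataset | tuple[ExperimentalDataset, list[sim.GrowthTrace]]:
    """Generate one seeded synthetic growth-rate dataset.

    Simulates ``cfg.replicates`` traces at (true_D, true_LS) long enough to
    cover both length ranges plus one long measurement window, then draws
    each synthetic cell from a random trace at a uniform random target
    length. Negative noisy rates are clipped at zero (measured rates are
    reported non-negative).

    Pre-simulated truth traces (from `simulate_truth_traces`, possibly under
    a different master seed) can be passed in to amortize the simulation
    across many noise realizations.
    """
    rng = np.random.default_rng(cfg.seed)
    groups = [
        (cfg.n_short, cfg.short_range, cfg.short_interval_min),
        (cfg.n_long, cfg.long_range, cfg.long_interval_min),
    ]
    groups = [g for g in groups if g[0] > 0]
    if traces is None:
        traces = simulate_truth_traces(cfg)

    lengths, rates, intervals = [], [], []
    for n_points, (lo, hi), interval_min in groups:
        dT_s = interval_min * 60.0
        for _ in range(n_points):
            trace = traces[rng.integers(len(traces))]
            target = rng.uniform(lo, hi)
            t, L = trace.times_s, trace.lengths_nm
            period = float(np.median(np.diff(t)))
            i = min(int(np.searchsorted(L, target)), len(L) - 1)
            # nearest sample one interval later (same rule as the rate curve)
            t_end = t[i] + dT_s
            j = int(np.clip(np.searchsorted(t, t_end), 1, len(t) - 1))
            if t_end - t[j - 1] < t[j] - t_end:
                j -= 1
            if abs(t[j] - t_end) > period / 2.0 + 1e-9:  # window off the trace end
                continue
            l1, l2 = _quantize(np.array([L[i], L[j]]), cfg.projection_factor, cfg.pixel_nm)
            rate = (l2 - l1) / interval_min
            rate += rng.normal(0.0, cfg.noise_sd) if cfg.noise_sd > 0 else 0.0
            lengths.append((l1 + l2) / 2.0)
            rates.append(max(rate, 0.0))
            intervals.append(interval_min)
    data = ExperimentalDataset(np.array(lengths), np.array(rates), np.array(intervals))
    return (data, traces) if return_traces else data
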