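# Methods

## Model

Flagellin export through the flagellar channel is modelled as single-file
diffusion with injection. The channel is a 1D segment [0, L]; the filament
(and hence the channel) has length L, which grows as monomers crystallize
at the tip. Each monomer is a rod of length ℓ = 56 nm — the unfolded FlaE
peptide, scaled linearly from the 74-nm/494-residue FliC reference
(74 × 379/494 = 56.77 nm, truncated to the canonical 56 nm the model
uses — `flagrow.synthetic.unfolded_length` returns the un-truncated value).
Monomer dynamics are overdamped: inertia is negligible at low Reynolds
number and no external force acts along the channel, so each monomer's
position follows the pure Wiener update `x += sqrt(2 D Δt) Z`. Collisions
are resolved by clipping the move at contact (the motion "pauses where
neighbours meet" rather than being rejected); the base is reflecting; a
monomer whose front edge reaches the tip crystallizes immediately,
elongating the filament by ΔL = 5.2/11 = 0.47 nm (one 11-monomer helical
turn adds 5.2 nm).

Loading: flagellins arrive at the base on a fixed clock of rate S_load
(deterministic intervals 1/S_load; a Poisson option exists for sensitivity
checks but is not the default, since the loading rate is specified as a
fixed working frequency of the export apparatus). An insertion places the
new monomer at [0, ℓ] and pushes each resident k (1-indexed from the base)
to `x'_k = max(x_k, kℓ)` — the minimal displacement that makes room. Entry
succeeds iff at most LS residents move and no pushed front edge passes the
tip. Two readings of the push rule ("at most LS monomers displaced" vs
"only monomers within LS·ℓ of the base can be pushed") are provably
equivalent here, because the displaced set is always a prefix of the file
and resident k needing displacement implies it sits below kℓ.

A blocked arrival waits at the base and retries the entry rule every time
step, entering the moment it becomes satisfiable; only one flagellin can
wait, and an arrival that finds the slot occupied diffuses away
(`blocked_monomer="wait"`, the default). The alternative reading — every
blocked arrival is dropped and entry is only possible on clock ticks
(`blocked_monomer="discard"`) — throttles entry near jamming and bends the
best-fit rate curve around 1100 nm instead of ~1500 nm (plateau mean over
400–1500 nm ≈ 43.4 instead of ≈ 47.5 nm/min); the waiting rule is the
default because it reproduces the published plateau width. The first
arrival happens at t = 1/S_load.

## Parameters

| parameter | meaning | default | units |
|---|---|---|---|
| D | apparent diffusion coefficient in the channel | fitted; best fit 5000 | nm²/s |
| LS | loading strength (max residents pushed per insertion) | fitted; best fit 12 | — |
| S_load | loading attempt rate | 1.7 | 1/s |
| ℓ | unfolded monomer length | 56 | nm |
| ΔL | filament increment per crystallized monomer | 0.47 | nm |
| Δt | simulation time step | (ΔL)²/D | s |
| L0 | initial filament length | ℓ | nm |

S_load = 1.7 Hz is the measured plateau growth rate converted to a monomer
flux (≈50 nm/min ÷ 0.47 nm). The loading-limited ceiling is therefore
S_load·ΔL·60 = 47.94 nm/min, which the simulator reproduces at high D.
L0 = ℓ because the channel must be able to hold one monomer before the
first crystallization; growth-rate curves above ~200 nm are insensitive to
this choice (the initial channel-filling transient is visible below it).

## Numerics

- Δt = (ΔL)²/D makes the rms step √2·ΔL ≈ 0.66 nm, far below ℓ. Halving Δt
  changes mean rate curves by less than replicate scatter (asserted in the
  test suite).
- Monomers are updated in a fresh uniformly random permutation each step
  and clipped against neighbours' current positions. A fixed sweep
  direction could bias net transport in a dense file; when compared under
  the fixed-clock loading reading at the best-fit parameters, base→tip,
  tip→base and random orders gave plateau means within ~1 nm/min, so the
  choice is not load-bearing.
- The production engine is a numba kernel; normals are drawn in bulk and
  consumed in order, so runs are exactly reproducible from the seed. A
  pure-Python reference implementation of the entry and diffusion rules is
  unit-tested against worked examples and cross-checked statistically
  against the kernel.
- Crystallization is checked after each individual monomer's move, and
  after an insertion push, never deferred to the end of a sweep.
- Helix arc lengths: the 2D projected length has no closed form and is
  integrated adaptively (scipy `quad`, absolute tolerance 1e-6 relative to
  z). The correction factor is a slope-through-origin least-squares fit of
  L3D against L2D over 0–10 µm at 100 points; because both lengths are
  exactly linear in whole turns the slope is insensitive to the sampled
  range (per-turn ratio 1805.7/1656.4 = 1.0901). The helix axis is assumed
  parallel to the imaging plane; cell-body tilt is not modelled.
- Rate curves: instantaneous rate (L(T+ΔT) − L(T))/ΔT assigned to the
  midpoint length, one window per recorded sample (1-s sampling), window
  endpoint matched to the nearest sample within half a sampling period.
  The 100-point median filter is centered and rounded up to 101 points;
  endpoint windows shrink instead of padding. Replicate curves are pooled
  and sorted by length before filtering.
- Cost: E(D,LS) = Σ(Vᵢ_model − Vᵢ_exp)²/(N−1) over all N data points, with
  the model curve linearly interpolated and clamped to its nearest endpoint
  outside its span (experimental lengths may slightly exceed the simulated
  stop length; every such evaluation logs a warning). Grid cells whose
  simulation hits the time cap before the stop length are flagged, written
  as NaN in contour output, and excluded from the arg-min; ties break
  toward smaller D, then smaller LS.

## Synthetic data

`SynthConfig` defaults emulate the measurement campaign the fitting stage
was designed for: 72 cells at 5-min intervals with lengths 400–2800 nm and
103 cells at 20-min intervals with lengths 1000–7500 nm, one point per
cell, lengths sampled uniformly within each range (the real length
distribution is unreported). Measurement is emulated by dividing each
window-endpoint length by the 1.09 projection factor, snapping to the 65-nm
pixel grid, correcting back, then differencing; additive Gaussian rate
noise (default SD 5 nm/min) stands in for all remaining measurement error —
no noise magnitude is reported for the real data, so this value was chosen
once to match the visual scatter of the published rate-vs-length cloud and
is configurable. Negative noisy rates are clipped at zero, matching the
non-negative reported rates. What passing synthetic-data tests show is that
the pipeline recovers generating parameters under this noise model; they
cannot rule out structured errors real microscopy introduces (tracing bias,
focus drift, length-dependent noise, non-uniform length sampling).

## Problem sizes

Simulation cost scales as T·D/(ΔL)² steps, so the test suite and
acceptance script use deliberately scaled runs: plateau statistics from
three replicates to 1600 nm; the diffusion-limited regime from one trace to
4200 nm (where the model rate is already below 20 nm/min) rather than the
full 7500 nm; parameter recovery on a 3×3 grid — a factor of two in D
around the best fit (2500/5000/10000 nm²/s) crossed with the endpoints and
best fit of the loading-strength range (0/12/25) — against synthetic
campaigns of 60 cells with lengths ≤ 2400 nm, with the grid simulated once
(time cap 4200 s per cell; slower cells are flagged and excluded, as in any
grid run) and ten independently seeded noise realizations scored against
it. Full-scale runs (lengths to 7.5 µm, the 20×26 default grid) use the
same code paths via `SynthConfig()` and `default_D_grid()`/
`default_LS_grid()`.

## Known limitations

- The model's plateau can never exceed 47.94 nm/min (the loading ceiling),
  slightly below the ~50 nm/min quoted for the measured plateau; the mean
  5-min rate over 400–1500 nm at the best-fit parameters is ≈47.5 nm/min.
- The channel is identified with the filament: no hook/rod offset, no
  explicit secretion-apparatus geometry, no monomer flexibility or
  hydrodynamic interactions.
- The energetics are quasi-static estimates (W = n·kT·v·s/D with ζ = kT/D);
  the kT-per-ATP conversion of 20 is back-derived from the published
  75.3 kT ≡ 3.77 ATP pair and configurable.
- Grid search is the only fitting strategy offered — the cost surface from
  stochastic simulations is noisy, and replicate averaging (default 3) is
  the only variance-reduction device.
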