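# flagrow

**Injection-diffusion modelling of bacterial flagellar growth.**

Bacterial flagella are self-assembled from tens of thousands of flagellin
monomers that are exported, unfolded, through the filament's own 2-nm
central channel and crystallize at the distal tip. In *Vibrio
alginolyticus* the filament first elongates at a constant ~50 nm/min while
shorter than ~1500 nm, then slows sharply, down to ~9 nm/min at 7500 nm.
`flagrow` implements the injection-diffusion model that explains this
length dependence, together with the surrounding analysis pipeline, for
anyone studying type III secretion kinetics or single-file transport in
narrow channels.

## The model

Monomers (rigid rods of length ℓ = 56 nm, the unfolded FlaE peptide) are
injected at the channel base at a fixed loading rate S_load = 1.7 Hz and
perform overdamped single-file Brownian motion: at low Reynolds number the
Langevin equation `ζ dx/dt = η(t)` integrates as the Wiener update

```
x(t + Δt) = x(t) + sqrt(2 D Δt) · Z,   Z ~ N(0, 1)
```

with hard-core exclusion between neighbours, a reflecting base, and an
absorbing tip: a monomer reaching the tip crystallizes immediately,
elongating the filament by ΔL = 5.2/11 = 0.47 nm. The secretion apparatus
can push up to *LS* resident monomers forward (the *loading strength*) to
make room for a new one; a blocked monomer diffuses away. Short filaments
grow at the loading-limited ceiling S_load · ΔL = 47.9 nm/min; long ones
are diffusion-limited and jam, so the rate falls.

The two free parameters — the apparent diffusion coefficient *D* and *LS* —
are fitted to growth-rate-vs-length data by explicit grid search on the
cost function

```
E(D, LS) = Σᵢ (Vᵢ_model − Vᵢ_exp)² / (N − 1)
```

where the model curve is built exactly like the measurements: 5-min
instantaneous rates `(L(T+ΔT) − L(T))/ΔT` assigned to midpoint lengths and
smoothed with a 100-point running median. Helical filaments are measured as
2D projections, so lengths are corrected by the slope of L3D vs L2D
(1.09 for the 0.16-µm-radius, 1.5-µm-pitch *Vibrio* helix). A synthetic
data generator emulates the measurement campaign (one point per cell,
65-nm pixel quantization, additive rate noise) so the whole pipeline is
testable end to end without microscopy data.

## Worked example

```
$ python examples/03_growth_rate_curve.py
1144 five-minute windows from a 1443-s trace
length_nm  rate_nm_per_min (median-filtered)
      200    47.7
      350    47.6
      500    47.6
      650    47.6
      800    47.6
      950    47.6
     1100    47.6
short filaments grow near the loading-limited ceiling 1.7/s * 0.47 nm * 60 = 47.9 nm/min
```

A filament simulated at the best-fit parameters (D = 5000 nm²/s, LS = 12)
grows at the loading-limited ceiling while short — the model's plateau,
which holds to ~1500 nm before diffusion becomes rate-limiting — while the
channel occupancy climbs (`examples/02` prints it rising alongside; the
rate at 4000 nm is already below a third of the plateau). The other examples cover projection
correction (`01`), secretion energetics (`04`: 75.3 kT to insert against
12 residents in 0.1 s, 12.5 kT over the full 0.6-s cycle), and parameter
recovery from synthetic data by grid search (`05`).

The same operations are scriptable from the shell:

```
flagrow simulate --D 5000 --LS 12 --lstop 2000 --seed 1 --out trace.csv
flagrow rates --trace trace.csv --interval-min 5 --filter 100 --out rates.csv
flagrow fit --data rates.csv --dgrid 1500:200000:log20 --lsgrid 0:25 --out contour.csv
```

Every CLI run writes a `*.manifest.json` with the config, seeds and file
digests needed to replay it exactly.

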