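# voroshear

Voronoi vertex-model tissue mechanics under quasi-static shear:
rigidity, yield stress, avalanches, and stress inference from cell-edge
statistics.

## What it does

Confluent biological tissues behave like soft glassy solids: below a
critical target shape index `p0` they are rigid, above it they flow.
`voroshear` simulates a 2D Voronoi vertex model — `N` cells whose shapes
are the Voronoi polygons of their centers, with energy
`eps = sum_i [kappa_A (a_i - 1)^2 + (p_i - p0)^2]` — under athermal
quasi-static simple shear with Lees–Edwards boundary conditions, and
analyzes the resulting plasticity. The package provides:

- **Geometry** (`voroshear.geometry`): periodic Voronoi tessellation
  valid at arbitrary shear strain, with edge/vertex bookkeeping.
- **Mechanics** (`voroshear.mechanics`): exact analytic forces, virial
  shear stress, and a linear-response shear modulus that accounts for
  non-affine relaxation, each backed by an independent
  finite-difference oracle.
- **Shear protocol** (`voroshear.shear`): strain steps of `2e-3` with
  FIRE + Newton minimization to a residual force of `1e-14`
  (zero-energy fluid states are accepted at the numerical floor), frame
  recording, T1-event detection, yield stress and solid-fraction
  observables.
- **Plasticity** (`voroshear.plasticity`): avalanche segmentation into
  type I (fluid precursor) and type II (solid precursor, power-law
  distributed with exponent `tau ≈ -1.36`), discrete maximum-likelihood
  power-law fitting with bootstrap errors and simulated KS goodness,
  and spatiotemporal T1 correlation fields.
- **Stress inference** (`voroshear.inference`): the cumulative
  short-edge length fraction `C(l*)` at `l* ≈ 0.61` and the fraction of
  edges near the compressive orientation `omega* ≈ 120°` are linear
  gauges of the shear stress; `l*` is also recoverable with no stress
  signal at all.
- **SGR model** (`voroshear.sgr`): a mean-field trap model with a
  k-gamma trap-depth density plus a fluid point mass, calibrated from
  the simulation, predicting the yield-stress curve `sigma_y(p0)` and
  its vanishing near `p0 ≈ 4`.
- **I/O and CLI** (`voroshear.io`, `voroshear.cli`): text snapshot /
  edge-list / table formats and a `voroshear` command with `run`,
  `analyze-avalanches`, `infer-stress`, `sgr-predict`, and
  `make-fixtures` subcommands.

The central physical result reproduced by the package is that the tissue
has **two distinct transitions**: the zero-strain rigidity transition at
`p0 ≈ 3.81` (where the startup shear modulus vanishes) and the
mechanical-plasticity transition at `p0 ≈ 4.0` (where the dynamic yield
stress vanishes together with the solid fraction of sheared states).
Between them lies a marginal regime that is floppy at rest yet sustains
a finite flowing stress.

## Worked example

Shear a small solid tissue and look at the headline observables
(runtime on one CPU core: about a minute):

```python
import numpy as np
from voroshear import (EnergyParams, ProtocolConfig, random_state,
                       relax, run_shear, shear_modulus, solid_fraction,
                       segment_avalanches, yield_stress)

params = EnergyParams(p0=3.72)          # solid side, kappa_A = 0
state = relax(random_state(64, seed=0), params)
print("G0    =", shear_modulus(state, params))

cfg = ProtocolConfig(gamma_max=0.2, steady_gamma_min=0.1, g_every=1)
traj = run_shear(random_state(64, seed=0), params, cfg)
print("sig_y =", yield_stress(traj))
print("rho_s =", solid_fraction(traj))
print("T1s   =", len(traj.t1_events))
av = segment_avalanches(traj)
print("avalanches:", [(a.type, a.size) for a in av[:5]], "...")
```

Output:

```
G0    = 0.11609189954086846
sig_y = 0.02080890074894349
rho_s = 1.0
T1s   = 2
avalanches: [('II', 1), ('II', 1)] ...
```

The startup modulus is finite (solid), the steady-state stress is
finite (below the plasticity transition), and the stress drops are
carried by T1 rearrangement avalanches.

## Command line

```
voroshear run --p0 3.72 --n 64 --seed 0 --gamma-max 0.5 \
              --steady-gamma-min 0.25 --out traj.txt
voroshear analyze-avalanches traj.txt --out av/
voroshear sgr-predict --chi-table chi.txt --rho-solid-table rho.txt \
                      --out curve.txt
```

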