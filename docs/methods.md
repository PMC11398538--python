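# Methods

This document records the model, the numerical choices, and the known
limitations of `voroshear`.

## 1. Model

### Energy functional

The tissue is a confluent monolayer of `N` cells in a periodic box of
area `N` (unit mean cell area). The degrees of freedom are the cell
centers `r_i`; the cell shapes are the Voronoi polygons of the centers.
The dimensionless energy is

```
eps = sum_i [ kappa_A * (a_i - 1)^2 + (p_i - p0)^2 ]
```

where `a_i` and `p_i` are the area and perimeter of cell `i` and `p0` is
the target shape index. The default regime sets `kappa_A = 0` (perimeter
energy only, with the Voronoi constraint keeping areas near 1) and unit
perimeter stiffness. `p0` is the single control parameter: low `p0`
produces a rigid solid, high `p0` a floppy zero-energy fluid, with a
rigidity transition near `p0 ≈ 3.81` at zero strain.

### Periodic geometry under simple shear

Simple shear with strain `gamma` is imposed through Lees–Edwards
boundary conditions: crossing the box in `y` carries an `x` offset of
`gamma * Ly`. Because offsets differing by a multiple of `Lx` are
equivalent, every imaging operation (position wrapping, minimum-image
separation, ghost replication, edge bookkeeping) uses the *reduced*
offset

```
s(gamma) = gamma*Ly - round(gamma*Ly / Lx) * Lx  in [-Lx/2, Lx/2)
```

so that the tessellation is exactly periodic in strain with period
`Lx / Ly` and remains correct at strains beyond 1.

### Tessellation

The Voronoi diagram is built from a Delaunay triangulation of the cell
centers plus a band of ghost images (width `margin`, default 2.5 length
units, sufficient for near-uniform point sets). Polygon vertices are the
circumcenters of the Delaunay triangles. A triangle of the periodic
tessellation is guaranteed correct only if its full circumcircle lies
inside the replicated band (otherwise an excluded image point could
invalidate it), so after each build the code checks that every
circumcircle touching a primary cell is contained in the band and
retries with a doubled margin if not. Tessellation of a degenerate point
set (cocircular quadruples at machine precision, coincident points)
raises `DegenerateTissueError` rather than returning a silently wrong
mesh.

### Forces, stress, and moduli

Forces are the exact analytic gradient of the energy with respect to the
cell centers, including the motion of the Voronoi vertices
(circumcenters) with the generators. They are validated against central
finite differences of the energy to a relative accuracy of `1e-6`.

The shear stress is the virial expression

```
sigma = (1/(2*A_box)) * sum_edges T_e * l_e * sin(2*theta_e)
```

with edge tension `T_e = 2*(p_a - p0) + 2*(p_b - p0)` summed over the
two cells adjacent to edge `e`, length `l_e`, and orientation
`theta_e`. For the Voronoi model this equals the strain derivative of
the energy density under an *affine deformation of the polygon
vertices at fixed topology*; `affine_energy_slope` implements that
deformation directly and is used as the numerical oracle for the stress
(agreement to `1e-6` relative).

Because the true degrees of freedom are the centers, not the vertices,
the quasi-static modulus is computed from the stress rather than from
the energy curvature:

```
G = dsigma/dgamma |_r  -  (grad_r sigma) . H^+ . Xi
```

where `H` is the Hessian of the energy in the center coordinates, `Xi =
d(grad_r eps)/dgamma` is the affine force, and `H^+` the pseudo-inverse
with the two trivial translation modes (and any numerically null modes)
projected out. This matches a full re-minimized finite-difference
modulus to better than `1e-5` relative on solid states. The
finite-difference oracle `finite_difference_modulus` shears the box by
`±dgamma`, re-minimizes, and differences the stress.

## 2. Quasi-static shear protocol

Strain is applied in steps of `dgamma = 2e-3` by an affine
transformation of the centers plus a shift of the Lees–Edwards offset,
followed by energy minimization at fixed strain:

1. a short L-BFGS pre-relaxation (cheap descent to the basin),
2. FIRE with the standard parameter set (`dt_max` scaling, `N_min = 5`,
   `f_inc = 1.1`, `f_dec = 0.5`, `alpha_start = 0.1`),
3. a Newton polish with a finite-difference Hessian once the residual
   force falls below `polish_tol = 1e-4`, driving it to the target
   `force_tol = 1e-14`.

In the fluid phase the minimum lies on a zero-energy manifold where the
residual is pure roundoff and cannot reach `1e-14`; a state with energy
below `1e-22` *and* residual below `1e-12` is accepted as converged
("floor rule"), and its shear modulus is reported as exactly 0. Failure
to converge raises `MinimizationError` carrying the best state reached.

Per recorded frame the protocol stores positions, strain, energy,
stress, residual, the Delaunay adjacency (for T1 detection), and
optionally the linear-response modulus. T1 events are detected as
matched lost/gained neighbor pairs between consecutive frames; FIRE
iteration counts provide a within-step "time" coordinate for events
recorded from minimization snapshots.

### Yield stress and solid fraction

The macroscopic yield stress is the steady-state average of `sigma`
over `gamma >= steady_gamma_min`. The solid fraction `rho_solid` is the
fraction of steady-state frames whose modulus exceeds a noise floor of
`1e-8`: it interpolates between 1 (always rigid between plastic events)
and 0 (never rigid), and is the order parameter of the mechanical
plasticity transition — the yield stress vanishes together with
`rho_solid` near `p0 ≈ 4`, noticeably above the zero-strain rigidity
point `3.81`.

## 3. Plasticity analysis

Avalanches are contiguous strain steps with a stress drop exceeding
`1e-6` that contain T1 events; the size `s` is the T1 count. Avalanches
are typed by the mechanical state of the precursor frame: **type II**
(solid precursor, modulus above the noise floor — elastic loading
released by a plastic event) and **type I** (fluid precursor). Type-II
sizes follow a power law `P(s) ~ s^tau` with `tau ≈ -1.36`.

The exponent is fitted by discrete maximum likelihood (Hurwitz-zeta
normalization) with bootstrap standard errors and a Kolmogorov–Smirnov
goodness test calibrated by simulation from the fitted law. Synthetic
power-law samples for the calibration use an exact discrete rejection
sampler (no truncation bias).

Spatiotemporal correlations between T1 events use the conditional
probability field `phi(r, dt)`: given an event at the origin, the
probability that a later event at lag `dt` falls in the displacement
bin `r`, counted over both pair orders and mirrored (`r -> -r`), so the
field is symmetric by construction. Under a Poisson null the folded
field is flat (chi-squared test after dividing the 4-fold multiplicity
out of the folded counts). On sheared solids the inter-peak separation
and the field width along the flow direction grow with lag.

The kinematic susceptibility of an edge of length `L` and orientation
`phi` under shear rate `gamma_dot` is `dL/dt = gamma_dot * L *
sin(2*phi)`; it is most negative (fastest shrinking, T1 trigger) at
`phi = 3*pi/4`.

## 4. Stress inference from edge statistics

From a single frame's edge ensemble two stress-free statistics are
computed:

- `C(l)`: the cumulative length fraction carried by edges shorter than
  `l`,
- `F(omega)`: the fraction of edges whose orientation lies within a
  window `delta_omega` (default 18 degrees) of `omega`.

Scanning `(l, omega)` for the best linear correlation of `C(l)` and
`F(omega)` with the known shear stress across steady-state frames gives
a ridge of high `|R|` with a maximum near `l* ≈ 0.61` and `omega* ≈ 120
degrees`: short-edge abundance and the population of edges near the
compressive orientation are linear stress gauges. The same `l*` is
recoverable *without any stress signal* by scanning the cross
correlation of `C(l)` with `F(omega*)` over frames
(`lstar_without_stress`), which is the basis for stress inference from
static images. `avalanche_risk` bins an arbitrary scalar risk signal
against observed event counts to produce an empirical risk curve.

## 5. Soft glassy rheology (SGR) model

The mean-field trap model uses a k-gamma trap-depth density

```
rho(E) = (1 - f0) * kappa^kappa / Gamma(kappa) * E^(kappa-1) * exp(-kappa*E) + f0 * delta(E)
```

with shape `kappa = 2` and a point mass `f0` at zero depth representing
the fluid-like element fraction. An element of depth `E` strained by
`l` yields with Arrhenius rate `exp(-(E - k*l^2/2)/chi)` at effective
temperature `chi`; the elastic constant is `k = 0.0386` (calibrated
from the simulated mean stress drop per T1). The steady state under
rate `gamma_dot` is solved by quadrature using the log-erfi closed form
of the survival function; the macroscopic stress is `k * <l>`.

In the quasi-static limit the yield stress has the closed form

```
sigma_y(chi -> 0, f0 = 0) = sqrt(k/2) * <E> / <sqrt(E)>
                          = sqrt(k/2) * kappa * Gamma(kappa) / Gamma(kappa + 1/2)   (at unit mean depth)
```

used as a 1% oracle for the numerical rate-ladder extrapolation
(`quasistatic_yield_stress` evaluates a decreasing sequence of rates
and Richardson-extrapolates). `sigma` is monotone decreasing in both
`chi` and `f0`.

The calibration maps simulation to the model: `chi` from the ratio of
the mean per-event energy release to the mean trap depth, and `f0(p0)`
by inverting the measured solid fraction through `solid_fraction_map`
(`rho_solid = 1 - f0` weighted by the trapped-element survival). The
predicted yield curve `sigma_y(p0)` is proportional to `rho_solid(p0)`
at fixed `chi` and vanishes where the solid fraction does, near
`p0 ≈ 4`. At a finite smallest ladder rate a fully fluid system retains
a tiny residue (`~1e-6`), which is why "vanishing" is assessed against
a `1e-4` tolerance.

## 6. Problem sizes

The package's reference ensembles are sized to run on a single CPU
core in minutes:

- `N = 64` cells per realization,
- startup-rigidity scan: 8 values of `p0` in `[3.74, 3.88]` times 8
  seeds at `gamma = 0`,
- solid ensemble: `p0 = 3.72`, strain ramp to `gamma_max = 0.6–0.7`
  with steady-state statistics from `gamma >= 0.3`, 3–4 seeds,
- transition scan: `p0 in {3.90, 3.95, 4.00, 4.05}`, ramp to 0.5,
  steady statistics from 0.25.

These sizes reproduce all the qualitative results and the headline
numbers within the stated tolerances. Larger systems (`N = 400`,
`gamma_max = 6`, tens of seeds) sharpen the statistics — particularly
the avalanche exponent, whose desk-scale tail counts are small — at
proportionally larger cost; the protocol defaults (`dgamma`,
`force_tol`) are already the production values, so scaling up is a
matter of `n`, `gamma_max`, and seed count only.

## 7. Assumptions and limitations

- **Voronoi constraint.** Cells are Voronoi polygons of their centers;
  arbitrary vertex configurations (as in free-vertex models) are not
  representable, and the stress/modulus formulas are specific to this
  constraint.
- **Athermal, quasi-static.** No thermal noise and no rate dependence
  in the simulation; rate effects enter only through the SGR model.
- **`kappa_A = 0` default.** The perimeter-only regime is the one
  studied quantitatively; `kappa_A > 0` is supported by the energy,
  force, and stress code but the protocol-level results are not
  characterized there.
- **Finite-size effects.** At `N = 64` the rigidity point and the
  avalanche exponent carry ensemble scatter of order the stated
  tolerances; individual seeds can deviate more. Three statistics are
  known to be out of reach at the desk scale and need the larger
  ensembles (`N = 400`, long ramps, tens of seeds):
  the type-II avalanche exponent (the system-size cutoff near `s ~ 10`
  and the small event count bias the maximum-likelihood exponent steep,
  to ~`-2.1 ± 0.24` instead of `-1.36`), the stress-free `l*` region
  (the `R_{C,F}` maximum sits on a high-`l` anisotropy channel at
  `l ≈ 0.9` because per-frame edge counts are small; the fixed-`120°`
  column still peaks at `l ≈ 0.65`), and the growth of the
  correlation-field peak separation and width with time lag (only a few
  tens of reference events populate the central slices).
- **Degenerate tessellations.** Perfect lattices at special strains
  produce cocircular quadruples; the tessellation refuses (raises)
  rather than breaking ties arbitrarily. The shear protocol avoids
  this by starting from disordered states.
- **Modulus pseudo-inverse cutoff.** Null-mode projection uses a fixed
  relative eigenvalue cutoff; marginal states with near-zero but
  physical modes can make `G` sensitive to that cutoff. The
  floor rule reports such states as fluid (`G = 0`) only when the
  energy itself is at roundoff.
- **SGR mean-field.** The trap model has no spatial structure, so it
  predicts yield stress and its `p0` dependence but not correlations
  or avalanche geometry.
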