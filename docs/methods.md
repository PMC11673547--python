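# Methods

This note documents the model equations, the numerical choices, the
defaults and their rationale, and what the validation scenes do and do not
establish.

## Vessel geometry

The bifurcation is defined by three adjustable parameters: bifurcation
index `n`, radius ratio `r = rd1^n / rd2^n`, and total branching angle
`A`. Radii always satisfy Murray's law `rp^n = rd1^n + rd2^n`; daughters
are labelled so `rd1 <= rd2`. The branching angles follow the
minimum-pumping-power relations, which are the angle relations of a
triangle with sides `rp^2, rd1^2, rd2^2`; the closed form for `cos(A)` is
therefore an exact consistency check on `alpha + beta` and is verified to
1e-6 degrees on every construction. When `A` is imposed instead (the
study designs that vary the angle independently), it is split between the
daughters in proportion to the optimal split; for configurations whose
optimal angle degenerates to zero (`n = 2` with equal daughters) the split
is symmetric. Imposing `A` never alters the radii, so the Murray identity
holds for every constructed vessel.

Coordinates: parent axis along +y, inlet at y = 0, bifurcation in the x-y
plane, daughter 1 rotated by `+alpha`, daughter 2 by `-beta`. Segment
lengths are free parameters (default: parent and daughters both `8 rp`;
the model itself does not constrain them).

The lumen is implicit. Each daughter's radius blends from `rp` at the
junction to its own radius over a blend length (default `2 rp`) through
the sigmoid `F(d) = a1 G(a2 d + b2) + b1`. A sigmoid's derivative is never
exactly zero at a finite endpoint, so first-derivative continuity at the
blend ends is enforced to tolerance by fixing the dimensionless sharpness
`a2 * blend_length = 20`, which keeps the endpoint slope below 1e-3 of the
mid-blend slope. The parent tube is capped at the junction plane and the
daughters are capped at the junction from the other side; inlet and outlet
planes carry no wall (particles are recycled there instead). Signed
distances and outward normals are closed-form per branch; the lumen is the
min-union of the branches and, when a lesion is active, of its bulge
sphere. The union can only ever enlarge the lumen.

## Fluid solver

Blood is water-like: rest density 1000 kg/m^3, equal-mass particles
`m = rho0 * spacing^3` at lattice spacing `h/2` (about 30-40 neighbors for
an interior particle). Density uses the poly6 kernel including the self
term; pressure forces use the symmetrised spiky-gradient form (pairwise
equal and opposite); viscosity uses the viscosity-kernel Laplacian with
the dimensionless coefficient `mu = 4.0`. The printed model constants
carry no unit system that closes; they are treated as the defining
coefficients of the scheme and are all configurable.

Incompressibility is enforced as a coupled pair of corrections run every
frame after a semi-implicit Euler step:

1. a *density-invariance* pass in the position-based-fluids family:
   constraint `C_i = max(rho_i/rho0 - 1, 0)` (compression only — free
   boundaries are allowed to be rarefied, as is standard), Lagrange
   multipliers with a relative regulariser of 1e-6, iterated until the max
   density error is below `density_tolerance` (default 1%) or the
   iteration cap (default 16) is reached; accumulated displacements are
   folded back into the velocities;
2. a *divergence-free* pass in the DFSPH family on the velocities,
   iterated until the mean |d rho/dt|/rho0 falls below
   `divergence_tolerance` (default 1 s^-1). Two stabilisers are standard
   and necessary: 0.5 Jacobi under-relaxation (the symmetric pair update
   otherwise overshoots the pairwise solution by exactly 2x), and
   excluding particles with fewer than 20 neighbors from driving the
   constraint, since their apparent divergence is kernel truncation, not
   flow. Multiplier state is not warm-started across frames; at steady
   state the density pass converges in 1-3 iterations from scratch, so
   warm starting buys little here and cold starts keep frames independent
   given positions and velocities.

Solver failure to converge within the caps is reported (residuals in the
frame report, a warning in standalone use), not fatal.

A state-equation pressure `p = max(0, k (rho - rho0))` (stiffness `k` =
50 m^2/s^2) is maintained for force analysis and export only; the
projection, not this pressure, enforces incompressibility.

**Walls.** The boundary is the analytic implicit surface; there is no wall
particle layer. An escaped particle is projected along the inward normal
to half a spacing inside the wall (a short Newton iteration, since the
blended-radius SDF is not exactly metric), its outward normal velocity is
removed (no penetration, free slip) and its tangential velocity is damped
by `1 - mu_b * dt` with `mu_b = 30.0` — the wall-side viscous interaction
of the model. The collision never increases kinetic energy.

**Circulation.** Flow is driven by a plug inflow (default 0.5 m/s, a
configuration choice — the model states no body force and no inflow
profile) imposed in a short forcing zone at the inlet, plus recycling:
particles crossing a daughter outlet (or drifting backwards past the
inlet) are re-inserted at the inlet on a jittered disk position drawn from
the run RNG, with plug velocity. Insertions per frame are capped at the
number of inlet slots; surplus crossers stay queued beyond the outlet.
Particle count and total mass are conserved exactly.

## Aneurysm growth

The lesion is saccular: a sphere of radius `R` centred at
`site + 0.5 R n_hat`, so it stays attached to the wall and forms a mouth
(the offset factor is configurable). Growth follows the force balance
`F_aneurysm = F_blood - F_fluid - F_protein` with

* `F_blood`: each particle within the capture radius (default `2h`)
  contributes `(m_i/rho_i)(-grad p_i + mu lap v_i + F_adv)`; the maximum
  projection on the outward site normal, clamped at zero, is used. The
  clamp encodes the growth-only scope: inward pushes cannot shrink a
  lesion.
* `F_fluid = rho_f c s v_w` with `v_w = dR_prev / t_growth` — the
  surrounding tissue fluid as a compressible pseudo-fluid.
* `F_protein = (K_C S_C + K_E S_E) * dR_prev / R` — collagen and elastin
  as linear springs under hoop strain `sigma = dR/R`.

The increment `dR = F_blood / (m/t^2 + rho_f c s/t + (K_C S_C+K_E S_E)/R)`
is evaluated every `growth_interval` frames (default 10) rather than every
step — growth is vastly slower than the flow and the interval emulates the
accelerated-lesion timescale while keeping the solver stable. The law's
printed constants mix dimensions; no dimensional consistency is asserted.
`m` (effective wall mass, default 1 kg) and `t` (growth timescale, default
1 s) close the law and are configurable, as is everything else in it.
Rupture is out of scope.

## Wall shear stress

Wall particles are fluid particles within `delta` (default `h/2`, one
spacing) of the wall; each carries the outward normal at its wall
projection, and normal coordinates are measured along that normal from
the projection point (this is what "perpendicular to the wall" means on a
curved wall). The WSS sum accumulates the *tangential vector*
`sum_j m_j C_xi v_t,j / rho_j * dW/dx_n` and reports `mu` times its
magnitude — the continuum WSS is the magnitude of the tangential traction,
and this form reduces to `|mu dv_t/dx_n|` in the planar Couette limit
(verified analytically: the full-support moment of the spiky radial
derivative integrates to exactly -1).

`N_bar` averages neighbor counts over *all* fluid particles, not only wall
particles, and both `N_bar` and `C_xi = N_bar/N_i` are recomputed every
frame. The dimensionless `mu = 4.0` is used verbatim inside the sum; an
optional `mu_phys` rescales reported values to a physical viscosity — the
two are proportional, so every structural comparison is unaffected.

## Validation scenes and what they show

The fixtures are synthetic scenes with known answers: a free cube settling
in a box (density residual under gravity), a planar Couette channel with
an imposed linear shear (WSS against `mu*gamma`; central bottom-wall
particles agree within a few percent after correction), a straight tube
with plug flow (circulation bookkeeping, growth), and single-particle
cases (closed-form density). They exercise the numerics, not the
physiology: a real artery is elastic, pulsatile, non-Newtonian and
patient-shaped, and none of that is modelled. Passing these scenes shows
the discretisation and the corrections behave as designed at desk scale,
not that the simulator is clinically predictive.

**Reference run sizes.** The reference correction-coefficient study uses
the G2 preset at desk scale: parent radius 0.06 m against `h = 0.025 m`,
segment lengths `8 rp`, ~5,400 particles, 200 priming frames and 600
recorded frames. At this scale the time-averaged frame-mean `C_xi` falls
around 1.29 with frame means in roughly [1.27, 1.31] — wall-adjacent
particles see on average a quarter fewer neighbors than the bulk. The
multi-scenario orifice study uses reduced vessels (`rp = 0.05 m`, lengths
`4 rp`, ~1,600 particles), 250 priming frames (about one vessel transit,
so the recorded window is quasi-steady), 350 recorded frames sampled
every other frame, a common seed across scenarios (a paired design: with
shared random numbers, differences between cases are structural), and an
orifice patch of 2.5 lesion radii so each sample averages a few dozen wall
particles. Scenario differences are summarised by a ranked-separation
score: the spread of series means over the pooled within-series standard
deviation.

## Known limitations

* No wall particle layer: near-wall density is systematically low, which
  the compression-only constraint tolerates but which softens the fluid
  near boundaries.
* The inflow forcing zone imposes a plug profile rather than developing
  one; entry lengths are not physical.
* Growth increments at desk scale are micrometres per evaluation — the
  lesion's geometric feedback on the flow is weak within a short run;
  long-horizon growth studies need many more frames or a larger
  `t_growth`-side scaling.
* The WSS field is noisy frame to frame (particle discreteness plus wall
  collisions); structural comparisons should always be made on
  time-averaged series, as the studies module does.
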