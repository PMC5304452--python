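# Methods

`phonosim` simulates voice production as a three-way interaction between
glottal airflow, vocal fold tissue dynamics and duct acoustics, at a
size that runs on a single workstation core.  This note records the
models, the numerical choices, the parameters that matter, and the
limits of what the desk-scale configuration can and cannot show.

## Physical model

**Airflow.** The glottal flow is incompressible, viscous and unsteady:

    div U = 0
    dU/dt + (U . grad) U = -(1/rho0) grad P + nu0 lap U

with air density `rho0 = 1.1455 kg/m^3` (body temperature) and kinematic
viscosity `nu0 = 6.6e-5 m^2/s`.  The viscosity is deliberately inflated
(about 4x air) so the glottal Reynolds number is roughly a quarter of the
physiological value; this keeps the desk grids meaningful at the price of
suppressing fine supraglottal turbulence.  The flow is driven by a fixed
transglottal pressure drop, gauge `+dP` at the tracheal inlet and `0` at
the mouth (default `dP = 800 Pa`, a moderate loudness), applied as
Dirichlet pressures with zero-gradient velocity.  The drop is ramped in
over `pressure_ramp` (default 1 ms) so the start-up does not act as an
impulsive acoustic source.

**Acoustics.** Sound is carried by the linearized perturbed compressible
equations (LPCE) riding on the incompressible solution:

    d(rho')/dt + (U . grad) rho' + rho0 div u'            = 0
    d(u')/dt   + grad(u' . U) + (1/rho0) grad p'          = 0
    d(p')/dt   + (U . grad) p' + gamma P div u' + (u' . grad) P = -DP/Dt

The material derivative of the incompressible pressure is the sound
source.  `P` in the `gamma P div u'` term is the absolute pressure: an
ambient part fixed by the speed of sound through
`c = sqrt(gamma P_amb / rho0)` (default `c = 352 m/s`, so
`P_amb ~ 101.4 kPa`), plus the incompressible gauge pressure.  Total
fields reported downstream are sums: `p = P + p'`, `u = U + u'`.
Boundary conditions follow the hard-walled, fully reflective convention:
`du'/dn = 0`-type wall mirrors on all duct and fold surfaces, `p' = 0`
and `u' = 0` at the inlet, and a complete-reflection open end
(`p' = 0`, zero velocity gradient) at the mouth.  These lossless
boundaries exaggerate acoustic flux on purpose — they are the standard
idealization for this model family — so acoustic amplitudes should be
read comparatively, not absolutely.

**Tissue.** Each vocal fold is a layered linear viscoelastic continuum
(cover / ligament / body) obeying the Navier equation.  The material is
transversely isotropic with the isotropy plane in the coronal cross
section and the stiff axis along the anterior-posterior direction; each
layer carries five elastic constants plus a Kelvin-Voigt viscosity
(`sigma_visc = eta de/dt`).  Reference values (SI-converted from the
conventional g/cm^3, kPa, poise):

| layer    | rho (kg/m^3) | E_p (kPa) | nu_p | E_pz (kPa) | nu_pz | G_pz (kPa) | eta (Pa s) |
|----------|--------------|-----------|------|------------|-------|------------|------------|
| cover    | 1043         | 2.01      | 0.9  | 40         | 0.0   | 10         | 0.5        |
| ligament | 1043         | 3.31      | 0.9  | 66         | 0.0   | 40         | 0.75       |
| body     | 1043         | 3.99      | 0.9  | 80         | 0.0   | 20         | 1.25       |

The large longitudinal moduli realize the in-plane motion constraint: in
a 3D fold they raise the fundamental frequency several-fold and keep the
vibration essentially coronal.  A hard floor on axial motion remains —
clamped-end bending kinematically requires an axial displacement of
order (thickness/length) times the transverse one — so "in-plane" means
dominance, not absence.

**Contact.** Fold collision is modeled by two artificial non-slip,
non-penetrable planes at `+-0.1 mm` about the medial plane: any surface
node crossing its plane is projected back onto it with zero velocity and
released when the dynamics pull it away.  This enforces a minimum
glottal gap of exactly 0.2 mm; the resulting leakage flow during
"closure" is the price of keeping a fluid passage the flow solver can
resolve.

## Geometry

All geometry is parametric and synthetic.  The duct is a straight
channel along the inferior-superior axis: 3.05 cm subglottal section,
the glottal span, and a 17.4 cm supraglottal tract (so the tract acts as
a quarter-wave resonator with F1 = c/4L ~ 506 Hz).  The folds are a
mirror-symmetric pair whose medial surface is piecewise linear: a
convergent entry ramp, a straight medial segment at the rest half-gap
(default 0.2 mm), and a divergent exit ramp; entry/exit angles and
fractions are configurable.  Layer tags are assigned by distance from
the loaded (medial + inferior + superior) surface: cover within 0.5 mm,
ligament within the next 1.1 mm, body elsewhere.

Two representations are generated from the same specs: a signed-distance
level set sampled on the flow grid (fluid positive) and a simplicial FE
mesh (triangles in 2D, tetrahedra by extrusion in 3D, with fixed
anterior/posterior end planes).  During a coupled run the level set is
rebuilt every step from the deformed FE boundary polygons, evaluated
analytically near the folds and falling back to the static duct distance
elsewhere.

**2D mounting.** A 2D coronal section has no anterior/posterior
attachment, so nothing carries the net superior push of the subglottal
pressure (~7 N/m per fold at 0.8 kPa) and a faithful 2D fold with the
reference moduli deflects by millimetres.  The desk preset therefore
mounts the fold in a recess: the inferior and superior surfaces are
clamped lateral of `mount_x` (default 4 mm from the midline), exactly
the way physical fold replicas are glued into a backing block.  For the
same reason the desk preset scales the three elastic moduli of every
layer by 5x ("2D-equivalent stiffness"); the reference values above
remain the package defaults and are what the solid-solver tests verify.

## Discretization

**Flow** uses a staggered (MAC) arrangement on a non-uniform Cartesian
grid refined around the glottis, and a fractional-step scheme: explicit
advection (second-order central blended with first-order upwind,
`upwind = 0.4` by default in coupled runs, 0 in the verification tests),
explicit diffusion, then a pressure Poisson projection solved by a
cached sparse LU factorization (re-factorized only when cell tags
change).  Discrete continuity holds to solver precision (~1e-14).

The immersed folds are treated sharp-interface / ghost-cell: velocity
nodes just inside the solid mirror the fluid field about the boundary so
interpolated wall velocities equal the local tissue velocity.  Two
details matter and are easy to get wrong:

* *Momentum vs continuity values.*  Mirrored ghost values are used only
  in advection/diffusion stencils.  The projection sees the wall at cell
  granularity: any face not between two fluid cells carries exactly the
  local tissue-velocity component (zero for static walls).  Using the
  mirrored values in the divergence leaks mass through the boundary at a
  rate comparable to the glottal flow itself.
* *Pressure decoupling.*  Pressure cells behind the interface are
  excluded from the Poisson system (homogeneous Neumann), so wall
  pressure never contaminates fluid stencils.

**Acoustics** uses sixth-order tridiagonal compact differences with
fourth/third-order one-sided closures, classical four-stage Runge-Kutta
in time, and an explicit low-pass filter (eighth order in the interior,
reduced order near boundaries) applied every substep; the reduced-order
boundary rows are what keep the one-sided closures stable under RK4.
Non-uniform grids are handled by the index-space metric of the same
scheme.  Around the immersed folds the operators are assembled *segment
wise*: on every grid line, each contiguous run of fluid cells (extended
by its ghost endpoints) gets its own compact system, so the tridiagonal
inverse never couples fluid points across a solid wall — with a single
global operator the scheme is violently unstable.  Runs shorter than 8
cells degrade to explicit second/first-order differences.  The whole
subcycle loop (20 RK4 substeps per flow step, `dt_ac = dt_flow / 20`)
runs inside a numba kernel; a pure scipy path implements the same
operators (banded `A f' = B f` solves) and a test asserts the two paths
agree to round-off.

**Tissue** is discretized with linear simplices and marched by
Newmark-beta (average acceleration), unconditionally stable and
energy-conserving without damping; the effective matrix is factorized
once per time-step size.  2D runs use plane strain with the isotropy
plane in-plane.

**Coupling** is the explicit staggered loop: flow step -> 20 acoustic
subcycles (frozen U, P, DP/Dt) -> surface traction
`-(P + p') n + viscous` sampled one cell off the surface on the fluid
side -> solid step -> contact projection -> lumen update (markers, level
set, tags, fresh-cell fill).  One deliberate stabilization is added to
the textbook loop: the traction is smoothed exponentially over a few
steps (`traction_relax = 0.2`, lag ~ 5 dt ~ 12 us against vibration
periods of ~4 ms).  Without it the loose exchange develops the classic
added-mass two-step flip-flop as soon as the glottis narrows, because
moving the channel walls must instantaneously squeeze fluid through the
small gap.  The smoothing is three orders of magnitude faster than any
physical timescale in the problem.

## Desk-scale study conditions

The `desk2d` preset is the package's runnable phonation case: 2D, grid
44 x 96 cells (finest ~0.14 mm across the glottis, ~0.34 mm along it),
`dt_flow = 2.5 us` (advective CFL ~ 0.4 at the observed jet speeds;
acoustic subcycle CFL ~ 0.45), fold pair with 0.2 mm rest half-gap, 45
degree entry/exit ramps, recess mounting at 4 mm, 2D-equivalent moduli
(5x), reference air/acoustic constants and contact model.  The preset
starts from the folds' static equilibrium under the developed flow (800
rigid-fold flow steps, one static solve, clocks reset): starting from
rest instead adds ~50 ms of slow mean-position settling before the limit
cycle is clean, with no effect on the limit cycle itself.  Flow rates
are reported in mL/s using a 16 mm effective anterior-posterior depth.
A run of 20 000 steps covers ~50 ms — with the equilibrium start, an
amplitude-growth phase of ~10 ms followed by a clean limit cycle at the
fundamental frequency the preset settles into (~230-240 Hz).  The test
suite integrates a 16 000-step version of the same preset and asserts
the qualitative phonation physics on the final eight cycles: sustained
periodicity, convergent-during-opening / divergent-during-closing
glottal geometry, and 1:1 frequency locking of the two leading POD
coefficients.

The `paper3d` preset records the full-scale 3D constants (64 x 256 x 192
grid, dt = 1.149 us, ~29 000 tets, 60 000 steps) for reference; loading
and validating it works, but running it is a cluster-scale exercise and
the 3D flow/acoustic solver paths are not implemented — the 3D code
paths cover geometry, level sets and the FE solid only.

## Analysis conventions

* `F0` is measured from the periodicity of the *opening* signal
  (parabolically interpolated spectral peak; autocorrelation as
  fallback), because acoustic ripples contaminate flow-rate periodicity.
* The open quotient `tau0` counts the phase-averaged opening as "open"
  above the cycle minimum plus 5 % of the min-to-peak range, which makes
  it insensitive to the artificial 0.2 mm leakage gap.
* The skewness quotient `tau_s` is computed on the phase-averaged
  *incompressible* flow rate; rise runs from the pulse onset (last
  near-minimum bin, threshold 1 % of the pulse height) to the peak, fall
  from the peak to the next near-minimum bin, so a flat closed phase
  contributes to neither.
* POD uses the snapshot method (SVD of mean-centered displacement
  snapshots of the medial surface); energies are fractions of the total
  fluctuation variance.
* Spectra are Hann-windowed one-sided amplitude spectra with coherent
  gain compensated.

## What passing the desk tests does and does not show

The synthetic geometry reproduces the *topology* and scales of the
physiological airway (layered folds, narrow glottis, sub/supraglottal
ducts) but none of its anatomical irregularity; the 2D section cannot
show anterior-posterior (zipper-like) modes, and the reduced Reynolds
number plus the upwind blend suppress supraglottal jet turbulence, so
high-frequency broadband content is absent by construction.  Quantities
tied to full-scale 3D runs — F0 near 200 Hz with unscaled moduli, the
specific open/skewness quotients, POD energy percentages — are reported
by the desk runs but are not expected to match 3D reference values; what
the desk configuration demonstrates is the mechanism: self-sustained
flow-induced oscillation, mucosal-wave-like convergent/divergent motion,
source-filter interaction through a quarter-wave resonator, and an
acoustic flow component of the same order as the incompressible one.

## Numerical edge cases

* Grid lines whose fluid run shrinks below 8 (even 2-3) cells keep
  working at reduced order; an isolated fluid cell gets a zero
  derivative.
* A ghost cell whose image-point stencil contains no fluid cell falls
  back to the nearest fluid value.
* Cell re-tagging as the folds move triggers rebuilds of the segmented
  acoustic operators and the Poisson factorization; fresh fluid cells
  are filled from fluid neighbors (acoustics) or the local wall velocity
  (flow).
* Contact projection zeroes all velocity components of a captured node
  (non-slip) and releases it purely through the dynamics.
* Checkpoints store every state array including the traction-smoothing
  accumulator, so a restore continues bit-identically on the same
  platform.
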