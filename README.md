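# phonosim

Desk-scale simulation of voice production as a three-way
fluid-structure-acoustics interaction: incompressible glottal airflow,
finite-element vocal fold tissue, and duct acoustics, coupled in an
explicit staggered loop, with an analysis suite for the quantities voice
scientists actually look at (glottal waveform metrics, flow-rate
decomposition, spectra, quarter-wave formants, proper orthogonal
decomposition of the fold vibration).

It is intended for people studying phonation mechanics and
source-filter interaction who want a transparent, fully scriptable model
that runs in minutes on one core — not a production aeroacoustics code.

## The model in brief

* **Flow** — unsteady viscous incompressible Navier-Stokes,

  `div U = 0`,  `dU/dt + (U.grad)U = -(1/rho0) grad P + nu0 lap U`,

  on a staggered Cartesian grid with a sharp-interface ghost-cell
  immersed boundary for the moving folds; fractional-step projection
  with a direct sparse Poisson solve; driven by a fixed transglottal
  pressure drop (default 0.8 kPa).

* **Acoustics** — the linearized perturbed compressible equations
  (LPCE), driven by the material derivative `DP/Dt` of the
  incompressible pressure; sixth-order compact differences (assembled
  segment-wise around the immersed boundary), four-stage Runge-Kutta,
  20 acoustic substeps per flow step.  Total pressure/velocity are the
  sums `p = P + p'`, `u = U + u'`.

* **Tissue** — layered (cover/ligament/body) transversely isotropic
  linear viscoelastic folds, `rho_tiss d2d/dt2 = div sigma`, linear
  simplex FEM with Newmark-beta time stepping, fixed
  lateral/anterior/posterior boundaries, traction-loaded glottal
  surface, and a hard-wall contact model enforcing a 0.2 mm minimum
  glottal gap.

* **Coupling** — per step: flow -> acoustics (subcycled) -> surface
  traction `-(P + p') n + viscous` -> solid -> contact -> lumen update.

`docs/methods.md` documents every model choice, default and limitation.

## Worked example

Run the bundled desk-scale 2D phonation case and analyze it:

```
phonosim run desk2d --steps 20000 --output-dir out
phonosim analyze out/record.h5 --window 5
phonosim pod out/record.h5 --modes 3
phonosim formants --length 0.174 --c 352 --n 3
```

`run` prints a log line every 200 steps (step, time, minimum glottal
gap, total outlet flow, flow divergence residual, acoustic CFL) and
writes the glottal record (CSV + HDF5), a restartable checkpoint and
VTK snapshots.  On this preset the folds settle into self-sustained
vibration at roughly 230 Hz with peak openings around 0.5 mm, total
flow rates of order 100-300 mL/s, and an acoustic flow component of the
same order as the incompressible one — the source-filter interaction
the model exists to capture.  `analyze` then reports the waveform
metrics as JSON (fundamental frequency, mean/peak flow, open quotient,
skewness quotient) and writes spectra; `pod` prints the energy split of
the leading vibration modes and writes their coefficients.  `formants`
evaluates the quarter-wave resonances of the 17.4 cm tract:

```
F1 = 505.7 Hz
F2 = 1517.2 Hz
F3 = 2528.7 Hz
```

A single-solver benchmark of the acoustic module against the same
formula is built in:

```
phonosim resonance-test --length 0.174 --c 352
```

which excites a hard-walled open-closed tube with a broadband pulse and
compares the lowest spectral peak of the closed-end pressure with
`c/4L` (they agree to well under 1 %).

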