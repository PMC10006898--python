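# Methods

## Forward model

The head is an air-free hemisphere of radius r sitting on the plane z = 0;
lengths are centimetres, potentials are carried in μV, and dipole strength
is a working-unit magnitude (the literature this model family comes from
mixes Coulomb-metre and A·cm conventions; no dimensional conversion is
attempted, so strength, conductivity and potential units are consistent
tags rather than SI quantities).

A dipole is the 7-tuple (l_x, l_y, l_z, μ_x, μ_y, μ_z, s) with ‖μ‖ = 1,
s ≥ 0, and l strictly inside the hemisphere.  Sensor j receives from dipole
i the inverse-square (Biot–Savart-like) field

    f_ji = ρ_ji · s_i · g_ji·μ_i + n_j,
    g_ji = (w_j − l_i) / (4π ζ_ji d_ji³),

with two propagation factors:

* **Per-path conductivity** ζ_ji ~ U(low, high), defaults (0.1, 0.9).  A
  signal crosses an unknown mix of soft tissue, spongy and compact bone and
  skin; rather than a layered shell model, each (sensor, dipole) path gets
  one i.i.d. uniform draw.  The draw is made once per recording and held
  fixed across time samples — sources and geometry do not move, so only
  this reading makes a longer recording more informative.  The prefactor
  1/(4π ζ_ji) is applied exactly once (ζ_ji substitutes the constant ζ in
  the gain definition; applying both would square the conductivity factor).
* **Distance attenuation** ρ(d) = β − α d, with β = 1 and
  α = 0.99/(2r) fixed by two endpoint conditions: a source directly under
  an electrode loses nothing (ρ(0) = 1), and a source a full head diameter
  away is attenuated to 1% (ρ(2r) = 0.01).  ρ is deterministic given the
  geometry.

Multiple dipoles superpose linearly at every sensor.  Sources are fixed in
location, orientation and magnitude over a recording; each of the N sample
columns adds an independent Gaussian white noise draw, homoscedastic across
sensors (covariance σ²I).  σ is either given directly or derived from a
target signal-to-noise ratio, defined as a power ratio averaged over
sensors: σ² = mean_j(noiseless_j²) / SNR, default SNR = 20.  With N ≥ 100
the realized ratio is within a few percent of the target.

### Sensor placement

Random montages are area-uniform on the hemisphere (φ ~ U[0, 2π),
cos θ ~ U(0, 1]) — the standard meaning of "uniformly distributed over the
scalp"; the rim has probability zero and every generated sensor satisfies
z ≥ 0 and ‖w‖ = r.  The bundled `biosemi64` montage is the standard
BioSemi 64-electrode (10–20 family) direction table projected radially onto
the sphere of the configured radius; a handful of its electrodes sit
slightly below the equatorial plane and are kept where the standard puts
them.  Arbitrary montages load from a plain-text `label x y z` file.

## Inverse solver

The fit minimizes the weighted L2 residual

    J = ½ Σ_t (F_t − F̂(p))ᵀ W (F_t − F̂(p)),   s.t. ‖μ_i‖₂ = 1 (each i),

over the stacked 7n parameters.  W defaults to the identity.  Because the
prediction is constant in time, J decomposes exactly into a data-dependent
constant plus N/2 · ‖f̄ − F̂(p)‖²_W where f̄ is the time-averaged signal;
the implementation computes it that way, so cost evaluations are O(m · n)
regardless of N.

The 4-parameter orientation representation (unit μ plus scalar s) is used
with an explicit equality constraint per dipole, handled by SLSQP (an SQP
method satisfying the KKT conditions at the returned point).  Analytic
gradients are supplied.  Choices that matter:

* **Objective scaling.** μV-scale signals put J at 1e-9..1e-3, starving
  SLSQP's absolute ftol test; the objective is normalized internally by the
  cost of a zero prediction and reported unscaled.  Default ftol 1e-14 on
  the scaled objective, max 500 iterations per SQP run.
* **Restarts.** The SQP is restarted from its own solution up to 3 times
  (resetting the Hessian approximation buys extra digits near the optimum);
  an iteration-limit exit is treated as converged when a whole restart
  improves the scaled cost by less than 1e-9 relative at a feasible point.
* **Bounds and feasibility.** Locations are box-bounded and kept inside
  0.99 r by an inequality constraint; μ components in [−1, 1]; s in
  (0, s_max].  Constraining s > 0 removes the (μ, s) → (−μ, −s) ambiguity.
  An initial guess outside the head is an error; non-convergence is a
  reported flag, never an exception.  The constraint residual tolerance is
  1e-6.
* **Global initialization.** Multi-dipole residual surfaces are multimodal
  and plain descent from a distant guess reliably stalls in secondary
  minima.  By default the solver therefore augments the user's guess with a
  deterministic sequential coarse-grid scan (grid pitch r/8, each candidate
  joined with the already-found dipoles and all moments re-solved by linear
  least squares), followed by a joint variable-projection refinement of the
  locations (L-BFGS-B on the projected objective, envelope-theorem
  gradients).  The constrained SQP then runs from the scan start, from a
  variable-projection refinement of the user's guess, and from the raw
  user guess; the best feasible final cost wins.  The 3-parameter s·μ
  linear substep appears only inside this initialization and in the test
  suite's independent grid oracle; the returned estimate always satisfies
  the constrained 7-parameter formulation's KKT conditions.
* **Cost history.** Diagnostics record feasible iterates that improve on
  the running best (accepted iterates), a monotone sequence by
  construction; raw SQP merit-function iterates need not be monotone.

### Fitting-model conductivity

The generator's ζ_ji draws are not observable from data, so the default
**expected** fitting mode replaces them with the midpoint of the configured
range — the only model realizable on real recordings.  A **clairvoyant**
mode reuses the stored true draws and exists for model-consistency studies
on synthetic data only (in that mode the scan-derived start is reordered by
minimal-distance assignment against the stored truth so each parameter slot
keeps the conductivity column drawn for it).  The mismatch left by the
expected model acts as a per-sensor multiplicative gain error of order one
and — unlike measurement noise — does not shrink with more samples; it
dominates the expected-mode error budget (the acceptance suite measures a
median localization error of order 10% of the head diameter for the
three-dipole benchmark, versus millimetres in clairvoyant mode).

### Error reporting

Estimated dipoles are matched to true ones by minimal-total-distance
assignment (the cost is invariant to relabeling).  Localization error is
the Euclidean distance between true and matched estimated locations.  The
per-parameter error percentage is 100·|est − true|/scale with scale =
|true|, falling back to the head radius (locations) or 1 (orientation
components, strength) when the true value is below 1e-9; a dipole's "total"
error is the unweighted mean over its seven parameters.  Small-magnitude
true parameters (e.g. an orientation component of 0.17) therefore dominate
relative errors — a property of the metric worth remembering when reading
sweep tables.

## Sensitivity study

`run_sweep` walks a (sensor count × sample count) grid; each cell repeats
n_repeats times: fresh area-uniform electrode placement, fresh simulation
at the target SNR, fit from the truth perturbed by a fixed-magnitude offset
(1 cm in a seeded random direction; orientation and strength perturbed
similarly), per-parameter error percentages recorded.  Cell statistics are
means with normal-approximation 95% confidence intervals over repeats;
non-converged fits are kept in the raw table but excluded from aggregates.
Seeds are derived per (cell, repeat) by counter from one base seed, so the
sweep is deterministic and order-independent.

Defaults: the three-dipole benchmark scenario (one deep, one intermediate,
one shallow source), 20 repeats, clairvoyant fitting — the sweep probes
error versus data volume, which is noise-driven; expected-mode fitting adds
a data-volume-independent mismatch floor that masks those trends.  Each
scenario dipole is simulated and fitted **separately** by default: the
per-dipole error surfaces are only meaningful down to small electrode
counts this way, since a joint three-dipole fit has 21 parameters and is
under-determined below 21 sensors.  `fit_jointly=True` activates the trio
simultaneously (used for the depth-ordering check, where cross-talk between
nearby sources is part of the effect being measured).

`find_optimum` returns the cheapest cell (fewest sensors, then fewest
samples) attaining the smallest mean total error; `depth_effect_report`
ranks dipoles by mean total error against their depth below the scalp —
electrodes receive weaker, spatially flatter fields from deeper sources, so
deeper ⇒ larger error on average.

## What the generator does and does not emulate

It emulates: superposed static dipole fields with inverse-square decay,
path-dependent conductivity heterogeneity, distance-based attenuation,
montage geometry (random or standard), and white sensor noise at a
controlled SNR.  It does not emulate: layered-shell or realistic (BEM/FEM)
volume conduction, anisotropic conductivity, time-varying source waveforms,
correlated or non-Gaussian noise, artifacts (blinks, muscle, line noise),
or electrode-position error.  Passing tests therefore demonstrate correct
estimation under this model family, not clinical-grade localization on real
EEG.

## Problem sizes and reproducibility

The test and acceptance runs use the canonical scenario sizes — 36
electrodes × 250 samples for the three-dipole benchmark (20 Monte-Carlo
repeats where repeats are called for), 64 electrodes × 250 samples for the
8.5 cm-head study (5 seeds per dipole), and a coarse sweep grid
({19, 36, 64, 100} sensors × 500 samples and 19 sensors × {50, 100, 200,
400} samples at 10 repeats per cell).  All randomness flows from named
seeds; identical seeds give bit-identical recordings, fits and sweeps.

## Known limitations

* At the default SNR of 20, the three-dipole benchmark (three sources
  within ~3 cm of each other) is ill-conditioned enough that the global
  minimum of the noisy cost sits several millimetres to centimetres from
  the true locations even with clairvoyant conductivity — a noise floor of
  the estimation problem, not of the solver (noiseless recovery is exact to
  ~1e-4 cm, and fits started at the truth drift to the same cost level).
* Expected-mode fitting carries the irreducible conductivity-mismatch floor
  described above.
* The grid scan adds deterministic but non-trivial cost for many dipoles
  (grid size × n sequential passes); pitch is configurable.
* Units are tags, not SI; no forward-model calibration to physical μV is
  attempted.
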