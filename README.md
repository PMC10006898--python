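# dipolefit

Simulation and estimation of equivalent current dipoles from EEG-like scalp
signals on a hemispherical head model.

Localized neural activity is classically modelled as a point current dipole:
seven numbers per source — a position **l** = (l_x, l_y, l_z) inside the
head, a unit orientation **μ**, and a moment magnitude *s*.  `dipolefit`
provides both halves of the source-localization problem for this model:

* a **forward simulator** that synthesizes the m × N matrix of scalp
  potentials produced by a set of fixed dipoles, and
* an **inverse solver** that recovers each dipole's seven parameters from a
  recorded signal matrix by constrained nonlinear least squares,

plus a Monte-Carlo **sensitivity study** of how recovery accuracy depends on
the number of electrodes and the number of time samples.  It is aimed at
people prototyping or benchmarking source-localization pipelines on fully
controlled synthetic data.

## Model

The head is a hemisphere of radius r (default 10 cm) with +x through the
right ear, +y through the nasion and +z up.  Sensor j at **w**_j receives
from dipole i at **l**_i (distance d_ji = ‖**w**_j − **l**_i‖):

```
f_ji = ρ_ji · s_i · g_ji · μ_i + n_j,     g_ji = (w_j − l_i) / (4π ζ_ji d_ji³)
```

an inverse-square point-source field with two propagation factors: a
per-path conductivity ζ_ji ~ U(0.1, 0.9), drawn once per (sensor, dipole)
pair to mimic the unknown mix of brain tissue, bone and skin each path
crosses, and a received-signal-strength attenuation ρ(d) = β − αd pinned at
ρ(0) = 1 and ρ(2r) = 0.01.  Dipole contributions superpose; n_j is Gaussian
white noise whose variance is set from a target signal-to-noise power ratio
(default 20).  Sources are fixed over a recording, so only the noise varies
across the N samples.

The solver minimizes the weighted L2 residual

```
J = ½ Σ_t (F_t − F̂(p))ᵀ W (F_t − F̂(p)),      subject to ‖μ_i‖₂ = 1
```

over all 7n parameters jointly (SQP with analytic gradients, unit-norm
equality constraints handled through the KKT conditions, s > 0 to remove the
sign ambiguity).  Because multi-dipole residual surfaces are multimodal, the
solver first locates the global basin with a deterministic coarse-grid scan
in which dipole moments are eliminated by a linear least-squares substep.
Since the generator's conductivity draws are not observable, the default
fitting model replaces ζ_ji by the midpoint of its range; a "clairvoyant"
mode that reuses the true draws exists for synthetic model-consistency
studies.  See `docs/methods.md` for the full account.

## Worked example

```python
import numpy as np
from dipolefit import SolverConfig, fit, make_fixture, snr_of

fx = make_fixture("table1", seed=1)       # 3 dipoles, 36 sensors, 250 samples
rec = fx.simulate()
print(f"simulated {rec.n_sensors} sensors x {rec.n_samples} samples, "
      f"realized SNR = {snr_of(rec):.1f}")

res = fit(rec, 3, SolverConfig(initial_guess=fx.initial_guess, mode="clairvoyant"))
print(f"converged: {res.converged}, final cost J = {res.final_cost:.3e}")
for i, row in enumerate(res.estimate[res.matching]):
    err_mm = 10 * res.localization_error_per_dipole[i]
    print(f"dipole {i+1}: l = ({row[0]:+.2f}, {row[1]:+.2f}, {row[2]:+.2f}) cm, "
          f"mu = ({row[3]:+.2f}, {row[4]:+.2f}, {row[5]:+.2f}), s = {row[6]:.2f}, "
          f"location error = {err_mm:.1f} mm")
```

Output:

```
simulated 36 sensors x 250 samples, realized SNR = 22.0
converged: True, final cost J = 7.914e-05
dipole 1: l = (+2.01, +0.67, +6.34) cm, mu = (+0.68, +0.27, +0.68), s = 0.11, location error = 3.7 mm
dipole 2: l = (+2.32, +1.30, +7.50) cm, mu = (+0.28, +0.18, +0.94), s = 0.20, location error = 0.9 mm
dipole 3: l = (+2.68, +2.78, +8.58) cm, mu = (+0.32, +0.30, +0.90), s = 0.30, location error = 7.9 mm
```

The fixture's three sources sit at three depths; the fit is a joint
21-parameter constrained problem.  Location errors of a few millimetres at
this noise level reflect the estimation noise floor of three nearby
correlated sources, not solver failure — the same fit on noiseless data
recovers locations to ~1e-4 cm (see the test suite).

The same workflow is available from the shell:

```sh
dipolefit fixture --name table1 --seed 1 --out runs/
dipolefit fit --signals runs/table1.signals.csv --n-dipoles 3 --out runs/fit.json
dipolefit sweep --config sweep.yaml --out runs/sweep/
```

Recordings are stored as plain text: a signals CSV (sensors × samples), a
sensor position file and a JSON sidecar with the head model, seeds and —
for synthetic data — the ground truth.

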