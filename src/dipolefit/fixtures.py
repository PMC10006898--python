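"""Canonical synthetic scenarios used across the tests and examples.

``table1`` is the three-dipole benchmark on the 10 cm hemisphere (36
uniform-random electrodes, 250 samples, SNR ~ 20) with one deep, one
intermediate and one shallow source; ``table2`` places three dipoles in an
8.5 cm head observed by the standard BioSemi-64 montage;
``single-dipole-noiseless`` is the zero-noise scenario used for exactness
tests.  The published orientation row of the deep dipole is not a unit
vector as printed; it is normalized here (its magnitude is carried by the
strength convention unchanged).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .forward_model import DipoleParameters, EEGRecording, NoiseModel, simulate_recording
from .head_geometry import HeadModel, SensorArray, load_standard_montage, sample_uniform_sensors

__all__ = ["FixtureSet", "make_fixture", "table1_dipoles", "table2_dipoles", "FIXTURE_NAMES"]

FIXTURE_NAMES = ("table1", "table2", "single-dipole-noiseless")


def _unit(v) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    return v / np.linalg.norm(v)


def table1_dipoles() -> tuple[DipoleParameters, ...]:
    """The three benchmark dipoles (deep, intermediate, shallow)."""
    return (
        DipoleParameters((2.25, 0.82, 6.58), _unit((0.32, 0.12, 0.29)), 0.1),
        DipoleParameters((2.37, 1.37, 7.52), _unit((0.29, 0.17, 0.94)), 0.2),
        DipoleParameters((2.18, 2.18, 8.46), _unit((0.24, 0.24, 0.94)), 0.3),
    )


# Published starting points for the joint three-dipole fit, one row per
# dipole: (l, mu, s).
TABLE1_INITIAL_GUESS = np.array(
    [
        [3.0, 2.0, 3.0, 0.0, 0.0, 1.0, 0.3],
        [1.0, -3.0, 3.0, 0.43, -0.75, 0.50, 0.3],
        [1.0, 0.0, 4.0, 0.43, 0.25, 0.87, 0.1],
    ]
)


def table2_dipoles() -> tuple[DipoleParameters, ...]:
    """Three dipoles at the published mm locations, in cm, in the 8.5 cm head.

    Only the locations are published for this scenario; orientations and
    strengths reuse the three-dipole benchmark values.
    """
    bench = table1_dipoles()
    locations_cm = np.array(
        [
            [0.911, 3.207, 3.854],
            [3.996, -5.443, 3.437],
            [-1.501, -2.978, 5.942],
        ]
    )
    return tuple(
        DipoleParameters(loc, d.orientation, d.strength)
        for loc, d in zip(locations_cm, bench)
    )


TABLE2_INITIAL_GUESS = np.array(
    [
        [0.0, 2.0, 3.0, 0.0, 0.0, 1.0, 0.2],
        [3.0, -4.0, 2.5, 0.0, 0.0, 1.0, 0.2],
        [-0.5, -2.0, 5.0, 0.0, 0.0, 1.0, 0.2],
    ]
)


@dataclass(frozen=True)
class FixtureSet:
    """A fully specified scenario: head, sources, electrodes, noise, seeds."""

    name: str
    head: HeadModel
    dipoles: tuple[DipoleParameters, ...]
    sensors: SensorArray
    n_samples: int
    noise: NoiseModel
    seed: int
    initial_guess: np.ndarray

    def simulate(self) -> EEGRecording:
        """Synthesize the recording; bit-identical for the embedded seed."""
        return simulate_recording(
            self.dipoles, self.sensors, self.head, self.n_samples, self.noise, self.seed
        )


def make_fixture(name: str, seed: int = 1) -> FixtureSet:
    """Build a named scenario.  The seed drives sensor placement (where the
    montage is random) and the simulation draws."""
    if name == "table1":
        head = HeadModel(radius_cm=10.0)
        sensors = sample_uniform_sensors(head, 36, seed=seed)
        return FixtureSet(
            name=name,
            head=head,
            dipoles=table1_dipoles(),
            sensors=sensors,
            n_samples=250,
            noise=NoiseModel(target_snr=20.0),
            seed=seed,
            initial_guess=TABLE1_INITIAL_GUESS.copy(),
        )
    if name == "table2":
        head = HeadModel(radius_cm=8.5)
        sensors = load_standard_montage("biosemi64", head)
        return FixtureSet(
            name=name,
            head=head,
            dipoles=table2_dipoles(),
            sensors=sensors,
            n_samples=250,
            noise=NoiseModel(target_snr=20.0),
            seed=seed,
            initial_guess=TABLE2_INITIAL_GUESS.copy(),
        )
    if name == "single-dipole-noiseless":
        head = HeadModel(radius_cm=10.0)
        sensors = sample_uniform_sensors(head, 24, seed=seed)
        dip = DipoleParameters((2.0, 1.0, 5.0), (0.36, 0.48, 0.80), 0.2)
        return FixtureSet(
            name=name,
            head=head,
            dipoles=(dip,),
            sensors=sensors,
            n_samples=10,
            noise=NoiseModel(sigma=0.0),
            seed=seed,
            initial_guess=np.array([[1.0, 0.0, 4.0, 0.0, 0.0, 1.0, 0.1]]),
        )
    raise KeyError(f"unknown fixture {name!r}; known: {FIXTURE_NAMES}")
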