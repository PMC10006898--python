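"""Forward EEG model: dipole-to-scalp gains, attenuation, noise.

A current dipole ``i`` with location ``l_i`` (inside the hemisphere), unit
orientation ``mu_i`` and magnitude ``s_i`` contributes, at electrode ``j``,

    f_ji = rho_ji * s_i * g_ji . mu_i,      g_ji = (w_j - l_i) / (4 pi zeta_ji d_ji^3)

an inverse-square (Biot-Savart-like) point-source field scaled by two
propagation factors: a per-path conductivity ``zeta_ji`` drawn uniformly at
random (the signal crosses soft tissue, bone and skin in unknown
proportions), and a received-signal-strength attenuation ``rho_ji`` that
decays linearly with distance from 1.0 (co-located) to 0.01 at the full head
diameter.  Contributions of multiple dipoles superpose; Gaussian white
measurement noise is added per sample.  Sources are fixed over the recording:
only the noise varies from sample to sample, so the propagation draws are
made once per (sensor, dipole) pair.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .head_geometry import HeadModel, SensorArray

__all__ = [
    "DipoleParameters",
    "NoiseModel",
    "SimulationTruth",
    "EEGRecording",
    "rss_coefficient",
    "sample_conductivity",
    "gain_matrix",
    "noiseless_mean",
    "simulate_recording",
    "snr_of",
]

_UNIT_TOL = 1e-9


@dataclass(frozen=True)
class DipoleParameters:
    """One dipole's 7-parameter state: location (cm), unit orientation, strength.

    The orientation must have unit norm (to 1e-9); magnitude is carried
    separately in ``strength`` so the pair (mu, s) has four parameters.
    Strength units are working units ("A.cm" in the tables); no dimensional
    conversion is attempted.
    """

    location: np.ndarray
    orientation: np.ndarray
    strength: float

    def __post_init__(self) -> None:
        loc = np.asarray(self.location, dtype=float).reshape(3)
        ori = np.asarray(self.orientation, dtype=float).reshape(3)
        if abs(np.linalg.norm(ori) - 1.0) > _UNIT_TOL:
            raise ValueError(
                f"orientation must be unit norm, got |mu| = {np.linalg.norm(ori)}"
            )
        if self.strength < 0:
            raise ValueError("strength must be nonnegative")
        object.__setattr__(self, "location", loc)
        object.__setattr__(self, "orientation", ori)
        object.__setattr__(self, "strength", float(self.strength))

    @classmethod
    def from_moment(cls, location, moment) -> "DipoleParameters":
        """Build from the 3-parameter moment vector ``s * mu``."""
        moment = np.asarray(moment, dtype=float).reshape(3)
        s = float(np.linalg.norm(moment))
        if s == 0:
            raise ValueError("zero moment has no orientation")
        return cls(location=location, orientation=moment / s, strength=s)

    def as_vector(self) -> np.ndarray:
        """Stack into ``(l_x, l_y, l_z, mu_x, mu_y, mu_z, s)``."""
        return np.concatenate([self.location, self.orientation, [self.strength]])

    def validate_inside(self, head: HeadModel) -> None:
        r = np.linalg.norm(self.location)
        if r >= head.radius_cm or self.location[2] < 0:
            raise ValueError(
                f"dipole at {self.location} is not strictly inside the hemisphere"
            )


@dataclass(frozen=True)
class NoiseModel:
    """Gaussian white sensor noise, specified by sigma (uV) or by target SNR.

    Exactly one of ``sigma`` and ``target_snr`` is given.  ``sigma = 0`` is
    the noiseless limit.  When ``target_snr`` is given, sigma is derived per
    scenario so that the noiseless signal power averaged over sensors divided
    by the noise power equals the target.
    """

    sigma: float | None = None
    target_snr: float | None = None

    def __post_init__(self) -> None:
        has_sigma = self.sigma is not None
        has_snr = self.target_snr is not None
        if has_sigma == has_snr:
            raise ValueError("specify exactly one of sigma and target_snr")
        if has_sigma and self.sigma < 0:
            raise ValueError("sigma must be nonnegative")
        if has_snr and not self.target_snr > 0:
            raise ValueError("target_snr must be positive")

    def resolve_sigma(self, noiseless: np.ndarray) -> float:
        """Noise standard deviation for a scenario with the given mean signal."""
        if self.sigma is not None:
            return float(self.sigma)
        mean_power = float(np.mean(np.square(noiseless)))
        if mean_power == 0:
            raise ValueError(
                "cannot derive sigma from target_snr for an all-zero signal"
            )
        return math.sqrt(mean_power / self.target_snr)


@dataclass(frozen=True)
class SimulationTruth:
    """Ground truth of a synthetic recording: sources and propagation draws."""

    dipoles: tuple[DipoleParameters, ...]
    conductivity: np.ndarray  # (m, n_dipoles) zeta draws
    attenuation: np.ndarray  # (m, n_dipoles) rho values at the true geometry
    noiseless: np.ndarray  # (m,) noiseless sensor means
    sigma: float


@dataclass(frozen=True)
class EEGRecording:
    """An m x N multichannel signal matrix (uV) with provenance."""

    signals: np.ndarray
    sensors: SensorArray
    head: HeadModel
    truth: SimulationTruth | None = None
    sample_rate: float | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        sig = np.atleast_2d(np.asarray(self.signals, dtype=float))
        if not np.all(np.isfinite(sig)):
            raise ValueError("signals must be finite")
        if sig.shape[0] != self.sensors.n_sensors:
            raise ValueError(
                f"signal rows ({sig.shape[0]}) != sensor count ({self.sensors.n_sensors})"
            )
        object.__setattr__(self, "signals", sig)

    @property
    def n_sensors(self) -> int:
        return self.signals.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signals.shape[1]


def rss_coefficient(d, head: HeadModel):
    """Distance-based received-signal-strength attenuation rho(d) = -alpha d + beta.

    The line is pinned at rho(0) = 1.0 (dipole directly under the sensor:
    nothing is lost) and rho(2r) = 0.01 (source and sensor a full head
    diameter apart: the reading is negligible).
    """
    d = np.asarray(d, dtype=float)
    if np.any((d < 0) | (d > head.diameter_cm)):
        raise ValueError(
            f"distance must lie in [0, {head.diameter_cm}] cm, got {d}"
        )
    out = head.beta - head.alpha * d
    return out if out.ndim else float(out)


def sample_conductivity(
    head: HeadModel, m: int, n_dipoles: int, seed: int | np.random.Generator
) -> np.ndarray:
    """Draw the (sensor, dipole) conductivity matrix, i.i.d. U(low, high).

    One draw per propagation path, held fixed for the whole recording.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return rng.uniform(head.conductivity_low, head.conductivity_high, size=(m, n_dipoles))


def gain_matrix(dipole_loc, sensors, conductivities) -> np.ndarray:
    """The m x 3 gain (lead-field) matrix of one dipole.

    Row j maps the dipole moment vector to the potential at sensor j:
    ``(w_j - l) / (4 pi zeta_j |w_j - l|^3)``.  ``conductivities`` is a
    scalar or an m-vector of per-path values.
    """
    w = sensors.positions if isinstance(sensors, SensorArray) else np.atleast_2d(sensors)
    l = np.asarray(dipole_loc, dtype=float).reshape(3)
    zeta = np.broadcast_to(np.asarray(conductivities, dtype=float), (w.shape[0],))
    u = w - l
    d = np.linalg.norm(u, axis=1)
    if np.any(d == 0):
        raise ZeroDivisionError("dipole coincides with a sensor (d = 0)")
    return u / (4 * np.pi * zeta * d**3)[:, None]


def noiseless_mean(
    dipoles, sensors: SensorArray, head: HeadModel, conductivity
) -> np.ndarray:
    """Noiseless sensor means: superposition of attenuated dipole fields.

    ``conductivity`` is a scalar (one value for every path) or an
    (m, n_dipoles) matrix of per-path draws.  The attenuation rho is always
    the deterministic linear law evaluated at the actual geometry.
    """
    w = sensors.positions
    m = w.shape[0]
    n = len(dipoles)
    zeta = np.asarray(conductivity, dtype=float)
    if zeta.ndim == 0:
        zeta = np.broadcast_to(zeta, (m, n))
    elif zeta.shape != (m, n):
        raise ValueError(f"conductivity must be scalar or ({m}, {n}), got {zeta.shape}")
    total = np.zeros(m)
    for i, dip in enumerate(dipoles):
        g = gain_matrix(dip.location, sensors, zeta[:, i])
        d = np.linalg.norm(w - dip.location, axis=1)
        rho = rss_coefficient(d, head)
        total += rho * dip.strength * (g @ dip.orientation)
    return total


def simulate_recording(
    dipoles,
    sensors: SensorArray,
    head: HeadModel,
    n_samples: int,
    noise: NoiseModel,
    seed: int,
) -> EEGRecording:
    """Synthesize an m x N recording from fixed dipoles plus per-sample noise.

    Conductivity draws are made once per (sensor, dipole) path; every sample
    column shares the same noiseless mean and receives an independent
    Gaussian noise draw.  Bit-identical for identical seeds.
    """
    if n_samples < 1:
        raise ValueError("need at least one sample")
    dipoles = tuple(dipoles)
    for dip in dipoles:
        dip.validate_inside(head)
    m = sensors.n_sensors
    rng = np.random.default_rng(seed)
    zeta = sample_conductivity(head, m, len(dipoles), rng)
    if dipoles:
        mean = noiseless_mean(dipoles, sensors, head, zeta)
        dists = np.stack(
            [np.linalg.norm(sensors.positions - d.location, axis=1) for d in dipoles],
            axis=1,
        )
        rho = rss_coefficient(dists, head)
    else:
        if noise.sigma is None:
            raise ValueError("an all-noise recording needs an explicit sigma")
        mean = np.zeros(m)
        rho = np.zeros((m, 0))
    sigma = noise.resolve_sigma(mean)
    signals = mean[:, None] + rng.normal(0.0, sigma, size=(m, n_samples)) if sigma > 0 \
        else np.tile(mean[:, None], (1, n_samples))
    truth = SimulationTruth(
        dipoles=dipoles,
        conductivity=zeta,
        attenuation=rho,
        noiseless=mean,
        sigma=sigma,
    )
    return EEGRecording(signals=signals, sensors=sensors, head=head, truth=truth, seed=seed)


def snr_of(recording: EEGRecording) -> float:
    """Realized signal-to-noise ratio: mean over sensors of signal/noise power.

    Requires provenance (the stored noiseless component).  Returns ``inf``
    for a noiseless recording.
    """
    if recording.truth is None:
        raise ValueError("SNR requires the recording's true noiseless component")
    mean = recording.truth.noiseless
    resid = recording.signals - mean[:, None]
    noise_power = np.mean(np.square(resid), axis=1)
    if np.all(noise_power == 0):
        return math.inf
    if np.any(noise_power == 0):  # degenerate mixed case
        return math.inf
    return float(np.mean(np.square(mean) / noise_power))
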