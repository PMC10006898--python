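"""Hemispherical head geometry: coordinate transforms and electrode placement.

The head is modelled as a half sphere of radius ``radius_cm`` sitting on the
plane ``z = 0``.  The Cartesian head frame is RAS-like: +x through the right
ear, +y through the nasion, +z up.  Dipoles live strictly inside the
hemisphere; electrodes sit on the scalp surface (``|w| = radius``).  All
lengths are centimetres unless a function says otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np

__all__ = [
    "HeadModel",
    "SensorArray",
    "spherical_to_cartesian",
    "cartesian_to_spherical",
    "sample_uniform_sensors",
    "load_standard_montage",
    "distance",
]


@dataclass(frozen=True)
class HeadModel:
    """Hemispherical head with random-conductivity and attenuation settings.

    Parameters
    ----------
    radius_cm
        Scalp radius in cm.  10 cm for the synthetic studies; 8.5 cm for the
        variant matched to the standard 64-channel montage head.
    conductivity_low, conductivity_high
        Bounds of the uniform distribution from which the per-path
        conductivity ``zeta`` is drawn (dimensionless working units).
    """

    radius_cm: float = 10.0
    conductivity_low: float = 0.1
    conductivity_high: float = 0.9

    def __post_init__(self) -> None:
        if not self.radius_cm > 0:
            raise ValueError(f"radius_cm must be positive, got {self.radius_cm}")
        if not (0 < self.conductivity_low <= self.conductivity_high):
            raise ValueError(
                "conductivity bounds must satisfy 0 < low <= high, got "
                f"({self.conductivity_low}, {self.conductivity_high})"
            )

    @property
    def diameter_cm(self) -> float:
        return 2.0 * self.radius_cm

    @property
    def beta(self) -> float:
        """Attenuation intercept: a co-located source/sensor pair loses nothing."""
        return 1.0

    @property
    def alpha(self) -> float:
        """Attenuation slope, fixed so the coefficient is 0.01 at the full diameter."""
        return 0.99 / self.diameter_cm

    @property
    def conductivity_mid(self) -> float:
        """Midpoint of the conductivity range (the expected-model value)."""
        return 0.5 * (self.conductivity_low + self.conductivity_high)


def spherical_to_cartesian(r, theta, phi) -> np.ndarray:
    """Map spherical coordinates to head-frame Cartesian coordinates.

    ``theta`` is the polar angle from +z in [0, pi/2] (the rim is included),
    ``phi`` the azimuth in [0, 2*pi).  Broadcasts; returns an array with
    trailing axis (x, y, z).
    """
    r = np.asarray(r, dtype=float)
    theta = np.asarray(theta, dtype=float)
    phi = np.asarray(phi, dtype=float)
    if np.any(r < 0):
        raise ValueError("radial distance must be nonnegative")
    if np.any((theta < 0) | (theta > np.pi / 2)):
        raise ValueError("polar angle must lie in [0, pi/2] for the hemisphere")
    if np.any((phi < 0) | (phi >= 2 * np.pi)):
        raise ValueError("azimuth must lie in [0, 2*pi)")
    st = np.sin(theta)
    return np.stack(
        (r * st * np.cos(phi), r * st * np.sin(phi), r * np.cos(theta)), axis=-1
    )


def cartesian_to_spherical(xyz) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Inverse of :func:`spherical_to_cartesian`; returns ``(r, theta, phi)``.

    Points must lie in the upper half space (``z >= 0``).  ``phi`` is wrapped
    to [0, 2*pi); at the pole it is 0 by convention.
    """
    xyz = np.asarray(xyz, dtype=float)
    x, y, z = xyz[..., 0], xyz[..., 1], xyz[..., 2]
    if np.any(z < 0):
        raise ValueError("point lies below the hemisphere base (z < 0)")
    r = np.sqrt(x * x + y * y + z * z)
    # atan2 form is well conditioned at the pole, unlike arccos(z/r)
    theta = np.arctan2(np.hypot(x, y), z)
    phi = np.mod(np.arctan2(y, x), 2 * np.pi)
    phi = np.where(phi >= 2 * np.pi, 0.0, phi)  # guard the wrap rounding to 2*pi
    phi = np.where((x == 0) & (y == 0), 0.0, phi)
    return r, theta, phi


@dataclass(frozen=True)
class SensorArray:
    """Ordered electrode positions on the scalp plus montage metadata."""

    positions: np.ndarray
    montage_name: str = "custom"
    labels: tuple[str, ...] | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        pos = np.atleast_2d(np.asarray(self.positions, dtype=float))
        if pos.ndim != 2 or pos.shape[1] != 3:
            raise ValueError(f"positions must be (m, 3), got {pos.shape}")
        if pos.shape[0] < 1:
            raise ValueError("at least one sensor is required")
        if len(np.unique(pos, axis=0)) != pos.shape[0]:
            raise ValueError("sensor positions must be distinct")
        object.__setattr__(self, "positions", pos)
        if self.labels is None:
            object.__setattr__(
                self, "labels", tuple(f"E{j + 1}" for j in range(pos.shape[0]))
            )
        elif len(self.labels) != pos.shape[0]:
            raise ValueError("number of labels must match number of sensors")
        else:
            object.__setattr__(self, "labels", tuple(self.labels))

    @property
    def n_sensors(self) -> int:
        return self.positions.shape[0]

    def validate_on_scalp(self, head: HeadModel, rtol: float = 1e-9) -> None:
        norms = np.linalg.norm(self.positions, axis=1)
        if not np.allclose(norms, head.radius_cm, rtol=rtol, atol=0):
            raise ValueError("sensor positions do not lie on the scalp sphere")


def sample_uniform_sensors(head: HeadModel, m: int, seed: int | np.random.Generator) -> SensorArray:
    """Draw ``m`` electrodes area-uniformly on the scalp hemisphere.

    Area-uniform means azimuth ~ U[0, 2*pi) and cos(theta) ~ U(0, 1], so the
    expected height of a sensor is radius/2.  Reproducible for a fixed seed.
    """
    if m < 1:
        raise ValueError(f"need at least one sensor, got m={m}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    # 1 - U[0,1) lies in (0,1]: the rim (cos(theta)=0) has probability zero
    # and the pole is attainable.
    cos_theta = 1.0 - rng.random(m)
    phi = rng.uniform(0.0, 2 * np.pi, m)
    xyz = spherical_to_cartesian(head.radius_cm, np.arccos(cos_theta), phi)
    return SensorArray(
        positions=xyz,
        montage_name="uniform-random",
        seed=int(seed) if not isinstance(seed, np.random.Generator) else None,
    )


def _read_position_file(path: Path) -> tuple[list[str], np.ndarray]:
    labels: list[str] = []
    rows: list[list[float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 4:
                raise ValueError(
                    f"{path}:{lineno}: expected 'label x y z', got {line!r}"
                )
            labels.append(parts[0])
            try:
                rows.append([float(v) for v in parts[1:]])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-numeric coordinate") from exc
    if not rows:
        raise ValueError(f"{path}: no sensor positions found")
    return labels, np.array(rows, dtype=float)


def load_standard_montage(name: str | Path, head: HeadModel) -> SensorArray:
    """Load a named montage or a position file, projected onto the scalp.

    ``"biosemi64"`` uses a bundled table of the standard BioSemi 64-electrode
    directions (10-20 family).  Any other value is treated as a path to a
    plain-text position file with one ``label x y z`` line per sensor (cm, or
    unit vectors — the norm is irrelevant since every position is rescaled
    radially onto the sphere of the given head radius).  Standard montages
    extend slightly below the equatorial plane of the hemisphere; those
    electrodes are kept as-is.
    """
    if isinstance(name, str) and name.lower() == "biosemi64":
        src = resources.files("dipolefit.data").joinpath("biosemi64.txt")
        with resources.as_file(src) as p:
            labels, dirs = _read_position_file(p)
        montage = "biosemi64"
    else:
        path = Path(name)
        if not path.exists():
            raise KeyError(
                f"unknown montage {name!r}: not a known label and no such file"
            )
        labels, dirs = _read_position_file(path)
        montage = str(path)
    norms = np.linalg.norm(dirs, axis=1)
    if np.any(norms == 0):
        raise ValueError("montage contains a zero position vector")
    positions = head.radius_cm * dirs / norms[:, None]
    return SensorArray(positions=positions, montage_name=montage, labels=tuple(labels))


def distance(a, b) -> np.ndarray:
    """Euclidean distance between points (broadcasting over leading axes)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    return np.linalg.norm(a - b, axis=-1)
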