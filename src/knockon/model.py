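"""Shared domain types for selectivity-filter permeation analysis.

The data model mirrors how single-channel permeation runs are analysed in
practice: a :class:`Replica` holds one voltage-clamped trajectory as a set of
per-particle axial traces plus per-subunit backbone dihedral series; region and
site boundaries are per-frame z-planes derived from landmark atom groups, so
that slow drift of the filter does not bias region assignment.

Axial coordinates are in nm, frame spacing in ns, voltages in mV and dihedral
angles in degrees wrapped to (-180, 180].
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Dict, List, Optional, Sequence

import numpy as np

__all__ = [
    "Species",
    "Direction",
    "ParticleTrace",
    "Replica",
    "RegionBoundaries",
    "SiteBoundaries",
    "PermeationEvent",
    "ConductanceEstimate",
    "KnockonError",
    "ConfigurationError",
    "FormatError",
    "GeometryError",
    "DomainError",
]


class KnockonError(Exception):
    """Base class for all package errors."""


class ConfigurationError(KnockonError):
    """A run configuration references something that does not exist."""


class FormatError(KnockonError):
    """An input file violates the native tabular dialect."""


class GeometryError(KnockonError):
    """Boundary planes are inconsistent (e.g. lower above upper)."""


class DomainError(KnockonError, ValueError):
    """A numeric argument is outside its physical domain."""


class Species(str, Enum):
    """Particle species. ``LANDMARK`` marks boundary-defining atoms."""

    K = "K"
    NA = "NA"
    WATER = "WATER"
    LANDMARK = "LANDMARK"

    @classmethod
    def coerce(cls, value) -> "Species":
        if isinstance(value, cls):
            return value
        return cls(str(value).upper())


#: single-letter occupancy alphabet used in configuration strings
SPECIES_LETTER = {Species.K: "K", Species.NA: "N", Species.WATER: "W"}


class Direction(str, Enum):
    OUTWARD = "OUTWARD"
    INWARD = "INWARD"


@dataclass
class ParticleTrace:
    """Axial time series of one particle.

    Parameters
    ----------
    particle_id : str
        Opaque identifier, unique within a replica.
    species : Species
        One of K, NA, WATER or LANDMARK.
    z : ndarray, shape (T,)
        Axial coordinate in nm; NaN allowed where ``present`` is False.
    present : ndarray of bool, shape (T,)
        Whether the particle is resolved in each frame.
    xy : ndarray, shape (T, 2), optional
        In-plane coordinates, used only for radial gating of site occupancy.
    """

    particle_id: str
    species: Species
    z: np.ndarray
    present: Optional[np.ndarray] = None
    xy: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.species = Species.coerce(self.species)
        self.z = np.asarray(self.z, dtype=float)
        if self.present is None:
            self.present = np.isfinite(self.z)
        self.present = np.asarray(self.present, dtype=bool)
        if self.present.shape != self.z.shape:
            raise FormatError(
                f"trace {self.particle_id}: present/z length mismatch"
            )
        if not np.all(np.isfinite(self.z[self.present])):
            raise FormatError(
                f"trace {self.particle_id}: non-finite z in a present frame"
            )
        if self.xy is not None:
            self.xy = np.asarray(self.xy, dtype=float)
            if self.xy.shape != (self.z.size, 2):
                raise FormatError(
                    f"trace {self.particle_id}: xy must have shape (T, 2)"
                )

    @property
    def n_frames(self) -> int:
        return int(self.z.size)


@dataclass
class Replica:
    """One voltage-clamped trajectory.

    ``dihedrals`` holds the four per-subunit carbonyl N-CA-C-O dihedral
    series (degrees, wrapped to (-180, 180]); ``landmarks`` maps a group
    name to the stacked z-series (n_members, T) of its member atoms.
    """

    traces: List[ParticleTrace]
    dt: float  # ns between frames
    voltage: float  # mV, signed
    box_z: np.ndarray  # nm, per frame
    landmarks: Dict[str, np.ndarray] = field(default_factory=dict)
    dihedrals: Optional[np.ndarray] = None  # (4, T) degrees

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise DomainError("dt must be positive")
        lengths = {t.n_frames for t in self.traces}
        if len(lengths) > 1:
            raise FormatError(f"traces disagree on frame count: {sorted(lengths)}")
        if lengths:
            T = lengths.pop()
        elif np.ndim(self.box_z) > 0:
            T = int(np.asarray(self.box_z).size)
        elif self.landmarks:
            T = int(np.atleast_2d(next(iter(self.landmarks.values()))).shape[-1])
        else:
            T = 0
        self.box_z = np.broadcast_to(
            np.asarray(self.box_z, dtype=float), (T,)
        ).copy() if np.ndim(self.box_z) == 0 else np.asarray(self.box_z, dtype=float)
        if self.box_z.shape != (T,):
            raise FormatError("box_z length must equal the frame count")
        for name, series in self.landmarks.items():
            arr = np.asarray(series, dtype=float)
            if arr.ndim == 1:
                arr = arr[None, :]
            if arr.shape[1] != T:
                raise FormatError(f"landmark group {name!r} has wrong length")
            self.landmarks[name] = arr
        if self.dihedrals is not None:
            self.dihedrals = np.asarray(self.dihedrals, dtype=float)
            if self.dihedrals.shape != (4, T):
                raise FormatError("dihedrals must have shape (4, T)")

    @property
    def n_frames(self) -> int:
        return int(self.box_z.size)

    @property
    def duration_us(self) -> float:
        """Sampled duration in microseconds, ``(T - 1) * dt``."""
        return max(self.n_frames - 1, 0) * self.dt * 1e-3

    def trace(self, particle_id: str) -> ParticleTrace:
        for t in self.traces:
            if t.particle_id == particle_id:
                return t
        raise KeyError(particle_id)

    def species_traces(self, species: Species) -> List[ParticleTrace]:
        species = Species.coerce(species)
        return [t for t in self.traces if t.species == species]


@dataclass
class RegionBoundaries:
    """Per-frame planes splitting the box into the four permeation regions.

    Region 1 is below the filter entrance (``z_lower``), region 2 the lower
    half of the filter, region 3 the upper half (``z_mid`` splits them) and
    region 4 everything above ``z_upper``.
    """

    z_lower: np.ndarray
    z_mid: np.ndarray
    z_upper: np.ndarray

    def __post_init__(self) -> None:
        self.z_lower = np.atleast_1d(np.asarray(self.z_lower, dtype=float))
        self.z_mid = np.atleast_1d(np.asarray(self.z_mid, dtype=float))
        self.z_upper = np.atleast_1d(np.asarray(self.z_upper, dtype=float))
        if not (self.z_lower.shape == self.z_mid.shape == self.z_upper.shape):
            raise FormatError("boundary series must share one length")
        bad = ~((self.z_lower < self.z_mid) & (self.z_mid < self.z_upper))
        if np.any(bad):
            raise GeometryError(
                f"z_lower < z_mid < z_upper violated in {int(bad.sum())} frame(s)"
            )

    @classmethod
    def static(cls, z_lower: float, z_upper: float, n_frames: int) -> "RegionBoundaries":
        lo = np.full(n_frames, float(z_lower))
        hi = np.full(n_frames, float(z_upper))
        return cls(lo, 0.5 * (lo + hi), hi)

    @property
    def n_frames(self) -> int:
        return int(self.z_lower.size)


@dataclass
class SiteBoundaries:
    """Ordered planes delimiting the axial ion binding sites.

    ``planes`` has shape (n_sites + 1, T) with strictly increasing values in
    every frame; ``site_names`` orders sites by ascending z (cavity site
    first, S0 last). ``radial_cutoff`` is the maximum distance from the pore
    axis for a particle to count as a site occupant; it is only enforced for
    traces that carry xy coordinates.
    """

    planes: np.ndarray
    site_names: Sequence[str] = ("Scav", "S4", "S3", "S2", "S1", "S0")
    radial_cutoff: float = 0.35

    def __post_init__(self) -> None:
        self.planes = np.asarray(self.planes, dtype=float)
        if self.planes.ndim == 1:
            self.planes = self.planes[:, None]
        if self.planes.shape[0] != len(self.site_names) + 1:
            raise FormatError("need len(site_names) + 1 plane series")
        if np.any(np.diff(self.planes, axis=0) <= 0):
            raise GeometryError("site planes must be strictly increasing")

    @classmethod
    def uniform(
        cls,
        boundaries: RegionBoundaries,
        cavity_width: float = 0.3,
        s0_width: float = 0.3,
        radial_cutoff: float = 0.35,
    ) -> "SiteBoundaries":
        """Split [z_lower, z_upper] into four equal sites S4..S1, with a
        cavity site below and S0 above."""
        lo, hi = boundaries.z_lower, boundaries.z_upper
        w = (hi - lo) / 4.0
        planes = np.stack(
            [lo - cavity_width, lo, lo + w, lo + 2 * w, lo + 3 * w, hi, hi + s0_width]
        )
        return cls(planes, radial_cutoff=radial_cutoff)

    @classmethod
    def from_oxygen_layers(
        cls,
        layer_z: Dict[str, np.ndarray],
        cavity_width: float = 0.3,
        s0_width: float = 0.3,
        radial_cutoff: float = 0.35,
    ) -> "SiteBoundaries":
        """Build planes from coordinating-oxygen layer mean z-series.

        ``layer_z`` maps the five oxygen layers (S4 floor hydroxyls up to the
        top carbonyl layer) to per-frame mean z.  Each binding site spans the
        gap between two adjacent layers, so the inter-site planes are the
        layer means themselves, with cavity/S0 margins added outside.
        """
        layers = [np.atleast_1d(np.asarray(v, float)) for v in layer_z.values()]
        if len(layers) != 5:
            raise ConfigurationError("expected five oxygen layers (S4 floor .. S1 top)")
        stack = np.stack(layers)
        order = np.argsort(stack[:, 0])
        stack = stack[order]
        lo, hi = stack[0], stack[-1]
        planes = np.concatenate(
            [(lo - cavity_width)[None], stack, (hi + s0_width)[None]]
        )
        return cls(planes, radial_cutoff=radial_cutoff)

    @property
    def n_sites(self) -> int:
        return len(self.site_names)

    @property
    def n_frames(self) -> int:
        return int(self.planes.shape[1])

    def site_index(self, name: str) -> int:
        return list(self.site_names).index(name)

    def centers(self) -> np.ndarray:
        """Per-site interval midpoints, shape (n_sites, T)."""
        return 0.5 * (self.planes[:-1] + self.planes[1:])


@dataclass(frozen=True)
class PermeationEvent:
    """A completed sequential traversal of the four axial regions."""

    particle_id: str
    species: Species
    direction: Direction
    completion_frame: int

    def time_ns(self, dt: float) -> float:
        return self.completion_frame * dt


@dataclass
class ConductanceEstimate:
    """Replica-averaged conductance with a Student-t 95% CI.

    ``pooled`` is total net events over total time (the paper's headline
    form); ``ci95_halfwidth`` is NaN when fewer than two replicas exist.
    """

    per_replica: np.ndarray  # pS
    mean: float
    ci95_halfwidth: float
    n_replicas: int
    pooled: Optional[float] = None

    @property
    def ci_defined(self) -> bool:
        return self.n_replicas >= 2 and np.isfinite(self.ci95_halfwidth)
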