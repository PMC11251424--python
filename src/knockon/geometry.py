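"""Region-boundary construction and the applied-field formula."""

from __future__ import annotations

from typing import Optional

import numpy as np

from .model import (
    ConfigurationError,
    DomainError,
    GeometryError,
    RegionBoundaries,
    Replica,
)

__all__ = ["compute_region_boundaries", "electric_field"]


def compute_region_boundaries(
    replica: Replica,
    lower_group: str = "sf_lower",
    upper_group: str = "sf_upper",
) -> RegionBoundaries:
    """Place the filter entrance/exit planes from landmark atom groups.

    The entrance plane is the per-frame mean z of ``lower_group`` (by default
    the oxygens that floor the lowest binding site), the exit plane the mean z
    of ``upper_group`` (top carbonyl layer); the midpoint plane is their
    arithmetic mean.

    Raises
    ------
    ConfigurationError
        If a named landmark group is absent from the replica.
    GeometryError
        If the entrance lies at or above the exit in any frame.
    """
    for name in (lower_group, upper_group):
        if name not in replica.landmarks:
            raise ConfigurationError(
                f"landmark group {name!r} not found; available: "
                f"{sorted(replica.landmarks)}"
            )
    z_lower = replica.landmarks[lower_group].mean(axis=0)
    z_upper = replica.landmarks[upper_group].mean(axis=0)
    if np.any(z_lower >= z_upper):
        raise GeometryError("lower boundary group lies above the upper group")
    return RegionBoundaries(z_lower, 0.5 * (z_lower + z_upper), z_upper)


def electric_field(voltage: float, box_z: float) -> float:
    """Uniform applied field E = dV / d_z.

    Parameters
    ----------
    voltage : float
        Transmembrane voltage in volts (signed).
    box_z : float
        Full axial box length in nm; the whole box enters because the applied
        potential drops across the entire periodic cell.

    Returns
    -------
    float
        Field in V/nm.
    """
    if box_z <= 0:
        raise DomainError(f"box_z must be positive, got {box_z}")
    return voltage / box_z
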