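"""Adapter from standard MD trajectory formats to the native data model.

Thin layer over MDAnalysis: a topology (PDB/GRO) plus a coordinate series
(XTC/TRR/DCD, or a multi-model PDB) is mapped to a :class:`knockon.Replica`
via atom selections.  Selections use the MDAnalysis selection language, e.g.
``{"K": "name K", "WATER": "name OW", "sf_lower": "name OG1 and resid 75"}``.

Coordinates are converted from Angstrom to nm.  Dihedral series can be
computed from four-atom selections per subunit.
"""

from __future__ import annotations

from typing import Dict, Optional, Sequence

import numpy as np

from .model import ConfigurationError, ParticleTrace, Replica, Species
from .io import unwrap_z

__all__ = ["load_md_replica"]

A_TO_NM = 0.1


def load_md_replica(
    topology,
    trajectory=None,
    species_selections: Optional[Dict[str, str]] = None,
    landmark_selections: Optional[Dict[str, str]] = None,
    dihedral_selections: Optional[Sequence[str]] = None,
    dt_ns: Optional[float] = None,
    voltage_mv: float = 0.0,
    unwrap: bool = True,
) -> Replica:
    """Read an MD trajectory into the native data model.

    Parameters
    ----------
    topology, trajectory
        Paths understood by ``MDAnalysis.Universe``.
    species_selections : dict
        Species name ("K", "NA", "WATER") to selection string.
    landmark_selections : dict
        Landmark group name to selection string; groups must be non-empty.
    dihedral_selections : sequence of 4 selection strings, optional
        Each must select exactly 4 atoms (N, CA, C, O) of one subunit.
    dt_ns : float, optional
        Frame spacing override; defaults to the trajectory's own dt (ps).
    """
    import MDAnalysis as mda
    from MDAnalysis.lib.distances import calc_dihedrals

    if hasattr(topology, "trajectory"):  # an existing Universe
        u = topology
    elif trajectory is not None:
        u = mda.Universe(topology, trajectory)
    else:
        u = mda.Universe(topology)
    T = len(u.trajectory)

    species_selections = species_selections or {}
    landmark_selections = landmark_selections or {}
    groups = {}
    for sp, sel in species_selections.items():
        groups[("species", sp)] = u.select_atoms(sel)
    for name, sel in landmark_selections.items():
        ag = u.select_atoms(sel)
        if len(ag) == 0:
            raise ConfigurationError(f"landmark selection {name!r} matched no atoms")
        groups[("landmark", name)] = ag
    dih_groups = []
    for sel in dihedral_selections or []:
        ag = u.select_atoms(sel)
        if len(ag) != 4:
            raise ConfigurationError(
                f"dihedral selection {sel!r} must match exactly 4 atoms"
            )
        dih_groups.append(ag)

    z = {key: np.empty((len(ag), T)) for key, ag in groups.items()}
    box_z = np.empty(T)
    dihedrals = np.empty((len(dih_groups), T)) if dih_groups else None
    for j, ts in enumerate(u.trajectory):
        box_z[j] = ts.dimensions[2] * A_TO_NM if ts.dimensions is not None else np.inf
        for key, ag in groups.items():
            z[key][:, j] = ag.positions[:, 2] * A_TO_NM
        for g, ag in enumerate(dih_groups):
            p = ag.positions
            ang = calc_dihedrals(
                p[0][None], p[1][None], p[2][None], p[3][None], box=ts.dimensions
            )
            dihedrals[g, j] = np.degrees(ang[0])

    if not np.all(np.isfinite(box_z)):
        box_z = np.full(T, np.inf)

    traces = []
    present = np.ones(T, dtype=bool)
    for (kind, name), ag in groups.items():
        sp = Species.coerce(name) if kind == "species" else Species.LANDMARK
        for i, atom in enumerate(ag):
            zz = z[(kind, name)][i]
            if unwrap and np.all(np.isfinite(box_z)):
                zz = unwrap_z(zz, present, box_z)
            traces.append(ParticleTrace(f"{name}:{atom.index}", sp, zz, present.copy()))

    landmarks = {}
    for (kind, name), ag in groups.items():
        if kind == "landmark":
            landmarks[name] = np.stack(
                [t.z for t in traces if t.particle_id.startswith(f"{name}:")]
            )

    if dt_ns is None:
        dt_ps = getattr(u.trajectory, "dt", None)
        dt_ns = dt_ps / 1000.0 if dt_ps else 1.0
    if dihedrals is not None and dihedrals.shape[0] != 4:
        raise ConfigurationError("expected four dihedral selections (one per subunit)")

    return Replica(
        traces=traces,
        dt=dt_ns,
        voltage=voltage_mv,
        box_z=box_z if np.all(np.isfinite(box_z)) else np.full(T, 1e9),
        landmarks=landmarks,
        dihedrals=dihedrals,
    )
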