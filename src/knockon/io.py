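"""Native tabular trajectory dialect (read/write) and z-unwrapping.

A replica directory holds three files:

``trajectory.tsv``
    UTF-8, tab-separated, header row; one row per (frame, particle) with
    columns ``frame, particle, species, z`` and optional ``x, y``.  Frames a
    particle is absent from simply have no row.
``dihedrals.tsv``
    Optional; columns ``frame, subunit, angle_deg`` for subunits 0..3.
``meta.json``
    ``dt_ns``, ``voltage_mv``, ``box_z`` (scalar or per-frame list),
    ``n_frames`` and ``landmarks`` mapping group names to particle ids.

Floats are written with 17 significant digits so a write/load round trip
reproduces every series bit-identically.  On load, z-coordinates are
unwrapped so that no particle moves more than half the box between
consecutive present frames — a periodic-image wrap must never register as a
teleport across the filter.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd

from .model import (
    ConfigurationError,
    FormatError,
    ParticleTrace,
    Replica,
    Species,
)

__all__ = ["write_replica", "load_replica", "unwrap_z"]

TRAJ_FILE = "trajectory.tsv"
DIH_FILE = "dihedrals.tsv"
META_FILE = "meta.json"
FLOAT_FMT = "%.17g"


def unwrap_z(z: np.ndarray, present: np.ndarray, box_z: np.ndarray) -> np.ndarray:
    """Remove periodic-image jumps from one axial series (in place safe copy)."""
    z = z.copy()
    idx = np.flatnonzero(present)
    if idx.size < 2:
        return z
    zi = z[idx]
    box = box_z[idx[1:]]
    d = np.diff(zi)
    shift = -box * np.round(d / box)
    z[idx[1:]] += np.cumsum(shift)
    return z


def write_replica(replica: Replica, path) -> Path:
    """Write a replica directory in the native dialect."""
    outdir = Path(path)
    outdir.mkdir(parents=True, exist_ok=True)

    frames_col = []
    pid_col = []
    sp_col = []
    z_col = []
    has_xy = any(t.xy is not None for t in replica.traces)
    x_col, y_col = [], []
    for tr in replica.traces:
        f = np.flatnonzero(tr.present)
        frames_col.append(f)
        pid_col.extend([tr.particle_id] * f.size)
        sp_col.extend([tr.species.value] * f.size)
        z_col.append(tr.z[f])
        if has_xy:
            if tr.xy is None:
                x_col.append(np.full(f.size, np.nan))
                y_col.append(np.full(f.size, np.nan))
            else:
                x_col.append(tr.xy[f, 0])
                y_col.append(tr.xy[f, 1])
    data = {
        "frame": np.concatenate(frames_col) if frames_col else np.array([], int),
        "particle": pid_col,
        "species": sp_col,
        "z": np.concatenate(z_col) if z_col else np.array([]),
    }
    if has_xy:
        data["x"] = np.concatenate(x_col)
        data["y"] = np.concatenate(y_col)
    pd.DataFrame(data).to_csv(
        outdir / TRAJ_FILE, sep="\t", index=False, float_format=FLOAT_FMT
    )

    if replica.dihedrals is not None:
        T = replica.n_frames
        df = pd.DataFrame(
            {
                "frame": np.repeat(np.arange(T), 4),
                "subunit": np.tile(np.arange(4), T),
                "angle_deg": replica.dihedrals.T.reshape(-1),
            }
        )
        df.to_csv(outdir / DIH_FILE, sep="\t", index=False, float_format=FLOAT_FMT)

    landmark_members: Dict[str, list] = {}
    member_of: Dict[str, str] = {}
    lm_traces = {t.particle_id: t for t in replica.traces if t.species == Species.LANDMARK}
    for name, series in replica.landmarks.items():
        members = []
        for row in series:
            for pid, tr in lm_traces.items():
                if pid in member_of:
                    continue
                if np.array_equal(tr.z, row):
                    members.append(pid)
                    member_of[pid] = name
                    break
        landmark_members[name] = members
    box = replica.box_z
    box_out = float(box[0]) if np.all(box == box[0]) else [float(b) for b in box]
    meta = {
        "dt_ns": replica.dt,
        "voltage_mv": replica.voltage,
        "box_z": box_out,
        "n_frames": replica.n_frames,
        "landmarks": landmark_members,
    }
    (outdir / META_FILE).write_text(json.dumps(meta, indent=2, sort_keys=True))
    return outdir


def load_replica(
    path,
    landmarks: Optional[Dict[str, Sequence[str]]] = None,
    unwrap: bool = True,
) -> Replica:
    """Load a replica directory written in the native dialect.

    Parameters
    ----------
    path : str or Path
        Replica directory.
    landmarks : dict, optional
        Override the landmark definition from ``meta.json``: group name to
        list of particle ids.  A referenced particle that is missing from the
        trajectory is a configuration error.
    unwrap : bool
        Unwrap z-coordinates across periodic images (default True).
    """
    indir = Path(path)
    meta_path = indir / META_FILE
    if not meta_path.exists():
        raise FormatError(f"missing {META_FILE} in {indir}")
    meta = json.loads(meta_path.read_text())
    T = int(meta["n_frames"])
    box = np.asarray(meta["box_z"], dtype=float)
    box_z = np.full(T, float(box)) if box.ndim == 0 else box
    if box_z.size != T:
        raise FormatError("box_z list length disagrees with n_frames")

    df = pd.read_csv(indir / TRAJ_FILE, sep="\t", float_precision="round_trip")
    required = {"frame", "particle", "species", "z"}
    if not required.issubset(df.columns):
        raise FormatError(f"trajectory table needs columns {sorted(required)}")
    if df["frame"].size and (df["frame"].min() < 0 or df["frame"].max() >= T):
        raise FormatError("frame index outside [0, n_frames)")
    has_xy = {"x", "y"}.issubset(df.columns)

    traces = []
    for pid, grp in df.groupby("particle", sort=True):
        sp = set(grp["species"])
        if len(sp) > 1:
            raise FormatError(f"particle {pid} has inconsistent species {sp}")
        f = grp["frame"].to_numpy()
        if np.unique(f).size != f.size:
            raise FormatError(f"duplicate frame rows for particle {pid}")
        z = np.full(T, np.nan)
        z[f] = grp["z"].to_numpy()
        present = np.zeros(T, dtype=bool)
        present[f] = True
        xy = None
        if has_xy:
            xv = grp["x"].to_numpy()
            if np.any(np.isfinite(xv)):
                xy = np.full((T, 2), np.nan)
                xy[f, 0] = xv
                xy[f, 1] = grp["y"].to_numpy()
        if unwrap:
            z = unwrap_z(z, present, box_z)
        traces.append(ParticleTrace(str(pid), Species.coerce(sp.pop()), z, present, xy))

    dih = None
    dih_path = indir / DIH_FILE
    if dih_path.exists():
        dd = pd.read_csv(dih_path, sep="\t", float_precision="round_trip")
        dih = np.full((4, T), np.nan)
        dih[dd["subunit"].to_numpy(), dd["frame"].to_numpy()] = dd[
            "angle_deg"
        ].to_numpy()

    groups = landmarks if landmarks is not None else meta.get("landmarks", {})
    by_id = {t.particle_id: t for t in traces}
    lm: Dict[str, np.ndarray] = {}
    for name, members in groups.items():
        series = []
        for pid in members:
            if pid not in by_id:
                raise ConfigurationError(
                    f"landmark group {name!r} references missing particle {pid!r}"
                )
            series.append(by_id[pid].z)
        if not series:
            raise ConfigurationError(f"landmark group {name!r} is empty")
        lm[name] = np.stack(series)

    return Replica(
        traces=traces,
        dt=float(meta["dt_ns"]),
        voltage=float(meta["voltage_mv"]),
        box_z=box_z,
        landmarks=lm,
        dihedrals=dih,
    )
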