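"""Per-frame site occupancy, configuration strings and mechanism signatures.

Each binding site (Scav, S4..S1, S0, ascending z) is an axial interval; the
occupant of a site is the particle whose z lies in the interval (and within
the radial cutoff of the pore axis, when in-plane coordinates are available).
Ions win ties over water, and among equals the particle nearest the site
center wins, with particle id as a stable final tie-break.

Configuration strings read S1 -> S4 (extracellular to intracellular) over the
alphabet {K, N, W, 0}: "KWKW" is the canonical water-interleaved (soft
knock-on) arrangement, "KKKK" the fully ion-loaded direct knock-on one.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .model import (
    RegionBoundaries,
    Replica,
    SiteBoundaries,
    Species,
    SPECIES_LETTER,
)

__all__ = [
    "OccupancyTable",
    "assign_sites",
    "DensityProfile",
    "density_profile",
    "TransitionRecord",
    "classify_transitions",
    "configuration_census",
    "waters_between_ions",
]

logger = logging.getLogger(__name__)

SF_SITES = ("S1", "S2", "S3", "S4")
_PRIORITY = {Species.K: 0, Species.NA: 0, Species.WATER: 1}  # ions beat water


@dataclass
class OccupancyTable:
    """Occupancy labels and occupant ids per frame and site.

    ``labels`` has shape (T, n_sites) over {K, N, W, 0}; ``occupants`` the
    matching particle ids (None when empty).  Sites are ordered ascending in
    z, matching ``site_names``.
    """

    site_names: Tuple[str, ...]
    labels: np.ndarray
    occupants: np.ndarray

    @property
    def n_frames(self) -> int:
        return int(self.labels.shape[0])

    def site_column(self, name: str) -> int:
        return self.site_names.index(name)

    def config_strings(self, sites: Sequence[str] = SF_SITES) -> np.ndarray:
        """Per-frame configuration strings in S1..S4 order."""
        cols = [self.site_column(s) for s in sites]
        sub = self.labels[:, cols]
        return np.array(["".join(row) for row in sub])


def assign_sites(
    replica: Replica,
    sites: SiteBoundaries,
    pore_axis: Tuple[float, float] = (0.0, 0.0),
) -> OccupancyTable:
    """Classify the occupant of every binding site in every frame."""
    T = replica.n_frames
    S = sites.n_sites
    planes = np.broadcast_to(sites.planes, (S + 1, T))
    centers = sites.centers()

    rows: List[np.ndarray] = []
    for ti, trace in enumerate(replica.traces):
        if trace.species not in _PRIORITY:
            continue
        z = trace.z
        idx = np.zeros(T, dtype=np.int64)
        for p in planes:
            idx += (z >= p)
        ok = trace.present & (idx >= 1) & (idx <= S)
        if trace.xy is not None:
            r = np.hypot(trace.xy[:, 0] - pore_axis[0], trace.xy[:, 1] - pore_axis[1])
            ok &= r <= sites.radial_cutoff
        frames = np.flatnonzero(ok)
        if frames.size == 0:
            continue
        site = idx[frames] - 1
        dist = np.abs(z[frames] - centers[site, frames])
        prio = np.full(frames.size, _PRIORITY[trace.species])
        rows.append(
            np.rec.fromarrays(
                [frames, site, prio, dist, np.full(frames.size, ti)],
                names="frame,site,prio,dist,trace",
            )
        )

    labels = np.full((T, S), "0", dtype="<U1")
    occupants = np.full((T, S), None, dtype=object)
    if rows:
        cand = np.concatenate([np.asarray(r) for r in rows])
        # stable resolution: ion > water, then nearest to center, then id order
        order = np.lexsort(
            (cand["trace"], cand["dist"], cand["prio"], cand["site"], cand["frame"])
        )
        cand = cand[order]
        key = cand["frame"] * S + cand["site"]
        first = np.concatenate([[True], key[1:] != key[:-1]])
        # two ions contending for one filter site is worth flagging; crowded
        # bulk-side sites (Scav/S0 overlap the reservoirs) are expected
        sf_idx = {list(sites.site_names).index(s) for s in ("S1", "S2", "S3", "S4")
                  if s in sites.site_names}
        ion_clash = (~first) & (cand["prio"] == 0) & np.isin(cand["site"], list(sf_idx))
        if np.any(ion_clash):
            logger.warning(
                "%d filter site-frames held two ions; nearest-to-center kept",
                int(ion_clash.sum()),
            )
        win = cand[first]
        for f, s, ti in zip(win["frame"], win["site"], win["trace"]):
            tr = replica.traces[ti]
            labels[f, s] = SPECIES_LETTER[tr.species]
            occupants[f, s] = tr.particle_id
    return OccupancyTable(tuple(sites.site_names), labels, occupants)


@dataclass
class DensityProfile:
    """Axial probability density of each species in filter-aligned coordinates.

    Bin centers are z minus the per-frame filter entrance plane; the density
    integrates to the mean per-frame particle count inside the histogram
    window (so the K+ profile of a doubly occupied filter integrates to 2).
    """

    bin_edges: np.ndarray
    densities: Dict[str, np.ndarray]

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


def density_profile(
    replicas: Replica | Sequence[Replica],
    boundaries: RegionBoundaries | Sequence[RegionBoundaries],
    n_bins: int = 24,
    species: Sequence[Species] = (Species.K, Species.NA, Species.WATER),
    margin: float = 0.0,
) -> DensityProfile:
    """Histogram filter-aligned axial positions, pooled over replicas.

    Pooling is frame-weighted (unweighted by replica length).  ``margin``
    extends the window below the entrance and above the exit plane.
    """
    if n_bins < 4:
        raise ValueError("need at least 4 bins")
    if isinstance(replicas, Replica):
        replicas = [replicas]
        boundaries = [boundaries]  # type: ignore[list-item]
    spans = [float(np.mean(b.z_upper - b.z_lower)) for b in boundaries]
    span = float(np.mean(spans))
    edges = np.linspace(-margin, span + margin, n_bins + 1)
    width = edges[1] - edges[0]
    wanted = [Species.coerce(s) for s in species]
    counts = {SPECIES_LETTER[s]: np.zeros(n_bins) for s in wanted}
    total_frames = 0
    for rep, b in zip(replicas, boundaries):
        total_frames += rep.n_frames
        for trace in rep.traces:
            if trace.species not in wanted:
                continue
            zz = (trace.z - b.z_lower)[trace.present]
            h, _ = np.histogram(zz, bins=edges)
            counts[SPECIES_LETTER[trace.species]] += h
    if total_frames == 0:
        return DensityProfile(edges, {k: v for k, v in counts.items()})
    dens = {k: v / (total_frames * width) for k, v in counts.items()}
    return DensityProfile(edges, dens)


@dataclass(frozen=True)
class TransitionRecord:
    """One change of filter-site occupant identities between two frames."""

    frame_before: int
    frame_after: int
    config_before: str
    config_after: str
    jump_type: str  # STEPWISE | DIRECT_JUMP | OTHER


def classify_transitions(occ: OccupancyTable) -> List[TransitionRecord]:
    """Classify every frame pair where a filter-site occupant changes.

    STEPWISE: every particle present in both frames moved at most one site.
    DIRECT_JUMP: an ion moved two or more sites in one frame interval (the
    jump-type seen when an ion hops S3 -> S1 without a resolvable
    intermediate).  OTHER: anything else (e.g. only water making long moves,
    or a complete exchange of occupants).
    """
    sf_cols = [occ.site_column(s) for s in SF_SITES if s in occ.site_names]
    configs = occ.config_strings([s for s in SF_SITES if s in occ.site_names])
    records: List[TransitionRecord] = []
    prev_map: Optional[Dict[str, int]] = None
    prev_frame = 0
    ion_letters = {"K", "N"}
    for t in range(occ.n_frames):
        cur_map = {
            occ.occupants[t, s]: s
            for s in range(len(occ.site_names))
            if occ.occupants[t, s] is not None
        }
        if prev_map is not None:
            changed = any(
                occ.occupants[t, c] != occ.occupants[prev_frame, c] for c in sf_cols
            )
            if changed:
                shared = set(cur_map) & set(prev_map)
                moves = {p: cur_map[p] - prev_map[p] for p in shared}
                species_of = {}
                for p in shared:
                    s = cur_map[p]
                    species_of[p] = occ.labels[t, s]
                ion_jump = any(
                    abs(d) >= 2 and species_of[p] in ion_letters
                    for p, d in moves.items()
                )
                if ion_jump:
                    kind = "DIRECT_JUMP"
                elif shared and all(abs(d) <= 1 for d in moves.values()):
                    kind = "STEPWISE"
                else:
                    kind = "OTHER"
                records.append(
                    TransitionRecord(
                        prev_frame, t, str(configs[prev_frame]), str(configs[t]), kind
                    )
                )
        prev_map, prev_frame = cur_map, t
    return records


def configuration_census(occ: OccupancyTable) -> Dict[str, float]:
    """Fraction of frames per S1..S4 configuration string (sums to 1)."""
    configs = occ.config_strings()
    if configs.size == 0:
        return {}
    uniq, counts = np.unique(configs, return_counts=True)
    total = counts.sum()
    order = np.argsort(-counts, kind="stable")
    return {str(uniq[i]): counts[i] / total for i in order}


def waters_between_ions(occ: OccupancyTable) -> np.ndarray:
    """Number of water molecules between consecutive ions inside S1..S4.

    For every frame with at least two ions in the filter, returns the count
    of 'W' labels strictly between each adjacent ion pair (vacancies do not
    contribute).  Restricted to the four canonical sites.
    """
    cols = [occ.site_column(s) for s in SF_SITES]
    sub = occ.labels[:, cols]
    gaps: List[int] = []
    for row in sub:
        ion_pos = [i for i, c in enumerate(row) if c in ("K", "N")]
        for a, b in zip(ion_pos[:-1], ion_pos[1:]):
            gaps.append(int(np.sum(row[a + 1 : b] == "W")))
    return np.asarray(gaps, dtype=int)
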