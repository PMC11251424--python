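"""Four-region assignment and the sequential permeation-event counter.

The box is split into four axial regions: below the filter (1), lower filter
half (2), upper filter half (3) and above the filter (4).  An outward
permeation event is a completed sequential traversal 1 -> 2 -> 3 -> 4; inward
events are the mirror image.  Particles that start inside the filter are not
counted unless they first leave to a terminal region and then traverse fully —
this matches net-flux bookkeeping, where only complete crossings carry charge.

The counter is a per-particle checkpoint automaton.  A particle arms for
outward counting whenever it visits region 1 (and for inward at region 4);
while armed, the checkpoint pointer advances on visits to 2 then 3 in order,
and the passage completes on the next arrival in region 4.  Any visit to a
terminal region re-arms the automaton in that region's direction, so a
passage broken by touching either end of the box never completes; this makes
the counter exactly antisymmetric under time reversal.  Fast recrossings
between saved frames are invisible at coarse frame strides; this is a
property of the estimator, not corrected here.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence

import numpy as np

from .model import (
    Direction,
    ParticleTrace,
    PermeationEvent,
    RegionBoundaries,
    Replica,
    Species,
)

__all__ = [
    "assign_regions",
    "count_events",
    "EventLedger",
    "count_replica_events",
    "net_outward",
    "water_copermeation",
    "CopermeationSummary",
]

ANALYTE_SPECIES = (Species.K, Species.NA, Species.WATER)


def assign_regions(trace: ParticleTrace, boundaries: RegionBoundaries) -> np.ndarray:
    """Per-frame region codes {1,2,3,4}; 0 where the particle is absent.

    Intervals are half-open with the lower bound inclusive: a particle exactly
    on ``z_mid`` is in region 3, exactly on ``z_upper`` in region 4.
    """
    if trace.n_frames != boundaries.n_frames:
        raise ValueError("trace and boundaries must share the frame count")
    z = trace.z
    codes = np.ones(z.size, dtype=np.int8)
    codes += (z >= boundaries.z_lower).astype(np.int8)
    codes += (z >= boundaries.z_mid).astype(np.int8)
    codes += (z >= boundaries.z_upper).astype(np.int8)
    codes[~trace.present] = 0
    return codes


def count_events(
    regions: np.ndarray,
    species: Species = Species.K,
    particle_id: str = "",
) -> List[PermeationEvent]:
    """Run the checkpoint automaton over one particle's region series.

    Absent frames (code 0) are skipped.  Events are attributed to the frame of
    the terminal-region arrival that completes the sequence.
    """
    species = Species.coerce(species)
    regions = np.asarray(regions)
    present = np.flatnonzero(regions > 0)
    events: List[PermeationEvent] = []
    armed = 0  # 0 unarmed, +1 outward (origin 1), -1 inward (origin 4)
    prog = 0  # checkpoints passed since arming (0, 1 or 2)
    # run-compress: automaton state changes only when the region changes
    codes = regions[present]
    if codes.size:
        change = np.empty(codes.size, dtype=bool)
        change[0] = True
        change[1:] = codes[1:] != codes[:-1]
        frames = present[change]
        codes = codes[change]
    else:
        frames = present
    for t, r in zip(frames, codes):
        if r == 1:
            if armed == -1 and prog == 2:
                events.append(
                    PermeationEvent(particle_id, species, Direction.INWARD, int(t))
                )
            armed, prog = 1, 0
        elif r == 4:
            if armed == 1 and prog == 2:
                events.append(
                    PermeationEvent(particle_id, species, Direction.OUTWARD, int(t))
                )
            armed, prog = -1, 0
        elif r == 2:
            if armed == 1 and prog == 0:
                prog = 1
            elif armed == -1 and prog == 1:
                prog = 2
        elif r == 3:
            if armed == -1 and prog == 0:
                prog = 1
            elif armed == 1 and prog == 1:
                prog = 2
    return events


@dataclass
class EventLedger:
    """All permeation events of a replica plus per-species tallies."""

    events: List[PermeationEvent] = field(default_factory=list)

    def _count(self, direction: Direction) -> Dict[str, int]:
        out: Dict[str, int] = defaultdict(int)
        for ev in self.events:
            if ev.direction == direction:
                out[ev.species.value] += 1
        return dict(out)

    @property
    def n_outward(self) -> Dict[str, int]:
        return self._count(Direction.OUTWARD)

    @property
    def n_inward(self) -> Dict[str, int]:
        return self._count(Direction.INWARD)

    def net_outward(self, species: Species) -> int:
        s = Species.coerce(species).value
        return self.n_outward.get(s, 0) - self.n_inward.get(s, 0)

    @property
    def net_outward_by_species(self) -> Dict[str, int]:
        keys = set(self.n_outward) | set(self.n_inward)
        return {k: self.n_outward.get(k, 0) - self.n_inward.get(k, 0) for k in keys}

    def extend(self, events: Iterable[PermeationEvent]) -> None:
        self.events.extend(events)
        self.events.sort(key=lambda e: (e.completion_frame, e.particle_id))


def count_replica_events(
    replica: Replica,
    boundaries: RegionBoundaries,
    species: Sequence[Species] = ANALYTE_SPECIES,
) -> EventLedger:
    """Assign regions and count events for every analyte trace of a replica."""
    wanted = {Species.coerce(s) for s in species}
    ledger = EventLedger()
    for trace in replica.traces:
        if trace.species not in wanted:
            continue
        codes = assign_regions(trace, boundaries)
        ledger.extend(count_events(codes, trace.species, trace.particle_id))
    ledger.events.sort(key=lambda e: (e.completion_frame, e.particle_id))
    return ledger


def net_outward(ledger: EventLedger) -> Dict[str, int]:
    """Net outward event count per species (outward minus inward)."""
    return ledger.net_outward_by_species


@dataclass
class CopermeationSummary:
    """Water-to-ion net event ratio; ``ratio`` is None when no net ion flux."""

    net_water: int
    net_ion: int
    ratio: Optional[float]
    net_by_species: Dict[str, int]


def water_copermeation(ledger: EventLedger) -> CopermeationSummary:
    """Ratio of net water to net ion (K+ and Na+) permeation events.

    A ratio of 0 is the direct knock-on signature (water-free permeation);
    1 is one water co-transported per ion, as in soft knock-on.
    """
    nets = ledger.net_outward_by_species
    net_water = nets.get(Species.WATER.value, 0)
    net_ion = nets.get(Species.K.value, 0) + nets.get(Species.NA.value, 0)
    ratio = net_water / net_ion if net_ion != 0 else None
    return CopermeationSummary(net_water, net_ion, ratio, nets)
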