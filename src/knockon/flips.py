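"""Carbonyl-flip detection, flip-event segmentation and water->flip causality.

A subunit's carbonyl is "flipped" when its backbone N-CA-C-O dihedral falls
in the closed window [-130, -50] degrees (angles on the (-180, 180] branch).
Flip events are maximal runs of consecutive flipped frames; the causality
analysis asks whether water already occupied the central filter sites (S2/S3)
in the frames immediately preceding flip onset, and whether water-preceded
flips last longer.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional

import numpy as np

from .occupancy import OccupancyTable

__all__ = [
    "FLIP_WINDOW",
    "classify_flip",
    "FlipCensus",
    "simultaneous_flip_census",
    "FlipEvent",
    "segment_flip_events",
    "CausalitySummary",
    "water_flip_causality",
]

#: closed dihedral window defining the flipped state, degrees
FLIP_WINDOW = (-130.0, -50.0)


def classify_flip(angle) -> np.ndarray | bool:
    """True where the dihedral lies inside the flipped-state window.

    Accepts scalars or arrays; the window is closed at both ends (a
    measure-zero convention fixed for determinism).
    """
    a = np.asarray(angle, dtype=float)
    out = (a >= FLIP_WINDOW[0]) & (a <= FLIP_WINDOW[1])
    return bool(out) if np.isscalar(angle) else out


@dataclass
class FlipCensus:
    """Distribution of the number of simultaneously flipped subunits."""

    fractions: np.ndarray  # index N = 0..4
    fraction_any: float  # N >= 1

    def as_dict(self) -> Dict[str, float]:
        d = {str(n): float(f) for n, f in enumerate(self.fractions)}
        d["at_least_one"] = float(self.fraction_any)
        return d


def simultaneous_flip_census(flips: np.ndarray) -> FlipCensus:
    """Histogram the per-frame count of flipped subunits, normalized."""
    flips = np.asarray(flips, dtype=bool)
    n_sub, T = flips.shape
    counts = flips.sum(axis=0)
    hist = np.bincount(counts, minlength=n_sub + 1).astype(float)
    hist /= max(T, 1)
    return FlipCensus(hist, float(hist[1:].sum()))


@dataclass
class FlipEvent:
    """One maximal run of flipped frames on a single subunit."""

    subunit: int
    onset_frame: int
    offset_frame: int  # inclusive
    duration_ns: float
    edge_start: bool = False  # run begins at the first frame of the series
    edge_end: bool = False  # run ends at the last frame
    water_in_s23_at_onset: Optional[bool] = None

    @property
    def edge_truncated(self) -> bool:
        return self.edge_start or self.edge_end

    @property
    def n_frames(self) -> int:
        return self.offset_frame - self.onset_frame + 1


def segment_flip_events(
    flips: np.ndarray, dt: float, min_duration: int = 1
) -> List[FlipEvent]:
    """Maximal flipped runs per subunit, discarding runs shorter than
    ``min_duration`` frames; runs touching the series edges are flagged."""
    if min_duration < 1:
        raise ValueError("min_duration must be >= 1")
    flips = np.asarray(flips, dtype=bool)
    events: List[FlipEvent] = []
    T = flips.shape[1]
    for s in range(flips.shape[0]):
        x = flips[s].astype(np.int8)
        d = np.diff(np.concatenate([[0], x, [0]]))
        onsets = np.flatnonzero(d == 1)
        offsets = np.flatnonzero(d == -1) - 1
        for a, b in zip(onsets, offsets):
            if b - a + 1 < min_duration:
                continue
            events.append(
                FlipEvent(
                    subunit=s,
                    onset_frame=int(a),
                    offset_frame=int(b),
                    duration_ns=(b - a + 1) * dt,
                    edge_start=a == 0,
                    edge_end=b == T - 1,
                )
            )
    events.sort(key=lambda e: (e.onset_frame, e.subunit))
    return events


@dataclass
class CausalitySummary:
    """Water->flip causality tally.

    Events whose onset window precedes frame 0 are excluded from the
    fraction but counted in ``n_excluded``; edge-truncated events keep their
    tag but are excluded from the duration statistics.
    """

    fraction_water_first: Optional[float]
    n_water_first: int
    n_no_water: int
    n_excluded: int
    median_duration_water_first_ns: Optional[float]
    median_duration_no_water_ns: Optional[float]
    durations_water_first_ns: List[float] = field(default_factory=list)
    durations_no_water_ns: List[float] = field(default_factory=list)


def water_flip_causality(
    events: List[FlipEvent],
    occ: OccupancyTable,
    lookback: int = 1,
) -> CausalitySummary:
    """Tag each flip event by whether water was already in S2/S3 before onset.

    An event is "water-first" iff S2 or S3 holds a water in any of the
    ``lookback`` frames immediately before its onset.  Events starting at
    frame 0 have no lookback window and are excluded from the fraction.
    """
    if lookback < 1:
        raise ValueError("lookback must be >= 1")
    cols = [occ.site_column("S2"), occ.site_column("S3")]
    water_s23 = (occ.labels[:, cols] == "W").any(axis=1)
    n_first = n_dry = n_excl = 0
    dur_first: List[float] = []
    dur_dry: List[float] = []
    for ev in events:
        if ev.onset_frame == 0:
            ev.water_in_s23_at_onset = None
            n_excl += 1
            continue
        lo = max(ev.onset_frame - lookback, 0)
        tag = bool(water_s23[lo : ev.onset_frame].any())
        ev.water_in_s23_at_onset = tag
        if tag:
            n_first += 1
            if not ev.edge_truncated:
                dur_first.append(ev.duration_ns)
        else:
            n_dry += 1
            if not ev.edge_truncated:
                dur_dry.append(ev.duration_ns)
    n_tagged = n_first + n_dry
    return CausalitySummary(
        fraction_water_first=n_first / n_tagged if n_tagged else None,
        n_water_first=n_first,
        n_no_water=n_dry,
        n_excluded=n_excl,
        median_duration_water_first_ns=float(np.median(dur_first)) if dur_first else None,
        median_duration_no_water_ns=float(np.median(dur_dry)) if dur_dry else None,
        durations_water_first_ns=dur_first,
        durations_no_water_ns=dur_dry,
    )
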