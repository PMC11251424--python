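"""Kinetic Monte Carlo generator of single-file filter trajectories.

The filter is modelled as a four-site single-file column between an
intracellular cavity reservoir and the extracellular bulk.  The column
advances by concerted shifts sampled with the Gillespie algorithm: a shift
inserts a particle at one end, moves every occupant one site and expels the
occupant at the other end.  Two mechanism regimes are provided:

* ``DIRECT`` — the column holds only ions; water never enters the filter.
  One forward shift permeates one ion (direct knock-on).
* ``SOFT`` — the column alternates ion/water.  A forward knock-on cycle is a
  pair of half-shifts (ion in / ion out, then water in / water out) with a
  short-lived intermediate in between; each completed cycle co-permeates
  exactly one ion and one water.  Cycles are atomic: a cycle that would
  complete after the trajectory end is discarded, so the ground-truth
  water:ion ratio of counted events is exactly one.

Sampled occupants are mapped to z = site center + truncated Gaussian jitter
(so re-assignment of sites from coordinates is exact by construction); bulk
particles perform reflected random walks in slabs below and above the filter.
Dihedral series are generated by a two-state per-subunit Markov model whose
flip-on hazard can be gated on water occupying S2/S3 (``water_triggered``),
left free (``spontaneous``) or disabled.

All randomness derives from one root seed through named child streams, so a
given seed reproduces the trajectory bit for bit.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np

from .model import (
    Direction,
    ParticleTrace,
    RegionBoundaries,
    Replica,
    SiteBoundaries,
    Species,
)

__all__ = [
    "FlipModel",
    "MechanismSpec",
    "GroundTruthEvent",
    "GroundTruth",
    "SyntheticTrajectory",
    "simulate",
    "emit",
]

# --- fixed synthetic geometry (nm) -----------------------------------------
Z_LOWER = 4.0  # filter entrance plane
Z_UPPER = 5.2  # filter exit plane
N_SITES = 4
SITE_W = (Z_UPPER - Z_LOWER) / N_SITES
BOX_Z = 10.0
BELOW_SLAB = (2.6, 3.9)  # cavity-side bulk, strictly inside region 1
ABOVE_SLAB = (5.3, 6.6)  # extracellular bulk, strictly inside region 4
JITTER_SD = 0.05
JITTER_MAX = SITE_W / 2 - 0.03  # keep occupants strictly inside their site
BULK_STEP_SD = 0.04

SITE_CENTERS = Z_LOWER + SITE_W * (np.arange(N_SITES) + 0.5)  # S4..S1 ascending


@dataclass
class FlipModel:
    """Two-state flip kinetics; probabilities are per-frame hazards."""

    kind: str = "none"  # none | water_triggered | spontaneous
    p_on: float = 0.0
    p_off: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("none", "water_triggered", "spontaneous"):
            raise ValueError(f"unknown flip model {self.kind!r}")
        for p in (self.p_on, self.p_off):
            if not 0.0 <= p <= 1.0:
                raise ValueError("flip probabilities must lie in [0, 1]")


@dataclass
class MechanismSpec:
    """Mechanism regime and kinetic parameters of the generator.

    ``hop_rate`` is the forward column-advance initiation rate in events/us
    (one permeating ion per event in DIRECT mode; one ion plus one water per
    knock-on cycle in SOFT mode). ``voltage_bias`` is the forward:backward
    rate asymmetry imposed by the applied field.  Na+ entries are thinned by
    ``na_rate_scale`` relative to K+, which is enough to exercise the
    selectivity estimators without claiming energetic realism.
    """

    mode: str = "DIRECT"
    hop_rate: float = 49.4  # events/us, the wild-type-like rate at +300 mV
    voltage_bias: float = 50.0
    species_mix: Dict[str, float] = field(default_factory=lambda: {"K": 1.0})
    na_rate_scale: float = 0.02
    flip_model: FlipModel = field(default_factory=FlipModel)

    def __post_init__(self) -> None:
        self.mode = self.mode.upper()
        if self.mode not in ("DIRECT", "SOFT"):
            raise ValueError("mode must be DIRECT or SOFT")
        if self.hop_rate < 0 or self.voltage_bias <= 0:
            raise ValueError("rates must be nonnegative, bias positive")
        total = sum(self.species_mix.values())
        if total <= 0 or any(v < 0 for v in self.species_mix.values()):
            raise ValueError("species_mix must be nonnegative with positive sum")
        self.species_mix = {k.upper(): v / total for k, v in self.species_mix.items()}
        if isinstance(self.flip_model, dict):
            self.flip_model = FlipModel(**self.flip_model)

    @property
    def water_coupled(self) -> bool:
        """Forced True in SOFT mode, False in DIRECT."""
        return self.mode == "SOFT"

    def _ion_accept(self) -> float:
        """Mean acceptance probability of an ion entry under Na+ thinning."""
        return sum(
            frac * (self.na_rate_scale if sp == "NA" else 1.0)
            for sp, frac in self.species_mix.items()
        )

    def expected_net_outward(self, duration_us: float) -> Dict[str, float]:
        """Expected net outward crossings (all traversals, boundary-free)."""
        k_f = self.hop_rate * self._ion_accept()
        net = (1.0 - 1.0 / self.voltage_bias) * k_f * duration_us
        out = {
            sp: net
            * frac
            * (self.na_rate_scale if sp == "NA" else 1.0)
            / self._ion_accept()
            for sp, frac in self.species_mix.items()
        }
        out["WATER"] = net if self.water_coupled else 0.0
        return out

    def expected_counted_net_outward(self, duration_us: float) -> Dict[str, float]:
        """Expected net events seen by the permeation counter.

        The counter never counts the particles that start inside the filter
        (4 ions in DIRECT, 2 ions + 2 waters in SOFT), so their eventual
        exits are subtracted from the raw crossing expectation.  Exact
        renewal bookkeeping, not a fitted correction.
        """
        raw = self.expected_net_outward(duration_us)
        init_sp = self._initial_ion_species()
        out = dict(raw)
        if self.mode == "DIRECT":
            out[init_sp] = max(0.0, out.get(init_sp, 0.0) - N_SITES)
        else:
            out[init_sp] = max(0.0, out.get(init_sp, 0.0) - 2)
            out["WATER"] = max(0.0, out["WATER"] - 2)
        return out

    def _initial_ion_species(self) -> str:
        return max(self.species_mix, key=lambda k: (self.species_mix[k], k))


@dataclass(frozen=True)
class GroundTruthEvent:
    particle_id: str
    species: str
    direction: str
    time_ns: float


@dataclass
class GroundTruth:
    """Generator-side record of what actually permeated and flipped."""

    events: List[GroundTruthEvent]
    n_outward: Dict[str, int]
    n_inward: Dict[str, int]
    expected_net_outward: Dict[str, float]
    expected_counted_net_outward: Dict[str, float]
    flip_events: List[Tuple[int, int, int]]  # (subunit, onset, offset)

    @property
    def net_outward(self) -> Dict[str, int]:
        keys = set(self.n_outward) | set(self.n_inward)
        return {k: self.n_outward.get(k, 0) - self.n_inward.get(k, 0) for k in keys}

    @property
    def water_ion_ratio(self) -> Optional[float]:
        nets = self.net_outward
        ion = nets.get("K", 0) + nets.get("NA", 0)
        if ion == 0:
            return None
        return nets.get("WATER", 0) / ion


@dataclass
class SyntheticTrajectory:
    replica: Replica
    ground_truth: GroundTruth
    spec: MechanismSpec
    region_boundaries: RegionBoundaries
    site_boundaries: SiteBoundaries
    seed: int
    duration_us: float
    dt_ns: float


class _Particle:
    __slots__ = ("pid", "species", "spawn_ns", "segments", "entered_from")

    def __init__(self, pid: str, species: Species, spawn_ns: float, loc) -> None:
        self.pid = pid
        self.species = species
        self.spawn_ns = spawn_ns
        self.segments: List[Tuple[float, object]] = [(spawn_ns, loc)]
        self.entered_from: Optional[str] = None

    def move(self, t: float, loc) -> None:
        self.segments.append((t, loc))


def _fold(x: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Fold a free walk into [lo, hi] (pathwise reflected walk)."""
    width = hi - lo
    y = np.mod(x - lo, 2 * width)
    y = np.where(y > width, 2 * width - y, y)
    return lo + y


def simulate(
    spec: MechanismSpec,
    duration_us: float = 10.0,
    dt_ns: float = 1.0,
    seed: int = 0,
    voltage_mv: float = 300.0,
) -> SyntheticTrajectory:
    """Generate one synthetic replica with ground truth.

    The trajectory spans ``T = round(duration/dt) + 1`` frames at spacing
    ``dt_ns`` so the sampled duration is exactly the requested one.
    """
    if duration_us <= 0 or dt_ns <= 0:
        raise ValueError("duration and dt must be positive")
    T = int(round(duration_us * 1000.0 / dt_ns)) + 1
    duration_ns = (T - 1) * dt_ns

    k_f = spec.hop_rate / 1000.0  # per ns
    k_r = k_f / spec.voltage_bias
    # SOFT intermediate (WKWK) decay: a couple of times the cycle rate, so the
    # intermediate is visibly populated yet the resting configuration dominates
    k_fast = 2.0 * max(k_f + k_r, 1e-12)
    if k_f > 0 and dt_ns > 1.0 / (k_f + k_r):
        warnings.warn(
            "frame spacing exceeds the mean event waiting time; "
            "sampled trajectories will alias the jump chain",
            stacklevel=2,
        )

    root = np.random.SeedSequence(seed)
    rng_chain, rng_bulk, rng_jit, rng_flip = [
        np.random.default_rng(s) for s in root.spawn(4)
    ]

    soft = spec.mode == "SOFT"
    init_ion = Species(spec._initial_ion_species())

    particles: List[_Particle] = []
    counter = {"K": 0, "NA": 0, "WATER": 0}

    def new_particle(species: Species, t: float, loc) -> _Particle:
        counter[species.value] += 1
        pid = f"{species.value}{counter[species.value]:04d}"
        p = _Particle(pid, species, t, loc)
        particles.append(p)
        return p

    # initial column, bottom (S4) to top (S1)
    if soft:
        col_species = [Species.WATER, init_ion, Species.WATER, init_ion]
    else:
        col_species = [init_ion] * N_SITES
    column = [new_particle(sp, 0.0, ("site", i)) for i, sp in enumerate(col_species)]

    pools: Dict[Tuple[str, str], List[_Particle]] = {}
    pool_species = set(spec.species_mix) | ({"WATER"} if soft else set())

    def pool(side: str, sp: Species) -> List[_Particle]:
        return pools.setdefault((side, sp.value), [])

    def spawn_bulk(side: str, sp: Species, t: float) -> None:
        pool(side, sp).append(new_particle(sp, t, (side,)))

    for sp_name in sorted(pool_species):
        for _ in range(4):
            spawn_bulk("below", Species(sp_name), 0.0)
            spawn_bulk("above", Species(sp_name), 0.0)

    def take(side: str, sp: Species, t: float) -> _Particle:
        q = pool(side, sp)
        if not q:
            spawn_bulk(side, sp, t)  # emergency spawn; used immediately
        p = q.pop(0)
        if len(q) < 2:
            spawn_bulk(side, sp, t)
        return p

    gt_events: List[GroundTruthEvent] = []
    n_out = {"K": 0, "NA": 0, "WATER": 0}
    n_in = {"K": 0, "NA": 0, "WATER": 0}
    config_changes: List[Tuple[float, Tuple[str, ...]]] = [
        (0.0, tuple(p.species.value for p in column))
    ]

    def record_config(t: float) -> None:
        config_changes.append((t, tuple(p.species.value for p in column)))

    def shift(direction: str, entering: _Particle, t: float) -> None:
        """Concerted single-file shift; updates itineraries and ground truth."""
        nonlocal column
        if direction == "fwd":
            leaving = column[-1]
            column = [entering] + column[:-1]
            entering.move(t, ("site", 0))
            entering.entered_from = "below"
            for i in range(1, N_SITES):
                column[i].move(t, ("site", i))
            leaving.move(t, ("above",))
            pool("above", leaving.species).append(leaving)
            if leaving.entered_from == "below":
                n_out[leaving.species.value] += 1
                gt_events.append(
                    GroundTruthEvent(
                        leaving.pid, leaving.species.value, Direction.OUTWARD.value, t
                    )
                )
            leaving.entered_from = None
        else:
            leaving = column[0]
            column = column[1:] + [entering]
            entering.move(t, ("site", N_SITES - 1))
            entering.entered_from = "above"
            for i in range(N_SITES - 1):
                column[i].move(t, ("site", i))
            leaving.move(t, ("below",))
            pool("below", leaving.species).append(leaving)
            if leaving.entered_from == "above":
                n_in[leaving.species.value] += 1
                gt_events.append(
                    GroundTruthEvent(
                        leaving.pid, leaving.species.value, Direction.INWARD.value, t
                    )
                )
            leaving.entered_from = None
        record_config(t)

    def pick_ion() -> Species:
        names = sorted(spec.species_mix)
        probs = np.array([spec.species_mix[n] for n in names])
        return Species(str(rng_chain.choice(names, p=probs)))

    t = 0.0
    rate_total = k_f + k_r
    while rate_total > 0:
        t += rng_chain.exponential(1.0 / rate_total)
        if t >= duration_ns:
            break
        fwd = rng_chain.random() < k_f / rate_total
        direction = "fwd" if fwd else "rev"
        # which end of the column the new particle alternates against
        edge = column[0] if fwd else column[-1]
        if soft:
            t2 = t + rng_chain.exponential(1.0 / k_fast)
            # species of the two half-shifts, preserving alternation
            first_is_ion = edge.species == Species.WATER
            ion_sp = pick_ion()
            if ion_sp == Species.NA and rng_chain.random() >= spec.na_rate_scale:
                continue  # thinned Na+ entry: null event
            if t2 >= duration_ns:
                break  # atomic cycle would not complete; discard it
            side = "below" if fwd else "above"
            sp1 = ion_sp if first_is_ion else Species.WATER
            sp2 = Species.WATER if first_is_ion else ion_sp
            shift(direction, take(side, sp1, t), t)
            shift(direction, take(side, sp2, t2), t2)
            t = t2
        else:
            ion_sp = pick_ion()
            if ion_sp == Species.NA and rng_chain.random() >= spec.na_rate_scale:
                continue
            side = "below" if fwd else "above"
            shift(direction, take(side, ion_sp, t), t)

    # ---------------- frame sampling ----------------------------------------
    frame_times = np.arange(T) * dt_ns

    def first_frame(time_ns: float) -> int:
        return int(math.ceil(time_ns / dt_ns - 1e-9))

    traces: List[ParticleTrace] = []
    for p in particles:
        z = np.full(T, np.nan)
        present = np.zeros(T, dtype=bool)
        segs = p.segments
        for k, (t0, loc) in enumerate(segs):
            j0 = first_frame(t0)
            j1 = first_frame(segs[k + 1][0]) if k + 1 < len(segs) else T
            j1 = min(j1, T)
            if j0 >= j1:
                continue
            n = j1 - j0
            if loc[0] == "site":
                c = SITE_CENTERS[loc[1]]
                jit = np.clip(
                    rng_jit.normal(0.0, JITTER_SD, n), -JITTER_MAX, JITTER_MAX
                )
                z[j0:j1] = c + jit
            else:
                lo, hi = BELOW_SLAB if loc[0] == "below" else ABOVE_SLAB
                if k == 0:
                    start = rng_bulk.uniform(lo, hi)
                else:
                    # just expelled from the filter: appears near its mouth
                    start = hi - 0.1 if loc[0] == "below" else lo + 0.1
                steps = rng_bulk.normal(0.0, BULK_STEP_SD, n)
                steps[0] = 0.0
                z[j0:j1] = _fold(start + np.cumsum(steps), lo, hi)
            present[j0:j1] = True
        traces.append(ParticleTrace(p.pid, p.species, z, present))

    # landmark traces pin the analysis boundaries to the true geometry
    landmarks: Dict[str, np.ndarray] = {}
    for name, zval, tag in (
        ("sf_lower", Z_LOWER, "LML"),
        ("sf_upper", Z_UPPER, "LMU"),
    ):
        members = []
        for i in range(2):
            arr = np.full(T, zval)
            traces.append(
                ParticleTrace(f"{tag}{i}", Species.LANDMARK, arr, np.ones(T, bool))
            )
            members.append(arr)
        landmarks[name] = np.stack(members)

    # ---------------- occupancy-at-frames and dihedrals ---------------------
    cfg = np.empty((T, N_SITES), dtype="<U5")
    times = np.array([c[0] for c in config_changes])
    idx = np.searchsorted(times, frame_times + 1e-9, side="right") - 1
    cfg_list = [c[1] for c in config_changes]
    for j in range(T):
        cfg[j] = cfg_list[idx[j]]
    # column order is S4..S1 ascending; S3 = col 1, S2 = col 2
    water_s23 = (cfg[:, 1] == "WATER") | (cfg[:, 2] == "WATER")

    flipped = np.zeros((4, T), dtype=bool)
    fm = spec.flip_model
    if fm.kind != "none" and T > 1:
        gate = (
            water_s23 if fm.kind == "water_triggered" else np.ones(T, dtype=bool)
        )
        u_on = rng_flip.random((4, T))
        u_off = rng_flip.random((4, T))
        for s in range(4):
            state = False
            for j in range(1, T):
                if state:
                    if u_off[s, j] < fm.p_off:
                        state = False
                else:
                    if gate[j - 1] and u_on[s, j] < fm.p_on:
                        state = True
                flipped[s, j] = state

    dihedrals = np.empty((4, T))
    n_flip = int(flipped.sum())
    flip_angles = np.clip(rng_flip.normal(-90.0, 12.0, n_flip), -128.0, -52.0)
    rest_angles = np.clip(rng_flip.normal(115.0, 12.0, dihedrals.size - n_flip), 62.0, 168.0)
    dihedrals[flipped] = flip_angles
    dihedrals[~flipped] = rest_angles

    flip_events: List[Tuple[int, int, int]] = []
    for s in range(4):
        x = flipped[s].astype(np.int8)
        d = np.diff(np.concatenate([[0], x, [0]]))
        for a, b in zip(np.flatnonzero(d == 1), np.flatnonzero(d == -1) - 1):
            flip_events.append((s, int(a), int(b)))

    replica = Replica(
        traces=traces,
        dt=dt_ns,
        voltage=voltage_mv,
        box_z=np.full(T, BOX_Z),
        landmarks=landmarks,
        dihedrals=dihedrals,
    )
    region_b = RegionBoundaries.static(Z_LOWER, Z_UPPER, T)
    site_b = SiteBoundaries.uniform(region_b)
    gt = GroundTruth(
        events=gt_events,
        n_outward=dict(n_out),
        n_inward=dict(n_in),
        expected_net_outward=spec.expected_net_outward(duration_ns / 1000.0),
        expected_counted_net_outward=spec.expected_counted_net_outward(
            duration_ns / 1000.0
        ),
        flip_events=flip_events,
    )
    return SyntheticTrajectory(
        replica, gt, spec, region_b, site_b, seed, duration_ns / 1000.0, dt_ns
    )


def emit(traj: SyntheticTrajectory, path) -> Path:
    """Write the trajectory in the native tabular dialect plus a ground-truth
    sidecar JSON; the directory is loadable by :func:`knockon.io.load_replica`."""
    from .io import write_replica

    outdir = Path(path)
    write_replica(traj.replica, outdir)
    gt = traj.ground_truth
    sidecar = {
        "seed": traj.seed,
        "duration_us": traj.duration_us,
        "dt_ns": traj.dt_ns,
        "mechanism": asdict(traj.spec),
        "n_outward": gt.n_outward,
        "n_inward": gt.n_inward,
        "net_outward": gt.net_outward,
        "water_ion_ratio": gt.water_ion_ratio,
        "expected_net_outward": gt.expected_net_outward,
        "expected_counted_net_outward": gt.expected_counted_net_outward,
        "events": [asdict(e) for e in gt.events],
        "flip_events": gt.flip_events,
        "geometry": {"z_lower": Z_LOWER, "z_upper": Z_UPPER, "box_z": BOX_Z},
    }
    (outdir / "ground_truth.json").write_text(
        json.dumps(sidecar, indent=2, sort_keys=True)
    )
    return outdir
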