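"""End-to-end analysis pipeline: load -> regions -> events -> conductance ->
occupancy -> transitions -> flips -> causality, with validated configuration
and machine-readable outputs."""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd
import yaml

from . import electrics, events as ev, flips as fl, geometry, occupancy as occ
from .io import load_replica
from .model import ConfigurationError, Replica, SiteBoundaries, Species

__all__ = ["RunConfig", "run_pipeline"]

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Validated pipeline configuration; unknown keys are rejected."""

    input_dirs: List[str]
    output_dir: str
    landmark_lower: str = "sf_lower"
    landmark_upper: str = "sf_upper"
    voltage_mv: Optional[float] = None  # override replica metadata
    n_bins: int = 24
    radial_cutoff: float = 0.35
    cavity_width: float = 0.3
    s0_width: float = 0.3
    flip_min_duration: int = 1
    causality_lookback: int = 1
    do_occupancy: bool = True
    do_flips: bool = True

    def __post_init__(self) -> None:
        if isinstance(self.input_dirs, (str, Path)):
            self.input_dirs = [str(self.input_dirs)]
        if not self.input_dirs:
            raise ConfigurationError("at least one input directory is required")
        if self.n_bins < 4:
            raise ConfigurationError("n_bins must be >= 4")
        if self.flip_min_duration < 1 or self.causality_lookback < 1:
            raise ConfigurationError("flip_min_duration and lookback must be >= 1")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        if "input_dirs" not in raw or "output_dir" not in raw:
            raise ConfigurationError("config requires input_dirs and output_dir")
        return cls(**raw)


def _check_voltage(replica: Replica, cfg: RunConfig) -> float:
    v = cfg.voltage_mv if cfg.voltage_mv is not None else replica.voltage
    if v == 0:
        raise ConfigurationError(
            "voltage is zero/missing; set voltage_mv for conductance analysis"
        )
    return v


def run_pipeline(config: RunConfig) -> Dict:
    """Run every analysis stage over the configured replicas.

    Writes per-stage tables (TSV) and a single ``summary.json`` plus a
    human-readable ``report.txt`` to the output directory, and returns the
    summary dict.  Identical inputs and configuration produce byte-identical
    outputs.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    replicas: List[Replica] = []
    for d in config.input_dirs:
        t0 = time.perf_counter()
        rep = load_replica(d)
        logger.info("load %s: T=%d (%.2fs)", d, rep.n_frames, time.perf_counter() - t0)
        replicas.append(rep)
    voltages = [_check_voltage(r, config) for r in replicas]

    summary: Dict = {"replicas": []}
    event_rows = []
    per_rep_g: Dict[str, List[float]] = {}
    all_boundaries = []
    occ_tables = []

    for ri, (rep, v) in enumerate(zip(replicas, voltages)):
        b = geometry.compute_region_boundaries(
            rep, config.landmark_lower, config.landmark_upper
        )
        all_boundaries.append(b)
        ledger = ev.count_replica_events(rep, b)
        coperm = ev.water_copermeation(ledger)
        for e in ledger.events:
            event_rows.append(
                {
                    "replica": ri,
                    "particle": e.particle_id,
                    "species": e.species.value,
                    "direction": e.direction.value,
                    "frame": e.completion_frame,
                    "time_ns": e.completion_frame * rep.dt,
                }
            )
        rep_summary = {
            "index": ri,
            "n_frames": rep.n_frames,
            "duration_us": rep.duration_us,
            "voltage_mv": v,
            "n_outward": ledger.n_outward,
            "n_inward": ledger.n_inward,
            "net_outward": ledger.net_outward_by_species,
            "water_ion_ratio": coperm.ratio,
        }
        for sp in ("K", "NA", "WATER"):
            g = electrics.conductance(
                ledger.net_outward(Species(sp)), rep.duration_us, v
            )
            rep_summary[f"conductance_{sp}_pS"] = g
            per_rep_g.setdefault(sp, []).append(g)

        if config.do_occupancy:
            sites = SiteBoundaries.uniform(
                b,
                cavity_width=config.cavity_width,
                s0_width=config.s0_width,
                radial_cutoff=config.radial_cutoff,
            )
            table = occ.assign_sites(rep, sites)
            occ_tables.append(table)
            census = occ.configuration_census(table)
            transitions = occ.classify_transitions(table)
            kinds = pd.Series([t.jump_type for t in transitions])
            rep_summary["census_top"] = dict(list(census.items())[:8])
            rep_summary["transition_counts"] = (
                kinds.value_counts().to_dict() if len(kinds) else {}
            )
            rep_summary["mean_waters_between_ions"] = (
                float(np.mean(w)) if (w := occ.waters_between_ions(table)).size else None
            )
            pd.DataFrame(
                {
                    "frame": np.arange(table.n_frames),
                    **{
                        name: table.labels[:, table.site_column(name)]
                        for name in table.site_names
                    },
                }
            ).to_csv(outdir / f"occupancy_r{ri}.tsv", sep="\t", index=False)
            pd.DataFrame([t.__dict__ for t in transitions]).to_csv(
                outdir / f"transitions_r{ri}.tsv", sep="\t", index=False
            )

        if config.do_flips and rep.dihedrals is not None:
            flipped = fl.classify_flip(rep.dihedrals)
            census_f = fl.simultaneous_flip_census(flipped)
            events_f = fl.segment_flip_events(flipped, rep.dt, config.flip_min_duration)
            rep_summary["flip_census"] = census_f.as_dict()
            rep_summary["n_flip_events"] = len(events_f)
            if config.do_occupancy and occ_tables:
                causality = fl.water_flip_causality(
                    events_f, occ_tables[-1], config.causality_lookback
                )
                rep_summary["flip_causality"] = {
                    "fraction_water_first": causality.fraction_water_first,
                    "n_water_first": causality.n_water_first,
                    "n_no_water": causality.n_no_water,
                    "n_excluded": causality.n_excluded,
                    "median_duration_water_first_ns": causality.median_duration_water_first_ns,
                    "median_duration_no_water_ns": causality.median_duration_no_water_ns,
                }
            pd.DataFrame(
                [
                    {
                        "subunit": e.subunit,
                        "onset_frame": e.onset_frame,
                        "offset_frame": e.offset_frame,
                        "duration_ns": e.duration_ns,
                        "edge_truncated": e.edge_truncated,
                        "water_in_s23_at_onset": e.water_in_s23_at_onset,
                    }
                    for e in events_f
                ]
            ).to_csv(outdir / f"flips_r{ri}.tsv", sep="\t", index=False)

        summary["replicas"].append(rep_summary)

    pd.DataFrame(
        event_rows,
        columns=["replica", "particle", "species", "direction", "frame", "time_ns"],
    ).to_csv(outdir / "events.tsv", sep="\t", index=False)

    summary["conductance"] = {}
    for sp, gs in per_rep_g.items():
        est = electrics.mean_ci(gs)
        total_net = sum(
            r["net_outward"].get(sp, 0) for r in summary["replicas"]
        )
        total_dur = sum(r["duration_us"] for r in summary["replicas"])
        pooled = electrics.conductance(total_net, total_dur, voltages[0])
        summary["conductance"][sp] = {
            "mean_pS": est.mean,
            "ci95_pS": None if not est.ci_defined else est.ci95_halfwidth,
            "pooled_pS": pooled,
            "n_replicas": est.n_replicas,
            "n_net_events": total_net,
        }

    prof = occ.density_profile(replicas, all_boundaries, n_bins=config.n_bins)
    pd.DataFrame(
        {
            "bin_z_nm": np.repeat(prof.bin_centers, len(prof.densities)),
            "species": list(prof.densities) * len(prof.bin_centers),
            "density": np.stack(list(prof.densities.values()), axis=1).reshape(-1),
        }
    ).to_csv(outdir / "density_profile.tsv", sep="\t", index=False)

    (outdir / "summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True) + "\n"
    )
    (outdir / "report.txt").write_text(render_report(summary))
    return summary


def render_report(summary: Dict) -> str:
    """Plain-text digest of a pipeline summary."""
    lines = ["permeation analysis report", "=" * 26, ""]
    for rep in summary["replicas"]:
        lines.append(
            f"replica {rep['index']}: {rep['n_frames']} frames, "
            f"{rep['duration_us']:.3f} us at {rep['voltage_mv']:+.0f} mV"
        )
        lines.append(f"  net outward events: {rep['net_outward']}")
        ratio = rep.get("water_ion_ratio")
        lines.append(
            "  water:ion ratio: "
            + (f"{ratio:.3f}" if ratio is not None else "undefined (no net ion flux)")
        )
        if "census_top" in rep:
            top = ", ".join(f"{k}={v:.3f}" for k, v in rep["census_top"].items())
            lines.append(f"  top configurations: {top}")
        if "flip_census" in rep:
            lines.append(
                f"  flipped-subunit fractions: {rep['flip_census']}"
            )
        if "flip_causality" in rep:
            fc = rep["flip_causality"]
            frac = fc["fraction_water_first"]
            lines.append(
                "  flips preceded by water in S2/S3: "
                + (f"{frac:.3f}" if frac is not None else "n/a")
                + f" ({fc['n_water_first']}/{fc['n_water_first'] + fc['n_no_water']})"
            )
        lines.append("")
    for sp, c in summary.get("conductance", {}).items():
        ci = c["ci95_pS"]
        lines.append(
            f"{sp}: mean {c['mean_pS']:.3f} pS"
            + (f" +- {ci:.3f} (95% CI)" if ci is not None else "")
            + f", pooled {c['pooled_pS']:.3f} pS over {c['n_replicas']} replica(s)"
        )
    return "\n".join(lines) + "\n"
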