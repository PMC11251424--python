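"""Generator ground truth, determinism, single-file invariants, recovery."""

import json

import numpy as np
import pytest
from scipy import stats

import knockon as k


class TestDeterminism:
    def test_same_seed_bit_identical(self):
        spec = k.MechanismSpec(mode="SOFT")
        a = k.simulate(spec, 0.3, 0.5, seed=9)
        b = k.simulate(spec, 0.3, 0.5, seed=9)
        for ta, tb in zip(a.replica.traces, b.replica.traces):
            assert ta.particle_id == tb.particle_id
            assert np.array_equal(ta.z, tb.z, equal_nan=True)
        assert np.array_equal(a.replica.dihedrals, b.replica.dihedrals)

    def test_different_seeds_differ(self):
        spec = k.MechanismSpec(mode="DIRECT")
        a = k.simulate(spec, 0.3, 0.5, seed=1)
        b = k.simulate(spec, 0.3, 0.5, seed=2)
        assert len(a.ground_truth.events) != len(b.ground_truth.events) or any(
            ea.time_ns != eb.time_ns
            for ea, eb in zip(a.ground_truth.events, b.ground_truth.events)
        )


class TestGroundTruth:
    def test_direct_mode_never_permeates_water(self, direct_traj):
        gt = direct_traj.ground_truth
        assert gt.n_outward.get("WATER", 0) == 0
        assert gt.n_inward.get("WATER", 0) == 0

    def test_soft_mode_ratio_exactly_one(self, soft_traj):
        assert soft_traj.ground_truth.water_ion_ratio == 1.0

    def test_event_rate_within_poisson_noise(self, direct_traj):
        gt = direct_traj.ground_truth
        expected = gt.expected_net_outward["K"]
        observed = gt.n_outward["K"] - gt.n_inward["K"]
        assert abs(observed - expected) < 3 * np.sqrt(expected) + 4

    def test_sodium_thinning_slows_sodium(self):
        spec = k.MechanismSpec(mode="DIRECT", species_mix={"NA": 1.0})
        traj = k.simulate(spec, 1.0, 1.0, seed=13)
        n_na = traj.ground_truth.n_outward.get("NA", 0)
        # effective rate ~ hop_rate * na_rate_scale ~ 1/us
        assert n_na <= 8


class TestSingleFile:
    def test_no_shared_sites_and_no_pass_through(self, soft_traj, soft_analysis):
        occ = soft_analysis["occupancy"]
        sf = [occ.site_column(s) for s in ("S4", "S3", "S2", "S1")]
        prev = None
        for t in range(occ.n_frames):
            cur = {occ.occupants[t, c]: c for c in sf if occ.occupants[t, c]}
            ids = list(cur)
            assert len(ids) == len(set(ids))
            if prev:
                shared = [p for p in ids if p in prev]
                # relative order along z is preserved between frames
                before = sorted(shared, key=lambda p: prev[p])
                after = sorted(shared, key=lambda p: cur[p])
                assert before == after
            prev = cur


class TestPipelineRecovery:
    def test_direct_counts_match_ground_truth_exactly(
        self, direct_traj, direct_analysis
    ):
        gt = direct_traj.ground_truth
        ledger = direct_analysis["ledger"]
        assert ledger.n_outward.get("K", 0) == gt.n_outward["K"]
        assert ledger.n_inward.get("K", 0) == gt.n_inward["K"]

    def test_soft_counts_match_ground_truth_exactly(self, soft_traj, soft_analysis):
        gt = soft_traj.ground_truth
        ledger = soft_analysis["ledger"]
        for sp in ("K", "WATER"):
            assert ledger.net_outward(k.Species(sp)) == gt.net_outward[sp]

    def test_conductance_recovery_across_seeds(self):
        """Pooled analyzed conductance sits in the 95% Poisson band of the
        generator's analytic expectation (10 seeds, halfwidths shrink ~1/sqrt n)."""
        spec = k.MechanismSpec(mode="DIRECT")
        per_seed = []
        total = 0
        expected = 0.0
        for seed in range(10):
            traj = k.simulate(spec, 2.0, 1.0, seed=200 + seed)
            b = k.compute_region_boundaries(traj.replica)
            ledger = k.count_replica_events(traj.replica, b)
            net = ledger.net_outward(k.Species.K)
            total += net
            expected += traj.ground_truth.expected_counted_net_outward["K"]
            per_seed.append(k.conductance(net, traj.duration_us, 300.0))
        lo, hi = stats.poisson.interval(0.95, expected)
        assert lo <= total <= hi
        # replicate the seed sample: halfwidth shrinks ~1/sqrt(n) once the
        # t-quantile has flattened (n = 40 vs 160)
        est40 = k.mean_ci(per_seed * 4)
        est160 = k.mean_ci(per_seed * 16)
        assert est40.ci95_halfwidth / est160.ci95_halfwidth == pytest.approx(2.0, rel=0.1)


class TestEmit:
    def test_emitted_files_reproduce_in_memory_analysis(self, tmp_path, direct_traj):
        k.emit(direct_traj, tmp_path)
        loaded = k.load_replica(tmp_path)
        b_mem = k.compute_region_boundaries(direct_traj.replica)
        b_load = k.compute_region_boundaries(loaded)
        for trace in direct_traj.replica.traces:
            if trace.species == k.Species.LANDMARK:
                continue
            mem = k.assign_regions(trace, b_mem)
            out = k.assign_regions(loaded.trace(trace.particle_id), b_load)
            assert np.array_equal(mem, out)

    def test_sidecar_counts_match_ledger(self, tmp_path, soft_traj):
        k.emit(soft_traj, tmp_path)
        gt = json.loads((tmp_path / "ground_truth.json").read_text())
        assert gt["n_outward"] == soft_traj.ground_truth.n_outward
        assert len(gt["events"]) == len(soft_traj.ground_truth.events)

    def test_two_seeds_same_schema(self, tmp_path):
        spec = k.MechanismSpec(mode="DIRECT")
        for seed in (1, 2):
            d = tmp_path / f"s{seed}"
            k.emit(k.simulate(spec, 0.1, 0.5, seed=seed), d)
            assert (d / "trajectory.tsv").exists()
            assert (d / "meta.json").exists()
            assert (d / "ground_truth.json").exists()


class TestValidation:
    def test_bad_mode_rejected(self):
        with pytest.raises(ValueError):
            k.MechanismSpec(mode="SIDEWAYS")

    def test_aliasing_warning(self):
        spec = k.MechanismSpec(mode="DIRECT", hop_rate=500.0)
        with pytest.warns(UserWarning, match="alias"):
            k.simulate(spec, 0.05, 10.0, seed=0)

    def test_water_coupling_forced_by_mode(self):
        assert k.MechanismSpec(mode="SOFT").water_coupled
        assert not k.MechanismSpec(mode="DIRECT").water_coupled
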