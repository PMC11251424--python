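"""Site occupancy classification, configuration census, transitions, density."""

import numpy as np
import pytest

import knockon as k
from knockon.occupancy import OccupancyTable


def _replica(traces, T=5):
    return k.Replica(traces, dt=1.0, voltage=300.0, box_z=np.full(T, 10.0))


def _trace(pid, sp, z_value, T=5, xy=None):
    return k.ParticleTrace(pid, sp, np.full(T, z_value), xy=xy)


# uniform sites over [4.0, 5.2]: S4 [4.0,4.3) .. S1 [4.9,5.2); centers at .15 offsets
S4, S3, S2, S1 = 4.15, 4.45, 4.75, 5.05


class TestAssignSites:
    def test_single_occupant(self, static_sites):
        rep = _replica([_trace("i", "K", S2)])
        occ = k.assign_sites(rep, static_sites)
        assert occ.config_strings()[0] == "0K00"

    def test_alternating_soft_configuration(self, static_sites):
        rep = _replica([
            _trace("k1", "K", S1), _trace("w1", "WATER", S2),
            _trace("k2", "K", S3), _trace("w2", "WATER", S4),
        ])
        occ = k.assign_sites(rep, static_sites)
        assert occ.config_strings()[0] == "KWKW"

    def test_sodium_letter(self, static_sites):
        occ = k.assign_sites(_replica([_trace("n", "NA", S3)]), static_sites)
        assert occ.config_strings()[0] == "00N0"

    def test_radial_cutoff_excludes(self, static_sites):
        T = 5
        far = _trace("i", "K", S2, xy=np.full((T, 2), 0.5))  # r ~ 0.71 > 0.35
        near = _trace("j", "K", S3, xy=np.full((T, 2), 0.1))
        occ = k.assign_sites(_replica([far, near]), static_sites)
        assert occ.config_strings()[0] == "00K0"

    def test_ion_beats_water(self, static_sites):
        rep = _replica([_trace("w", "WATER", S2 - 0.01), _trace("i", "K", S2 + 0.05)])
        occ = k.assign_sites(rep, static_sites)
        # the water is nearer the center but the ion still wins the site
        assert occ.config_strings()[0] == "0K00"

    def test_permutation_invariance(self, static_sites):
        traces = [
            _trace("a", "K", S1), _trace("b", "WATER", S2),
            _trace("c", "K", S3), _trace("d", "WATER", S4),
        ]
        occ1 = k.assign_sites(_replica(traces), static_sites)
        occ2 = k.assign_sites(_replica(traces[::-1]), static_sites)
        assert np.array_equal(occ1.labels, occ2.labels)
        assert np.array_equal(occ1.occupants, occ2.occupants)

    def test_particle_occupies_at_most_one_site(self, soft_traj, soft_analysis):
        occ = soft_analysis["occupancy"]
        for t in range(0, occ.n_frames, 97):
            ids = [p for p in occ.occupants[t] if p is not None]
            assert len(ids) == len(set(ids))


class TestCensus:
    def test_counting(self):
        labels = np.array(
            [list("0KWKW0")] * 2 + [list("0WKWK0")] + [list("0KKKK0")]
        )
        occ = OccupancyTable(("Scav", "S4", "S3", "S2", "S1", "S0"), labels,
                             np.full(labels.shape, None, dtype=object))
        census = k.configuration_census(occ)
        # labels columns ascend S4..S1; strings read S1..S4
        assert census == {"WKWK": 0.5, "KWKW": 0.25, "KKKK": 0.25}

    def test_fractions_sum_to_one(self, soft_analysis):
        census = k.configuration_census(soft_analysis["occupancy"])
        assert sum(census.values()) == pytest.approx(1.0, abs=1e-12)

    def test_direct_run_has_no_water_in_filter(self, direct_analysis):
        census = k.configuration_census(direct_analysis["occupancy"])
        assert all("W" not in cfg for cfg in census)


class TestTransitions:
    def _table(self, rows):
        labels = np.array([list(r) for r in rows])
        occ = np.empty(labels.shape, dtype=object)
        occ[:] = None
        for t in range(labels.shape[0]):
            for s in range(labels.shape[1]):
                if labels[t, s] != "0":
                    occ[t, s] = f"{labels[t, s]}{s}"
        return labels, occ

    def test_stepwise_shift(self):
        # whole column advances one site; occupant ids move with it
        names = ("Scav", "S4", "S3", "S2", "S1", "S0")
        labels = np.array([list("0KWKW0"), list("00KWKW")])
        occupants = np.array(
            [[None, "a", "b", "c", "d", None], [None, None, "a", "b", "c", "d"]],
            dtype=object,
        )
        recs = k.classify_transitions(OccupancyTable(names, labels, occupants))
        assert len(recs) == 1 and recs[0].jump_type == "STEPWISE"

    def test_ion_direct_jump(self):
        names = ("Scav", "S4", "S3", "S2", "S1", "S0")
        labels = np.array([list("00K000"), list("0000K0")])
        occupants = np.array(
            [[None, None, "ion", None, None, None],
             [None, None, None, None, "ion", None]],
            dtype=object,
        )
        recs = k.classify_transitions(OccupancyTable(names, labels, occupants))
        assert len(recs) == 1 and recs[0].jump_type == "DIRECT_JUMP"

    def test_no_change_no_record(self):
        names = ("Scav", "S4", "S3", "S2", "S1", "S0")
        labels = np.array([list("0K0000")] * 3)
        occupants = np.array(
            [[None, "ion", None, None, None, None]] * 3, dtype=object
        )
        assert k.classify_transitions(OccupancyTable(names, labels, occupants)) == []

    def test_soft_run_is_dominated_by_single_file_motion(self, soft_analysis):
        recs = k.classify_transitions(soft_analysis["occupancy"])
        kinds = {r.jump_type for r in recs}
        assert kinds <= {"STEPWISE", "DIRECT_JUMP", "OTHER"}
        n_step = sum(r.jump_type == "STEPWISE" for r in recs)
        assert n_step >= 0.5 * len(recs)


class TestDensityProfile:
    def test_pinned_ions_occupy_single_bin(self):
        b = k.RegionBoundaries.static(4.0, 5.2, 5)
        rep = _replica([_trace("i", "K", 4.45)])
        prof = k.density_profile(rep, b, n_bins=12)
        d = prof.densities["K"]
        assert np.count_nonzero(d) == 1
        # integrates to one ion per frame
        assert d.sum() * (prof.bin_edges[1] - prof.bin_edges[0]) == pytest.approx(1.0)

    def test_uniform_positions_give_flat_profile(self):
        rng = np.random.default_rng(0)
        T = 4000
        b = k.RegionBoundaries.static(4.0, 5.2, T)
        tr = k.ParticleTrace("i", "K", rng.uniform(4.0, 5.2, T))
        rep = k.Replica([tr], 1.0, 300.0, np.full(T, 10.0))
        prof = k.density_profile(rep, b, n_bins=8)
        counts = prof.densities["K"] * (prof.bin_edges[1] - prof.bin_edges[0]) * T
        p = 1 / 8
        sigma = np.sqrt(T * p * (1 - p))
        assert np.all(np.abs(counts - T * p) < 5 * sigma)

    def test_direct_run_water_free_filter(self, direct_traj, direct_analysis):
        prof = k.density_profile(
            direct_traj.replica, direct_analysis["boundaries"], n_bins=12
        )
        assert np.all(prof.densities["W"] == 0.0)
        assert prof.densities["K"].sum() > 0

    def test_too_few_bins_rejected(self, direct_traj, direct_analysis):
        with pytest.raises(ValueError):
            k.density_profile(direct_traj.replica, direct_analysis["boundaries"], 3)


class TestWatersBetweenIons:
    def test_simple_gaps(self):
        names = ("Scav", "S4", "S3", "S2", "S1", "S0")
        labels = np.array([list("0KWKW0"), list("0KWWK0")])
        occ = OccupancyTable(names, labels, np.full(labels.shape, None, dtype=object))
        gaps = k.waters_between_ions(occ)
        assert gaps.tolist() == [1, 2]
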