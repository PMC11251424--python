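"""Data model invariants, boundary geometry, native dialect round trips."""

import numpy as np
import pytest

import knockon as k
from knockon.io import unwrap_z


class TestBoundaries:
    def test_midpoint_arithmetic(self):
        T = 3
        rep = k.Replica(
            traces=[],
            dt=1.0,
            voltage=300.0,
            box_z=np.full(T, 10.0),
            landmarks={
                "sf_lower": np.full((2, T), 2.0),
                "sf_upper": np.full((2, T), 3.2),
            },
        )
        b = k.compute_region_boundaries(rep)
        assert np.allclose(b.z_lower, 2.0)
        assert np.allclose(b.z_mid, 2.6)
        assert np.allclose(b.z_upper, 3.2)

    def test_translation_covariance(self):
        T = 2
        lower = np.array([[2.0, 2.1]])
        upper = np.array([[3.2, 3.3]])
        rep = k.Replica([], 1.0, 300.0, np.full(T, 10.0),
                        landmarks={"sf_lower": lower, "sf_upper": upper})
        b = k.compute_region_boundaries(rep)
        assert b.z_lower[1] - b.z_lower[0] == pytest.approx(0.1)
        assert b.z_mid[1] - b.z_mid[0] == pytest.approx(0.1)
        assert b.z_upper[1] - b.z_upper[0] == pytest.approx(0.1)

    def test_missing_landmark_is_configuration_error(self):
        rep = k.Replica([], 1.0, 300.0, np.full(2, 10.0),
                        landmarks={"sf_lower": np.full((1, 2), 2.0)})
        with pytest.raises(k.ConfigurationError):
            k.compute_region_boundaries(rep)

    def test_inverted_planes_are_geometry_error(self):
        rep = k.Replica([], 1.0, 300.0, np.full(2, 10.0),
                        landmarks={"sf_lower": np.full((1, 2), 5.0),
                                   "sf_upper": np.full((1, 2), 4.0)})
        with pytest.raises(k.GeometryError):
            k.compute_region_boundaries(rep)

    def test_region_boundaries_ordering_enforced(self):
        with pytest.raises(k.GeometryError):
            k.RegionBoundaries(np.array([5.0]), np.array([4.0]), np.array([6.0]))


class TestElectricField:
    def test_direct_division(self):
        assert k.electric_field(0.3, 15.0) == pytest.approx(0.02)

    def test_sign_propagation(self):
        assert k.electric_field(-0.3, 15.0) == pytest.approx(-0.02)

    def test_zero_box_rejected(self):
        with pytest.raises(k.DomainError):
            k.electric_field(0.3, 0.0)


class TestSiteBoundaries:
    def test_uniform_partition(self):
        b = k.RegionBoundaries.static(4.0, 5.2, 2)
        s = k.SiteBoundaries.uniform(b)
        assert list(s.site_names) == ["Scav", "S4", "S3", "S2", "S1", "S0"]
        # S4..S1 exactly partition [z_lower, z_upper]
        assert s.planes[1, 0] == pytest.approx(4.0)
        assert s.planes[5, 0] == pytest.approx(5.2)
        assert np.all(np.diff(s.planes[:, 0]) > 0)

    def test_oxygen_layer_planes(self):
        layers = {f"L{i}": np.array([4.0 + 0.3 * i]) for i in range(5)}
        s = k.SiteBoundaries.from_oxygen_layers(layers)
        # each site spans the gap between adjacent layers: the S4/S3 plane is
        # the second layer, and S4..S1 cover [4.0, 5.2]
        assert s.planes[2, 0] == pytest.approx(4.3)
        assert s.planes[1, 0] == pytest.approx(4.0)
        assert s.planes[5, 0] == pytest.approx(5.2)


class TestTraces:
    def test_nonfinite_present_z_rejected(self):
        with pytest.raises(k.FormatError):
            k.ParticleTrace("p", "K", np.array([1.0, np.inf]),
                            present=np.array([True, True]))

    def test_frame_count_mismatch_rejected(self):
        with pytest.raises(k.FormatError):
            k.Replica(
                [k.ParticleTrace("a", "K", np.zeros(3)),
                 k.ParticleTrace("b", "K", np.zeros(4))],
                1.0, 300.0, np.full(3, 10.0),
            )


class TestUnwrap:
    def test_wrap_jump_removed(self):
        box = np.full(4, 10.0)
        z = np.array([9.8, 0.1, 0.4, 0.7])  # crosses the periodic boundary once
        out = unwrap_z(z, np.ones(4, bool), box)
        assert np.allclose(out, [9.8, 10.1, 10.4, 10.7])

    def test_no_jump_is_identity(self):
        z = np.array([4.0, 4.2, 4.1])
        out = unwrap_z(z, np.ones(3, bool), np.full(3, 10.0))
        assert np.array_equal(out, z)

    def test_unwrapped_steps_below_half_box(self, tmp_path):
        # wrapped input becomes continuous on load
        T = 6
        z = np.array([9.0, 9.6, 0.2, 0.8, 1.4, 2.0])
        tr = k.ParticleTrace("p", "K", z)
        rep = k.Replica([tr], 1.0, 300.0, np.full(T, 10.0))
        k.write_replica(rep, tmp_path)
        loaded = k.load_replica(tmp_path)
        dz = np.abs(np.diff(loaded.trace("p").z))
        assert np.all(dz < 5.0)


class TestNativeDialect:
    def test_round_trip_bit_identical(self, tmp_path, soft_traj):
        k.write_replica(soft_traj.replica, tmp_path)
        loaded = k.load_replica(tmp_path)
        orig = {t.particle_id: t for t in soft_traj.replica.traces}
        assert set(orig) == {t.particle_id for t in loaded.traces}
        for t in loaded.traces:
            o = orig[t.particle_id]
            assert t.species == o.species
            assert np.array_equal(t.present, o.present)
            assert np.array_equal(t.z[t.present], o.z[o.present])
        assert np.array_equal(loaded.dihedrals, soft_traj.replica.dihedrals)
        assert loaded.dt == soft_traj.replica.dt
        assert loaded.voltage == soft_traj.replica.voltage

    def test_absence_round_trips(self, tmp_path):
        z = np.array([4.1, np.nan, 4.3])
        tr = k.ParticleTrace("p", "K", z)
        rep = k.Replica([tr], 1.0, 300.0, np.full(3, 10.0))
        k.write_replica(rep, tmp_path)
        loaded = k.load_replica(tmp_path)
        assert loaded.trace("p").present.tolist() == [True, False, True]

    def test_bad_landmark_reference(self, tmp_path, direct_traj):
        k.write_replica(direct_traj.replica, tmp_path)
        with pytest.raises(k.ConfigurationError):
            k.load_replica(tmp_path, landmarks={"sf_lower": ["nope"]})

    def test_landmark_groups_survive_round_trip(self, tmp_path, direct_traj):
        k.write_replica(direct_traj.replica, tmp_path)
        loaded = k.load_replica(tmp_path)
        assert set(loaded.landmarks) == {"sf_lower", "sf_upper"}
        b = k.compute_region_boundaries(loaded)
        assert np.all(b.z_lower < b.z_mid) and np.all(b.z_mid < b.z_upper)
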