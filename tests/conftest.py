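import numpy as np
import pytest

import knockon as k


@pytest.fixture(scope="session")
def direct_traj():
    """Water-free direct knock-on run: 1 us at 0.25 ns frames, +300 mV."""
    return k.simulate(
        k.MechanismSpec(mode="DIRECT"), duration_us=1.0, dt_ns=0.25, seed=7
    )


@pytest.fixture(scope="session")
def soft_traj():
    """Water-coupled soft knock-on run with water-triggered carbonyl flips."""
    spec = k.MechanismSpec(
        mode="SOFT", flip_model=k.FlipModel("water_triggered", 0.15, 0.05)
    )
    return k.simulate(spec, duration_us=1.0, dt_ns=0.25, seed=11)


@pytest.fixture(scope="session")
def direct_analysis(direct_traj):
    rep = direct_traj.replica
    b = k.compute_region_boundaries(rep)
    ledger = k.count_replica_events(rep, b)
    occ = k.assign_sites(rep, direct_traj.site_boundaries)
    return {"boundaries": b, "ledger": ledger, "occupancy": occ}


@pytest.fixture(scope="session")
def soft_analysis(soft_traj):
    rep = soft_traj.replica
    b = k.compute_region_boundaries(rep)
    ledger = k.count_replica_events(rep, b)
    occ = k.assign_sites(rep, soft_traj.site_boundaries)
    return {"boundaries": b, "ledger": ledger, "occupancy": occ}


@pytest.fixture()
def static_sites():
    """Uniform site boundaries over a static filter [4.0, 5.2] nm, 5 frames."""
    b = k.RegionBoundaries.static(4.0, 5.2, 5)
    return k.SiteBoundaries.uniform(b)


def make_replica(traces, T, dt=1.0, voltage=300.0, box_z=10.0, **kw):
    """Convenience constructor for hand-built replicas."""
    return k.Replica(traces=traces, dt=dt, voltage=voltage, box_z=np.full(T, box_z), **kw)
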