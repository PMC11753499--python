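import numpy as np
import pytest

from flexgel.config import PolymerConfiguration, chain_topology
from flexgel.params import SimulationParameters


@pytest.fixture(scope="session")
def params():
    """Default parameter set (flexible chains, K_theta = 0)."""
    return SimulationParameters()


@pytest.fixture(scope="session")
def stiff_params():
    """Parameters with a moderate bending constant."""
    return SimulationParameters(K_theta=50.0)


def make_random_config(
    n_chains=4,
    dp=5,
    box_edge=8.0,
    seed=0,
    min_sep=0.85,
    crosslinks=(),
    flexible=False,
    avoid_cutoff=None,
):
    """Random wrapped configuration with chain topology and a minimum
    separation, optionally avoiding pair distances near a cutoff (so that
    finite differences never straddle the discontinuity in the truncated
    force)."""
    rng = np.random.default_rng(seed)
    n = n_chains * dp
    for _ in range(500):
        pos = rng.uniform(0.0, box_edge, size=(n, 3))
        disp = pos[:, None, :] - pos[None, :, :]
        disp -= box_edge * np.rint(disp / box_edge)
        d = np.sqrt((disp**2).sum(-1))
        iu = np.triu_indices(n, k=1)
        dv = d[iu]
        if dv.min() < min_sep:
            continue
        if avoid_cutoff is not None and np.any(np.abs(dv - avoid_cutoff) < 1e-3):
            continue
        break
    else:
        raise RuntimeError("could not draw a valid random configuration")
    chain_of, bonds, angles = chain_topology([dp] * n_chains)
    return PolymerConfiguration(
        positions=pos,
        velocities=rng.normal(size=(n, 3)),
        chain_of=chain_of,
        bonds=bonds,
        angles=angles,
        crosslinks=np.asarray(list(crosslinks), dtype=np.int64).reshape(-1, 2),
        box_edge=box_edge,
        flexible=flexible,
    )


@pytest.fixture
def random_config():
    return make_random_config()
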