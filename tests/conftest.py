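import numpy as np
import pytest

import sifkit as sk


@pytest.fixture(scope="session")
def g2m():
    return sk.g2m_model()


@pytest.fixture(scope="session")
def mapk():
    return sk.mapk_model()


@pytest.fixture(scope="session")
def g2m_wt_readout(g2m):
    return sk.g2m_readout(g2m)


@pytest.fixture(scope="session")
def mapk_wt_traj(mapk):
    return sk.integrate(mapk)


@pytest.fixture(scope="session")
def mapk_wt_metrics(mapk_wt_traj):
    return sk.mapk_metrics(mapk_wt_traj)


@pytest.fixture(scope="session")
def decay():
    return sk.linear_decay_model(k=0.3, s0=1.0, horizon=10.0)


def triangular_trajectory(n_per_side=200, t_rise=1.0, t_total=2.0, scale=1.0,
                          dilate=1.0):
    """A triangular pulse rising 0->scale over [0, t_rise] and falling
    back to 0 at t_total, optionally dilated in time."""
    t1 = np.linspace(0.0, t_rise, n_per_side, endpoint=False)
    t2 = np.linspace(t_rise, t_total, n_per_side + 1)
    t = np.concatenate([t1, t2]) * dilate
    s = np.concatenate([t1 / t_rise,
                        (t_total - t2) / (t_total - t_rise)]) * scale
    return sk.Trajectory(times=t, states=s[None, :], species=("pulse",))
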