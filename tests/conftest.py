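import numpy as np
import pytest

from vocalmap.devsim import SimConfig, babble_generator
from vocalmap.pm_map import PerceptualMotorMap
from vocalmap.spaces import N_ARTIC, N_SOUND, UNIT_BOX_IDX, JDIR_IDX
from vocalmap.trajectories import MotorTrajectory


def random_artic(rng, n=1):
    """Random valid articulatory configuration rows (derivatives unbounded)."""
    vals = np.empty((n, N_ARTIC))
    vals[:, UNIT_BOX_IDX] = rng.uniform(0, 1, size=(n, 10))
    vals[:, 10:19] = rng.normal(0, 2, size=(n, 9))
    vals[:, JDIR_IDX] = rng.uniform(-1, 1, size=n)
    return vals if n > 1 else vals[0]


def random_sound(rng, n=1, per=None):
    """Random valid sound rows (zeroing rules applied by construction)."""
    vals = rng.normal(0, 3, size=(n, N_SOUND))
    p = rng.integers(0, 2, size=n) if per is None else np.full(n, per)
    vals[:, 1] = p
    aper = p == 0
    vals[np.ix_(aper, np.array([2, 3, 4, 7, 8, 9]))] = 0.0
    vals[np.ix_(~aper, np.array([5, 6, 10, 11]))] = 0.0
    return vals if n > 1 else vals[0]


def sine_motor_trajectory(domain_end=2.0, n=129, syllables=2, phase=0.0, amp=0.8, offset=None):
    """A smooth analytic motor trajectory with a controllable jaw cycle."""
    t = np.linspace(0.0, domain_end, n)
    u = t / domain_end * syllables
    vals = np.zeros((n, N_ARTIC))
    base = np.full(10, 0.5) if offset is None else offset
    vals[:, :10] = base
    vals[:, 2] = 0.5 + 0.3 * np.sin(2 * np.pi * u + phase)  # c2 wiggles
    vals[:, 10:19] = 0.0
    vals[:, JDIR_IDX] = amp * np.sin(2 * np.pi * u)
    return MotorTrajectory(times=t, values=vals)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_map():
    """A map initialized with a handful of babbles (shared fixture, read-only)."""
    cfg = SimConfig(seed=7, n_babbles=6)
    pm = PerceptualMotorMap()
    for b in babble_generator(cfg, seed=11):
        pm.record_vocalization(b)
    return pm
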