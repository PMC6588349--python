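import numpy as np
import pytest

from tmdlab.photobleach import IntensityTrace
from tmdlab.simulate import SimPullConfig, gen_photobleach_cohort
from tmdlab.stoichiometry import StoichiometryModel


def make_staircase(levels, seg_lengths, dt=0.05, noise_sd=0.0, rng=None,
                   trace_id="stair"):
    """Piecewise-constant trace: levels[i] held for seg_lengths[i] samples."""
    y = np.concatenate([np.full(n, lv, dtype=float)
                        for lv, n in zip(levels, seg_lengths)])
    if noise_sd > 0:
        y = y + (rng or np.random.default_rng(0)).normal(0, noise_sd, y.size)
    t = np.arange(y.size) * dt
    return IntensityTrace(trace_id, t, y)


@pytest.fixture(scope="session")
def small_cohort():
    """1,000-spot mixed cohort at the study's labeling conditions."""
    model = StoichiometryModel(p=0.8, b=0.0, f_dimer=0.6)
    cfg = SimPullConfig(n_spots=1000, model=model, seed=11)
    return gen_photobleach_cohort(cfg)
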