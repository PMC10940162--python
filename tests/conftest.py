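import numpy as np
import pandas as pd
import pytest

from minusend import simulate


@pytest.fixture(scope="session")
def monomer_model() -> simulate.MonomerModel:
    return simulate.MonomerModel(family="lognormal", mean=1000.0, cv=0.35)


@pytest.fixture(scope="session")
def monomer_sample(monomer_model) -> simulate.IntensityDataset:
    return simulate.gen_monomer_intensities(monomer_model, 10_000, seed=11)


def _times(values):
    return [np.nan if v is None else float(v) for v in values]


@pytest.fixture(scope="session")
def hand_event_table() -> simulate.EventTable:
    """20 hand-scored complexes over two fields of view.

    Active: 12/20 (60%).  Of the active, 5 acquired a binder (41.67%);
    2 of those 5 started minus-end growth (release: 40% of bound, 16.67%
    of active) with binding→growth delays of 100 s and 200 s.  Four
    active complexes depolymerized; 2 of the 4 re-nucleated (50%).
    """
    n = 20
    active = [True] * 12 + [False] * 8
    t_nuc = _times([10.0] * 12 + [None] * 8)
    t_bind = _times([50.0] * 5 + [None] * 15)
    t_growth = _times([150.0, 250.0] + [None] * 18)
    t_release = list(t_growth)
    t_dep = _times([None] * 4 + [100.0] * 4 + [None] * 12)
    t_renuc = _times([None] * 4 + [200.0] * 2 + [None] * 14)
    df = pd.DataFrame({
        "complex_id": range(n),
        "fov": [i % 2 for i in range(n)],
        "active": active,
        "t_nucleate": t_nuc, "t_depoly": t_dep, "t_renucleate": t_renuc,
        "t_bind": t_bind, "t_growth_onset": t_growth,
        "t_release": t_release})
    return simulate.EventTable(df, window=(0.0, 600.0))


@pytest.fixture(scope="session")
def sawtooth_track() -> simulate.Track:
    """Noiseless sawtooth: 5 cycles of 300 s growth at +1 µm/min followed
    by 60 s shrinkage at -5 µm/min, sampled every 3 s."""
    dt = 3.0
    times = np.arange(0.0, 1800.0 + dt / 2, dt)
    pos = np.empty_like(times)
    for i, t in enumerate(times):
        c = t % 360.0
        pos[i] = c / 60.0 if c < 300.0 else 5.0 - (c - 300.0) * 5.0 / 60.0
    return simulate.Track(times, pos, frame_interval=dt)
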