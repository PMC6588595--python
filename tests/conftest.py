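import numpy as np
import pytest

from scnburst import GenConfig, bin_spikes, gen_spike_trains


@pytest.fixture(scope="session")
def wt_five_cycles():
    """Summary statistics of a full-scale wild-type simulation.

    Five circadian cycles across 12 electrodes; returns the global maximum
    100-ms bin rate and the electrode-mean 1-min rate series (the slice-level
    firing rhythm).  Heavy, so computed once per session and reduced to the
    quantities the tests need.
    """
    cfg = GenConfig(preset="wt", n_electrodes=12, duration_h=5 * 23.86, seed=101)
    trains = gen_spike_trains(cfg)
    fine = bin_spikes(trains, 0.1)
    max_bin_rate = max(float(r.max()) for r in fine.rates.values())
    n_fine_bins = fine.n_bins * len(fine.electrodes)
    del fine
    coarse = bin_spikes(trains, 60.0)
    mean_1min = coarse.mean_rate()
    del trains, coarse
    return {
        "cfg": cfg,
        "max_bin_rate_hz": max_bin_rate,
        "n_fine_bins": n_fine_bins,
        "mean_1min_hz": np.asarray(mean_1min),
    }
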