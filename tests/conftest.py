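import numpy as np
import pandas as pd
import pytest

import medipdmr as m


@pytest.fixture(scope="session")
def small_sim():
    """A small null simulation shared by read-only tests."""
    cfg = m.SimConfig(seed=42, n_chrom=1, chrom_length=200_000,
                      n_samples_per_group=4, mean_depth=20)
    return m.simulate(cfg)


@pytest.fixture()
def results_frame():
    """Hand-built genome-ordered window test result frame."""
    def make(p_values, start0=0, window=100, chrom="chr1", gaps=None):
        n = len(p_values)
        starts = np.arange(n) * window + start0
        if gaps:
            for i, g in gaps.items():
                starts[i:] += g
        return pd.DataFrame({
            "chrom": chrom,
            "start": starts,
            "end": starts + window,
            "p_value": np.asarray(p_values, dtype=float),
        })
    return make
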