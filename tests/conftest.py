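import numpy as np
import pandas as pd
import pytest

import traelkit as tk


@pytest.fixture(scope="session")
def desk_layout() -> tk.GenomeLayout:
    return tk.uniform_layout(2, 500_000)


@pytest.fixture(scope="session")
def desk_experiment(desk_layout):
    """Default desk-scale fork simulation: 10 origins, all firing."""
    params = tk.ForkSimParams(
        origins=tk.evenly_spaced_origins(desk_layout, 5), firing_probability=1.0, seed=7
    )
    ends, truth = tk.simulate_trael_experiment(desk_layout, params)
    return params, ends, truth


def ends_frame(rows):
    """Build a read-end table from (chrom, pos, strand, count) tuples."""
    return pd.DataFrame(rows, columns=["chrom", "pos", "strand", "count"])


@pytest.fixture
def single_origin_layout():
    return tk.GenomeLayout({"chrA": 200_000})


def make_probe(raw, bin_size=100, side="downstream", **kw):
    defaults = dict(
        origin_id="ORI_test", chrom="chrA", origin_pos=100_000, side=side,
        bin_size=bin_size, raw=np.asarray(raw, dtype=float),
    )
    defaults.update(kw)
    return tk.ForkProbe(**defaults)
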