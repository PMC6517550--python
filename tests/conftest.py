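import numpy as np
import pandas as pd
import pytest

import growthmodulon as gm
from growthmodulon.counts import drop_all_zero_genes
from growthmodulon.de import DEFAULT_LFC_CUTOFFS, call_degs, fit_rate_course


@pytest.fixture(scope="session")
def small_config():
    """Desk-scale design: full 40-sample layout, few genes."""
    return gm.SimulationConfig(
        n_genes=400,
        modulon_size=60,
        condition_private_deg_count=30,
        n_regulons=10,
        planted_enriched_regulons=2,
        regulon_size_range=(5, 15),
        seed=11,
    )


@pytest.fixture(scope="session")
def small_sim(small_config):
    counts, meta, truth = gm.simulate_counts(small_config)
    return counts, meta, truth


@pytest.fixture(scope="session")
def small_fits(small_sim):
    """Per-condition fit tables and DEG sets on the small simulation."""
    counts, meta, _ = small_sim
    counts = drop_all_zero_genes(counts)
    sf = gm.rle_size_factors(counts)
    fits, degs = {}, []
    for cond in meta["condition"].unique():
        sel = meta["condition"] == cond
        ids = meta.loc[sel, "sample_id"].tolist()
        f = fit_rate_course(
            counts[ids],
            meta.loc[sel, "mu"].to_numpy(dtype=float),
            sf[ids],
            condition=cond,
        )
        fits[cond] = f
        degs.append(call_degs(f, 0.05, DEFAULT_LFC_CUTOFFS[cond]))
    return fits, degs


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
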