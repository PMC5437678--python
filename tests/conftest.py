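import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import gbmscape as gb

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_records(rows):
    """Build a cytosine table from (chrom, pos, strand, context, n_meth, n_unmeth)."""
    return pd.DataFrame(
        [(c, p, s, m, u, x) for (c, p, s, x, m, u) in rows],
        columns=["chrom", "pos", "strand", "n_meth", "n_unmeth", "context"],
    )


@pytest.fixture(scope="session")
def default_sim():
    """Default-condition simulation at seed 1, shared across tests."""
    cfg = gb.SimulationConfig(seed=1)
    ann = gb.simulate_annotation(cfg)
    pos = gb.simulate_cytosine_positions(ann, cfg)
    return {
        "config": cfg,
        "annotation": ann,
        "positions": pos,
        "wt": gb.simulate_methylome(ann, cfg, "WT", 0, pos),
        "kd1": gb.simulate_methylome(ann, cfg, "kd", 0, pos),
        "kd2": gb.simulate_methylome(ann, cfg, "kd", 1, pos),
    }


@pytest.fixture(scope="session")
def small_sim():
    """A compact simulation (1 x 150 kb, 40 genes) for faster end-to-end tests."""
    cfg = gb.SimulationConfig(seed=7, n_chroms=1, chrom_length=150_000,
                              n_genes=40, n_tes=20)
    ann = gb.simulate_annotation(cfg)
    pos = gb.simulate_cytosine_positions(ann, cfg)
    return {
        "config": cfg,
        "annotation": ann,
        "positions": pos,
        "wt": gb.simulate_methylome(ann, cfg, "WT", 0, pos),
        "kd1": gb.simulate_methylome(ann, cfg, "kd", 0, pos),
        "kd2": gb.simulate_methylome(ann, cfg, "kd", 1, pos),
    }
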