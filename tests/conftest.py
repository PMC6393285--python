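import numpy as np
import pandas as pd
import pytest

from pol3dyn.synthetic_data import SimConfig


def make_frags(rows):
    """Fragment frame from (chrom, start, end, weight, pair_id) tuples."""
    return pd.DataFrame(
        rows, columns=["chrom", "start", "end", "weight", "pair_id"]
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)


@pytest.fixture
def small_cfg():
    """Compact simulated experiment used by fast end-to-end tests."""
    return SimConfig(
        genome_length=400_000,
        n_chromosomes=2,
        n_loci_by_type={"tRNA": 10, "SINE": 4, "Rn5s": 1, "Rn4.5s": 1},
        depth_per_sample=80_000,
        n_trna_clusters=1,
        n_background_pol2=6,
        seed=11,
    )
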