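import warnings

import numpy as np
import pandas as pd
import pytest

from prosper_prs import simulate as sim
from prosper_prs.data_io import GenotypePanel, SumStats


@pytest.fixture(autouse=True)
def _quiet_known_warnings():
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="zero-variance score")
        warnings.filterwarnings("ignore", message=".*candidate PRSs but only.*")
        from sklearn.exceptions import ConvergenceWarning
        warnings.filterwarnings("ignore", category=ConvergenceWarning)
        yield


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def small_config():
    """Tiny two-population study used by fast structural tests."""
    return sim.SimConfig(p_snps=200, block_size=40, n_gwas=(20_000, 8_000),
                         n_tune=400, n_valid=400, seed=7)


@pytest.fixture
def small_study(small_config):
    ld, snp_table, member, freqs = sim.gen_ld_blocks(small_config)
    truth = sim.simulate_effects(small_config, ld)
    ss = [sim.simulate_sumstats(truth, ld[pop], small_config.n_gwas[i], seed=11 + i)
          for i, pop in enumerate(small_config.populations)]
    return {"config": small_config, "ld": ld, "truth": truth, "sumstats": ss,
            "snp_table": snp_table}


def make_sumstats(population="POP", n_snps=5, r=None, seed=0):
    rng = np.random.default_rng(seed)
    r = rng.uniform(-0.1, 0.1, n_snps) if r is None else np.asarray(r, dtype=float)
    df = pd.DataFrame({
        "snp_id": [f"rs{i}" for i in range(len(r))],
        "chrom": "1", "pos": np.arange(1, len(r) + 1),
        "a1": "A", "a2": "G", "r": r, "n": 10_000, "freq": 0.3,
    })
    return SumStats(population, df)


def make_panel(dosages, standardized=False, chrom="1"):
    dosages = np.asarray(dosages, dtype=float)
    n, p = dosages.shape
    snps = pd.DataFrame({"snp_id": [f"rs{i}" for i in range(p)], "chrom": chrom,
                         "pos": np.arange(1, p + 1), "a1": "A", "a2": "G"})
    return GenotypePanel(np.array([f"s{i}" for i in range(n)], dtype=object),
                         snps, dosages, standardized=standardized)
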