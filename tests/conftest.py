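import numpy as np
import pytest

import zebupop as z


def make_panel(calls, positions=None, chrom=None, breeds=None, prefix="s"):
    """Small hand-built panel; calls is an (n_samples, n_markers) array
    using -1 for missing."""
    calls = np.asarray(calls, dtype=np.int8)
    n, m = calls.shape
    if positions is None:
        positions = (np.arange(m) + 1) * 1000
    if chrom is None:
        chrom = ["1"] * m
    markers = z.MarkerMap(
        marker_id=np.array([f"m{j}" for j in range(m)], dtype=object),
        chromosome=np.asarray(chrom, dtype=object),
        position_bp=np.asarray(positions, dtype=np.int64),
        allele_ref=np.full(m, "A", dtype=object),
        allele_alt=np.full(m, "G", dtype=object),
    )
    if breeds is None:
        breeds = ["B1"] * n
    return z.GenotypePanel(
        sample_ids=[f"{prefix}{i}" for i in range(n)],
        breed_labels=list(breeds),
        markers=markers,
        calls=calls,
    )


@pytest.fixture(scope="session")
def two_breed_panel():
    """Two moderately diverged breeds, n=50, HWE within breed."""
    cfg = z.SimConfig(seed=101, n_per_breed=50, n_markers=5000, breed_f=(0.05, 0.2))
    return z.balding_nichols_panel(cfg)


@pytest.fixture(scope="session")
def diverged_pools():
    """Deeply diverged true frequency pools on a shared 10k-marker map."""
    cfg = z.SimConfig(seed=202, n_markers=10000)
    return z.pool_freq_table(cfg, "indicine"), z.pool_freq_table(cfg, "taurine")
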