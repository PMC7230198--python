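import numpy as np
import pandas as pd
import pytest

from hostadapt import changescan


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)


def make_profile(delta, scaffold="s1", chrom_class="autosome"):
    """Build a ChangeProfile from a delta vector (single or per-SNP labels)."""
    delta = np.asarray(delta, dtype=float)
    n = delta.size
    scaffold = np.broadcast_to(np.asarray(scaffold, dtype=object), (n,))
    chrom_class = np.broadcast_to(np.asarray(chrom_class, dtype=object), (n,))
    pos = np.empty(n, dtype=int)
    for scaf in pd.unique(scaffold):
        idx = np.flatnonzero(scaffold == scaf)
        pos[idx] = 100 * (1 + np.arange(idx.size))
    return changescan.ChangeProfile(
        pd.DataFrame(
            {
                "scaffold": scaffold,
                "position": pos,
                "chrom_class": chrom_class,
                "p0": 0.5,
                "p1": 0.5,
                "delta": delta,
            }
        )
    )


@pytest.fixture
def profile_factory():
    return make_profile
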