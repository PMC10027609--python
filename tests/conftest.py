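import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20230220)


@pytest.fixture(scope="session")
def random_site_table():
    """Factory for randomized raw site tables (sorted, with indels and
    low-depth sites mixed in) used to exercise the filtering pipeline."""
    import pandas as pd

    def make(seed, n_sites=800, n_chroms=3):
        r = np.random.default_rng(seed)
        rows = []
        for c in range(1, n_chroms + 1):
            pos = np.cumsum(r.integers(10, 400, size=n_sites // n_chroms))
            for p in pos:
                ref, alt = r.choice(list("ACGT"), size=2, replace=False)
                if r.random() < 0.03:  # indel to be dropped
                    ref = ref + "T"
                rows.append(
                    {
                        "chrom": f"Chr{c}",
                        "pos": int(p),
                        "ref": ref,
                        "alt": alt,
                        "necrotic_ref": int(r.poisson(60)),
                        "necrotic_alt": int(r.poisson(60)),
                        "healthy_ref": int(r.poisson(70)),
                        "healthy_alt": int(r.poisson(55)),
                    }
                )
        return pd.DataFrame(rows)

    return make
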