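import numpy as np
import pytest

from mr2s.harmonize import HarmonizedInstrument


def make_instruments(beta_exp, beta_out, se_out, se_exp=None, rsids=None,
                     locus_class=None):
    """Build a kept-instrument list from plain arrays."""
    beta_exp = np.asarray(beta_exp, dtype=float)
    beta_out = np.asarray(beta_out, dtype=float)
    se_out = np.asarray(se_out, dtype=float)
    se_exp = np.full_like(beta_exp, 0.01) if se_exp is None else np.asarray(se_exp, float)
    rsids = rsids or [f"rs{i}" for i in range(len(beta_exp))]
    return [HarmonizedInstrument(rsid=r, beta_exp=b, se_exp=sb, eaf=0.3,
                                 beta_out=g, se_out=sg, locus_class=locus_class)
            for r, b, sb, g, sg in zip(rsids, beta_exp, se_exp, beta_out, se_out)]


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_instruments(rng):
    """Five random instruments with heterogeneous weights."""
    b = rng.uniform(0.05, 0.5, size=5)
    g = 0.1 * b + rng.normal(0, 0.02, size=5)
    s = rng.uniform(0.01, 0.05, size=5)
    return make_instruments(b, g, s)
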