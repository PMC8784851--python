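import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make tests/oracles.py importable

from tsmr.gwas_io import SummaryStats, VariantAssociation
from tsmr.instruments import HarmonizedInstrument, InstrumentSet


def make_iset(beta_exp, se_exp, beta_out, se_out, eaf=None, n_exp=100_000):
    """Build an InstrumentSet directly from parallel arrays."""
    n = len(beta_exp)
    eaf = eaf if eaf is not None else [0.3] * n
    return InstrumentSet(
        instruments=[
            HarmonizedInstrument(
                variant_id=f"rs{j + 1:04d}",
                beta_exp=float(beta_exp[j]),
                se_exp=float(se_exp[j]),
                beta_out=float(beta_out[j]),
                se_out=float(se_out[j]),
                eaf=None if eaf[j] is None else float(eaf[j]),
                n_exp=n_exp,
            )
            for j in range(n)
        ]
    )


def random_iset(rng, n=20, beta_causal=0.3):
    """A well-conditioned random instrument set for oracle comparisons."""
    bx = rng.uniform(0.05, 0.3, n) * rng.choice([-1, 1], n)
    sx = rng.uniform(0.005, 0.02, n)
    sy = rng.uniform(0.01, 0.05, n)
    by = beta_causal * bx + sy * rng.standard_normal(n)
    return make_iset(bx, sx, by, sy)


def make_stats(label, rows):
    """rows: iterable of (vid, ea, oa, eaf, beta, se, pval, n)."""
    stats = SummaryStats(trait_label=label)
    for vid, ea, oa, eaf, beta, se, pval, n in rows:
        stats.add(VariantAssociation(vid, ea, oa, eaf, beta, se, pval, n))
    return stats


@pytest.fixture
def rng():
    return np.random.default_rng(20260904)
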