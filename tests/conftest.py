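import numpy as np
import pytest

from cismr.summary_data import (HarmonizedDataset, LDReference, SummaryStats,
                                VariantRecord)


def make_variants(n, eaf=0.3, prefix="snp"):
    eaf = np.broadcast_to(np.asarray(eaf, dtype=float), (n,))
    return [VariantRecord(f"{prefix}{i}", "1", i + 1, "A", "G", float(eaf[i]))
            for i in range(n)]


def make_dataset(beta_x, beta_y, se_x=None, se_y=None, corr=None, p_x=None,
                 eaf=0.3, n_x=10_000, n_y=50_000):
    """Assemble a HarmonizedDataset from raw arrays (tests' workhorse)."""
    beta_x = np.asarray(beta_x, dtype=float)
    beta_y = np.asarray(beta_y, dtype=float)
    p = len(beta_x)
    se_x = np.full(p, 0.01) if se_x is None else np.asarray(se_x, dtype=float)
    se_y = np.full(p, 0.01) if se_y is None else np.asarray(se_y, dtype=float)
    corr = np.eye(p) if corr is None else np.asarray(corr, dtype=float)
    if p_x is None:
        from scipy import stats
        p_x = np.clip(2 * stats.norm.sf(np.abs(beta_x / se_x)), 1e-300, 1.0)
    variants = make_variants(p, eaf=eaf)
    stats_obj = SummaryStats(variants, beta_x=beta_x, se_x=se_x,
                             p_x=np.asarray(p_x, dtype=float),
                             beta_y=beta_y, se_y=se_y, n_x=n_x, n_y=n_y)
    ld = LDReference(variants, corr, n_ref=1000)
    omega = corr * np.outer(se_y, se_y)
    return HarmonizedDataset(stats=stats_obj, ld=ld, omega=omega)


@pytest.fixture
def toy_dataset():
    """Three moderately correlated variants with a true ratio near 0.5."""
    corr = np.array([[1.0, 0.4, 0.1],
                     [0.4, 1.0, 0.3],
                     [0.1, 0.3, 1.0]])
    return make_dataset(beta_x=[0.2, 0.15, 0.1],
                        beta_y=[0.10, 0.075, 0.05],
                        se_y=[0.01, 0.012, 0.015],
                        corr=corr)
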