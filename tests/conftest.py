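import numpy as np
import pandas as pd
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")

from cismr.simulate import make_ld_panel, make_study_layout
from cismr.sumstats import SumStats


@pytest.fixture(scope="session")
def panel50():
    """50-variant AR(1) panel with adjacent correlation 0.9."""
    return make_ld_panel(50, 0.9, seed=11)


@pytest.fixture(scope="session")
def study_layout():
    """Fixed LD panel / region map of the default synthetic study."""
    return make_study_layout()


def make_sumstats(variant_ids, betas, ses, *, trait="t", trait_type="quantitative",
                  chrom="1", pos=None, ea=None, nea=None, eaf=None, n=10_000):
    """Hand-build a small SumStats table for unit tests."""
    from scipy import stats

    k = len(variant_ids)
    betas = np.asarray(betas, float)
    ses = np.asarray(ses, float)
    p = np.maximum(2 * stats.norm.sf(np.abs(betas / ses)), 1e-300)
    table = pd.DataFrame({
        "variant_id": variant_ids,
        "chrom": chrom,
        "pos": pos if pos is not None else np.arange(100, 100 + k * 10, 10),
        "ea": ea if ea is not None else ["A"] * k,
        "nea": nea if nea is not None else ["G"] * k,
        "eaf": eaf if eaf is not None else [0.3] * k,
        "beta": betas,
        "se": ses,
        "pvalue": p,
        "n": float(n),
    })
    return SumStats(trait=trait, trait_type=trait_type, table=table)
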