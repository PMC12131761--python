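import numpy as np
import pandas as pd
import pytest

from metabomr.instruments import InstrumentSet
from metabomr.sumstats import COLUMNS, SummaryStats


def make_sumstats(variant_ids, betas, ses, pos=None, eaf=0.3, n=10_000,
                  effect_allele="A", other_allele="G", chrom="1",
                  trait_name="trait", trait_type="quantitative"):
    """Hand-rolled SummaryStats builder for small fixtures."""
    m = len(variant_ids)
    from scipy import stats
    betas = np.asarray(betas, float)
    ses = np.asarray(ses, float)
    df = pd.DataFrame({
        "variant_id": variant_ids,
        "chrom": chrom,
        "pos": pos if pos is not None else np.arange(1, m + 1) * 1000,
        "effect_allele": effect_allele if isinstance(effect_allele, list)
        else [effect_allele] * m,
        "other_allele": other_allele if isinstance(other_allele, list)
        else [other_allele] * m,
        "eaf": eaf if isinstance(eaf, (list, np.ndarray)) else [eaf] * m,
        "beta": betas, "se": ses,
        "p": np.clip(2 * stats.norm.sf(np.abs(betas / ses)),
                     np.nextafter(0, 1), 1.0),
        "n": n,
    })
    return SummaryStats(df[COLUMNS], trait_name=trait_name,
                        trait_type=trait_type, n=n)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def clean_instruments(rng):
    """20 strong instruments with a true causal effect of 0.1."""
    k, theta = 20, 0.1
    bx = rng.uniform(0.03, 0.08, k) * rng.choice([-1, 1], k)
    sx = np.full(k, 0.004)
    sy = np.full(k, 0.003)
    by = rng.normal(theta * bx, sy)
    bxh = rng.normal(bx, sx)
    return InstrumentSet.from_arrays(bxh, sx, by, sy), theta


@pytest.fixture
def outlier_instruments(clean_instruments, rng):
    """Clean set plus one grossly pleiotropic instrument."""
    ins, theta = clean_instruments
    t = ins.table.copy()
    extra = pd.DataFrame({"variant_id": ["v_outlier"], "beta_exp": [0.05],
                          "se_exp": [0.004], "beta_out": [0.05],
                          "se_out": [0.003], "f": [156.25]})
    t = pd.concat([t, extra], ignore_index=True)
    return InstrumentSet("exposure", "outcome", t), theta


from hypothesis import settings as _hyp_settings

_hyp_settings.register_profile("repro", derandomize=True)
_hyp_settings.load_profile("repro")
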