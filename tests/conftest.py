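import numpy as np
import pytest

from mrscreen.instruments import compute_f, compute_r2
from mrscreen.sumstats import HarmonizedIV, VariantAssociation


def make_iv(vid, beta_exp, se_exp, beta_out, se_out, eaf=0.3, n_exp=10000, n_out=50000,
            chrom="1", pos=None, pvalue_exp=1e-10):
    r2e = compute_r2(beta_exp, eaf, se_exp, n_exp)
    r2o = compute_r2(beta_out, eaf, se_out, n_out)
    return HarmonizedIV(
        variant_id=vid, beta_exp=beta_exp, se_exp=se_exp,
        beta_out=beta_out, se_out=se_out, eaf=eaf,
        r2_exp=r2e, r2_out=r2o, f_stat=compute_f(r2e, n_exp),
        pvalue_exp=pvalue_exp, n_exp=n_exp, n_out=n_out, chrom=chrom, pos=pos,
    )


def make_ivs(beta_exp, beta_out, se_exp=0.005, se_out=0.02, **kw):
    beta_exp = np.atleast_1d(np.asarray(beta_exp, dtype=float))
    beta_out = np.atleast_1d(np.asarray(beta_out, dtype=float))
    se_exp = np.broadcast_to(np.asarray(se_exp, dtype=float), beta_exp.shape)
    se_out = np.broadcast_to(np.asarray(se_out, dtype=float), beta_exp.shape)
    return [make_iv(f"v{i}", beta_exp[i], se_exp[i], beta_out[i], se_out[i], **kw)
            for i in range(len(beta_exp))]


def make_variant(vid, beta, se, pvalue, n=10000, ea="A", oa="G", eaf=0.3, chrom="1", pos=None):
    return VariantAssociation(variant_id=vid, effect_allele=ea, other_allele=oa,
                              beta=beta, se=se, pvalue=pvalue, n=n, eaf=eaf,
                              chrom=chrom, pos=pos)


@pytest.fixture
def iv_factory():
    return make_ivs


@pytest.fixture
def variant_factory():
    return make_variant
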