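import numpy as np
import pytest

from causalmr.sumstats_io import (
    ExposureInstrument,
    HarmonizedInstrument,
    OutcomeAssociation,
)


def make_harmonized(snp_id, beta_gp, se_gp, beta_gd, se_gd, pathway=None):
    return HarmonizedInstrument(snp_id=snp_id, beta_gp=beta_gp, se_gp=se_gp,
                                beta_gd=beta_gd, se_gd=se_gd, pathway=pathway)


def make_exposure(snp_id, beta=0.1, se=0.01, pval=1e-9, ea="A", oa="G", **kw):
    return ExposureInstrument(snp_id=snp_id, effect_allele=ea, other_allele=oa,
                              beta_gp=beta, se_gp=se, pvalue=pval, **kw)


def make_outcome(snp_id, beta=0.05, se=0.02, ea="A", oa="G", stratum="overall"):
    return OutcomeAssociation(snp_id=snp_id, effect_allele=ea, other_allele=oa,
                              beta_gd=beta, se_gd=se, stratum=stratum)


@pytest.fixture
def toy_instruments():
    """Five harmonized instruments with varied effects and precisions."""
    rng = np.random.default_rng(42)
    hs = []
    for k in range(5):
        bx = rng.uniform(0.05, 0.2)
        hs.append(make_harmonized(f"rs{k}", bx, 0.005, 0.4 * bx + rng.normal(0, 0.01),
                                  rng.uniform(0.01, 0.04)))
    return hs


@pytest.fixture
def exact_fit_instruments():
    """Points lying exactly on beta_gd = 0.4 * beta_gp (no intercept)."""
    return [make_harmonized(f"rs{k}", bx, 0.004, 0.4 * bx, 0.02)
            for k, bx in enumerate((0.05, 0.08, 0.12, 0.2))]
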