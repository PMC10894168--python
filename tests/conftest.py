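import numpy as np
import pytest

from cismr.gwas_io import HarmonizedPair, VariantAssociation


def make_variant(snp_id="rs1", chrom="1", pos=100, ea="A", oa="G",
                 eaf=0.3, beta=0.1, se=0.01, pval=1e-10, n=None):
    return VariantAssociation(
        snp_id=snp_id, chrom=chrom, pos=pos, effect_allele=ea, other_allele=oa,
        eaf=eaf, beta=beta, se=se, pval=pval, n=n)


def make_pairs(g, G, sy, sx=None, eaf=None):
    """HarmonizedPair list from parallel arrays of betas and outcome SEs."""
    g, G, sy = np.asarray(g, float), np.asarray(G, float), np.asarray(sy, float)
    sx = np.full_like(g, 1e-4) if sx is None else np.asarray(sx, float)
    eaf = np.full_like(g, 0.3) if eaf is None else np.asarray(eaf, float)
    return [
        HarmonizedPair(
            snp_id=f"rs{i}",
            exposure_beta=float(g[i]), exposure_se=float(sx[i]),
            exposure_eaf=float(eaf[i]),
            outcome_beta=float(G[i]), outcome_se=float(sy[i]),
            outcome_eaf=float(eaf[i]),
            harmonization_action="kept",
        )
        for i in range(len(g))
    ]


@pytest.fixture
def pairs_factory():
    return make_pairs


@pytest.fixture
def variant_factory():
    return make_variant


def matching_outcome(exposure, beta=0.01, se=0.05, pval=0.5):
    """Outcome records covering every exposure rsID with identical alleles."""
    return [
        VariantAssociation(
            snp_id=v.snp_id, chrom=v.chrom, pos=v.pos,
            effect_allele=v.effect_allele, other_allele=v.other_allele,
            eaf=v.eaf, beta=beta, se=se, pval=pval)
        for v in exposure
    ]


@pytest.fixture
def matching_outcome_factory():
    return matching_outcome
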