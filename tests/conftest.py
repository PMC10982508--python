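import numpy as np
import pytest
from hypothesis import settings

from mrbiome.gwas_io import SummaryDataset, VariantAssociation
from mrbiome.instruments import HarmonizedPair

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")


def variant(snp_id="rs1", chrom="1", pos=1000, ea="A", oa="G", beta=0.1,
            se=0.02, pvalue=1e-6, n=18340, eaf=0.3):
    return VariantAssociation(snp_id, chrom, pos, ea, oa, beta, se, pvalue, n, eaf)


def make_pairs(rng, n=30, theta=0.0, gamma_sd=0.06, se_x=0.012, se_y=0.004,
               alpha=None):
    """Null-model harmonized pairs straight from the summary-level model."""
    gamma = rng.normal(0.0, gamma_sd, n)
    bx = gamma + rng.normal(0.0, se_x, n)
    a = np.zeros(n) if alpha is None else np.asarray(alpha)
    by = theta * gamma + a + rng.normal(0.0, se_y, n)
    return [
        HarmonizedPair(f"rs{i:03d}", float(bx[i]), se_x, float(by[i]), se_y, "A", "G")
        for i in range(n)
    ]


def pairs_from(rows):
    """Build HarmonizedPairs from (beta_x, beta_y, se_y) triples."""
    return [
        HarmonizedPair(f"rs{i}", float(bx), 0.01, float(by), float(sy), "A", "G")
        for i, (bx, by, sy) in enumerate(rows)
    ]


@pytest.fixture
def rng():
    return np.random.default_rng(20240318)


def exposure_dataset(records, label="taxon", rank="genus"):
    return SummaryDataset.from_records(records, label, "exposure-taxon", rank)


def outcome_dataset(records, label="disease"):
    return SummaryDataset.from_records(records, label, "outcome-disease")
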