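import numpy as np
import pytest
from hypothesis import settings

from mrkit.harmonization import HarmonizedDataset, HarmonizedPair
from mrkit.summary_io import SummaryDataset, VariantAssociation

settings.register_profile("suite", derandomize=True, max_examples=100)
settings.load_profile("suite")

_ALLELES = [("A", "G"), ("T", "C"), ("C", "A"), ("G", "T")]


def make_variant(i, beta, se, pvalue, chrom="1", pos=None, eaf=0.3,
                 alleles=None, vid=None):
    a1, a2 = alleles if alleles else _ALLELES[i % len(_ALLELES)]
    return VariantAssociation(
        variant_id=vid or f"rs{i}",
        chrom=chrom,
        pos=pos if pos is not None else 1_000_000 * (i + 1),
        effect_allele=a1,
        other_allele=a2,
        beta=beta,
        se=se,
        pvalue=pvalue,
        eaf=eaf,
        n_total=10_000,
    )


def make_dataset(betas, ses, pvalues, label="trait", **kwargs):
    records = [make_variant(i, b, s, p, **kwargs)
               for i, (b, s, p) in enumerate(zip(betas, ses, pvalues))]
    return SummaryDataset(label, records, "binary")


def make_harmonized(bx, sx, by, sy) -> HarmonizedDataset:
    pairs = [
        HarmonizedPair(variant_id=f"rs{i}", beta_exposure=float(x),
                       se_exposure=float(sxi), beta_outcome=float(y),
                       se_outcome=float(syi), effect_allele="A")
        for i, (x, sxi, y, syi) in enumerate(zip(bx, sx, by, sy))
    ]
    return HarmonizedDataset(pairs=pairs, n_input=len(pairs))


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def random_harmonized(rng):
    """20 strong instruments generated around a true slope of 0.5."""
    k = 20
    bx = rng.normal(0.05, 0.01, k)
    sx = np.full(k, 0.002)
    sy = np.full(k, 0.004)
    by = rng.normal(0.5 * bx, sy)
    return make_harmonized(bx, sx, by, sy)
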