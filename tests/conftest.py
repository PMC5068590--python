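import numpy as np
import pandas as pd
import pytest

from grsvol.io import GenotypeMatrix, SummaryStats


def build_gm(
    dosages,
    positions=None,
    chroms=None,
    ids=None,
    allele_a="A",
    allele_b="G",
    sample_ids=None,
):
    """GenotypeMatrix from an (n_samples x m) array with simple metadata."""
    d = np.asarray(dosages, dtype=float)
    n, m = d.shape
    ids = ids if ids is not None else [f"rs{j}" for j in range(m)]
    variants = pd.DataFrame(
        {
            "variant_id": ids,
            "chrom": chroms if chroms is not None else ["1"] * m,
            "pos": positions if positions is not None else [1 + 1000 * j for j in range(m)],
            "allele_a": [allele_a] * m if isinstance(allele_a, str) else list(allele_a),
            "allele_b": [allele_b] * m if isinstance(allele_b, str) else list(allele_b),
        }
    )
    samples = sample_ids if sample_ids is not None else [f"S{i}" for i in range(n)]
    return GenotypeMatrix(samples, variants, d)


def build_ss(
    ids,
    weights,
    pvalues,
    positions=None,
    chroms=None,
    effect_allele="G",
    other_allele="A",
):
    """SummaryStats aligned by default with build_gm's (A, G) orientation."""
    m = len(ids)
    table = pd.DataFrame(
        {
            "variant_id": ids,
            "chrom": chroms if chroms is not None else ["1"] * m,
            "pos": positions if positions is not None else [1 + 1000 * j for j in range(m)],
            "effect_allele": [effect_allele] * m if isinstance(effect_allele, str) else list(effect_allele),
            "other_allele": [other_allele] * m if isinstance(other_allele, str) else list(other_allele),
            "weight": np.asarray(weights, dtype=float),
            "pvalue": np.asarray(pvalues, dtype=float),
        }
    )
    return SummaryStats(table)


@pytest.fixture
def gm_factory():
    return build_gm


@pytest.fixture
def ss_factory():
    return build_ss


@pytest.fixture
def rng():
    return np.random.default_rng(20151208)
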