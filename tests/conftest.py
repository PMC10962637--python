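import numpy as np
import pandas as pd
import pytest

from paleotwas import GeneModel, GenotypeDataset, SampleTable, simulate_study


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_dataset(dosages, r2=None, chrom=None, pos=None, ref="A", alt="G"):
    """Small GenotypeDataset from a raw (samples x snps) array."""
    dosages = np.asarray(dosages, float)
    n_samples, n_snps = dosages.shape
    r2 = np.ones(n_snps) if r2 is None else np.asarray(r2, float)
    snps = pd.DataFrame(
        {
            "snp_id": [f"snp_{j}" for j in range(n_snps)],
            "chrom": chrom if chrom is not None else ["1"] * n_snps,
            "pos": pos if pos is not None else [(j + 1) * 1000 for j in range(n_snps)],
            "ref": ref if isinstance(ref, list) else [ref] * n_snps,
            "alt": alt if isinstance(alt, list) else [alt] * n_snps,
            "r2": r2,
        }
    )
    return GenotypeDataset(
        sample_ids=[f"ind_{i}" for i in range(n_samples)], snps=snps, dosages=dosages
    )


def make_samples(dates):
    return SampleTable(
        pd.DataFrame(
            {
                "sample_id": [f"ind_{i}" for i in range(len(dates))],
                "date_bp": dates,
                "cohort": ["modern" if d == 0 else "ancient" for d in dates],
            }
        )
    )


def make_model(gene_id, snp_ids, weights, effect="G", other="A", tissue="T1", r2=0.3):
    n = len(snp_ids)
    return GeneModel(
        gene_id=gene_id,
        tissue=tissue,
        training_r2=r2,
        variants=pd.DataFrame(
            {
                "snp_id": snp_ids,
                "effect_allele": [effect] * n if isinstance(effect, str) else effect,
                "other_allele": [other] * n if isinstance(other, str) else other,
                "weight": weights,
            }
        ),
    )


@pytest.fixture(scope="session")
def small_study():
    """A modest simulated study reused by read-only tests."""
    return simulate_study(
        n_snps=400, n_genes=40, selected_genes={"gene_0": 1}, seed=777
    )
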