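"""Shared fixtures: small hand-built datasets and the synthetic 5-SNP panel."""

import numpy as np
import pytest

from epichi import (
    EffectLabel,
    EffectSpec,
    GenotypeDataset,
    build_population,
    hwe_genotype_freqs,
    sample_individuals,
)

#: Study conditions for the packaged synthetic 5-SNP panel: three loci carry
#: a planted additive^3 interaction (penetrance scale, baseline 0.3,
#: magnitude 0.25), two further SNPs are pure noise; all five are
#: independent, MAF 0.5, in HWE; 400 cases vs 400 controls.
FIVE_SNP_SEED = 7
FIVE_SNP_MAGNITUDE = 0.25
FIVE_SNP_BASELINE = 0.3
FIVE_SNP_N_PER_ARM = 400


def make_five_snp_dataset(seed: int = FIVE_SNP_SEED) -> GenotypeDataset:
    """Synthetic 5-SNP case-control panel with an aaa effect on snp1-3."""
    model = build_population(
        EffectSpec(n=3, baseline=FIVE_SNP_BASELINE,
                   effects={EffectLabel.from_pattern("aaa"): FIVE_SNP_MAGNITUDE}),
        freqs=hwe_genotype_freqs(3, 0.5))
    ds = sample_individuals(model, FIVE_SNP_N_PER_ARM, FIVE_SNP_N_PER_ARM,
                            seed=seed, snp_ids=["snp1", "snp2", "snp3"])
    rng = np.random.default_rng(seed + 1)
    noise = rng.binomial(2, 0.5, size=(ds.n_samples, 2)).astype(np.int8)
    return GenotypeDataset(
        sample_ids=ds.sample_ids,
        snp_ids=ds.snp_ids + ["snp4", "snp5"],
        phenotype=ds.phenotype,
        genotypes=np.hstack([ds.genotypes, noise]),
    )


@pytest.fixture(scope="session")
def five_snp_dataset() -> GenotypeDataset:
    return make_five_snp_dataset()


@pytest.fixture
def toy_dataset() -> GenotypeDataset:
    """Six samples, two SNPs, hand-checkable counts, one missing genotype."""
    return GenotypeDataset(
        sample_ids=[f"s{i}" for i in range(1, 7)],
        snp_ids=["rsA", "rsB"],
        phenotype=np.array([1, 1, 1, 0, 0, 0], dtype=np.int8),
        genotypes=np.array([[2, 2],
                            [2, 1],
                            [1, 0],
                            [0, 0],
                            [1, 1],
                            [-1, 2]], dtype=np.int8),
    )
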