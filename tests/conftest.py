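import numpy as np
import pytest

import serumpqtl as sp


@pytest.fixture(scope="session")
def small_cohort() -> sp.SampleTable:
    """Mixed three-cohort design: 6 CD (two visits), 8 UC, 4 NC."""
    return sp.simulate_cohort(6, 8, 4, n_plates=3, seed=11)


@pytest.fixture(scope="session")
def cd_cohort() -> sp.SampleTable:
    """CD-only design with repeated measures, 20 subjects."""
    return sp.simulate_cohort(20, 0, 0, n_plates=2, seed=12)


@pytest.fixture(scope="session")
def uc_cohort() -> sp.SampleTable:
    """UC-only design, 88 single-visit subjects (the study's UC size)."""
    return sp.simulate_cohort(0, 88, 0, n_plates=2, seed=13)


def make_cis_dataset(seed: int, n_subjects: int = 51, maf: float = 0.3,
                     beta_g: float = 0.8, n_decoy_variants: int = 0,
                     sigma_subject: float = 1.0, sigma_e: float = 1.0):
    """One cis probe with a causal variant, optionally flanked by decoys."""
    samples = sp.simulate_cohort(n_subjects, 0, 0, seed=seed)
    specs = [("rs_causal", "1", 1_000_000, maf)] + [
        (f"rs_decoy{i:02d}", "1", 1_010_000 + 10_000 * i, maf)
        for i in range(n_decoy_variants)
    ]
    genotypes = sp.simulate_genotypes(list(samples.subject_ids), specs, seed=seed)
    effects = [
        sp.EffectSpec("SLCIS1", cis_variant="rs_causal", beta_g=beta_g,
                      sigma_subject=sigma_subject, sigma_e=sigma_e,
                      chrom="1", pos=1_000_000)
    ]
    proteins = sp.simulate_proteome(samples, genotypes, effects, seed=seed)
    return samples, genotypes, proteins


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
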