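import numpy as np
import pandas as pd
import pytest

import prsmod as pm


def make_genotypes(dosages, counted, other, snp_ids=None, sample_ids=None):
    """Hand-build a GenotypeMatrix from plain lists."""
    d = np.asarray(dosages, dtype=float)
    n, m = d.shape
    return pm.GenotypeMatrix(
        sample_ids=np.array(
            sample_ids or [f"s{i}" for i in range(n)], dtype=object
        ),
        snp_ids=np.array(snp_ids or [f"snp{j}" for j in range(m)], dtype=object),
        counted_allele=np.array(counted, dtype=object),
        other_allele=np.array(other, dtype=object),
        dosages=d,
    )


def make_stats(snp_ids, ea, oa, beta, p, eaf=None):
    df = pd.DataFrame(
        {
            "snp_id": snp_ids,
            "effect_allele": ea,
            "other_allele": oa,
            "effect_size": beta,
            "p_value": p,
        }
    )
    if eaf is not None:
        df["eaf"] = eaf
    return df


@pytest.fixture(scope="session")
def small_cohort():
    """A compact default-condition cohort shared across read-only tests."""
    return pm.simulate_cohort(pm.SimulationConfig(n_samples=400, n_snps=300, seed=7))


@pytest.fixture(scope="session")
def default_cohort():
    """Study-scale cohort: n=940 under the generator defaults."""
    return pm.simulate_cohort(pm.SimulationConfig(seed=11))
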