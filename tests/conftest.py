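import numpy as np
import pandas as pd
import pytest

from gutomics import simulate as sim


@pytest.fixture(scope="session")
def small_config():
    """A reduced cohort: fast to generate, same layered structure."""
    return sim.default_config(seed=11, n_per_group=5, n_taxa=48, n_metabolites=24)


@pytest.fixture(scope="session")
def cohort(small_config):
    return sim.simulate_cohort(small_config)


@pytest.fixture(scope="session")
def meta(cohort):
    return cohort.samples.set_index("sample_id")


def toy_metadata(n_per_group=5, sexes=("female", "male"), site="jejunum"):
    """Flat single-site metadata: sex x diet cells of equal size."""
    rows = []
    for sex in sexes:
        for diet in ("LFD", "MFD"):
            for i in range(n_per_group):
                pid = f"{sex[0]}{diet}{i}"
                rows.append({"sample_id": f"{pid}_{site}", "pig_id": pid,
                             "sex": sex, "diet": diet, "site": site})
    return pd.DataFrame(rows).set_index("sample_id")
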