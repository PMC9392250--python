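import numpy as np
import pandas as pd
import pytest

import wssgwas as w
from wssgwas.pedigree import Pedigree


@pytest.fixture
def trio_pedigree():
    """Unrelated sire and dam with one offspring."""
    return Pedigree(
        pd.DataFrame({"animal": [1, 2, 3], "sire": [0, 0, 1], "dam": [0, 0, 2]})
    )


@pytest.fixture
def fullsib_mating_pedigree():
    """Two founders, two full sibs, and an offspring of the full sibs (F=0.25)."""
    return Pedigree(
        pd.DataFrame(
            {
                "animal": [1, 2, 3, 4, 5],
                "sire": [0, 0, 1, 1, 3],
                "dam": [0, 0, 2, 2, 4],
            }
        )
    )


@pytest.fixture(scope="session")
def small_dataset():
    """Shared small herd: 160 animals, 2 chromosomes x 40 SNPs, one 10% QTL."""
    cfg = w.SimulationConfig(
        n_founders=40, n_generations=2, n_per_generation=60,
        n_chromosomes=2, snps_per_chromosome=40,
        n_qtl=1, qtl_variance_fractions=[0.10], rng_seed=7,
    )
    return w.simulate_dataset(cfg)


@pytest.fixture(scope="session")
def small_fit(small_dataset):
    """Fitted single-step model on the shared herd (QC-passed genotypes)."""
    d = small_dataset
    geno, _ = w.run_qc(d.observed_genotypes)
    model = w.SingleStepRepeatabilityModel.from_dataframe(
        d.phenotypes.records, "y", d.pedigree, genotypes=geno
    )
    return model.fit(tol=1e-8)


def random_pedigree(rng: np.random.Generator, n_founders=20, n_extra=60) -> Pedigree:
    """Random valid pedigree used by property tests (parents precede offspring)."""
    animal = list(range(1, n_founders + 1))
    sire = [0] * n_founders
    dam = [0] * n_founders
    for i in range(n_founders, n_founders + n_extra):
        a = i + 1
        s, d = rng.choice(i, size=2, replace=False) + 1
        animal.append(a)
        # occasionally unknown parents
        sire.append(int(s) if rng.random() > 0.1 else 0)
        dam.append(int(d) if rng.random() > 0.1 else 0)
    return Pedigree(pd.DataFrame({"animal": animal, "sire": sire, "dam": dam}))
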