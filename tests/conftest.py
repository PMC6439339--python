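import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from pharmapop.model import GenotypeMatrix, VariantRecord
from pharmapop.simulate import COMPONENTS, SimulationConfig, simulate_study

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

#: Dirichlet alphas (African, European, NativeAmerican) x concentration 50
#: for the two Colombian-like study cohorts.
ANTIOQUIA_ALPHA = (0.07 * 50, 0.61 * 50, 0.32 * 50)
CHOCO_ALPHA = (0.76 * 50, 0.11 * 50, 0.13 * 50)


def make_gm(dosage, ids=None, counted=None, alleles=None, samples=None):
    """Build a GenotypeMatrix from a plain dosage array for unit tests."""
    dosage = np.asarray(dosage, dtype=np.int8)
    n, m = dosage.shape
    if ids is None:
        ids = [f"rs{j + 1}" for j in range(m)]
    if alleles is None:
        alleles = [("A", "G")] * m
    if samples is None:
        samples = [f"S{i + 1}" for i in range(n)]
    variants = [
        VariantRecord(id=ids[j], chrom="1", pos=100 * (j + 1),
                      ref=alleles[j][0], alt=alleles[j][1])
        for j in range(m)
    ]
    return GenotypeMatrix(samples, variants, dosage, counted)


@pytest.fixture(scope="session")
def small_study():
    """A compact two-cohort admixed study shared across test modules."""
    cfg = SimulationConfig(
        M=800,
        seed=11,
        diff=0.15,
        pharma_fraction=0.05,
        discordance_rate=0.05,
        cohorts=(
            {"name": "Antioquia", "n": 60, "alpha": ANTIOQUIA_ALPHA},
            {"name": "Choco", "n": 60, "alpha": CHOCO_ALPHA},
        ),
    )
    return simulate_study(cfg)


@pytest.fixture(scope="session")
def small_panel(small_study) -> pd.DataFrame:
    gm = small_study["genotypes"]
    return pd.DataFrame(
        small_study["panel"].T,
        index=pd.Index(gm.variant_ids, name="id"),
        columns=list(COMPONENTS),
    )
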