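import numpy as np
import pytest

from pleiometa import synthetic
from pleiometa.types import CohortSpec, EffectConfig, PhenotypeSpec


@pytest.fixture(scope="session")
def quant_pair():
    """Two correlated quantitative phenotypes (rho=0.6), no visit noise."""
    return (
        [PhenotypeSpec("P1", "quantitative", "marker"),
         PhenotypeSpec("P2", "quantitative", "marker")],
        synthetic.make_phenotype_correlation(2, 0.6, method="constant"),
    )


@pytest.fixture(scope="session")
def small_study(quant_pair):
    """Two cohorts x 800 subjects, one antagonistic and one null SNP."""
    phenos, corr = quant_pair
    cohorts = [CohortSpec(f"C{j+1}", 800, ("P1", "P2")) for j in range(2)]
    effects = [
        EffectConfig("snp_a", maf=0.3, betas={"P1": 0.4, "P2": -0.4},
                     pattern="antagonistic"),
        EffectConfig("snp_0", maf=0.3, pattern="null"),
    ]
    return synthetic.simulate_study(
        cohorts, phenos, corr, effects, seed=7, icc=1.0, missing_rate=0.0)


@pytest.fixture(scope="session")
def mixed_study():
    """Three cohorts with a marker (3 visits), a binary disease and a
    time-to-event outcome; cohort C3 lacks the survival outcome."""
    phenos = [
        PhenotypeSpec("M1", "quantitative", "marker", n_visits=3),
        PhenotypeSpec("M2", "quantitative", "marker", log_transform=True, n_visits=3),
        PhenotypeSpec("D1", "binary", "outcome"),
        PhenotypeSpec("S1", "time-to-event", "outcome"),
    ]
    corr = synthetic.make_phenotype_correlation(4, 0.4, seed=3)
    cohorts = [
        CohortSpec("C1", 400, ("M1", "M2", "D1", "S1")),
        CohortSpec("C2", 300, ("M1", "M2", "D1", "S1")),
        CohortSpec("C3", 250, ("M1", "M2", "D1")),
    ]
    effects = [
        EffectConfig("rs1", maf=0.25, betas={"M1": 0.3, "D1": 0.3}),
        EffectConfig("rs2", maf=0.3, pattern="null"),
    ]
    return synthetic.simulate_study(
        cohorts, phenos, corr, effects, seed=11, icc=0.6, missing_rate=0.05)
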