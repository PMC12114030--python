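import numpy as np
import pytest

from komet import CohortConfig, EhrSpec, VariantSpec, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A 600-sample cohort with one injected metabolite effect (beta=5 on
    M0003 for the 6 rs1 knockouts), covariate effects, 5% below-LOD
    censoring, covariate missingness, and one injected EHR association."""
    cfg = CohortConfig(
        n_samples=600,
        n_controls=258,
        n_metabolites=40,
        variants=[
            VariantSpec(
                "rs1", "GENE1", n_homozygous=6, n_heterozygous=10, maf=0.01,
                affected_metabolites=[("M0003", 5.0)],
            ),
            VariantSpec("rs2", "GENE2", n_homozygous=3, n_heterozygous=5, maf=0.005),
        ],
        covariate_effects={
            "M0001": [("age", 0.5), ("bmi", 0.3)],
            "M0002": [("smoking", 0.8)],
        },
        lod_quantile=0.05,
        covariate_missing_rates={"bmi": 0.1, "smoking": 0.05},
        ehr_specs=[EhrSpec("rs1", "E79", common_odds_ratio=5.0, baseline_rate=0.1)],
        seed=42,
    )
    return generate_cohort(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
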