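import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import cardiomod as cm

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def default_cohort() -> cm.Cohort:
    return cm.generate_cohort(cm.CohortConfig(seed=7))


@pytest.fixture(scope="session")
def small_sim():
    """A small genotype simulation shared by filtering/association tests."""
    truth = cm.TruthSet(
        modifiers=[cm.ModifierSpec("MODG1", "LVWT", 1.5, 0.30)],
        null_genes=[f"NULLG{i + 1}" for i in range(6)],
    )
    cohort = cm.generate_cohort(cm.CohortConfig(seed=11))
    gene_models = cm.make_gene_models(
        truth.modifier_genes + list(truth.null_genes))
    sim = cm.generate_genotypes(cohort, truth, cm.SimParams(), gene_models,
                                seed=11)
    return sim, truth, gene_models


@pytest.fixture()
def intercept_null_model():
    """Continuous intercept-only null model on a seeded Gaussian trait."""
    rng = np.random.default_rng(404)
    n = 24
    data = pd.DataFrame(
        {"lvwt": rng.normal(19, 5, n)},
        index=[f"S{i:03d}" for i in range(n)],
    )
    trait = cm.TraitSpec("LVWT", "continuous", ())
    return cm.fit_null_model(trait, data), data


def make_variant(chrom="chr1", pos=100, ref="A", alt="T", **kw) -> cm.VariantRecord:
    return cm.VariantRecord(chrom, pos, ref, alt, **kw)


@pytest.fixture()
def variant_factory():
    return make_variant
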