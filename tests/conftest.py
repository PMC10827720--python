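import numpy as np
import pytest

from mrbalance import cohort as cohmod
from mrbalance import expression_io as eio
from mrbalance import regulon as regmod


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def tiny_matrix():
    return eio.ExpressionMatrix(
        feature_ids=["f1", "f2", "f3"],
        sample_ids=["s1", "s2"],
        values=np.array([[1.0, 2.0], [3.0, 4.0], [5.0, 6.0]]),
        feature_level="isoform",
    )


@pytest.fixture(scope="session")
def default_cohort():
    """One default synthetic cohort shared across tests (read-only)."""
    return cohmod.generate_cohort(cohmod.SimParams(seed=11))


@pytest.fixture(scope="session")
def cohort_gene_matrix(default_cohort):
    return eio.aggregate_to_gene(
        default_cohort.expression, default_cohort.isoform_map, rule="sum"
    )


@pytest.fixture(scope="session")
def inferred_regulons(default_cohort, cohort_gene_matrix):
    """Regulons inferred from the shared cohort (alpha relaxed for n=400)."""
    cfg = regmod.RegulonConfig(alpha=1e-8, n_perm=500, seed=11)
    regs = {}
    for tf in (cohmod.TF1, cohmod.TF2):
        regs[tf] = regmod.infer_regulon(
            default_cohort.expression,
            cohort_gene_matrix,
            tf_id=tf,
            isoform_ids=default_cohort.isoform_map.tf_isoforms[tf],
            config=cfg,
            exclude={cohmod.TF1, cohmod.TF2},
        )
    return regs
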