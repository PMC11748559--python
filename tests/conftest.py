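import numpy as np
import pytest

import crlatent as cr


@pytest.fixture(scope="session")
def joint_cohort():
    """Synthetic cohort with planted latent structure and phenotypes."""
    return cr.model_based_cohort(K_true=3, S=120, O=25, P=3, seed=7)


@pytest.fixture(scope="session")
def fitted_joint(joint_cohort):
    """Joint microbiome/phenotype fit plus latent mixture, shared by tests."""
    model = cr.LatentCompositionModel(
        n_latent=3, alpha=0.975, max_iter=80_000, random_state=0
    ).fit(joint_cohort.table, phenotypes=joint_cohort.phenotypes)
    mixture = cr.LatentGaussianMixture(n_restarts=5, random_state=0).fit(model.embedding_)
    return model, mixture


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
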